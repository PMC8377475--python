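"""Radial gray-value profiles from tangential image stacks.

A volume of interest (VOI) is an ordered stack of 2-D gray images, sliced
tangentially and ordered bark→pith. Two-pass thresholding separates the
sample from air (pass 1) and cell-wall pixels from lumens (pass 2); per-slice
mean gray values over each mask give the xylem and cell-wall radial profiles.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import tifffile
from scipy import ndimage
from skimage.filters import threshold_otsu

__all__ = [
    "VOIStack",
    "GrayProfile",
    "UniformSliceWarning",
    "mask_sample",
    "mask_cell_wall",
    "extract_profiles",
    "read_stack",
    "write_stack",
]

GRAY_MAX = 65535


class UniformSliceWarning(UserWarning):
    """Raised when a slice has no gray-value contrast (likely outside the sample)."""


@dataclass
class VOIStack:
    """Ordered tangential gray-image stack with annotations.

    ``slices`` has shape (n_slices, rows, cols); slice index increases from
    the bark toward the pith. ``prev_boundary_index`` and ``cambium_window``
    (inclusive index range) are manual annotations.
    """

    slices: np.ndarray
    voxel_pitch: float
    prev_boundary_index: int
    cambium_window: tuple[int, int]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.slices = np.asarray(self.slices)
        if self.slices.ndim != 3 or self.slices.shape[0] < 2:
            raise ValueError("stack must be a 3-D array with at least 2 slices")
        if self.voxel_pitch <= 0:
            raise ValueError("voxel_pitch must be positive")
        n = self.slices.shape[0]
        if not 0 <= self.prev_boundary_index < n:
            raise ValueError("prev_boundary_index outside the stack")
        lo, hi = self.cambium_window
        if not (0 <= lo <= hi < n):
            raise ValueError("cambium_window outside the stack")
        if hi >= self.prev_boundary_index:
            raise ValueError("cambium_window must lie before prev_boundary_index")

    @property
    def n_slices(self) -> int:
        return self.slices.shape[0]

    def positions(self) -> np.ndarray:
        """Radial position (μm from the bark-most slice) of each slice center."""
        return np.arange(self.n_slices) * self.voxel_pitch


@dataclass
class GrayProfile:
    """Per-slice mean gray value vs radial position (μm from stack start)."""

    positions: np.ndarray
    values: np.ndarray
    kind: str  # "xylem" | "cell_wall"
    voxel_pitch: float
    n_pixels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.positions.size != self.values.size:
            raise ValueError("positions and values must have the same length")
        if self.positions.size >= 2:
            steps = np.diff(self.positions)
            if np.any(steps <= 0) or not np.allclose(steps, self.voxel_pitch, rtol=1e-6):
                raise ValueError("positions must increase by one voxel pitch per slice")
        finite = self.values[np.isfinite(self.values)]
        if finite.size and (finite.min() < 0 or finite.max() > GRAY_MAX):
            raise ValueError(f"gray values must lie in [0, {GRAY_MAX}]")
        if self.kind not in ("xylem", "cell_wall"):
            raise ValueError(f"unknown profile kind {self.kind!r}")

    def finite(self) -> tuple[np.ndarray, np.ndarray]:
        """(positions, values) with missing slices dropped — gaps propagate."""
        keep = np.isfinite(self.values)
        return self.positions[keep], self.values[keep]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"position_um": self.positions, "value": self.values,
                           "kind": self.kind})
        df["n_pixels"] = self.n_pixels if self.n_pixels is not None else np.nan
        return df[["position_um", "value", "n_pixels", "kind"]]

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, voxel_pitch: float | None = None) -> "GrayProfile":
        kinds = df["kind"].unique()
        if len(kinds) != 1:
            raise ValueError("frame must contain a single profile kind")
        pos = df["position_um"].to_numpy(dtype=float)
        if voxel_pitch is None:
            voxel_pitch = float(np.median(np.diff(pos))) if pos.size > 1 else 1.0
        npx = df["n_pixels"].to_numpy(dtype=float) if "n_pixels" in df else None
        return cls(positions=pos, values=df["value"].to_numpy(dtype=float),
                   kind=str(kinds[0]), voxel_pitch=voxel_pitch, n_pixels=npx)


def _otsu_or_none(pixels: np.ndarray) -> float | None:
    pixels = np.asarray(pixels)
    if pixels.size == 0 or pixels.min() == pixels.max():
        return None
    return float(threshold_otsu(pixels.ravel()))


def mask_sample(slice_: np.ndarray, threshold: float | None = None) -> np.ndarray:
    """Pass-1 mask: pixels belonging to the sample (wood + enclosed lumens).

    Background/air is assumed darker than the sample. Holes (lumens) in the
    above-threshold region are filled so they stay inside the sample mask.
    A contrast-free slice yields an empty mask and a UniformSliceWarning.
    """
    slice_ = np.asarray(slice_)
    if slice_.size == 0:
        raise ValueError("empty image")
    if threshold is None:
        threshold = _otsu_or_none(slice_)
        if threshold is None:
            # uniform zero = all air; uniform nonzero = sample fills the frame
            if slice_.flat[0] > 0:
                return np.ones(slice_.shape, dtype=bool)
            warnings.warn("slice has no gray-value contrast; returning empty mask",
                          UniformSliceWarning, stacklevel=2)
            return np.zeros(slice_.shape, dtype=bool)
    mask = slice_ > threshold
    if not mask.any():
        warnings.warn("no pixel above the sample threshold", UniformSliceWarning,
                      stacklevel=2)
        return mask
    return ndimage.binary_fill_holes(mask)


def mask_cell_wall(slice_: np.ndarray, sample_mask: np.ndarray,
                   threshold: float | None = None) -> np.ndarray:
    """Pass-2 mask: cell-wall pixels within the sample (lumens excluded)."""
    slice_ = np.asarray(slice_)
    sample_mask = np.asarray(sample_mask, dtype=bool)
    if not sample_mask.any():
        raise ValueError("sample mask is empty: pass-1 thresholding failed upstream")
    if threshold is None:
        threshold = _otsu_or_none(slice_[sample_mask])
        if threshold is None:
            # no in-sample contrast: nothing to exclude
            return sample_mask.copy()
    return sample_mask & (slice_ > threshold)


def extract_profiles(stack: VOIStack, sample_threshold: float | None = None,
                     wall_threshold: float | None = None,
                     exclusion_mask: np.ndarray | None = None,
                     max_missing_frac: float = 0.5) -> tuple[GrayProfile, GrayProfile]:
    """Per-slice mean gray over the sample and cell-wall masks.

    Both Otsu passes run per slice: the wall gray level varies radially (it
    is the measurand), so a single stack-wide threshold misclassifies dim
    cambium-side walls — wholesale on pass 2, and via empty sample masks on
    pass 1. Hole-filling keeps lumens inside the pass-1 mask either way.
    Pass ``sample_threshold``/``wall_threshold`` to force global values.
    Slices with empty masks are recorded as NaN, never as zero; more than
    ``max_missing_frac`` missing slices raises.

    ``exclusion_mask`` (same shape as the stack or a single slice) removes
    manually flagged regions (wide rays, resin ducts, cracks) from both masks.
    """
    imgs = stack.slices.astype(float)
    n = stack.n_slices
    xylem = np.full(n, np.nan)
    wall = np.full(n, np.nan)
    n_sample = np.zeros(n, dtype=int)
    n_wall = np.zeros(n, dtype=int)
    sample_masks = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UniformSliceWarning)
        for i in range(n):
            m = mask_sample(imgs[i], threshold=sample_threshold)
            if exclusion_mask is not None:
                excl = exclusion_mask[i] if exclusion_mask.ndim == 3 else exclusion_mask
                m = m & ~np.asarray(excl, dtype=bool)
            sample_masks.append(m)
    for i, m in enumerate(sample_masks):
        if not m.any():
            continue
        xylem[i] = imgs[i][m].mean()
        n_sample[i] = int(m.sum())
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UniformSliceWarning)
            wm = mask_cell_wall(imgs[i], m, threshold=wall_threshold)
        if wm.any():
            wall[i] = imgs[i][wm].mean()
            n_wall[i] = int(wm.sum())
    missing = np.mean(~np.isfinite(xylem))
    if missing > max_missing_frac:
        raise ValueError(
            f"{missing:.0%} of slices have empty masks; stack unusable"
        )
    pos = stack.positions()
    return (
        GrayProfile(positions=pos, values=xylem, kind="xylem",
                    voxel_pitch=stack.voxel_pitch, n_pixels=n_sample),
        GrayProfile(positions=pos, values=wall, kind="cell_wall",
                    voxel_pitch=stack.voxel_pitch, n_pixels=n_wall),
    )


def read_stack(path, voxel_pitch: float, prev_boundary_index: int,
               cambium_window: tuple[int, int]) -> VOIStack:
    """Read a multi-page TIFF as a VOIStack (slice order = page order)."""
    imgs = tifffile.imread(path)
    if imgs.ndim == 2:
        imgs = imgs[None]
    return VOIStack(slices=imgs, voxel_pitch=voxel_pitch,
                    prev_boundary_index=prev_boundary_index,
                    cambium_window=tuple(cambium_window))


def write_stack(path, stack: VOIStack) -> None:
    data = np.clip(np.rint(stack.slices), 0, GRAY_MAX).astype(np.uint16)
    tifffile.imwrite(path, data)
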