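"""Synthetic VOI stacks, gray profiles, and seasonal growth series.

Ground-truth generators for every downstream stage: a two-phase cell-wall
density profile (low at the cambium, rising across the maturing zone,
constant plateau in mature xylem), a wall/lumen lattice stack whose per-slice
wall mean reproduces that profile, and logistic seasonal growth with
tree-level circumferential heterogeneity. All generators are deterministic
under a fixed seed and return their truth for recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .profiles import GRAY_MAX, GrayProfile, VOIStack

__all__ = [
    "RingTruth",
    "TreeSigmoid",
    "SeasonTruth",
    "generate_profile",
    "generate_voi_stack",
    "generate_season",
    "logistic",
]

DEFAULT_VOXEL_PITCH = 2.49  # μm/px


@dataclass(frozen=True)
class RingTruth:
    """Ground truth for one synthetic forming ring (radial positions in μm)."""

    cambium_pos: float
    transition_pos: float
    prev_boundary_pos: float
    wall_plateau_gray: float = 30000.0
    lumen_gray: float = 4000.0
    noise_sd: float = 0.0
    voxel_pitch: float = DEFAULT_VOXEL_PITCH
    seed: int = 0
    cambium_gray: float | None = None       # default: 35% of the plateau
    phloem_gray: float | None = None        # bark-side rise (valley fixtures)
    cambium_flat_halfwidth: float = 0.0     # flat bottom centered on cambium_pos
    ramp: str = "knee"                      # "knee" | "smoothstep" | "linear"
    knee_um: float = 40.0                   # plateau-approach length of the knee ramp

    def __post_init__(self) -> None:
        if not self.cambium_pos < self.transition_pos:
            raise ValueError("ordering violated: cambium_pos must be < transition_pos")
        if not self.transition_pos <= self.prev_boundary_pos:
            raise ValueError(
                "ordering violated: transition_pos must be <= prev_boundary_pos")
        if not 0 <= self.lumen_gray < self.wall_plateau_gray <= GRAY_MAX:
            raise ValueError("need 0 <= lumen_gray < wall_plateau_gray <= 65535")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.voxel_pitch <= 0:
            raise ValueError("voxel_pitch must be positive")
        if self.ramp not in ("knee", "linear", "smoothstep"):
            raise ValueError(f"unknown ramp {self.ramp!r}")
        if self.knee_um <= 0:
            raise ValueError("knee_um must be positive")

    @property
    def cambium_level(self) -> float:
        if self.cambium_gray is not None:
            return self.cambium_gray
        return self.lumen_gray + 0.35 * (self.wall_plateau_gray - self.lumen_gray)

    def wall_gray(self, pos) -> np.ndarray:
        """Noise-free cell-wall gray value at radial position(s) pos (μm).

        With ``phloem_gray`` set, the profile also rises bark-ward of the
        cambium (mirroring the xylem-side ramp length and shape) so the
        cambium sits in a symmetric density valley, as on real profiles.
        """
        pos = np.asarray(pos, dtype=float)
        c, t = self.cambium_pos, self.transition_pos
        hw = self.cambium_flat_halfwidth
        lo, hi = self.cambium_level, self.wall_plateau_gray
        ramp_start = c + hw
        ramp_len = max(t - ramp_start, 1e-12)
        g = lo + (hi - lo) * self._ramp01(pos - ramp_start, ramp_len)
        if self.phloem_gray is not None:
            flat_lo = c - hw
            v = self._ramp01(flat_lo - pos, ramp_len)
            g = np.where(pos < flat_lo, lo + (self.phloem_gray - lo) * v, g)
        return g

    def _ramp01(self, dist, length: float) -> np.ndarray:
        """Monotone C1 unit ramp over [0, length], constant 1 beyond."""
        u = np.clip(np.asarray(dist, dtype=float) / length, 0.0, 1.0)
        if self.ramp == "smoothstep":
            return u * u * (3.0 - 2.0 * u)
        if self.ramp == "linear":
            return u
        # "knee": linear rise, then a fixed-width half-cosine approach to the
        # plateau — density flattens over a characteristic completion length
        # rather than a length proportional to the zone width
        k = min(self.knee_um, length) / length
        slope = 1.0 / (1.0 - k * (1.0 - 2.0 / np.pi))
        lin = slope * u
        knee = slope * (1.0 - k) + slope * k * (2.0 / np.pi) * np.sin(
            np.pi * (u - (1.0 - k)) / (2.0 * k))
        return np.where(u <= 1.0 - k, lin, np.minimum(knee, 1.0))

    @property
    def w_incr(self) -> float:
        return self.prev_boundary_pos - self.cambium_pos

    @property
    def w_maturing(self) -> float:
        return self.transition_pos - self.cambium_pos

    @property
    def w_mat(self) -> float:
        return self.prev_boundary_pos - self.transition_pos


def generate_profile(truth: RingTruth, n_points: int) -> GrayProfile:
    """A synthetic cell-wall gray profile sampled every voxel pitch."""
    if n_points < 20:
        raise ValueError("n_points must be >= 20")
    rng = np.random.default_rng(truth.seed)
    pos = np.arange(n_points) * truth.voxel_pitch
    vals = truth.wall_gray(pos)
    if truth.noise_sd > 0:
        vals = vals + rng.normal(0.0, truth.noise_sd, size=n_points)
    vals = np.clip(vals, 0.0, GRAY_MAX)
    return GrayProfile(positions=pos, values=vals, kind="cell_wall",
                       voxel_pitch=truth.voxel_pitch)


def generate_voi_stack(truth: RingTruth, slice_shape: tuple[int, int] = (64, 64),
                       cell_period_px: int = 8, wall_px: int = 3,
                       margin_px: int = 6, n_slices: int | None = None) -> VOIStack:
    """A tangential wall/lumen lattice stack reproducing the truth profile.

    Each slice holds a sample rectangle (outline drawn as wall so hole
    filling keeps lumens inside the sample) on an air background of gray 0.
    Wall pixels take the slice's radial wall gray, lumen pixels lumen_gray;
    pixel noise is normal with sd = truth.noise_sd. The sample and wall area
    fractions are stored in ``stack.meta`` as ground truth.
    """
    rows, cols = slice_shape
    if rows < 32 or cols < 32:
        raise ValueError("slice_shape must be at least 32x32")
    if cell_period_px < 4:
        raise ValueError("cell_period_px must be >= 4")
    if not 0 < wall_px < cell_period_px:
        raise ValueError("wall_px must be in (0, cell_period_px)")
    if n_slices is None:
        n_slices = int(np.ceil(truth.prev_boundary_pos / truth.voxel_pitch)) + 2
    rng = np.random.default_rng(truth.seed)

    rr, cc = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    sample = ((rr >= margin_px) & (rr < rows - margin_px)
              & (cc >= margin_px) & (cc < cols - margin_px))
    lattice = (rr % cell_period_px < wall_px) | (cc % cell_period_px < wall_px)
    border = sample & ~((rr >= margin_px + 1) & (rr < rows - margin_px - 1)
                        & (cc >= margin_px + 1) & (cc < cols - margin_px - 1))
    wall = sample & (lattice | border)
    lumen = sample & ~wall

    pos = np.arange(n_slices) * truth.voxel_pitch
    gray = truth.wall_gray(pos)
    stack = np.zeros((n_slices, rows, cols), dtype=float)
    for i in range(n_slices):
        img = np.zeros((rows, cols))
        img[wall] = gray[i]
        img[lumen] = truth.lumen_gray
        if truth.noise_sd > 0:
            img[sample] += rng.normal(0.0, truth.noise_sd, size=int(sample.sum()))
        stack[i] = np.clip(img, 0, GRAY_MAX)

    pitch = truth.voxel_pitch
    cam_idx = int(round(truth.cambium_pos / pitch))
    span = max(int(round((truth.cambium_flat_halfwidth + 60.0) / pitch)), 10)
    window = (max(cam_idx - span, 0), min(cam_idx + span, n_slices - 2))
    meta = {
        "truth": truth,
        "sample_fraction": float(sample.mean()),
        "wall_fraction": float(wall.sum() / sample.sum()),
    }
    return VOIStack(slices=stack, voxel_pitch=pitch,
                    prev_boundary_index=int(round(truth.prev_boundary_pos / pitch)),
                    cambium_window=window, meta=meta)


def logistic(t, asym: float, mid: float, scale: float) -> np.ndarray:
    """A / (1 + exp(-(t - mid)/scale))."""
    t = np.asarray(t, dtype=float)
    return asym / (1.0 + np.exp(-(t - mid) / scale))


@dataclass(frozen=True)
class TreeSigmoid:
    """Logistic growth parameters for one tree and one response."""

    asym: float   # μm
    mid: float    # DOY
    scale: float  # days

    def __post_init__(self) -> None:
        if self.asym <= 0 or self.scale <= 0:
            raise ValueError("asymptote and scale must be positive")

    def __call__(self, t) -> np.ndarray:
        return logistic(t, self.asym, self.mid, self.scale)


@dataclass(frozen=True)
class SeasonTruth:
    """Ground truth for a synthetic sampling season (one species)."""

    incr: tuple[TreeSigmoid, ...]
    mat: tuple[TreeSigmoid, ...]
    doys: tuple[int, ...]
    w_prev: tuple[float, ...]
    noise_sd: float = 0.0
    w_prev_cv: float = 0.0   # circumferential heterogeneity of w_prev
    biomass_lag: float = 0.0  # days the biomass sigmoid lags the mature one
    species: str = "synthetic"
    seed: int = 0

    def __post_init__(self) -> None:
        if not (len(self.incr) == len(self.mat) == len(self.w_prev)):
            raise ValueError("incr, mat and w_prev must have one entry per tree")
        if len(self.doys) < 6:
            raise ValueError("need at least 6 sampling dates")
        if np.any(np.diff(self.doys) <= 0):
            raise ValueError("sampling DOYs must be strictly increasing")
        for gi, gm in zip(self.incr, self.mat):
            if gm.asym > gi.asym:
                raise ValueError("mature asymptote must be <= increment asymptote")
        if any(w <= 0 for w in self.w_prev):
            raise ValueError("w_prev must be positive")

    @property
    def n_trees(self) -> int:
        return len(self.incr)


def _true_critical_dates(sig: TreeSigmoid, doys) -> tuple[float, float]:
    """Brute-force 5%/95% crossing dates of the noise-free sigmoid.

    Uses the pipeline's definition of the final width (median of the last
    three sampling dates) and a dense daily grid with linear interpolation.
    """
    grid = np.arange(float(doys[0]), float(doys[-1]) + 1.0)
    pred = sig(grid)
    final = float(np.median(sig(np.asarray(doys[-3:], dtype=float))))
    out = []
    for frac in (0.05, 0.95):
        target = frac * final
        idx = np.nonzero(pred >= target)[0]
        if idx.size == 0:
            out.append(float(grid[-1]))
            continue
        i = idx[0]
        if i == 0:
            out.append(float(grid[0]))
        else:
            t0, t1, y0, y1 = grid[i - 1], grid[i], pred[i - 1], pred[i]
            out.append(float(t0 + (target - y0) / (y1 - y0) * (t1 - t0)))
    return out[0], out[1]


def generate_season(truth: SeasonTruth) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Synthetic seasonal width and biomass tables plus their ground truth.

    Returns ``(widths, biomass, true_params)``:

    - widths: (species, tree, doy, w_incr, w_maturing, w_mat, w_prev)
    - biomass: (species, tree, doy, b_trunk, w_prev)
    - true_params: per tree, the noise-free tb/te for increment and mature
      growth (brute-force 1-day-grid oracle) and the asymptotes.

    Observed widths embed circumferential heterogeneity so that the Eq.-1
    style correction (w_obs · w_prev / mean(w_prev)) recovers the sigmoid.
    """
    rng = np.random.default_rng(truth.seed)
    doys = np.asarray(truth.doys, dtype=float)
    rows, brows, trows = [], [], []
    for k in range(truth.n_trees):
        gi, gm = truth.incr[k], truth.mat[k]
        base_prev = truth.w_prev[k]
        w_prev_j = base_prev * (1.0 + truth.w_prev_cv * rng.normal(size=doys.size))
        w_prev_j = np.maximum(w_prev_j, 0.05 * base_prev)
        # heterogeneity factor the Eq.-1 correction undoes
        het = w_prev_j.mean() / w_prev_j
        w_incr_true = gi(doys)
        w_mat_true = gm(doys)
        b_true = gm(doys - truth.biomass_lag)
        noise = rng.normal(0.0, truth.noise_sd, size=(3, doys.size))
        w_incr = np.maximum(w_incr_true * het + noise[0], 0.0)
        w_mat = np.clip(w_mat_true * het + noise[1], 0.0, w_incr)
        b_trunk = np.maximum(b_true * het + noise[2], 0.0)
        for j, d in enumerate(doys):
            rows.append((truth.species, k, int(d), w_incr[j],
                         w_incr[j] - w_mat[j], w_mat[j], w_prev_j[j]))
            brows.append((truth.species, k, int(d), b_trunk[j], w_prev_j[j]))
        tb_i, te_i = _true_critical_dates(gi, truth.doys)
        tb_m, te_m = _true_critical_dates(gm, truth.doys)
        trows.append((truth.species, k, tb_i, te_i, tb_m, te_m, gi.asym, gm.asym,
                      gi.mid, gm.mid))
    widths = pd.DataFrame(rows, columns=["species", "tree", "doy", "w_incr",
                                         "w_maturing", "w_mat", "w_prev"])
    biomass = pd.DataFrame(brows, columns=["species", "tree", "doy", "b_trunk",
                                           "w_prev"])
    true_params = pd.DataFrame(trows, columns=["species", "tree", "tb_incr",
                                               "te_incr", "tb_mat", "te_mat",
                                               "asym_incr", "asym_mat",
                                               "mid_incr", "mid_mat"])
    return widths, biomass, true_params
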