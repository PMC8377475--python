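"""Cambium and maturing→mature transition detection on cell-wall profiles.

The cambium is the flat minimum of the cell-wall gray profile inside a
manually annotated window; the maturing→mature transition is the bark-ward
edge of the plateau ("constant part") closest to the cambium. Flatness is
read off the fitted spline's derivative: a stretch is constant where the
pointwise 95% CI of the derivative contains 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .profiles import GrayProfile
from .splines import ConstantRun, derivative_band, find_constant_runs, fit_pspline

__all__ = [
    "RingWidths",
    "detect_cambium",
    "detect_transition",
    "measure_widths",
    "microtomy_increment",
    "DEFAULT_MIN_RUN_UM",
]

# min plateau extent: 5 grid points or 25 μm, whichever is larger
DEFAULT_MIN_RUN_POINTS = 5
DEFAULT_MIN_RUN_UM = 25.0

# detection wants a finer basis than generic smoothing: localizing a plateau
# edge to a few voxels needs knot spacing of the same order
_DETECT_BASIS_CAP = 120


@dataclass
class RingWidths:
    """Per-sample ring geometry (all positions μm from the stack start)."""

    cambium_pos: float
    prev_boundary_pos: float
    transition_pos: float
    w_incr: float
    w_maturing: float
    w_mat: float
    end_of_season: bool = False
    no_plateau: bool = False

    def __post_init__(self) -> None:
        if self.w_incr <= 0:
            raise ValueError("w_incr must be positive (check annotations/ordering)")
        if min(self.w_maturing, self.w_mat) < 0:
            raise ValueError("negative width: annotation or ordering bug")
        if abs((self.w_maturing + self.w_mat) - self.w_incr) > 1e-9 * max(self.w_incr, 1.0):
            raise ValueError("widths must satisfy w_maturing + w_mat = w_incr")

    def to_dict(self) -> dict:
        return {
            "cambium_um": self.cambium_pos,
            "transition_um": self.transition_pos,
            "boundary_um": self.prev_boundary_pos,
            "w_incr": self.w_incr,
            "w_maturing": self.w_maturing,
            "w_mat": self.w_mat,
            "flags": ";".join(f for f, on in
                              [("end_of_season", self.end_of_season),
                               ("no_plateau", self.no_plateau)] if on),
        }


def _min_run_points(voxel_pitch: float, min_run_length: int | None) -> int:
    if min_run_length is not None:
        return int(min_run_length)
    return max(DEFAULT_MIN_RUN_POINTS, int(np.ceil(DEFAULT_MIN_RUN_UM / voxel_pitch)))


def _detect_basis_dim(n: int) -> int:
    return int(np.clip(n // 4, 8, _DETECT_BASIS_CAP))


def _fit_and_runs(x: np.ndarray, y: np.ndarray, min_run: int, level: float,
                  basis_dim: int | None):
    fit = fit_pspline(x, y, basis_dim=basis_dim or _detect_basis_dim(x.size))
    band = derivative_band(fit, x, level=level)
    return fit, band, find_constant_runs(band, min_run_length=min_run)


def _merge_runs(runs: list[ConstantRun], grid: np.ndarray,
                max_gap: int) -> list[ConstantRun]:
    """Coalesce runs separated by at most ``max_gap`` grid points."""
    merged: list[ConstantRun] = []
    for run in runs:
        if merged and run.indices[0] - merged[-1].indices[1] - 1 <= max_gap:
            prev = merged[-1]
            merged[-1] = ConstantRun(start=prev.start, end=run.end,
                                     length=run.indices[1] - prev.indices[0] + 1,
                                     indices=(prev.indices[0], run.indices[1]))
        else:
            merged.append(run)
    return merged


def _run_median(run: ConstantRun, grid: np.ndarray) -> float:
    i, j = run.indices
    k = i + (j - i) // 2  # even count → lower (bark-ward) of the two central points
    return float(grid[k])


def detect_cambium(profile: GrayProfile, window: tuple[float, float],
                   min_run_length: int | None = None, level: float = 0.95,
                   basis_dim: int | None = None) -> float:
    """Median position of the flat density minimum within the cambium window.

    Fits a spline to the profile restricted to ``window`` (μm), finds the
    stretches where the derivative CI contains 0, and returns the median
    position of the run containing the minimum fitted value.
    """
    pos, val = profile.finite()
    lo, hi = window
    sel = (pos >= lo) & (pos <= hi)
    if sel.sum() < 10:
        raise ValueError("cambium window must contain at least 10 profile points")
    x, y = pos[sel], val[sel]
    # the cambium flat bottom can be far narrower than the ring-pass plateau
    # rule, and fits fragment it into short runs split by derivative ripple;
    # fragments separated by small gaps are merged back into one run and the
    # min-fitted-value rule anchors the choice, so no length filter is applied
    min_run = 1 if min_run_length is None else int(min_run_length)
    fit, band, runs = _fit_and_runs(x, y, min_run, level, basis_dim)
    runs = _merge_runs(runs, x, max_gap=5)
    # derivative CIs widen at the window edges and spawn spurious flat runs
    # there; the annotated window must bracket the minimum, so edge-touching
    # runs are dropped unless a run spans the entire window
    n_pts = x.size
    interior = [r for r in runs
                if (r.indices[0] > 0 and r.indices[1] < n_pts - 1)
                or (r.indices[0] == 0 and r.indices[1] == n_pts - 1)]
    if interior:
        runs = interior
    if not runs:
        raise ValueError(
            "no constant stretch in the cambium window; widen the window so it "
            "covers the density minimum")
    fitted = fit.predict(x)
    i_min = int(np.argmin(fitted))
    chosen = None
    for run in runs:
        i, j = run.indices
        if i <= i_min <= j:
            chosen = run
            break
    if chosen is None:
        # no run brackets the global minimum: take the run whose own minimum
        # fitted value is lowest
        chosen = min(runs, key=lambda r: fitted[r.indices[0]:r.indices[1] + 1].min())
    return _run_median(chosen, x)


def detect_transition(profile: GrayProfile, cambium_pos: float,
                      prev_boundary_pos: float, min_run_length: int | None = None,
                      level: float = 0.95, basis_dim: int | None = None,
                      ) -> tuple[float, bool]:
    """Bark-ward edge of the plateau closest to the cambium.

    Positions are re-expressed as distance from the cambium, a spline is
    fitted from 0 to the previous ring boundary, and the constant run closest
    to the cambium is selected; its left edge is the transition. Returns
    ``(transition_pos, no_plateau)`` in original stack coordinates; when no
    plateau exists (early season) the transition is placed at the previous
    boundary and the flag is set (the whole ring is still maturing).
    """
    if not cambium_pos < prev_boundary_pos:
        raise ValueError("cambium_pos must precede prev_boundary_pos")
    pos, val = profile.finite()
    sel = (pos >= cambium_pos) & (pos <= prev_boundary_pos)
    if sel.sum() < 10:
        raise ValueError("degenerate ring: fewer than 10 profile points")
    x = pos[sel] - cambium_pos
    y = val[sel]
    min_run = _min_run_points(profile.voxel_pitch, min_run_length)
    fit, _band, runs = _fit_and_runs(x, y, min_run, level, basis_dim)
    # the mature plateau is constant AND at high density: a flat stretch at
    # the cambium-side density minimum is the valley bottom, not maturity
    fitted = fit.predict(x)
    lo, hi = float(fitted.min()), float(fitted.max())
    cut = lo + 0.5 * (hi - lo)
    runs = [r for r in runs
            if fitted[r.indices[0]:r.indices[1] + 1].mean() >= cut]
    if not runs:
        return float(prev_boundary_pos), True
    first = runs[0]  # ordered by start: closest to the cambium
    if first.indices[0] == 0:
        # constant from the very first ring point: fully mature (end of season)
        return float(cambium_pos), False
    return float(cambium_pos + first.start), False


def measure_widths(profile: GrayProfile, cambium_pos: float,
                   prev_boundary_pos: float, min_run_length: int | None = None,
                   level: float = 0.95, basis_dim: int | None = None) -> RingWidths:
    """The three ring widths from the detected transition (Fig.-4 arithmetic).

    w_incr = prev_boundary − cambium; w_maturing = transition − cambium;
    w_mat = w_incr − w_maturing. A missing plateau flags the sample and sets
    w_maturing = w_incr; a plateau starting at the cambium flags end-of-season
    (w_maturing = 0).
    """
    w_incr = prev_boundary_pos - cambium_pos
    if w_incr <= 0:
        raise ValueError("prev_boundary_pos must exceed cambium_pos")
    transition_pos, no_plateau = detect_transition(
        profile, cambium_pos, prev_boundary_pos,
        min_run_length=min_run_length, level=level, basis_dim=basis_dim)
    w_maturing = transition_pos - cambium_pos
    w_mat = w_incr - w_maturing
    return RingWidths(cambium_pos=float(cambium_pos),
                      prev_boundary_pos=float(prev_boundary_pos),
                      transition_pos=float(transition_pos),
                      w_incr=float(w_incr), w_maturing=float(w_maturing),
                      w_mat=float(w_mat),
                      end_of_season=bool(w_maturing == 0.0),
                      no_plateau=no_plateau)


def microtomy_increment(w_mat: float, w_maturing: float, w_cambium: float) -> float:
    """Increment width from microtomy zones: w_mat + w_maturing + w_cambium/2."""
    if min(w_mat, w_maturing, w_cambium) < 0:
        raise ValueError("widths must be nonnegative")
    return w_mat + w_maturing + w_cambium / 2.0


def widths_table(records: list[dict]) -> pd.DataFrame:
    """Assemble RingWidths dicts (plus sample_id/doy keys) into the output table."""
    return pd.DataFrame.from_records(records)
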