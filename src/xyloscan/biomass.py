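"""Intra-seasonal biomass-production dynamics from xylem gray profiles.

b_trunk — the sum of the xylem gray-value profile over the forming ring — is
linearly related to the biomass accumulated at the trunk base. Completion
curves (width and biomass, each normalized by the median of its predictions
at the last three sampling dates) give the time lag between size growth and
biomass production across the season, and the daily-rate peaks give the
peak-to-peak lag.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .phenology import _eq1_correct, final_width
from .profiles import GrayProfile

__all__ = [
    "LagCurve",
    "compute_b_trunk",
    "correct_b_trunk",
    "completion_curves",
    "time_lag_curve",
    "peak_rate_lag",
]

FRACTION_STEP = 0.01

# a flat daily-rate maximum longer than this is flagged (tie rule matters)
PEAK_PLATEAU_FLAG_DAYS = 7


@dataclass
class LagCurve:
    """Time lag (days) between biomass and size-growth completion.

    ``lag[i]`` = first DOY the biomass completion reaches ``fractions[i]``
    minus the first DOY the width completion does; NaN where either process
    never reaches the fraction within the season (excluded from summaries).
    """

    fractions: np.ndarray
    doy_width: np.ndarray
    doy_biomass: np.ndarray
    lag: np.ndarray

    def __post_init__(self) -> None:
        if self.fractions.size != 101:
            raise ValueError("fraction grid must have 101 points (0 to 1 by 0.01)")

    @property
    def mean_lag(self) -> float:
        d = self.lag[np.isfinite(self.lag)]
        return float(d.mean()) if d.size else float("nan")

    @property
    def max_lag(self) -> float:
        d = self.lag[np.isfinite(self.lag)]
        return float(d.max()) if d.size else float("nan")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"fraction": self.fractions, "doy_width": self.doy_width,
                             "doy_biomass": self.doy_biomass, "lag_days": self.lag})


def compute_b_trunk(xylem_profile: GrayProfile, cambium_pos: float,
                    prev_boundary_pos: float) -> float:
    """Sum of xylem gray values over the forming ring (cambium → boundary)."""
    pos, val = xylem_profile.finite()
    sel = (pos >= cambium_pos) & (pos <= prev_boundary_pos)
    if not sel.any():
        warnings.warn("empty ring segment: b_trunk set to 0", UserWarning, stacklevel=2)
        return 0.0
    return float(val[sel].sum())


def correct_b_trunk(series: pd.DataFrame, group: str = "tree") -> pd.DataFrame:
    """Heterogeneity correction of b_trunk (same multiplicative form as widths)."""
    if (series["w_prev"] <= 0).any():
        raise ValueError("w_prev must be positive for every sample")
    out = series.copy()
    for _, idx in out.groupby(group).groups.items():
        w_prev = out.loc[idx, "w_prev"].to_numpy(dtype=float)
        out.loc[idx, "b_trunk"] = _eq1_correct(
            out.loc[idx, "b_trunk"].to_numpy(dtype=float), w_prev)
    return out


def completion_curves(grid: np.ndarray, width_pred: np.ndarray,
                      biomass_pred: np.ndarray, sampling_doys,
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Normalize both daily curves by their last-three-dates median prediction.

    Values may slightly exceed 1 late in the season; that is allowed.
    """
    out = []
    for pred in (width_pred, biomass_pred):
        norm = final_width(grid, pred, sampling_doys)
        if norm == 0:
            raise ValueError("zero normalizer: curve never grows")
        out.append(pred / norm)
    return out[0], out[1]


def _crossing(grid: np.ndarray, curve: np.ndarray, f: float) -> float:
    """First day the completion reaches f, linearly interpolated.

    NaN when the curve never reaches f, or when it already starts at/above f
    (left-censored: the crossing happened before the observation window).
    """
    if curve[0] >= f:
        return float("nan")
    idx = np.nonzero(curve >= f)[0]
    if idx.size == 0:
        return float("nan")
    i = int(idx[0])
    t0, t1, y0, y1 = grid[i - 1], grid[i], curve[i - 1], curve[i]
    return float(t0 + (f - y0) / (y1 - y0) * (t1 - t0))


def time_lag_curve(grid: np.ndarray, width_completion: np.ndarray,
                   biomass_completion: np.ndarray) -> LagCurve:
    """Lag(f) over the fraction grid {0, 0.01, ..., 1}.

    lag(f) = DOY the biomass completion first reaches f − DOY the width
    completion first reaches f. Fractions unreached by either curve are NaN
    and excluded from the mean/max summaries.
    """
    for c in (width_completion, biomass_completion):
        if np.any(np.diff(c) < -1e-9):
            raise ValueError("completion curves must be nondecreasing")
    fractions = np.round(np.arange(0.0, 1.0 + FRACTION_STEP / 2, FRACTION_STEP), 2)
    t_w = np.array([_crossing(grid, width_completion, f) for f in fractions])
    t_b = np.array([_crossing(grid, biomass_completion, f) for f in fractions])
    return LagCurve(fractions=fractions, doy_width=t_w, doy_biomass=t_b,
                    lag=t_b - t_w)


def peak_rate_lag(grid: np.ndarray, width_daily: np.ndarray,
                  biomass_daily: np.ndarray) -> dict:
    """DOY of maximum daily rate for each curve and their lag (biomass − width).

    Ties take the earliest day; a flat maximum longer than
    ``PEAK_PLATEAU_FLAG_DAYS`` sets ``plateau_flag``. A curve with all-zero
    rates has no defined peak: its DOY and the lag are NaN with ``flat_flag``.
    """
    out = {"plateau_flag": False, "flat_flag": False}
    peaks = []
    for name, daily in (("width", width_daily), ("biomass", biomass_daily)):
        days, rates = grid[1:], np.diff(daily)
        if rates.size == 0 or np.max(rates) <= 0:
            out["flat_flag"] = True
            out[f"doy_{name}_peak"] = float("nan")
            peaks.append(float("nan"))
            continue
        m = np.max(rates)
        at_max = np.nonzero(rates >= m * (1 - 1e-12))[0]
        if days[at_max[-1]] - days[at_max[0]] > PEAK_PLATEAU_FLAG_DAYS:
            out["plateau_flag"] = True
        peak = float(days[at_max[0]])
        out[f"doy_{name}_peak"] = peak
        peaks.append(peak)
    out["lag_days"] = peaks[1] - peaks[0]
    return out
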