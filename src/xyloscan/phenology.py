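"""Xylogenesis calendar from seasonal width series.

Corrected widths (circumferential-heterogeneity correction) are fitted per
tree with a monotone-increasing penalized spline; critical dates are the days
at which 5%/95% of the final width is formed, with durations and mean daily
rates derived from them, and daily rates from first differences of the daily
predictions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .splines import SmoothFit, fit_monotone_pspline

__all__ = [
    "PhenologyParams",
    "correct_widths",
    "fit_seasonal_curve",
    "final_width",
    "critical_dates",
    "durations_and_rates",
    "daily_rates",
    "estimate_phenology",
]

WIDTH_COLUMNS = ("w_incr", "w_maturing", "w_mat")


@dataclass
class PhenologyParams:
    """Critical dates, durations, and rates for one tree (or species median).

    d_xylo spans the whole xylogenesis: te_mat − tb_incr.
    """

    tb_incr: float
    te_incr: float
    tb_mat: float
    te_mat: float
    wb_incr: float
    we_incr: float
    wb_mat: float
    we_mat: float
    d_incr: float
    d_mat: float
    d_xylo: float
    r_incr: float | None
    r_mat: float | None
    final_w_incr: float
    final_w_mat: float
    te_incr_censored: bool = False
    te_mat_censored: bool = False

    def __post_init__(self) -> None:
        for tb, te, name in ((self.tb_incr, self.te_incr, "incr"),
                             (self.tb_mat, self.te_mat, "mat")):
            if tb > te:
                raise ValueError(f"tb_{name} must be <= te_{name}")
        if self.wb_incr >= self.we_incr or self.wb_mat >= self.we_mat:
            raise ValueError("wb must be < we")

    def to_dict(self) -> dict:
        d = dict(self.__dict__)
        d["flags"] = ";".join(f for f, on in
                              [("te_incr_censored", self.te_incr_censored),
                               ("te_mat_censored", self.te_mat_censored)] if on)
        d.pop("te_incr_censored")
        d.pop("te_mat_censored")
        return d


def _eq1_correct(values: np.ndarray, w_prev: np.ndarray) -> np.ndarray:
    return values * w_prev / w_prev.mean()


def correct_widths(series: pd.DataFrame, columns=WIDTH_COLUMNS,
                   group: str = "tree") -> pd.DataFrame:
    """Circumferential-heterogeneity correction, per tree.

    Each width is multiplied by its sample's previous-ring width divided by
    the tree-level mean of the previous-ring width over all sampling dates.
    """
    if (series["w_prev"] <= 0).any():
        raise ValueError("w_prev must be positive for every sample")
    out = series.copy()
    for _, idx in out.groupby(group).groups.items():
        w_prev = out.loc[idx, "w_prev"].to_numpy(dtype=float)
        for col in columns:
            if col in out:
                out.loc[idx, col] = _eq1_correct(
                    out.loc[idx, col].to_numpy(dtype=float), w_prev)
    return out


def fit_seasonal_curve(doys, widths, basis_dim: int | None = None,
                       ) -> tuple[SmoothFit, np.ndarray, np.ndarray]:
    """Monotone fit of one tree's corrected widths vs DOY.

    Returns ``(fit, grid, daily_pred)`` with the integer-DOY grid spanning
    the first to the last sampling date.
    """
    doys = np.asarray(doys, dtype=float)
    widths = np.asarray(widths, dtype=float)
    n_dates = np.unique(doys).size
    if n_dates < 6:
        raise ValueError("need at least 6 sampling dates per tree")
    if np.any(widths < 0):
        raise ValueError("widths must be nonnegative")
    if basis_dim is None:
        # sigmoids at biweekly sampling need a denser basis than the generic
        # n/2 default; GCV still controls the effective dof
        basis_dim = int(np.clip(n_dates - 2, 6, 16))
    fit = fit_monotone_pspline(doys, widths, basis_dim=basis_dim)
    grid = np.arange(np.ceil(doys.min()), np.floor(doys.max()) + 1.0)
    pred = fit.predict(grid)
    return fit, grid, pred


def final_width(grid: np.ndarray, pred: np.ndarray, sampling_doys) -> float:
    """Median prediction at the last three sampling dates."""
    sampling_doys = np.asarray(sampling_doys, dtype=float)
    if sampling_doys.size < 3:
        raise ValueError("need at least 3 sampling dates")
    last3 = np.sort(sampling_doys)[-3:]
    return float(np.median(np.interp(last3, grid, pred)))


def _first_crossing(grid: np.ndarray, pred: np.ndarray, target: float) -> float | None:
    """First day predictions reach target, linearly interpolated; None if never."""
    idx = np.nonzero(pred >= target)[0]
    if idx.size == 0:
        return None
    i = int(idx[0])
    if i == 0:
        return float(grid[0])
    t0, t1, y0, y1 = grid[i - 1], grid[i], pred[i - 1], pred[i]
    if y1 == y0:
        return float(t1)
    return float(t0 + (target - y0) / (y1 - y0) * (t1 - t0))


def critical_dates(grid: np.ndarray, pred: np.ndarray, final: float,
                   ) -> tuple[float, float, float, float, bool]:
    """(tb, te, wb, we, te_censored): 5%/95% crossing days of the daily curve.

    te is capped at the last grid day (censored flag) when 95% of the final
    width is not reached within the season.
    """
    if final <= 0:
        raise ValueError("final width must be positive")
    wb, we = 0.05 * final, 0.95 * final
    tb = _first_crossing(grid, pred, wb)
    if tb is None:
        raise ValueError("growth absent: 5% of the final width is never reached")
    te = _first_crossing(grid, pred, we)
    censored = te is None
    if censored:
        te = float(grid[-1])
    return tb, te, wb, we, censored


def durations_and_rates(tb_incr, te_incr, wb_incr=0.0, we_incr=1.0,
                        tb_mat=None, te_mat=None, wb_mat=0.0, we_mat=1.0,
                        final_w_incr=np.nan, final_w_mat=np.nan,
                        te_incr_censored=False, te_mat_censored=False,
                        ) -> PhenologyParams:
    """Durations and mean daily rates from critical dates.

    d = te − tb per process; r = (we − wb)/(te − tb); d_xylo = te_mat − tb_incr.
    A zero-length process leaves its rate undefined (None). When only the
    size-growth process is of interest the mature-process dates default to
    the size-growth ones and wb/we to nominal 0/1 (rates then meaningless).
    """
    if tb_mat is None:
        tb_mat = tb_incr
    if te_mat is None:
        te_mat = te_incr
    d_incr = te_incr - tb_incr
    d_mat = te_mat - tb_mat
    r_incr = (we_incr - wb_incr) / d_incr if d_incr > 0 else None
    r_mat = (we_mat - wb_mat) / d_mat if d_mat > 0 else None
    return PhenologyParams(
        tb_incr=tb_incr, te_incr=te_incr, tb_mat=tb_mat, te_mat=te_mat,
        wb_incr=wb_incr, we_incr=we_incr, wb_mat=wb_mat, we_mat=we_mat,
        d_incr=d_incr, d_mat=d_mat, d_xylo=te_mat - tb_incr,
        r_incr=r_incr, r_mat=r_mat,
        final_w_incr=final_w_incr, final_w_mat=final_w_mat,
        te_incr_censored=te_incr_censored, te_mat_censored=te_mat_censored)


def daily_rates(grid: np.ndarray, pred: np.ndarray, tb: float | None = None,
                te: float | None = None) -> tuple[np.ndarray, np.ndarray]:
    """First differences of the daily predictions over [tb, te].

    Returns ``(days, rates)`` with rates[i] the growth between days[i]-1 and
    days[i]; Σ rates telescopes to pred(end) − pred(start).
    """
    rates = np.diff(pred)
    days = grid[1:]
    if tb is not None:
        keep = days - 1 >= tb
        days, rates = days[keep], rates[keep]
    if te is not None:
        keep = days <= te
        days, rates = days[keep], rates[keep]
    return days, rates


def _tree_process(doys, widths, basis_dim=None):
    _fit, grid, pred = fit_seasonal_curve(doys, widths, basis_dim=basis_dim)
    final = final_width(grid, pred, doys)
    tb, te, wb, we, censored = critical_dates(grid, pred, final)
    return grid, pred, final, tb, te, wb, we, censored


def estimate_phenology(series: pd.DataFrame, correct: bool = True,
                       basis_dim: int | None = None) -> pd.DataFrame:
    """Per-tree phenology table from a seasonal width table.

    Expects columns (species, tree, doy, w_incr, w_mat, w_prev); applies the
    heterogeneity correction unless ``correct=False``, fits monotone curves
    for the increment and the mature width, and returns one row per tree.
    """
    if correct:
        series = correct_widths(series)
    rows = []
    for (species, tree), g in series.groupby(["species", "tree"]):
        g = g.sort_values("doy")
        doys = g["doy"].to_numpy(dtype=float)
        _, _, fin_i, tb_i, te_i, wb_i, we_i, cen_i = _tree_process(
            doys, g["w_incr"], basis_dim)
        _, _, fin_m, tb_m, te_m, wb_m, we_m, cen_m = _tree_process(
            doys, g["w_mat"], basis_dim)
        p = durations_and_rates(tb_i, te_i, wb_i, we_i, tb_m, te_m, wb_m, we_m,
                                final_w_incr=fin_i, final_w_mat=fin_m,
                                te_incr_censored=cen_i, te_mat_censored=cen_m)
        rows.append({"species": species, "tree": tree, **p.to_dict()})
    return pd.DataFrame(rows)


def species_medians(phenology: pd.DataFrame) -> pd.DataFrame:
    """Species-level medians of the per-tree parameters (median of trees)."""
    num = phenology.select_dtypes("number").columns.drop("tree", errors="ignore")
    return phenology.groupby("species")[list(num)].median().reset_index()
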