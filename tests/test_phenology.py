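import numpy as np
import pandas as pd
import pytest

from xyloscan import (correct_widths, critical_dates, daily_rates,
                      durations_and_rates, estimate_phenology, final_width,
                      fit_seasonal_curve, generate_season)
from xyloscan.phenology import species_medians
from xyloscan.simulate import logistic


def table(rows, cols=("species", "tree", "doy", "w_incr", "w_maturing",
                      "w_mat", "w_prev")):
    return pd.DataFrame(rows, columns=list(cols))


class TestCorrectWidths:
    def test_equal_w_prev_is_identity(self, season_truth):
        widths, _, _ = generate_season(season_truth)
        widths = widths.copy()
        widths["w_prev"] = 1200.0
        corrected = correct_widths(widths)
        np.testing.assert_allclose(corrected["w_incr"], widths["w_incr"])

    def test_worked_example(self):
        # tree mean(w_prev) = 1 with samples (2, 0.5, 0.5)
        df = table([("s", 0, 90, 10.0, 0.0, 10.0, 2.0),
                    ("s", 0, 104, 10.0, 0.0, 10.0, 0.5),
                    ("s", 0, 118, 10.0, 0.0, 10.0, 0.5)])
        out = correct_widths(df)
        assert out.loc[0, "w_incr"] == pytest.approx(20.0)

    def test_matches_brute_force_on_random_table(self):
        rng = np.random.default_rng(8)
        rows = []
        for tree in range(3):
            for doy in range(90, 260, 14):
                rows.append(("s", tree, doy, rng.uniform(10, 1000),
                             0.0, 0.0, rng.uniform(500, 2000)))
        df = table(rows)
        out = correct_widths(df)
        for tree, g in df.groupby("tree"):
            mean_prev = g["w_prev"].mean()
            expect = g["w_incr"] * g["w_prev"] / mean_prev
            np.testing.assert_allclose(out.loc[g.index, "w_incr"], expect)

    def test_nonpositive_w_prev_errors(self):
        df = table([("s", 0, 90, 10.0, 0.0, 10.0, 0.0)] * 6)
        with pytest.raises(ValueError, match="w_prev"):
            correct_widths(df)


class TestFitSeasonalCurve:
    def test_noise_free_logistic_within_1pct(self):
        doys = np.arange(90.0, 342.0, 14.0)
        y = logistic(doys, 1000.0, 170.0, 18.0)
        _fit, grid, pred = fit_seasonal_curve(doys, y)
        err = np.max(np.abs(pred - logistic(grid, 1000.0, 170.0, 18.0)))
        assert err < 0.01 * 1000.0

    def test_predictions_nondecreasing(self, season_truth):
        widths, _, _ = generate_season(season_truth)
        g = widths[widths["tree"] == 0]
        _fit, _grid, pred = fit_seasonal_curve(g["doy"], g["w_incr"])
        assert np.min(np.diff(pred)) >= -1e-8 * np.ptp(pred)

    def test_constant_shift_equivariance(self, season_truth):
        widths, _, _ = generate_season(season_truth)
        g = widths[widths["tree"] == 1]
        _f1, grid, p1 = fit_seasonal_curve(g["doy"], g["w_incr"])
        _f2, _g, p2 = fit_seasonal_curve(g["doy"], g["w_incr"] + 500.0)
        np.testing.assert_allclose(p2, p1 + 500.0, rtol=1e-5, atol=1e-3)

    def test_too_few_dates(self):
        with pytest.raises(ValueError, match="6 sampling dates"):
            fit_seasonal_curve([90, 104, 118, 132, 146], [1, 2, 3, 4, 5])


class TestFinalWidth:
    def test_median_of_last_three(self):
        grid = np.arange(90.0, 301.0)
        pred = np.interp(grid, [90, 250, 270, 290], [0, 980, 1000, 1010])
        assert final_width(grid, pred, [90, 150, 250, 270, 290]) == 1000.0

    def test_plateaued_curve(self):
        grid = np.arange(0.0, 100.0)
        pred = np.full(100, 42.0)
        assert final_width(grid, pred, [10, 50, 90]) == 42.0

    def test_needs_three_dates(self):
        with pytest.raises(ValueError, match="at least 3"):
            final_width(np.arange(10.0), np.arange(10.0), [1, 2])


class TestCriticalDates:
    def test_logistic_closed_form(self):
        asym, mid, scale = 1000.0, 170.0, 18.0
        grid = np.arange(90.0, 331.0)
        pred = logistic(grid, asym, mid, scale)
        final = float(np.median(pred[-3:]))
        tb, te, wb, we, cens = critical_dates(grid, pred, final)
        assert not cens
        for frac, got in ((0.05, tb), (0.95, te)):
            exact = mid - scale * np.log(asym / (frac * final) - 1.0)
            assert got == pytest.approx(exact, abs=0.5)

    def test_step_curve(self):
        grid = np.arange(0.0, 50.0)
        pred = np.where(grid < 20, 0.0, 100.0)
        tb, te, _wb, _we, _ = critical_dates(grid, pred, 100.0)
        assert abs(tb - te) < 1.0
        assert 19.0 <= tb <= te <= 20.0

    def test_censored_te(self):
        grid = np.arange(0.0, 50.0)
        pred = np.linspace(0, 50, 50)  # only reaches half of "final" 100
        tb, te, _wb, _we, cens = critical_dates(grid, pred, 100.0)
        assert cens and te == grid[-1]

    def test_growth_absent_errors(self):
        grid = np.arange(0.0, 50.0)
        with pytest.raises(ValueError, match="growth absent"):
            critical_dates(grid, np.zeros(50), 100.0)


class TestDurationsAndRates:
    def test_pine_microtomy_duration(self):
        p = durations_and_rates(tb_incr=100.0, te_incr=277.0)
        assert p.d_incr == 177.0

    def test_beech_microtomy_duration(self):
        p = durations_and_rates(tb_incr=122.0, te_incr=256.0)
        assert p.d_incr == 134.0

    def test_rate_arithmetic(self):
        p = durations_and_rates(tb_incr=100.0, te_incr=200.0, wb_incr=50.0,
                                we_incr=950.0)
        assert p.r_incr == pytest.approx(9.0)

    def test_zero_duration_rate_missing(self):
        p = durations_and_rates(tb_incr=150.0, te_incr=150.0, wb_incr=0.0,
                                we_incr=1.0)
        assert p.r_incr is None
        assert p.d_incr == 0.0

    def test_d_xylo_spans_xylogenesis(self):
        p = durations_and_rates(tb_incr=100.0, te_incr=250.0, tb_mat=130.0,
                                te_mat=280.0)
        assert p.d_xylo == 180.0


class TestDailyRates:
    def test_linear_curve_constant_rate(self):
        grid = np.arange(0.0, 30.0)
        _days, rates = daily_rates(grid, 3.0 * grid)
        np.testing.assert_allclose(rates, 3.0)

    def test_telescoping_identity(self, season_truth):
        widths, _, _ = generate_season(season_truth)
        g = widths[widths["tree"] == 2]
        _fit, grid, pred = fit_seasonal_curve(g["doy"], g["w_incr"])
        _days, rates = daily_rates(grid, pred)
        assert rates.sum() == pytest.approx(pred[-1] - pred[0], rel=1e-10)

    def test_logistic_rate_peaks_at_inflection(self):
        doys = np.arange(90.0, 342.0, 14.0)
        y = logistic(doys, 1000.0, 170.0, 18.0)
        _fit, grid, pred = fit_seasonal_curve(doys, y)
        days, rates = daily_rates(grid, pred)
        assert abs(days[np.argmax(rates)] - 170.0) <= 3.0


class TestEstimatePhenology:
    def test_recovers_truth(self, season_truth):
        widths, _, truth = generate_season(season_truth)
        phen = estimate_phenology(widths)
        m = phen.merge(truth, on=["species", "tree"], suffixes=("", "_true"))
        for col in ("tb_incr", "te_incr", "tb_mat", "te_mat"):
            err = (m[col] - m[f"{col}_true"]).abs().median()
            assert err <= 14.0, col

    def test_ordering_mature_lags_increment(self, season_truth):
        widths, _, _ = generate_season(season_truth)
        phen = estimate_phenology(widths)
        assert (phen["tb_incr"] <= phen["tb_mat"] + 1e-9).all()
        assert (phen["te_incr"] <= phen["te_mat"] + 1e-9).all()

    def test_scale_equivariance(self, season_truth):
        widths, _, _ = generate_season(season_truth)
        phen1 = estimate_phenology(widths)
        scaled = widths.copy()
        for c in ("w_incr", "w_maturing", "w_mat"):
            scaled[c] = scaled[c] * 3.0
        phen2 = estimate_phenology(scaled)
        for c in ("tb_incr", "te_incr", "tb_mat", "te_mat", "d_incr", "d_mat"):
            np.testing.assert_allclose(phen2[c], phen1[c], atol=1e-6)
        np.testing.assert_allclose(phen2["r_incr"], 3.0 * phen1["r_incr"],
                                   rtol=1e-6)

    def test_species_medians(self, season_truth):
        widths, _, _ = generate_season(season_truth)
        phen = estimate_phenology(widths)
        med = species_medians(phen)
        assert len(med) == 1
        assert med.loc[0, "d_incr"] == pytest.approx(phen["d_incr"].median())
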