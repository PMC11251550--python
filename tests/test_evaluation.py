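"""RMSE, rates, time lag, and the continuous glucose error grid."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gluconet import (ForecastResult, cg_ega, compute_rates, p_ega, r_ega,
                      rmse, time_lag)


def make_result(reference, predicted, step=5.0):
    n = len(reference)
    times = pd.date_range("2022-01-01", periods=n, freq=f"{int(step)}min")
    return ForecastResult(times=times,
                          reference_glucose=np.asarray(reference, float),
                          predicted_glucose=np.asarray(predicted, float),
                          step_minutes=step)


class TestRmse:
    def test_identical_series(self):
        r = make_result([100, 120, 140], [100, 120, 140])
        assert rmse(r) == 0.0

    def test_constant_offset(self):
        r = make_result([100, 120, 140], [105, 125, 145])
        assert rmse(r) == pytest.approx(5.0)

    def test_symmetric_residuals(self):
        r = make_result([100, 100], [110, 90])
        assert rmse(r) == pytest.approx(10.0)

    def test_reorder_invariance_and_linear_scaling(self):
        rng = np.random.default_rng(0)
        ref = rng.uniform(80, 200, 50)
        resid = rng.normal(0, 10, 50)
        a = rmse(reference=ref, predicted=ref + resid)
        perm = rng.permutation(50)
        b = rmse(reference=ref[perm], predicted=(ref + resid)[perm])
        assert a == pytest.approx(b)
        c = rmse(reference=ref, predicted=ref + 3 * resid)
        assert c == pytest.approx(3 * a)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            rmse(reference=np.array([]), predicted=np.array([]))


class TestComputeRates:
    def test_difference_quotient(self):
        rates = compute_rates(np.array([100.0, 110.0]), 5.0)
        assert np.isnan(rates[0]) and rates[1] == pytest.approx(2.0)

    def test_constant_series_zero_rates(self):
        rates = compute_rates(np.full(5, 120.0), 5.0)
        np.testing.assert_allclose(rates[1:], 0.0)

    def test_rates_scale_inversely_with_step(self):
        values = np.array([100.0, 130.0, 90.0])
        np.testing.assert_allclose(compute_rates(values, 30.0)[1:],
                                   compute_rates(values, 5.0)[1:] / 6.0)

    def test_single_point_rejected(self):
        with pytest.raises(ValueError):
            compute_rates(np.array([100.0]), 5.0)

    def test_non_contiguous_points_flagged(self):
        times = pd.DatetimeIndex(["2022-01-01 00:00", "2022-01-01 00:05",
                                  "2022-01-01 00:20"])
        rates = compute_rates(np.array([100.0, 110.0, 120.0]), 5.0, times)
        assert not np.isnan(rates[1]) and np.isnan(rates[2])


class TestPointGrid:
    @pytest.mark.parametrize("ref,pred,rate,zone", [
        (100, 100, 0.0, "A"),     # exact
        (200, 230, 0.0, "A"),     # within 20%
        (50, 50, 0.0, "A"),       # exact in hypoglycemia
        (55, 75, 0.0, "D"),       # missed hypo, read euglycemic
        (60, 185, 0.0, "E"),      # hypo read as hyper
        (250, 100, 0.0, "D"),     # missed hyper
        (250, 60, 0.0, "E"),      # hyper read as hypo
        (100, 215, 0.0, "C"),     # overcorrection high
        (160, 40, 0.0, "C"),      # overcorrection low: 7/5*160-182 = 42
        (160, 45, 0.0, "B"),      # just above the lower C line
        (100, 125, 0.0, "B"),     # beyond 20% but benign
    ])
    def test_zone_boundaries(self, ref, pred, rate, zone):
        assert p_ega(ref, pred, rate) == zone

    def test_rapid_fall_expands_upper_limits(self):
        # 1.2*100 = 120 is the static A limit; falling at -1.5 adds 10
        assert p_ega(100, 125, 0.0) == "B"
        assert p_ega(100, 125, -1.5) == "A"
        assert p_ega(100, 138, -2.5) == "A"   # rapid fall adds 20

    def test_rapid_rise_expands_lower_limits(self):
        # 0.8*150 = 120 is the static lower A limit; rising at 1.5 takes 10
        assert p_ega(150, 115, 0.0) == "B"
        assert p_ega(150, 115, 1.5) == "A"
        assert p_ega(150, 102, 2.5) == "A"    # rapid rise takes 20

    @given(st.floats(25, 400), st.floats(-4, 4))
    @settings(max_examples=200, deadline=None)
    def test_diagonal_is_always_zone_a(self, glucose, rate):
        assert p_ega(glucose, glucose, rate) == "A"

    def test_non_positive_glucose_rejected(self):
        with pytest.raises(ValueError):
            p_ega(0.0, 100.0, 0.0)


class TestRateGrid:
    @pytest.mark.parametrize("ref_rate,pred_rate,zone", [
        (0.0, 0.0, "A"),
        (1.0, 1.0, "A"),
        (-3.0, 3.0, "uE"),    # reference falling fast, prediction rising
        (3.0, -3.0, "lE"),
        (0.0, 2.5, "uC"),     # stable reference, spurious rapid rise
        (0.0, -2.5, "lC"),
        (-3.5, 0.0, "uD"),    # rapid fall missed by a flat forecast
        (3.5, 0.0, "lD"),
        (1.0, 2.5, "B"),      # off by 1.5: adjacent band
        (4.0, 2.0, "A"),      # wedge: within a factor of two at high rates
        (-4.0, -2.0, "A"),
    ])
    def test_zone_assignments(self, ref_rate, pred_rate, zone):
        assert r_ega(ref_rate, pred_rate) == zone

    @given(st.floats(-4, 4))
    @settings(max_examples=200, deadline=None)
    def test_diagonal_is_always_zone_a(self, rate):
        assert r_ega(rate, rate) == "A"

    def test_undefined_rate_rejected(self):
        with pytest.raises(ValueError):
            r_ega(np.nan, 0.0)


class TestCgEga:
    def test_perfect_forecast_is_fully_accurate_in_every_region(self):
        rng = np.random.default_rng(1)
        # wander through all three glycemic regions
        ref = np.clip(150 + np.cumsum(rng.normal(0, 8, 400)), 45, 380)
        result = make_result(ref, ref)
        out = cg_ega(result)
        pct = out.percentages
        assert pct["accurate"] == pytest.approx(100.0)
        assert pct["erroneous"] == 0.0
        for region, counts in out.counts.items():
            total = sum(counts.values())
            if total:
                assert counts["accurate"] == total

    def test_category_percentages_partition(self):
        rng = np.random.default_rng(2)
        ref = np.clip(140 + np.cumsum(rng.normal(0, 6, 300)), 40, 400)
        pred = np.clip(ref + rng.normal(0, 25, 300), 40, 400)
        out = cg_ega(make_result(ref, pred))
        assert sum(out.percentages.values()) == pytest.approx(100.0)
        assert sum(sum(c.values()) for c in out.counts.values()) \
            == out.n_evaluated

    def test_flat_euglycemic_slightly_off_is_accurate(self):
        # reference 110 mg/dL, rate 0; prediction 112, rate 0:
        # P-EGA A and R-EGA A combine to accurate in euglycemia
        out = cg_ega(make_result([110, 110, 110], [112, 112, 112]))
        assert out.percentages["accurate"] == pytest.approx(100.0)

    def test_jagged_forecast_penalized_more_than_smoothed(self):
        # a smooth rising reference; a jagged forecast with the right values
        # but oscillating rates vs its moving-average smoothing
        t = np.arange(60)
        ref = 120 + t  # rising 0.2 mg/dL/min
        jagged = ref + np.where(t % 2 == 0, 14.0, -14.0)
        smooth = np.convolve(jagged, np.ones(3) / 3, mode="same")
        smooth[0], smooth[-1] = jagged[0], jagged[-1]
        z_jagged = r_ega(compute_rates(ref, 5.0)[1:],
                         compute_rates(jagged, 5.0)[1:])
        z_smooth = r_ega(compute_rates(ref, 5.0)[1:],
                         compute_rates(smooth, 5.0)[1:])
        assert (z_smooth != "A").sum() <= (z_jagged != "A").sum()
        out_j = cg_ega(make_result(ref, jagged))
        out_s = cg_ega(make_result(ref, smooth))
        assert out_s.percentages["erroneous"] \
            <= out_j.percentages["erroneous"]

    def test_empty_evaluable_set_rejected(self):
        times = pd.DatetimeIndex(["2022-01-01 00:00", "2022-01-01 00:20"])
        r = ForecastResult(times=times,
                           reference_glucose=np.array([100.0, 110.0]),
                           predicted_glucose=np.array([100.0, 110.0]),
                           step_minutes=5.0)
        with pytest.raises(ValueError):
            cg_ega(r)

    def test_point_detail_export_columns(self):
        out = cg_ega(make_result([110, 112, 114], [111, 113, 115]))
        assert list(out.point_detail.columns) == [
            "time", "reference_glucose", "predicted_glucose", "region",
            "p_zone", "r_zone", "category"]


class TestTimeLag:
    def test_constructed_two_sample_delay(self):
        rng = np.random.default_rng(3)
        ref = 140 + np.cumsum(rng.normal(0, 5, 200))
        pred = np.roll(ref, 2)
        result = make_result(ref[2:], pred[2:])
        assert time_lag(result, max_shift_minutes=30) == 10.0

    def test_identity_has_zero_lag(self):
        rng = np.random.default_rng(4)
        ref = 140 + np.cumsum(rng.normal(0, 5, 100))
        assert time_lag(make_result(ref, ref), 30) == 0.0

    def test_matches_exhaustive_shift_oracle(self):
        rng = np.random.default_rng(5)
        t = np.arange(300)
        ref = 150 + 40 * np.sin(2 * np.pi * t / 96)
        pred = 150 + 40 * np.sin(2 * np.pi * (t - 4) / 96) \
            + rng.normal(0, 3, 300)
        result = make_result(ref, pred)
        max_shift = 12
        corrs = [np.corrcoef(pred[s:], ref[:len(ref) - s if s else None])[0, 1]
                 for s in range(max_shift + 1)]
        expected = int(np.argmax(corrs)) * 5.0
        assert time_lag(result, max_shift_minutes=60) == expected

    def test_constant_series_warns_and_reports_zero(self):
        result = make_result(np.full(50, 120.0), np.full(50, 130.0))
        with pytest.warns(RuntimeWarning):
            assert time_lag(result, 30) == 0.0
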