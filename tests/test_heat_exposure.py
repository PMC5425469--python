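import numpy as np
import pytest

from transitloss.heat_exposure import (
    OutOfCalibrationError,
    HeatIndexValue,
    categorize_hi,
    categorize_min_temp,
    classify_week,
    fit_offset_spline,
    heat_index,
    suggest_breakpoints,
)


def nws_heat_index_reference(t, rh):
    """Independent brute-force evaluation of the published NWS polynomial."""
    hi = (
        -42.379
        + 2.04901523 * t
        + 10.14333127 * rh
        - 0.22475541 * t * rh
        - 0.00683783 * t * t
        - 0.05481717 * rh * rh
        + 0.00122874 * t * t * rh
        + 0.00085282 * t * rh * rh
        - 0.00000199 * t * t * rh * rh
    )
    if rh < 13 and 80 <= t <= 112:
        hi -= ((13 - rh) / 4) * ((17 - abs(t - 95)) / 17) ** 0.5
    if rh > 85 and 80 <= t <= 87:
        hi += ((rh - 85) / 10) * ((87 - t) / 5)
    return hi


class TestHeatIndex:
    def test_reference_point(self):
        assert heat_index(90.0, 50.0).hi == pytest.approx(94.60, abs=0.005)

    def test_below_domain_invalid(self):
        v = heat_index(75.0, 60.0)
        assert not v.valid and v.hi is None

    def test_humidity_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            heat_index(90.0, 101.0)
        with pytest.raises(ValueError):
            heat_index(90.0, -1.0)

    def test_monotone_in_humidity(self):
        for t in np.linspace(80, 100, 11):
            his = [heat_index(t, rh).hi for rh in np.arange(40, 101, 5) if rh <= 100]
            assert all(b >= a for a, b in zip(his, his[1:]))

    def test_agrees_with_independent_polynomial_on_grid(self):
        # dense grid over the calibrated domain, including both adjustment
        # regions (low RH and high RH)
        for t in np.linspace(80, 106, 53):
            for rh in np.linspace(0, 100, 101):
                assert heat_index(float(t), float(rh)).hi == pytest.approx(
                    nws_heat_index_reference(float(t), float(rh)), abs=1e-9
                )


class TestCategories:
    @pytest.mark.parametrize(
        "hi,label",
        [(80, "moderate"), (84, "moderate"), (85, "hot"), (86, "hot"),
         (92, "hot"), (93, "very_hot"), (106, "very_hot")],
    )
    def test_hi_bins(self, hi, label):
        assert categorize_hi(HeatIndexValue(float(hi), True)).label == label

    def test_hi_above_calibration_rejected(self):
        with pytest.raises(OutOfCalibrationError):
            categorize_hi(HeatIndexValue(107.0, True))

    @pytest.mark.parametrize(
        "tmin,tavg,label",
        [(45, 60, "cool"), (40, 55, "cool"), (50, 60, "cool"),
         (10, 30, "cold"), (39, 50, "cold"),
         (9, 25, "very_cold"), (-17, 0, "very_cold"),
         (55, 70, "baseline"), (51, 54, "baseline"), (60, 79, "baseline")],
    )
    def test_min_temp_bins(self, tmin, tavg, label):
        assert categorize_min_temp(float(tmin), float(tavg)).label == label

    def test_warm_minimum_hot_average_routes_to_hi_axis(self):
        assert categorize_min_temp(65.0, 85.0) is None

    def test_below_calibration_rejected(self):
        with pytest.raises(OutOfCalibrationError):
            categorize_min_temp(-18.0, 10.0)

    def test_idempotent_on_rounded_boundaries(self):
        # binning on rounded degrees: 84.4 rounds into moderate, 84.6 into hot
        assert categorize_hi(HeatIndexValue(84.4, True)).label == "moderate"
        assert categorize_hi(HeatIndexValue(84.6, True)).label == "hot"

    def test_classification_is_exhaustive_and_disjoint(self):
        rng = np.random.default_rng(11)
        labels = set()
        for _ in range(2000):
            t_min = rng.uniform(-17, 75)
            t_avg = t_min + rng.uniform(2, 25)
            rh = rng.uniform(5, 100)
            cat, reason = classify_week(t_avg, t_min, rh)
            assert (cat is None) != (reason is None)
            if cat is not None:
                labels.add(cat.label)
        assert {"baseline", "cool", "cold", "very_cold", "moderate"} <= labels


class TestBoundsOverride:
    def test_baseline_variant_50_79(self):
        # the documented alternative baseline lower bound (50 °F): a mild
        # 52 °F-average week becomes baseline instead of unclassifiable
        from transitloss.heat_exposure import override_category_bounds

        with pytest.raises(OutOfCalibrationError):
            categorize_min_temp(51.0, 52.0)
        prev = override_category_bounds({("BASELINE", "baseline"): (50, 79)})
        try:
            assert categorize_min_temp(51.0, 52.0).label == "baseline"
        finally:
            override_category_bounds(prev)
        with pytest.raises(OutOfCalibrationError):
            categorize_min_temp(51.0, 52.0)

    def test_unknown_key_rejected(self):
        from transitloss.heat_exposure import override_category_bounds

        with pytest.raises(KeyError):
            override_category_bounds({("HI", "scorching"): (107, 120)})


class TestOffsetSpline:
    def test_flat_truth_recovers_constant_rate(self):
        rng = np.random.default_rng(0)
        n = 2000
        x = rng.uniform(50, 100, n)
        total = rng.integers(100, 5000, n)
        rate = 0.003
        y = total * rate
        fit = fit_offset_spline(x, y, total)
        assert np.all(np.abs(fit.intensity - rate) < 0.05 * rate)

    def test_step_change_located(self):
        rng = np.random.default_rng(1)
        n = 5000
        x = rng.uniform(60, 100, n)
        total = rng.integers(500, 5000, n)
        rate = np.where(x > 85, 0.006, 0.002)
        y = rng.binomial(total, rate)
        fit = fit_offset_spline(x, y, total)
        slope = np.gradient(fit.intensity, fit.grid)
        assert abs(fit.grid[np.argmax(slope)] - 85.0) <= 2.0

    def test_weights_pull_fit_toward_heavy_subset(self):
        rng = np.random.default_rng(2)
        n = 1000
        x = np.concatenate([rng.uniform(60, 100, n), rng.uniform(60, 100, n)])
        lo = np.full(n, 200)
        hi = np.full(n, 200)
        total = np.concatenate([lo, hi])
        rate = np.concatenate([np.full(n, 0.002), np.full(n, 0.006)])
        y = (total * rate).astype(int)
        base = fit_offset_spline(x, y, total, smoothing=1.0).intensity.mean()
        total2 = np.concatenate([lo, hi * 8])
        y2 = (total2 * rate).astype(int)
        heavy = fit_offset_spline(x, y2, total2, smoothing=1.0).intensity.mean()
        assert heavy > base  # doubling the high-rate subset's head pulls up

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            fit_offset_spline(np.full(20, 70.0), np.zeros(20), np.full(20, 100))
        with pytest.raises(ValueError):
            fit_offset_spline(np.linspace(0, 1, 20), np.zeros(20), np.full(20, 0.5))


class TestBreakpoints:
    def test_flat_curve_falls_back_to_quantiles(self):
        grid = np.linspace(50, 100, 257)
        from transitloss.heat_exposure import SplineFit

        fit = SplineFit(grid=grid, intensity=np.full(257, 0.003), smoothing=None,
                        offset_used=True)
        pts = suggest_breakpoints(fit, 3)
        assert len(pts) == 3
        assert pts == pytest.approx(list(np.quantile(grid, [0.25, 0.5, 0.75])))

    def test_single_jump_detected(self):
        rng = np.random.default_rng(4)
        n = 4000
        x = rng.uniform(60, 100, n)
        total = rng.integers(500, 5000, n)
        rate = np.where(x > 82, 0.007, 0.002)
        y = rng.binomial(total, rate)
        fit = fit_offset_spline(x, y, total)
        pts = suggest_breakpoints(fit, 1)
        assert len(pts) == 1
        assert abs(pts[0] - 82.0) <= 2.0

    def test_k_validation(self):
        grid = np.linspace(50, 100, 257)
        from transitloss.heat_exposure import SplineFit

        fit = SplineFit(grid=grid, intensity=np.full(257, 0.003), smoothing=None,
                        offset_used=True)
        with pytest.raises(ValueError):
            suggest_breakpoints(fit, 0)
        with pytest.raises(ValueError):
            suggest_breakpoints(fit, 300)
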