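"""Slope classification, correction-factor calibration, curve agreement."""

import numpy as np
import pytest

from rdfd import (
    AltitudeCorrection,
    AltitudeProfile,
    calibrate_delta,
    classify_slope,
    curve_agreement,
    evaluate_delta,
    flat_segment_check,
    pointwise_delta,
    revise_dfd,
)
from rdfd.correction import DeltaPairs, slope_class_at
from rdfd.fatigue import DFDSeries
from rdfd.reference import (
    CALIBRATION_ALTITUDE_RANGE,
    DOWNSLOPE_CORRECTION_COEFS,
    UPSLOPE_CORRECTION_COEFS,
    downslope_correction_model,
    upslope_correction_model,
)

pv = np.polynomial.polynomial.polyval


class TestClassifySlope:
    def test_strictly_increasing_profile_is_up(self):
        t = np.arange(0.0, 3600.0, 10.0)
        profile = AltitudeProfile(times=t, altitudes=3500.0 + 0.3 * t)
        segments = classify_slope(profile)
        assert [s.slope_class for s in segments] == ["up"]

    def test_plateau_route_up_down_up(self):
        # valley -> highest pass -> basin dip -> plateau terminus
        knots_t = [0.0, 3600.0, 7200.0, 9000.0]
        knots_h = [3540.0, 4768.0, 4476.0, 4663.0]
        t = np.arange(0.0, 9000.0, 10.0)
        profile = AltitudeProfile(times=t, altitudes=np.interp(t, knots_t, knots_h))
        segments = classify_slope(profile)
        assert [s.slope_class for s in segments] == ["up", "down", "up"]
        assert segments[0].mean_gradient > 0 > segments[1].mean_gradient

    def test_constant_altitude_is_flat(self):
        t = np.arange(0.0, 3600.0, 10.0)
        profile = AltitudeProfile(times=t, altitudes=np.full(t.size, 4500.0))
        segments = classify_slope(profile)
        assert [s.slope_class for s in segments] == ["flat"]

    def test_segments_partition_span(self):
        t = np.arange(0.0, 9000.0, 10.0)
        h = 4000.0 + 500.0 * np.sin(2 * np.pi * t / 6000.0)
        profile = AltitudeProfile(times=t, altitudes=h)
        segments = classify_slope(profile)
        assert segments[0].start == t[0]
        assert segments[-1].end == t[-1]
        for a, b in zip(segments, segments[1:]):
            assert a.end == b.start
        classes = slope_class_at(segments, np.linspace(0.0, 8990.0, 50))
        assert set(classes) <= {"up", "down", "flat"}


class TestPointwiseDelta:
    def _series(self, values, source):
        t = 60.0 + 120.0 * np.arange(len(values))
        return DFDSeries(times=t, values=np.asarray(values, float), source=source)

    def test_delta_is_ratio(self):
        hrv = self._series([1.0] * 6, "hrv")
        blink = self._series([2.0] * 6, "blink")
        pairs = pointwise_delta(blink, hrv, np.full(6, 4000.0))
        assert np.allclose(pairs.deltas, 2.0)
        assert np.allclose(pairs.altitudes, 4000.0)

    def test_near_zero_hrv_windows_excluded(self):
        hrv = self._series([0.01, 1.0, 1.0, 1.0, 1.0, 1.0], "hrv")
        blink = self._series([5.0, 2.0, 2.0, 2.0, 2.0, 2.0], "blink")
        pairs = pointwise_delta(blink, hrv, np.full(6, 4000.0), epsilon=0.05)
        assert pairs.n_excluded == 1
        assert len(pairs) == 5

    def test_identical_series_delta_one(self):
        hrv = self._series(np.linspace(0.5, 3.0, 8), "hrv")
        blink = self._series(np.linspace(0.5, 3.0, 8), "blink")
        pairs = pointwise_delta(blink, hrv, np.full(8, 4200.0))
        assert np.allclose(pairs.deltas, 1.0)

    def test_insufficient_support_raises(self):
        hrv = self._series([0.01] * 6, "hrv")
        blink = self._series([1.0] * 6, "blink")
        with pytest.raises(ValueError, match="insufficient calibration support"):
            pointwise_delta(blink, hrv, np.full(6, 4000.0))


class TestCalibrateDelta:
    def test_noiseless_recovery_of_field_coefficients(self, rng):
        lo, hi = CALIBRATION_ALTITUDE_RANGE
        h = rng.uniform(lo, hi, 200)
        pairs = DeltaPairs(altitudes=h, deltas=pv(h, UPSLOPE_CORRECTION_COEFS),
                           times=np.arange(200.0))
        model = calibrate_delta(pairs, slope_class="up")
        rel = np.abs(model.coef_ - UPSLOPE_CORRECTION_COEFS) / np.abs(
            UPSLOPE_CORRECTION_COEFS
        )
        assert rel.max() < 1e-6

    def test_single_altitude_design_rejected(self):
        pairs = DeltaPairs(altitudes=np.full(10, 4000.0), deltas=np.ones(10),
                           times=np.arange(10.0))
        with pytest.raises(ValueError, match="ill-conditioned"):
            calibrate_delta(pairs)

    def test_noisy_recovery_within_five_percent(self):
        """Bounded 5% multiplicative noise, 100 pairs: fitted curve stays
        within 5% of truth across the range in >= 95% of seeds."""
        lo, hi = CALIBRATION_ALTITUDE_RANGE
        grid = np.linspace(lo, hi, 100)
        truth = pv(grid, UPSLOPE_CORRECTION_COEFS)
        hits = 0
        n_seeds = 200
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            h = rng.uniform(lo, hi, 100)
            noisy = pv(h, UPSLOPE_CORRECTION_COEFS) * (
                1 + rng.uniform(-0.05, 0.05, 100)
            )
            model = AltitudeCorrection().fit(h, noisy)
            est = pv(grid, model.coef_)
            hits += np.max(np.abs(est - truth) / truth) <= 0.05
        assert hits / n_seeds >= 0.95


class TestEvaluateDelta:
    def test_upslope_model_at_sea_level(self):
        assert evaluate_delta(upslope_correction_model(), 0.0) == pytest.approx(
            366.711
        )

    def test_downslope_model_at_sea_level(self):
        assert evaluate_delta(downslope_correction_model(), 0.0) == pytest.approx(
            493.703
        )

    def test_upslope_model_mid_route(self):
        value = evaluate_delta(upslope_correction_model(), 4000.0)
        assert value == pytest.approx(4.375, abs=1e-9)

    def test_extrapolation_beyond_calibration_range_warns(self):
        with pytest.warns(UserWarning, match="calibration"):
            evaluate_delta(upslope_correction_model(), 5000.0)

    def test_horner_matches_naive_summation(self):
        h = np.linspace(*CALIBRATION_ALTITUDE_RANGE, 50)
        for coefs in (UPSLOPE_CORRECTION_COEFS, DOWNSLOPE_CORRECTION_COEFS):
            model = AltitudeCorrection.from_coefficients(coefs)
            naive = sum(c * h**k for k, c in enumerate(coefs))
            assert np.allclose(model.predict(h), naive, rtol=1e-9)


class TestReviseDFD:
    def _hrv(self, values):
        t = 60.0 + 120.0 * np.arange(len(values))
        return DFDSeries(times=t, values=np.asarray(values, float), source="hrv")

    def test_identity_correction(self):
        hrv = self._hrv([0.5, 1.0, 2.0])
        model = AltitudeCorrection.from_coefficients([1.0])
        out = revise_dfd(hrv, model, np.full(3, 4000.0))
        assert np.allclose(out.values, hrv.values)
        assert out.source == "revised"

    def test_zero_dfd_stays_zero_and_homogeneous(self):
        model = AltitudeCorrection.from_coefficients(UPSLOPE_CORRECTION_COEFS,
                                                     h_range=(3540.0, 4768.0))
        h = np.linspace(3600.0, 4700.0, 5)
        base = self._hrv([0.0, 0.5, 1.0, 1.5, 2.0])
        out1 = revise_dfd(base, model, h)
        assert out1.values[0] == 0.0
        scaled = self._hrv(3.0 * base.values)
        out3 = revise_dfd(scaled, model, h)
        assert np.allclose(out3.values, 3.0 * out1.values)

    def test_simple_product(self):
        model = AltitudeCorrection.from_coefficients([2.0])
        out = revise_dfd(self._hrv([0.5]), model, [4000.0])
        assert out.values[0] == pytest.approx(1.0)

    def test_missing_class_model_raises(self):
        hrv = self._hrv([1.0, 1.0])
        models = {"up": AltitudeCorrection.from_coefficients([1.0])}
        with pytest.raises(ValueError, match="no correction model"):
            revise_dfd(hrv, models, [4000.0, 4100.0],
                       slope_classes=["up", "down"])

    def test_flat_class_defaults_to_unit_delta(self):
        hrv = self._hrv([1.0, 2.0])
        models = {"up": AltitudeCorrection.from_coefficients([3.0])}
        out = revise_dfd(hrv, models, [4000.0, 4100.0],
                         slope_classes=["up", "flat"])
        assert np.allclose(out.values, [3.0, 2.0])


class TestCurveAgreement:
    def _pair(self, a_vals, b_vals):
        t = 60.0 + 120.0 * np.arange(len(a_vals))
        return (DFDSeries(times=t, values=np.asarray(a_vals, float), source="hrv"),
                DFDSeries(times=t, values=np.asarray(b_vals, float), source="blink"))

    def test_identical_series(self):
        a, b = self._pair([1.0, 2.0, 3.0, 4.0], [1.0, 2.0, 3.0, 4.0])
        ca = curve_agreement(a, b)
        assert ca.ss_diff == 0.0
        assert ca.r_squared == pytest.approx(1.0)

    def test_exact_affine_relation(self):
        av = np.array([1.0, 2.0, 3.0, 5.0])
        a, b = self._pair(av, 2 * av + 1)
        ca = curve_agreement(a, b)
        assert ca.r_squared == pytest.approx(1.0)
        assert ca.ss_diff == pytest.approx(np.sum((av + 1.0) ** 2))

    def test_too_few_points_raises(self):
        a, b = self._pair([1.0, 2.0], [1.0, 2.0])
        with pytest.raises(ValueError, match="at least 3"):
            curve_agreement(a, b)

    def test_independent_noise_is_not_significant(self):
        """Monte-Carlo null: unrelated series rarely show agreement."""
        nonsig = 0
        n_seeds = 200
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            a, b = self._pair(rng.standard_normal(50), rng.standard_normal(50))
            nonsig += curve_agreement(a, b).f_pvalue > 0.05
        assert nonsig / n_seeds >= 0.90


class TestFlatSegmentCheck:
    def test_altitude_independent_delta_not_rejected(self):
        nonsig = 0
        n_seeds = 200
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            h = rng.uniform(4400.0, 4550.0, 40)
            delta = 1.0 + rng.normal(0.0, 0.1, 40)
            nonsig += flat_segment_check(h, delta).f_pvalue >= 0.05
        assert nonsig / n_seeds >= 0.90

    def test_linear_dependence_detected(self):
        h = np.linspace(4000.0, 4500.0, 30)
        report = flat_segment_check(h, 0.5 + 0.001 * h)
        assert report.f_pvalue < 1e-6
        assert not report.altitude_independent

    def test_constant_delta_zero_slope(self):
        report = flat_segment_check(np.linspace(4000.0, 4500.0, 20), np.ones(20))
        assert report.slope == 0.0
        assert report.f_statistic == 0.0
        assert report.altitude_independent
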