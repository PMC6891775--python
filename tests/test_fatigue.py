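"""Windowed HRV statistics, fatigue-degree algebra, window selection."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import brute_force_window_stats
from rdfd import (
    FatigueBaselines,
    FatigueDegree,
    RRISeries,
    blink_dfd,
    cohort_average,
    compute_baselines,
    compute_fatigue_metrics,
    compute_rrvc,
    window_hrv,
)
from rdfd.fatigue import (
    HRVWindow,
    WindowSelectionError,
    apply_selection_rule,
    summarize_selection,
)
from rdfd.reference import reference_window_table


def _series(intervals_ms, t0=0.0):
    times = t0 + np.cumsum(np.asarray(intervals_ms, dtype=float) / 1000.0)
    return RRISeries(times=times, intervals=intervals_ms)


class TestWindowHRV:
    def test_single_window_statistics(self):
        rr = _series([1000.0, 1010.0, 990.0, 1005.0])
        (w,) = window_hrv(rr, window_length=5.0, min_beats=2)
        m, sdnn, rrvc = brute_force_window_stats(rr.intervals)
        assert w.m_ms == pytest.approx(1001.25)
        assert w.sdnn_ms == pytest.approx(8.539126, rel=1e-6)
        assert w.rrvc == pytest.approx(0.008528465, rel=1e-6)
        assert (w.m_ms, w.sdnn_ms, w.rrvc) == pytest.approx((m, sdnn, rrvc))

    def test_constant_intervals_zero_variance(self):
        rr = _series(np.full(200, 1000.0))
        windows = window_hrv(rr, window_length=60.0)
        assert all(w.sdnn_ms == 0.0 and w.rrvc == 0.0 for w in windows)

    def test_beats_partition_into_windows(self):
        rr = _series(np.full(600, 1000.0))
        windows = window_hrv(rr, window_length=120.0)
        assert len(windows) == 5
        assert sum(w.n_beats for w in windows) == 600 - sum(
            1 for t in rr.times if t >= windows[-1].end
        )
        # no window overlap, contiguous grid
        for a, b in zip(windows, windows[1:]):
            assert b.start == a.end

    def test_low_beat_windows_rejected(self):
        rr = _series(np.full(10, 1000.0))
        with pytest.raises(ValueError, match="minimum beat count"):
            window_hrv(rr, window_length=5.0, min_beats=10)

    def test_matches_bruteforce_on_random_series(self, rng):
        for _ in range(20):
            iv = rng.uniform(600.0, 1200.0, 300)
            rr = _series(iv)
            for w in window_hrv(rr, window_length=30.0, min_beats=5):
                mask = (rr.times >= w.start) & (rr.times < w.end)
                m, sdnn, rrvc = brute_force_window_stats(rr.intervals[mask])
                assert w.m_ms == pytest.approx(m, rel=1e-12)
                assert w.sdnn_ms == pytest.approx(sdnn, rel=1e-12)
                assert w.rrvc == pytest.approx(rrvc, rel=1e-12)


class TestRRVCAndBaselines:
    @pytest.mark.parametrize(
        "sdnn,m,expected",
        [(50.0, 1000.0, 0.05), (0.0, 800.0, 0.0),
         (8.539126, 1001.25, 0.008528465)],
    )
    def test_rrvc_ratio(self, sdnn, m, expected):
        assert compute_rrvc(sdnn, m) == pytest.approx(expected, rel=1e-6)

    def test_rrvc_rejects_nonpositive_mean(self):
        with pytest.raises(ValueError):
            compute_rrvc(10.0, 0.0)

    def test_bdf_is_initial_minus_static(self):
        base = FatigueBaselines(rrvc_static=0.03, rrvc_initial=0.05)
        assert base.bdf == pytest.approx(0.02)

    def test_identical_baselines_degenerate(self):
        with pytest.raises(ValueError, match="degenerate baseline"):
            FatigueBaselines(rrvc_static=0.05, rrvc_initial=0.05)

    def test_initial_from_mean_of_first_k_windows(self):
        wins = [
            HRVWindow(1, 0, 120, 1000.0, 50.0, 0.05, 100),
            HRVWindow(2, 120, 240, 1000.0, 70.0, 0.07, 100),
        ]
        base = compute_baselines(None, wins, k=2, rrvc_static=0.03)
        assert base.rrvc_initial == pytest.approx(0.06)


class TestFatigueMetrics:
    def _windows(self, rrvcs):
        return [
            HRVWindow(i + 1, 120.0 * i, 120.0 * (i + 1), 1000.0,
                      1000.0 * v, v, 100)
            for i, v in enumerate(rrvcs)
        ]

    @pytest.mark.parametrize("rrvc_i,expected", [(0.07, 1.0), (0.05, 0.0),
                                                 (0.09, 2.0)])
    def test_dfd_values(self, rrvc_i, expected):
        base = FatigueBaselines(rrvc_static=0.03, rrvc_initial=0.05)
        metrics, series = compute_fatigue_metrics(self._windows([rrvc_i]), base)
        assert series.values[0] == pytest.approx(expected)

    @given(st.lists(st.floats(min_value=0.001, max_value=0.5), min_size=1,
                    max_size=30),
           st.floats(min_value=0.001, max_value=0.2),
           st.floats(min_value=0.005, max_value=0.2))
    @settings(max_examples=100, deadline=None)
    def test_algebraic_identities(self, rrvcs, static, bdf):
        base = FatigueBaselines(rrvc_static=static, rrvc_initial=static + bdf)
        metrics, _ = compute_fatigue_metrics(self._windows(rrvcs), base)
        assert np.allclose(metrics.fc - metrics.dfc, base.bdf, rtol=1e-12,
                           atol=1e-15)
        assert np.allclose(metrics.dfd * base.bdf, metrics.dfc, rtol=1e-12,
                           atol=1e-15)

    def test_dfd_strictly_increasing_in_rrvc(self):
        base = FatigueBaselines(rrvc_static=0.03, rrvc_initial=0.05)
        rrvcs = np.linspace(0.01, 0.3, 50)
        _, series = compute_fatigue_metrics(self._windows(rrvcs), base)
        assert np.all(np.diff(series.values) > 0)

    def test_dfd_invariant_under_interval_rescaling(self, rng):
        iv = rng.uniform(700.0, 1100.0, 600)
        times = np.cumsum(iv / 1000.0)
        for c in (0.5, 2.0, 3.7):
            rr1 = RRISeries(times=times, intervals=iv)
            rr2 = RRISeries(times=times, intervals=c * iv)
            w1 = window_hrv(rr1, 60.0)
            w2 = window_hrv(rr2, 60.0)
            b1 = compute_baselines(None, w1, rrvc_static=0.01)
            b2 = compute_baselines(None, w2, rrvc_static=0.01)
            _, s1 = compute_fatigue_metrics(w1, b1)
            _, s2 = compute_fatigue_metrics(w2, b2)
            assert np.allclose(s1.values, s2.values, rtol=1e-10)


class TestFatigueDegreeTransformer:
    def test_fit_transform_matches_formula(self):
        est = FatigueDegree(rrvc_static=0.03, k=1)
        x = np.array([0.05, 0.07, 0.09])
        out = est.fit_transform(x)
        assert np.allclose(out, [0.0, 1.0, 2.0])
        assert np.allclose(est.inverse_transform(out), x)

    def test_sklearn_param_interface(self):
        est = FatigueDegree(rrvc_static=0.03)
        assert est.get_params()["rrvc_static"] == 0.03
        est.set_params(k=2)
        assert est.k == 2


class TestCohortAverage:
    def test_single_driver_identity(self):
        wins = [HRVWindow(1, 0, 120, 1000.0, 50.0, 0.05, 100)]
        (out,) = cohort_average([wins])
        assert (out.m_ms, out.sdnn_ms, out.rrvc) == (1000.0, 50.0, 0.05)

    def test_parameters_averaged_then_ratio(self):
        a = [HRVWindow(1, 0, 120, 800.0, 40.0, 0.05, 90)]
        b = [HRVWindow(1, 0, 120, 1200.0, 60.0, 0.05, 110)]
        (out,) = cohort_average([a, b])
        assert out.m_ms == pytest.approx(1000.0)
        assert out.sdnn_ms == pytest.approx(50.0)
        assert out.rrvc == pytest.approx(0.05)
        assert out.n_drivers == 2

    def test_disjoint_coverage_averages_contributors_only(self):
        a = [HRVWindow(1, 0, 120, 800.0, 40.0, 0.05, 90)]
        b = [HRVWindow(1, 120, 240, 1200.0, 60.0, 0.05, 110)]
        out = cohort_average([a, b])
        assert len(out) == 2
        assert all(w.n_drivers == 1 for w in out)

    def test_empty_cohort_raises(self):
        with pytest.raises(ValueError):
            cohort_average([])


class TestBlinkDFD:
    @pytest.mark.parametrize("bf,expected", [(15.0, 0.0), (20.0, 1.0),
                                             (25.0, 2.0)])
    def test_structural_analogue(self, bf, expected):
        base = FatigueBaselines(rrvc_static=0.03, rrvc_initial=0.05,
                                bf_static=10.0, bf_initial=15.0)
        series = blink_dfd([60.0], [bf], base)
        assert series.values[0] == pytest.approx(expected)
        assert series.source == "blink"

    def test_degenerate_blink_baseline(self):
        with pytest.raises(ValueError, match="degenerate blink baseline"):
            FatigueBaselines(rrvc_static=0.03, rrvc_initial=0.05,
                             bf_static=15.0, bf_initial=15.0)


class TestWindowSelection:
    def test_field_table_default_rule_prefers_two_minutes(self):
        assert apply_selection_rule(reference_window_table(), "default") == 120.0

    def test_field_table_min_f_rule_picks_three_minutes(self):
        assert apply_selection_rule(reference_window_table(), "min-F") == 180.0

    def test_rule_disagreement_is_flagged(self):
        summary = summarize_selection(reference_window_table())
        assert summary == {"default": 120.0, "min_f": 180.0,
                           "rules_agree": False}

    def test_single_significant_candidate_wins_under_either_rule(self):
        import pandas as pd

        table = pd.DataFrame({"window_s": [60.0], "sig_f": [0.01], "f": [30.0]})
        assert apply_selection_rule(table, "default") == 60.0
        assert apply_selection_rule(table, "min-F") == 60.0

    def test_no_significant_candidate_raises_with_table(self):
        import pandas as pd

        table = pd.DataFrame({"window_s": [60.0, 120.0], "sig_f": [0.3, 0.6],
                              "f": [1.0, 0.5]})
        with pytest.raises(WindowSelectionError) as err:
            apply_selection_rule(table)
        assert err.value.table.shape == (2, 3)
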