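"""Tests for smoothing, QC, landmark calling and fluctuation statistics."""

import numpy as np
import pytest
from scipy import stats

from cdk2fluct.config import StressModelConfig, WashoutProtocol
from cdk2fluct import synth_traces as st
from cdk2fluct import trace_analysis as ta


class TestSmoothing:
    def test_constant_trace_unchanged(self, toy_trace_factory):
        tr = toy_trace_factory(np.arange(5) * 0.2, np.full(5, 0.7))
        np.testing.assert_allclose(ta.smooth_trace(tr).ratio, tr.ratio, rtol=1e-12)

    def test_three_point_mean(self, toy_trace_factory):
        tr = toy_trace_factory([0.0, 0.2, 0.4], [0.0, 3.0, 0.0])
        sm = ta.smooth_trace(tr, window=3)
        assert sm.ratio[1] == pytest.approx(1.0)

    def test_white_noise_variance_reduced_threefold(self, rng, toy_trace_factory):
        x = rng.normal(0, 1, 3000)
        tr = toy_trace_factory(np.arange(3000) * 0.2, x)
        sm = ta.smooth_trace(tr, window=3)
        assert np.var(sm.ratio[1:-1]) == pytest.approx(np.var(x) / 3, rel=0.1)

    def test_even_or_oversized_window_rejected(self, toy_trace_factory):
        tr = toy_trace_factory(np.arange(4) * 0.2, np.zeros(4))
        with pytest.raises(ValueError):
            ta.smooth_trace(tr, window=2)
        with pytest.raises(ValueError):
            ta.smooth_trace(tr, window=5)


class TestQcFilter:
    def test_equal_expression_keeps_everyone(self, toy_trace_factory):
        traces = [
            toy_trace_factory(np.arange(10) * 0.2, np.full(10, 0.5), cell_id=i)
            for i in range(100)
        ]
        kept, removed = ta.qc_filter(traces)
        assert len(kept) == 100 and not removed

    def test_jump_threshold_is_a_quarter_ratio_unit(self, toy_trace_factory):
        t = np.arange(6) * 0.2
        noisy = toy_trace_factory(t, [0.5, 0.5, 0.8, 0.8, 0.8, 0.8])  # 0.30 jump
        ok = toy_trace_factory(t, [0.5, 0.5, 0.7, 0.7, 0.7, 0.7])  # 0.20 jump
        kept, removed = ta.qc_filter([noisy, ok], expression_percentile=0)
        assert [tr.cell_id for tr, reason in removed] == [noisy.cell_id]
        assert removed[0][1] == "noisy"
        assert kept == [ok]

    def test_bottom_five_percent_expression_removed(self, toy_trace_factory):
        t = np.arange(10) * 0.2
        traces = []
        for i in range(100):
            nuc = np.zeros(10) if i < 5 else np.full(10, 1.0)
            traces.append(
                toy_trace_factory(t, np.full(10, 0.5), nuc=nuc, cell_id=i)
            )
        kept, removed = ta.qc_filter(traces)
        assert sorted(tr.cell_id for tr, _ in removed) == list(range(5))
        assert all(reason == "low_expression" for _, reason in removed)


class TestLandmarkCalling:
    def test_flat_trace_has_no_rise(self, toy_trace_factory):
        tr = toy_trace_factory(np.arange(50) * 0.2, np.full(50, 0.3))
        assert ta.call_cdk2_rise(tr) is None

    def test_noise_free_rise_called_within_two_frames(self, quiet_config):
        cell = st.simulate_population(quiet_config, n_cells=1, seed=0)[0]
        call = ta.call_cdk2_rise(ta.smooth_trace(cell.trace))
        assert call == pytest.approx(cell.true_cdk2_rise, abs=0.4)

    def test_rise_error_small_over_noisy_cohort(self, cycling_population):
        errors = []
        for cell in cycling_population:
            call = ta.call_cdk2_rise(ta.smooth_trace(cell.trace))
            if call is not None:
                errors.append(abs(call - cell.true_cdk2_rise))
        assert len(errors) > 0.95 * len(cycling_population)
        assert np.median(errors) < 0.4

    def test_zero_degron_never_calls_apc(self, toy_trace_factory):
        tr = toy_trace_factory(np.arange(50) * 0.2, np.full(50, 0.3))
        assert ta.call_apc_inactivation(tr) is None

    def test_noise_free_apc_called_within_two_frames(self, quiet_config):
        cell = st.simulate_population(quiet_config, n_cells=1, seed=0)[0]
        call = ta.call_apc_inactivation(cell.trace)
        assert call == pytest.approx(cell.true_apc_inactivation, abs=0.4)

    def test_cohort_lag_recovers_configured_degron_lag(self, cycling_population):
        lags = []
        for cell in cycling_population:
            rise = ta.call_cdk2_rise(ta.smooth_trace(cell.trace))
            apc = ta.call_apc_inactivation(cell.trace)
            if rise is not None and apc is not None:
                lags.append(apc - rise)
        assert np.mean(lags) == pytest.approx(3.0, abs=0.3)


class TestFluctuationPolyfit:
    def test_cubic_trace_has_zero_deviation(self, toy_trace_factory):
        t = np.arange(40) * 0.2
        tr = toy_trace_factory(t, 0.01 * t**3 - 0.05 * t**2 + 0.1 * t + 0.2)
        _, dev = ta.fluctuation_polyfit(tr, 0.0, activity_gate=np.inf)
        assert np.max(dev) < 1e-18

    def test_cubic_invariance_of_the_score(self, rng, toy_trace_factory):
        t = np.arange(40) * 0.2
        base = rng.normal(0.5, 0.05, len(t))
        shift = 0.3 + 0.02 * t - 0.01 * t**2 + 0.004 * t**3
        _, dev_a = ta.fluctuation_polyfit(
            toy_trace_factory(t, base), 0.0, activity_gate=np.inf
        )
        _, dev_b = ta.fluctuation_polyfit(
            toy_trace_factory(t, base + shift), 0.0, activity_gate=np.inf
        )
        np.testing.assert_allclose(dev_a, dev_b, atol=1e-10)

    def test_sine_residual_mean_square_is_half_amplitude_squared(
        self, toy_trace_factory
    ):
        t = np.arange(0, 8.0, 0.2)
        a = 0.05
        ratio = 0.3 + 0.05 * t + a * np.sin(2 * np.pi * t / 1.5)
        _, dev = ta.fluctuation_polyfit(toy_trace_factory(t, ratio), 0.0)
        assert np.mean(dev) == pytest.approx(a**2 / 2, rel=0.15)

    def test_scale_behavior_is_quadratic(self, rng, toy_trace_factory):
        t = np.arange(40) * 0.2
        x = rng.normal(0.5, 0.05, len(t))
        mean_fit = np.polyval(np.polyfit(t, x, 3), t)
        scaled = mean_fit + 3.0 * (x - mean_fit)
        _, dev1 = ta.fluctuation_polyfit(
            toy_trace_factory(t, x), 0.0, activity_gate=np.inf
        )
        _, dev3 = ta.fluctuation_polyfit(
            toy_trace_factory(t, scaled), 0.0, activity_gate=np.inf
        )
        np.testing.assert_allclose(dev3, 9.0 * dev1, rtol=1e-6)

    def test_stressed_cells_fluctuate_more_than_dipless(self):
        stressed = st.simulate_population(
            StressModelConfig(), n_cells=80, seed=3
        )
        calm = st.simulate_population(
            StressModelConfig(n_events=0), n_cells=80, seed=3
        )
        def mean_profile(cells):
            series = []
            for c in cells:
                series.append(
                    ta.fluctuation_polyfit(
                        ta.smooth_trace(c.trace), c.true_cdk2_rise
                    )
                )
            return ta.population_profile(series)
        prof_s = mean_profile(stressed)
        prof_c = mean_profile(calm)
        # compare on the S-phase part of the shared aligned axis (rise + 3 h on)
        shared = np.intersect1d(prof_s.aligned_time, prof_c.aligned_time)
        late = shared[shared >= 3.5]
        s_vals = prof_s.mean_sq_dev[np.isin(prof_s.aligned_time, late)]
        c_vals = prof_c.mean_sq_dev[np.isin(prof_c.aligned_time, late)]
        assert np.all(s_vals > c_vals)

    def test_short_segment_is_rejected(self, toy_trace_factory):
        tr = toy_trace_factory(np.arange(10) * 0.2, np.full(10, 0.5))
        with pytest.raises(ValueError):
            ta.fluctuation_polyfit(tr, 1.4)


class TestSecondDerivativeScore:
    def test_linear_trace_scores_zero(self, toy_trace_factory):
        t = np.arange(30) * 0.2
        _, score = ta.fluctuation_second_derivative(
            toy_trace_factory(t, 0.1 * t + 0.2), 0.0
        )
        np.testing.assert_allclose(score, 0.0, atol=1e-20)

    def test_quadratic_trace_scores_curvature_squared(self, toy_trace_factory):
        t = np.arange(30) * 0.2
        c = 0.3
        _, score = ta.fluctuation_second_derivative(
            toy_trace_factory(t, 0.5 * c * t**2), 0.0
        )
        np.testing.assert_allclose(score, c**2, rtol=1e-8)

    def test_rank_concordance_with_polyfit_score(self):
        """Both fluctuation scores order dip amplitudes the same way."""
        poly_means, d2_means = [], []
        for amp in (0.0, 0.04, 0.08, 0.12):
            cells = st.simulate_population(
                StressModelConfig(amplitude=amp), n_cells=50, seed=5
            )
            p, d = [], []
            for c in cells:
                sm = ta.smooth_trace(c.trace)
                p.append(np.mean(ta.fluctuation_polyfit(sm, c.true_cdk2_rise)[1]))
                d.append(
                    np.mean(ta.fluctuation_second_derivative(sm, c.true_cdk2_rise)[1])
                )
            poly_means.append(np.mean(p))
            d2_means.append(np.mean(d))
        tau = stats.kendalltau(poly_means, d2_means).statistic
        assert tau > 0.8


class TestPopulationProfile:
    def test_identical_cells_have_zero_sem(self):
        t = np.arange(5) * 0.2
        series = [(t, np.full(5, 0.3))] * 4
        prof = ta.population_profile(series)
        np.testing.assert_array_equal(prof.sem, 0.0)

    def test_mean_and_sem_arithmetic(self):
        t = np.array([0.0])
        prof = ta.population_profile([(t, [0.0]), (t, [2.0])])
        assert prof.mean_sq_dev[0] == pytest.approx(1.0)
        assert prof.sem[0] == pytest.approx(1.0)
        assert prof.n[0] == 2


class TestSlopeAndDrugResponse:
    def test_exact_line_slope_recovered(self, toy_trace_factory):
        t = np.arange(0, 12, 0.2)
        tr = toy_trace_factory(t, 0.8 + 0.08 * t)
        assert ta.s_phase_slope(tr, 0.0) == pytest.approx(0.08)

    def test_plateauing_trace_is_excluded(self, toy_trace_factory):
        t = np.arange(0, 12, 0.2)
        tr = toy_trace_factory(t, np.minimum(0.8 + 0.08 * t, 1.2))
        assert ta.s_phase_slope(tr, 0.0) is None

    def test_stressed_cohort_has_smaller_slope(self):
        cfg = StressModelConfig(ramp_slope=0.22, ramp_offset=0.66)
        stressed = st.simulate_population(cfg, n_cells=60, seed=9)
        calm = st.simulate_population(cfg.replace(n_events=0), n_cells=60, seed=9)
        def slopes(cells):
            out = []
            for c in cells:
                s = ta.s_phase_slope(
                    ta.smooth_trace(c.trace), c.true_apc_inactivation
                )
                if s is not None:
                    out.append(s)
            return out
        s_str, s_calm = slopes(stressed), slopes(calm)
        assert np.median(s_calm) > np.median(s_str)
        assert stats.mannwhitneyu(s_calm, s_str, alternative="greater").pvalue < 0.01

    def test_percent_change_arithmetic(self, toy_trace_factory):
        t = np.arange(0, 4, 0.2)
        ratio = np.where(t < 1.0, 1.0, 0.8)
        tr = toy_trace_factory(t, ratio)
        assert ta.percent_change(tr, 1.0) == pytest.approx(-20.0)

    def test_percent_change_of_constant_trace_is_zero(self, toy_trace_factory):
        tr = toy_trace_factory(np.arange(0, 4, 0.2), np.full(20, 0.9))
        assert ta.percent_change(tr, 1.0) == 0.0

    def test_dose_ordering_of_percent_change(self):
        cfg = StressModelConfig()
        medians = []
        for f in (0.1, 0.3, 0.5):
            cells = st.simulate_washout(
                cfg, WashoutProtocol(suppression_fraction=f), 50, seed=2
            )
            pc = [ta.percent_change(c.trace, 10.0) for c in cells]
            med = np.median(pc)
            assert med == pytest.approx(-100 * f, rel=0.20)
            medians.append(med)
        assert medians[0] > medians[1] > medians[2]


class TestRecoveryMetrics:
    def test_already_recovered_at_washout(self, toy_trace_factory):
        t = np.arange(0, 4, 0.2)
        tr = toy_trace_factory(t, np.full(len(t), 1.0))
        m = ta.recovery_metrics(tr, 1.0, 2.0)
        assert m.recovery_time == 0.0

    def test_piecewise_linear_crossing_interpolated_at_36_min(
        self, toy_trace_factory
    ):
        t = np.arange(0, 4.01, 0.2)
        ratio = np.full(len(t), 1.0)
        post = t >= 2.0
        ratio[post] = 0.2 + 0.1 * np.round((t[post] - 2.0) / 0.2)
        ratio[(t >= 1.0) & (t < 2.0)] = 0.2
        tr = toy_trace_factory(t, np.minimum(ratio, 1.0))
        m = ta.recovery_metrics(tr, 1.0, 2.0)
        assert m.recovery_time == pytest.approx(36.0, abs=1e-6)


class TestAutocorrelation:
    def test_sinusoid_min_at_half_period(self, toy_trace_factory):
        t = np.arange(0, 30, 0.2)
        tr = toy_trace_factory(t, np.sin(2 * np.pi * t / 2.0))
        lags, acf, lag_min = ta.autocorrelation_profile(
            [tr], [(0.0, 30.0)], max_lag=1.6
        )
        assert lag_min == pytest.approx(1.0, abs=1e-9)
        assert acf[lags == 1.0][0] < -0.9

    def test_white_noise_has_no_structure(self, rng, toy_trace_factory):
        n = 2000
        t = np.arange(n) * 0.2
        tr = toy_trace_factory(t, rng.normal(0, 1, n))
        lags, acf, _ = ta.autocorrelation_profile(
            [tr], [(0.0, t[-1])], max_lag=4.0, detrend_degree=3
        )
        assert np.all(np.abs(acf[1:]) < 3 / np.sqrt(n))

    def test_cycling_preset_anticorrelation_lag(self, cycling_population):
        windows = [
            (c.true_apc_inactivation, c.true_s_end) for c in cycling_population
        ]
        _, _, lag = ta.autocorrelation_profile(
            [c.trace for c in cycling_population], windows, max_lag=4.0
        )
        assert lag == pytest.approx(1.2, abs=0.2)

    def test_short_segments_are_skipped(self, toy_trace_factory):
        t = np.arange(0, 2, 0.2)
        tr = toy_trace_factory(t, np.sin(t))
        with pytest.raises(ValueError):
            ta.autocorrelation_profile([tr], [(0.0, 2.0)], max_lag=4.0)
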