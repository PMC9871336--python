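"""Estimators: truncated MLE, EM mixtures, saturation/linear fits, segmentation."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from kinrace import (
    DomainError,
    DwellMixture,
    InsufficientDataError,
    empirical_survival,
    estimate_segmented_velocity,
    fit_biexponential_truncated,
    fit_exponential_truncated,
    fit_langmuir,
    fit_linear,
    fit_michaelis_menten,
    simulate_dwell_times,
    simulate_half_site_release,
    simulate_pelleting,
)


class TestTruncatedExponential:
    def test_mle_is_sample_mean_without_cutoff(self):
        assert fit_exponential_truncated([1, 2, 3, 4, 5]).tau == pytest.approx(3.0)

    def test_truncation_shift_invariance(self):
        assert fit_exponential_truncated([2, 3, 4, 5, 6], cutoff=1).tau == (
            pytest.approx(3.0)
        )

    @given(
        shift=st.floats(min_value=0.01, max_value=10),
        cutoff=st.floats(min_value=0, max_value=2),
    )
    def test_shift_equivariance(self, shift, cutoff):
        """Fitting {x} at cutoff c equals fitting {x+d} at cutoff c+d."""
        rng = np.random.default_rng(0)
        x = rng.exponential(3.0, 500) + cutoff
        a = fit_exponential_truncated(x, cutoff)
        b = fit_exponential_truncated(x + shift, cutoff + shift)
        assert a.tau == pytest.approx(b.tau, rel=1e-9)

    def test_parameter_recovery_at_run_length_scale(self):
        """50,000 draws at tau 3.0 um, censored at 0.17 um, recover 3.0."""
        rng = np.random.default_rng(123)
        x = rng.exponential(3.0, 50_000)
        fit = fit_exponential_truncated(x, cutoff=0.17)
        sem = fit.tau / math.sqrt(fit.n_used)
        assert abs(fit.tau - 3.0) < 3 * sem
        assert fit.n_used <= fit.n_input

    def test_recovery_rate_under_noise(self):
        """Across 200 seeded 1,000-event replicates, tau lands within 10% of
        truth in at least 95% of runs."""
        hits = 0
        for rep in range(200):
            rng = np.random.default_rng(1000 + rep)
            x = rng.exponential(3.0, 1000)
            fit = fit_exponential_truncated(x, cutoff=0.17)
            hits += abs(fit.tau - 3.0) / 3.0 < 0.10
        assert hits >= 190

    def test_survival_mode_agrees_with_mle(self):
        rng = np.random.default_rng(5)
        x = rng.exponential(1.8, 5000)
        mle = fit_exponential_truncated(x, cutoff=0.3)
        ls = fit_exponential_truncated(x, cutoff=0.3, method="survival")
        assert ls.tau == pytest.approx(mle.tau, abs=mle.tau_ci95[0])

    def test_too_few_samples(self):
        with pytest.raises(InsufficientDataError):
            fit_exponential_truncated([1.0, 2.0], cutoff=0.0)

    def test_nonpositive_samples_rejected(self):
        with pytest.raises(DomainError):
            fit_exponential_truncated([1.0, -2.0, 3.0, 4.0, 5.0])


class TestBiexponential:
    def test_recovers_fast_and_slow_dwell_components(self):
        """Two-component mixture at the 0.03 s / 0.3 s dwell scales, censored
        at 0.02 s, recovered within 20% from 5,000 events."""
        mix = DwellMixture([(0.5, 0.03), (0.5, 0.3)])
        d = simulate_dwell_times(mix, 5000, seed=77)
        fit = fit_biexponential_truncated(d, cutoff=0.02)
        tau1, tau2 = fit.taus
        assert tau1 == pytest.approx(0.03, rel=0.2)
        assert tau2 == pytest.approx(0.3, rel=0.2)
        assert not fit.degenerate

    def test_weights_sum_to_one(self):
        d = simulate_dwell_times(DwellMixture([(0.4, 0.05), (0.6, 0.5)]), 2000, seed=8)
        fit = fit_biexponential_truncated(d)
        assert sum(fit.weights) == pytest.approx(1.0, abs=1e-9)
        assert fit.taus[0] < fit.taus[1]

    def test_single_exponential_data_flags_degenerate(self):
        d = simulate_dwell_times(DwellMixture([(1.0, 1.8)]), 3000, seed=12)
        fit = fit_biexponential_truncated(d, cutoff=0.3)
        assert fit.degenerate
        # degenerate mixture collapses to the single-exponential answer
        single = fit_exponential_truncated(d, cutoff=0.3)
        pooled = sum(w * t for w, t in fit.components)
        assert pooled == pytest.approx(single.tau, rel=0.05)

    def test_minimum_sample_size(self):
        with pytest.raises(InsufficientDataError):
            fit_biexponential_truncated(np.linspace(0.1, 1, 30))


class TestSaturationFits:
    def test_michaelis_menten_noiseless_round_trip(self):
        curve = simulate_half_site_release(
            [10, 25, 50, 100, 200, 500, 1000, 2000], 172.0, 119.0
        )
        fit = fit_michaelis_menten(curve.x, curve.y)
        assert fit.k_max == pytest.approx(172.0, rel=1e-6)
        assert fit.K_M == pytest.approx(119.0, rel=1e-6)

    def test_two_point_algebraic_recovery(self):
        x = [96.0, 1e6]
        y = [77.0, 154.0 * 1e6 / (96.0 + 1e6)]
        fit = fit_michaelis_menten([*x, 500.0], [*y, 154.0 * 500 / 596])
        assert fit.k_max == pytest.approx(154.0, rel=0.01)
        assert fit.K_M == pytest.approx(96.0, rel=0.01)

    def test_zero_signal_flagged(self):
        fit = fit_michaelis_menten([1, 10, 100], [0, 0, 0])
        assert fit.k_max == 0.0
        assert "no_signal" in fit.flags

    @pytest.mark.parametrize("kd, vmax", [(1.3, 0.97), (5.1, 0.24)])
    def test_langmuir_noiseless_round_trip(self, kd, vmax):
        curve = simulate_pelleting([0.25, 0.5, 1, 2, 4, 8, 16], kd, vmax)
        fit = fit_langmuir(curve.x, curve.y)
        assert fit.K_D == pytest.approx(kd, rel=1e-6)
        assert fit.V_max == pytest.approx(vmax, rel=1e-6)

    def test_langmuir_half_saturation_point(self):
        curve = simulate_pelleting([1.3], 1.3, 0.97)
        assert curve.y[0] == pytest.approx(0.97 / 2)

    def test_degenerate_design_rejected(self):
        with pytest.raises(DomainError):
            fit_michaelis_menten([5, 5, 5], [1, 2, 3])


class TestLinearFit:
    def test_exact_line(self):
        x = np.array([0.5, 1, 2, 3, 5])
        fit = fit_linear(x, 10.6 * x)
        assert fit.slope == pytest.approx(10.6, abs=1e-9)
        assert fit.intercept == pytest.approx(0.0, abs=1e-9)

    def test_charge_run_length_slope_low_ionic_strength(self):
        fit = fit_linear([4, 1, 0, -1], [14.3, 6.7, 2.6, 1.2])
        assert round(fit.slope, 1) == 2.7
        assert fit.slope_ci95 == pytest.approx(0.9, abs=0.05)

    def test_charge_run_length_slope_high_ionic_strength(self):
        fit = fit_linear([7, 4, 1], [5.6, 3.0, 0.5])
        assert fit.slope == pytest.approx(0.85, abs=1e-9)

    def test_weighted_equals_unweighted_for_equal_errors(self):
        x = [1, 2, 3, 4.0]
        y = [1.1, 1.9, 3.2, 3.9]
        a = fit_linear(x, y)
        b = fit_linear(x, y, y_err=[0.5] * 4)
        assert a.slope == pytest.approx(b.slope)
        assert b.weighted

    def test_all_x_identical_rejected(self):
        with pytest.raises(DomainError):
            fit_linear([2, 2, 2], [1, 2, 3])


class TestSegmentedVelocity:
    def test_uniform_trace_single_segment(self):
        t = np.arange(0, 2.01, 0.1)
        res = estimate_segmented_velocity(1.5 * t, t)
        assert res.n_segments == 1
        assert res.mean == pytest.approx(1.5, rel=1e-6)

    def test_pausing_trace_segmented_exceeds_end_to_end(self):
        """Run-pause-run trace: segmented mean stays near the motile speed
        while the end-to-end velocity is dragged down by the pause."""
        t = np.arange(0, 3.001, 0.1)
        pos = np.piecewise(
            t,
            [t < 1.0, (t >= 1.0) & (t < 2.0), t >= 2.0],
            [lambda t: 1.5 * t, 1.5, lambda t: 1.5 + 1.5 * (t - 2.0)],
        )
        res = estimate_segmented_velocity(pos, t)
        end_to_end = (pos[-1] - pos[0]) / (t[-1] - t[0])
        assert end_to_end == pytest.approx(1.0, abs=0.05)
        assert res.mean == pytest.approx(1.5, abs=0.15)
        assert res.mean > end_to_end

    def test_short_segment_excluded(self):
        # 1 pixel of motion between long pauses: below the 3-pixel floor
        t = np.arange(0, 2.01, 0.1)
        pos = np.where(t < 1.0, 0.0, 0.05)
        res = estimate_segmented_velocity(pos, t)
        assert res.n_segments == 0
        assert res.n_excluded >= 1

    def test_too_few_points(self):
        with pytest.raises(InsufficientDataError):
            estimate_segmented_velocity([0.0], [0.0])


class TestEmpiricalSurvival:
    def test_counting(self):
        assert empirical_survival([1, 2, 3]) == [
            (1.0, 1.0),
            (2.0, pytest.approx(2 / 3)),
            (3.0, pytest.approx(1 / 3)),
        ]

    def test_ties_collapse(self):
        assert empirical_survival([5, 5, 5]) == [(5.0, 1.0)]

    def test_starts_at_one(self):
        curve = empirical_survival([0.3, 9.1, 2.2, 4.4])
        assert curve[0][1] == 1.0
        assert curve[-1][1] == pytest.approx(1 / 4)

    def test_empty_rejected(self):
        with pytest.raises(InsufficientDataError):
            empirical_survival([])
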