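"""Trace averaging, exponential fitting, bimolecular rates, Eqs for k_O2/K_O2."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hexakin import (
    KineticTrace,
    average_traces,
    bimolecular_rate,
    binding_constants,
    correct_o2_dissociation,
    fit_single_exponential,
    fraction_to_KH,
)


def _exp_trace(k=0.34, amp=0.2, offset=0.05, n=100, t_max=None, noise_sd=0.0, seed=0):
    t_max = t_max if t_max is not None else 8.0 / k
    t = np.linspace(0.0, t_max, n)
    y = offset + amp * np.exp(-k * t)
    if noise_sd > 0:
        y = y + np.random.default_rng(seed).normal(0.0, noise_sd, n)
    return KineticTrace(times=t, signal=y)


class TestAverageTraces:
    def test_single_trace_averages_to_itself(self):
        tr = _exp_trace()
        mean = average_traces([tr])
        assert np.array_equal(mean.signal, tr.signal)

    def test_trace_and_negation_cancel(self):
        tr = _exp_trace(offset=0.0)
        neg = KineticTrace(times=tr.times, signal=-tr.signal)
        assert np.allclose(average_traces([tr, neg]).signal, 0.0)

    def test_mismatched_grids_rejected(self):
        a = _exp_trace(n=50)
        b = _exp_trace(n=60)
        with pytest.raises(ValueError):
            average_traces([a, b])

    def test_averaging_ten_replicates_shrinks_noise_about_sqrt10(self):
        clean = _exp_trace(noise_sd=0.0)
        reps = [_exp_trace(noise_sd=0.01, seed=s) for s in range(10)]
        mean = average_traces(reps)
        sd_single = np.std(reps[0].signal - clean.signal)
        sd_mean = np.std(mean.signal - clean.signal)
        assert 2.2 < sd_single / sd_mean < 4.5


class TestSingleExponentialFit:
    def test_noiseless_decay_recovered_to_high_precision(self):
        fit = fit_single_exponential(_exp_trace(k=0.34, amp=0.2, offset=0.05))
        assert fit.ok
        assert fit.k_obs == pytest.approx(0.34, rel=1e-6)
        assert fit.amplitude == pytest.approx(0.2, rel=1e-6)
        assert fit.offset == pytest.approx(0.05, rel=1e-6)

    def test_rising_recovery_gets_negative_amplitude(self):
        tr = _exp_trace(k=2.0, amp=-0.3, offset=0.3)
        fit = fit_single_exponential(tr, direction="recovery")
        assert fit.ok
        assert fit.k_obs == pytest.approx(2.0, rel=1e-6)
        assert fit.amplitude < 0

    def test_constant_trace_is_flagged_degenerate(self):
        t = np.linspace(0, 10, 50)
        fit = fit_single_exponential(KineticTrace(times=t, signal=np.full(50, 0.7)))
        assert not fit.ok
        assert fit.amplitude == 0.0
        assert "degenerate" in fit.message

    def test_noisy_trace_recovered_within_5_percent(self):
        fit = fit_single_exponential(_exp_trace(k=0.34, amp=0.2, noise_sd=0.004, seed=7))
        assert fit.ok
        assert fit.k_obs == pytest.approx(0.34, rel=0.05)
        assert np.isfinite(fit.stderr_k_obs) and fit.stderr_k_obs > 0

    def test_too_few_points_rejected(self):
        tr = KineticTrace(times=np.linspace(0, 1, 5), signal=np.exp(-np.linspace(0, 1, 5)))
        with pytest.raises(ValueError, match=">= 8"):
            fit_single_exponential(tr)


class TestBimolecularRate:
    def test_exact_line_through_two_concentrations(self):
        fit = bimolecular_rate([(100.0, 58.0), (1000.0, 580.0)])
        assert fit.k_prime == pytest.approx(0.58, rel=1e-12)
        assert fit.k_off_intercept == pytest.approx(0.0, abs=1e-10)
        assert fit.mode == "regression"

    def test_single_point_with_supplied_off_rate(self):
        fit = bimolecular_rate([(262.0, 38781.2)], k_off=5.2)
        assert fit.k_prime == pytest.approx((38781.2 - 5.2) / 262.0, rel=1e-12)
        assert fit.mode == "single-point"

    def test_single_point_without_off_rate_rejected(self):
        with pytest.raises(ValueError):
            bimolecular_rate([(262.0, 38781.2)])

    def test_identical_concentrations_rejected(self):
        with pytest.raises(ValueError, match="identical"):
            bimolecular_rate([(100.0, 58.0), (100.0, 60.0)])

    def test_negative_intercept_warned_not_clamped(self):
        with pytest.warns(UserWarning, match="negative intercept"):
            fit = bimolecular_rate([(1.0, 1.0), (2.0, 3.0)])
        assert fit.k_off_intercept == pytest.approx(-1.0)

    def test_noisy_regression_within_two_standard_errors(self):
        rng = np.random.default_rng(3)
        conc = np.array([100.0, 250.0, 500.0, 750.0, 1000.0])
        kobs = 0.58 * conc + 2.0 + rng.normal(0, 5.0, conc.size)
        fit = bimolecular_rate(list(zip(conc, kobs)))
        assert abs(fit.k_prime - 0.58) <= 2 * fit.stderr_k_prime


class TestCOCompetitionCorrection:
    def test_no_oxygen_leaves_k_obs_unchanged(self):
        assert correct_o2_dissociation(0.34, 148.0, 0.58, 0.0, 1000.0) == 0.34

    def test_matches_direct_arithmetic(self):
        expected = 0.34 * (1 + 148.0 * 56.2 / (0.58 * 1000.0))
        value = correct_o2_dissociation(0.34, 148.0, 0.58, 56.2, 1000.0)
        assert value == pytest.approx(expected, rel=1e-15)
        # consistent with the published moss k_O2 of 5.2 s^-1
        assert value == pytest.approx(5.2, rel=0.01)

    def test_zero_co_rejected(self):
        with pytest.raises(ValueError):
            correct_o2_dissociation(0.34, 148.0, 0.58, 56.2, 0.0)

    @settings(derandomize=True, max_examples=100)
    @given(
        k_obs=st.floats(1e-3, 10.0),
        o2=st.floats(0.0, 500.0),
        co=st.floats(1.0, 5000.0),
        scale=st.floats(0.1, 100.0),
    )
    def test_invariant_under_joint_concentration_scaling(self, k_obs, o2, co, scale):
        a = correct_o2_dissociation(k_obs, 148.0, 0.58, o2, co)
        b = correct_o2_dissociation(k_obs, 148.0, 0.58, o2 * scale, co * scale)
        assert b == pytest.approx(a, rel=1e-12)

    @settings(derandomize=True, max_examples=100)
    @given(
        o2_lo=st.floats(0.0, 200.0),
        d_o2=st.floats(0.0, 300.0),
        co_lo=st.floats(1.0, 2000.0),
        d_co=st.floats(0.0, 3000.0),
    )
    def test_monotone_in_each_concentration(self, o2_lo, d_o2, co_lo, d_co):
        base = correct_o2_dissociation(0.34, 148.0, 0.58, o2_lo, co_lo)
        assert correct_o2_dissociation(0.34, 148.0, 0.58, o2_lo + d_o2, co_lo) >= base
        assert correct_o2_dissociation(0.34, 148.0, 0.58, o2_lo, co_lo + d_co) <= base
        assert base >= 0.34


class TestBindingConstants:
    def test_moss_globin_affinities_from_rates_and_coordination(self):
        b = binding_constants(148.0, 5.2, K_H=fraction_to_KH(0.83))
        assert b.K_O2_pent == pytest.approx(148.0 / 5.2, rel=1e-12)
        assert round(b.K_O2_pent) == 28
        assert b.K_O2 == pytest.approx(b.K_O2_pent / (1 + b.K_H), rel=1e-12)
        assert b.K_O2 == pytest.approx(4.8, abs=0.05)

    def test_hornwort_globin_with_printed_override(self):
        b = binding_constants(208.0, 7.5, K_H=1.0, K_O2_pent_override=30.0)
        assert b.K_O2 == pytest.approx(15.0, rel=1e-12)
        assert b.K_O2_pent_from_rates == pytest.approx(208.0 / 7.5, rel=1e-12)

    def test_pentacoordinate_limit(self):
        b = binding_constants(130.0, 5.6, K_H=0.0)
        assert b.K_O2 == b.K_O2_pent

    def test_fully_hexacoordinate_limit_gives_zero_affinity(self):
        b = binding_constants(148.0, 5.2, K_H=float("inf"))
        assert b.K_O2 == 0.0

    def test_zero_off_rate_without_override_rejected(self):
        with pytest.raises(ValueError):
            binding_constants(148.0, 0.0, K_H=1.0)

    @settings(derandomize=True, max_examples=100)
    @given(
        k_prime=st.floats(1.0, 500.0),
        k_off=st.floats(0.01, 20.0),
        k_h=st.floats(0.0, 1000.0),
    )
    def test_affinity_identities_hold(self, k_prime, k_off, k_h):
        b = binding_constants(k_prime, k_off, K_H=k_h)
        assert b.K_O2_pent == pytest.approx(k_prime / k_off, rel=1e-9)
        assert b.K_O2 == pytest.approx(b.K_O2_pent / (1 + k_h), rel=1e-12)


class TestKineticTraceValidation:
    def test_rejects_bad_arrays(self):
        with pytest.raises(ValueError):
            KineticTrace(times=np.array([0.0, 1.0, 0.5]), signal=np.array([1.0, 2.0, 3.0]))
        with pytest.raises(ValueError):
            KineticTrace(times=np.array([-1.0, 0.0, 1.0]), signal=np.array([1.0, 2.0, 3.0]))
        with pytest.raises(ValueError):
            KineticTrace(times=np.array([0.0, 1.0]), signal=np.array([1.0, 2.0]))

    def test_unit_conversion_round_trip(self):
        tr = KineticTrace(times=np.array([0.0, 1.0, 2.0]), signal=np.array([3.0, 2.0, 1.0]), time_unit="h")
        sec = tr.with_times_in("s")
        assert np.allclose(sec.times, [0.0, 3600.0, 7200.0])
        assert np.allclose(sec.with_times_in("h").times, tr.times)
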