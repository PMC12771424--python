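"""Forward simulator: ODE correctness, rendered observables, determinism."""

import math

import numpy as np
import pytest
from scipy.linalg import expm

from hexakin import (
    KineticScheme,
    NoiseModel,
    SPECIES,
    auto_time_grid,
    fit_single_exponential,
    generate_autoox_series,
    generate_equilibrium_spectrum,
    generate_flash_photolysis_trace,
    generate_stopped_flow_displacement_trace,
    simulate_scheme,
)
from hexakin.simulate import DEFAULT_BASIS


def _random_scheme(rng):
    return KineticScheme(*rng.uniform(0.0, 10.0, 6))


class TestSimulateScheme:
    def test_zero_rates_freeze_the_initial_state(self):
        scheme = KineticScheme(0, 0, 0, 0, 0, 0)
        y0 = [0.2, 0.3, 0.4, 0.1]
        traj = simulate_scheme(scheme, y0, np.linspace(0, 10, 20), o2_uM=50, co_uM=50)
        assert np.allclose(traj.fractions, np.tile(y0, (20, 1)))

    def test_ligand_free_long_time_hexa_fraction_is_KH_partition(self):
        """With K_H = 1 and no ligand, half the heme ends hexacoordinate."""
        scheme = KineticScheme(1.0, 1.0, 148.0, 5.2, 0.58, 0.001)
        traj = simulate_scheme(scheme, {"penta_deoxy": 1.0}, np.linspace(0, 20, 50))
        assert traj.fraction("hexa_deoxy")[-1] == pytest.approx(0.5, abs=1e-6)
        # general partition: K_H/(1+K_H)
        scheme2 = KineticScheme(3.0, 1.0, 0.0, 0.0, 0.0, 0.0)
        traj2 = simulate_scheme(scheme2, {"penta_deoxy": 1.0}, np.linspace(0, 20, 50))
        assert traj2.fraction("hexa_deoxy")[-1] == pytest.approx(0.75, abs=1e-6)

    def test_trajectories_match_matrix_exponential_oracle(self, rng):
        """LSODA integration agrees with the exact linear-system solution on
        randomized schemes, and conserves total heme."""
        for _ in range(20):
            scheme = _random_scheme(rng)
            o2, co = rng.uniform(0.0, 50.0, 2)
            y0 = rng.dirichlet(np.ones(4))
            t = np.linspace(0.0, 0.5, 50)
            traj = simulate_scheme(scheme, y0, t, o2_uM=o2, co_uM=co)
            A = scheme.rate_matrix(o2, co)
            exact = np.array([expm(A * tt) @ y0 for tt in t])
            assert np.max(np.abs(traj.fractions - exact)) <= 1e-8
            assert np.max(np.abs(traj.fractions.sum(axis=1) - 1.0)) <= 1e-9

    def test_single_ligand_limit_is_exactly_single_exponential(self, moss_scheme):
        """With His rebinding disabled, penta + O2 relaxation follows the
        closed form with rate k'[O2] + k_off."""
        conc = 100.0
        lam = moss_scheme.k_prime_o2 * conc + moss_scheme.k_o2_off
        t = auto_time_grid(lam, n_points=60)
        traj = simulate_scheme(moss_scheme, {"penta_deoxy": 1.0}, t, o2_uM=conc)
        p_inf = moss_scheme.k_o2_off / lam
        closed = p_inf + (1 - p_inf) * np.exp(-lam * t)
        assert np.max(np.abs(traj.fraction("penta_deoxy") - closed)) <= 1e-8

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            KineticScheme(-1, 0, 0, 0, 0, 0)
        scheme = KineticScheme(1, 1, 1, 1, 1, 1)
        with pytest.raises(ValueError):
            simulate_scheme(scheme, [0.5, 0.2, 0.2, 0.2], np.linspace(0, 1, 10))
        with pytest.raises(ValueError):
            simulate_scheme(scheme, [1, 0, 0, 0], np.array([0.0, 0.5, 0.5]))
        with pytest.raises(ValueError):
            simulate_scheme(scheme, [1, 0, 0, 0], np.linspace(0, 1, 10), o2_uM=-5)


class TestFlashPhotolysis:
    def test_fitted_rate_matches_pseudo_first_order_closed_form(self, moss_scheme):
        """O2 rebinding in air: k_obs = k'[O2] + k_off to within 0.1 %."""
        conc = 262.0
        expected = 148.0 * conc + 5.2
        trace = generate_flash_photolysis_trace(
            moss_scheme, "O2", conc, 420.0, auto_time_grid(expected)
        )
        fit = fit_single_exponential(trace)
        assert fit.ok
        assert fit.k_obs == pytest.approx(expected, rel=1e-3)

    def test_zero_amplitude_scale_gives_identically_zero_trace(self, moss_scheme):
        trace = generate_flash_photolysis_trace(
            moss_scheme, "O2", 262.0, 420.0, auto_time_grid(4e4), amplitude_scale=0.0
        )
        assert np.all(trace.signal == 0.0)

    def test_same_seed_reproduces_bit_identical_traces(self, moss_scheme):
        kwargs = dict(
            scheme=moss_scheme,
            ligand="CO",
            conc=500.0,
            monitor_wavelength=412.0,
            time_grid=auto_time_grid(300.0),
            noise=NoiseModel(sd=0.05, seed=42),
        )
        a = generate_flash_photolysis_trace(**kwargs)
        b = generate_flash_photolysis_trace(**kwargs)
        assert np.array_equal(a.signal, b.signal)

    def test_invalid_inputs_rejected(self, moss_scheme):
        with pytest.raises(ValueError):
            generate_flash_photolysis_trace(moss_scheme, "O2", 0.0, 420.0, auto_time_grid(1.0))
        with pytest.raises(ValueError, match="outside"):
            generate_flash_photolysis_trace(moss_scheme, "O2", 262.0, 3000.0, auto_time_grid(1.0))
        with pytest.raises(ValueError):
            generate_flash_photolysis_trace(moss_scheme, "NO", 262.0, 420.0, auto_time_grid(1.0))


class TestStoppedFlowDisplacement:
    def test_without_oxygen_the_rate_is_the_o2_off_rate(self, moss_scheme):
        trace = generate_stopped_flow_displacement_trace(
            moss_scheme, 0.0, 1000.0, 412.0, auto_time_grid(5.2)
        )
        fit = fit_single_exponential(trace)
        assert fit.ok
        assert fit.k_obs == pytest.approx(moss_scheme.k_o2_off, rel=0.01)

    def test_co_competition_rate_for_moss_globin(self, moss_scheme):
        """At [O2] 56.2 uM / [CO] 1 mM, the displacement relaxation sits at
        ~0.34 s^-1, the published fit value for the moss protein."""
        k_pred = 5.2 / (1 + 148.0 * 56.2 / (0.58 * 1000.0))
        trace = generate_stopped_flow_displacement_trace(
            moss_scheme, 56.2, 1000.0, 412.0, auto_time_grid(k_pred)
        )
        fit = fit_single_exponential(trace)
        assert fit.ok
        assert fit.k_obs == pytest.approx(0.34, rel=0.01)

    def test_rate_depends_only_on_the_concentration_ratio(self, moss_scheme):
        k_pred = 5.2 / (1 + 148.0 * 56.2 / (0.58 * 1000.0))
        grid = auto_time_grid(k_pred)
        fits = []
        for scale in (1.0, 2.0):
            trace = generate_stopped_flow_displacement_trace(
                moss_scheme, 56.2 * scale, 1000.0 * scale, 412.0, grid
            )
            fits.append(fit_single_exponential(trace).k_obs)
        assert fits[0] == pytest.approx(fits[1], rel=1e-3)

    def test_co_required(self, moss_scheme):
        with pytest.raises(ValueError):
            generate_stopped_flow_displacement_trace(
                moss_scheme, 56.2, 0.0, 412.0, auto_time_grid(1.0)
            )


class TestEquilibriumSpectrum:
    def test_pure_fractions_reproduce_the_basis_exactly(self):
        penta = generate_equilibrium_spectrum(0.0)
        hexa = generate_equilibrium_spectrum(1.0)
        grid = penta.wavelengths
        assert np.array_equal(penta.absorbances, DEFAULT_BASIS.value("penta_deoxy", grid))
        assert np.array_equal(hexa.absorbances, DEFAULT_BASIS.value("hexa_deoxy", grid))

    def test_ferric_state_uses_ferric_basis(self):
        spec = generate_equilibrium_spectrum(1.0, state="ferric")
        assert np.array_equal(
            spec.absorbances, DEFAULT_BASIS.value("ferric_hexa", spec.wavelengths)
        )

    @pytest.mark.parametrize("bad", [-0.1, 1.5])
    def test_fraction_out_of_range_rejected(self, bad):
        with pytest.raises(ValueError):
            generate_equilibrium_spectrum(bad)


class TestAutooxSeries:
    def test_noiseless_round_trip_recovers_the_rate(self):
        from hexakin import extract_timecourse, fit_autoox

        series = generate_autoox_series(0.88, 5.0 / 0.88, 40)
        result = fit_autoox(extract_timecourse(series))
        assert result.ok
        assert result.k_ox_per_h == pytest.approx(0.88, rel=1e-3)

    def test_initial_spectrum_is_the_oxy_basis(self):
        series = generate_autoox_series(0.5, 4.0, 5)
        t0, spec0 = series[0]
        assert t0 == 0.0
        assert np.allclose(spec0.absorbances, DEFAULT_BASIS.value("oxy", spec0.wavelengths))

    def test_final_oxy_weight_follows_the_closed_form(self):
        k, dur = 0.52, 6.0
        series = generate_autoox_series(k, dur, 10)
        t_end, spec_end = series[-1]
        f = math.exp(-k * dur)
        grid = spec_end.wavelengths
        expected = f * DEFAULT_BASIS.value("oxy", grid) + (1 - f) * DEFAULT_BASIS.value(
            "ferric_hexa", grid
        )
        assert t_end == dur
        assert np.allclose(spec_end.absorbances, expected, atol=1e-12)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            generate_autoox_series(0.88, -1.0, 10)
        with pytest.raises(ValueError):
            generate_autoox_series(0.88, 5.0, 2)
        with pytest.raises(ValueError):
            generate_autoox_series(0.0, 5.0, 10)


class TestNoiseModel:
    def test_negative_sd_rejected(self):
        with pytest.raises(ValueError):
            NoiseModel(sd=-0.1)

    def test_species_order_is_stable(self):
        assert SPECIES == ("hexa_deoxy", "penta_deoxy", "oxy", "carbonmonoxy")
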