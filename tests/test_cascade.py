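"""Signaling-cascade ODE model: limits, steady states, response, ensembles."""

import math

import numpy as np
import pytest

from regazyme import (
    CascadeParams,
    Trajectory,
    build_signal_profile,
    population_cv,
    response_time,
    simulate_cascade,
    single_cell_ensemble,
    steady_state,
)


class TestSignalProfiles:
    def test_step_switches_at_onset(self):
        p = build_signal_profile("step", level=25.0, t_on=7.0)
        assert p(6.9) == 0.0
        assert p(7.1) == 25.0

    def test_pulse_returns_to_zero(self):
        p = build_signal_profile("pulse", level=5.0, t_on=10.0, width=20.0)
        assert p(9.0) == 0.0 and p(15.0) == 5.0 and p(31.0) == 0.0

    def test_square_wave_periodicity(self):
        p = build_signal_profile("square_wave", level=2.0, period=40.0, duty=0.25)
        for t in (1.0, 9.9, 10.1, 25.0, 39.9):
            assert p(t) == p(t + 40.0) == p(t + 80.0)
        assert p(5.0) == 2.0 and p(15.0) == 0.0

    def test_invalid_profiles_rejected(self):
        with pytest.raises(ValueError):
            build_signal_profile("square_wave", level=1.0, period=0.0)
        with pytest.raises(ValueError):
            build_signal_profile("step", level=-1.0)  # negative level
        with pytest.raises(ValueError):
            build_signal_profile("nope", level=1.0)


class TestSimulateCascade:
    def test_reporter_decay_closed_form(self):
        """With no signal, no leak, and no riboregulator, G decays at delta_G."""
        params = CascadeParams(beta_R=0.0, k_leak=0.0)
        profile = build_signal_profile("step", level=0.0)
        t = np.linspace(0.0, 60.0, 121)
        traj = simulate_cascade(params, profile, t, y0=(0.0, 0.0, 50.0))
        expected = 50.0 * np.exp(-params.delta_G * t)
        assert np.allclose(traj.G, expected, rtol=1e-6, atol=1e-8)

    def test_step_response_monotone_to_steady_state(self):
        params = CascadeParams()
        profile = build_signal_profile("step", level=25.0)
        t = np.linspace(0.0, 400.0, 401)
        traj = simulate_cascade(params, profile, t)
        assert (np.diff(traj.G) >= -1e-8).all()
        _, _, g_star = steady_state(params, 25.0)
        assert traj.G[-1] == pytest.approx(g_star, rel=1e-3)
        assert traj.Ru[-1] == pytest.approx(steady_state(params, 25.0)[0], rel=1e-3)

    def test_mass_balance_without_production(self):
        """With transcription off, total RNA decays at exactly delta_R."""
        params = CascadeParams(beta_R=0.0, k_leak=0.05)
        profile = build_signal_profile("step", level=10.0)
        t = np.linspace(0.0, 20.0, 81)
        traj = simulate_cascade(params, profile, t, y0=(30.0, 10.0, 0.0))
        total = traj.Ru + traj.Ra
        assert np.allclose(total, 40.0 * np.exp(-params.delta_R * t), rtol=1e-6)

    def test_states_nonnegative(self):
        params = CascadeParams(k_leak=0.01)
        profile = build_signal_profile("square_wave", level=25.0, period=30.0)
        t = np.linspace(0.0, 150.0, 301)
        traj = simulate_cascade(params, profile, t)
        assert (traj.Ru >= 0).all() and (traj.Ra >= 0).all() and (traj.G >= 0).all()


class TestSteadyState:
    def test_saturating_signal_limit(self):
        params = CascadeParams(k_leak=0.02)
        k_high = params.k_leak + params.k_cat
        expected_ra = params.beta_R * k_high / ((k_high + params.delta_R) * params.delta_R)
        ra = steady_state(params, 1e9)[1]
        assert ra == pytest.approx(expected_ra, rel=1e-6)

    def test_dead_ribozyme_gives_zero_output(self):
        params = CascadeParams(k_cat=0.0, k_leak=0.0)
        ru, ra, g = steady_state(params, 10.0)
        assert ra == 0.0 and g == 0.0 and ru > 0


class TestResponseTime:
    def test_exponential_rise_closed_form(self):
        """95% crossing of G*(1-exp(-delta_G t)) is at ln(20)/delta_G."""
        delta_g = 1.0 / 12.0
        t = np.linspace(0.0, 240.0, 4801)
        g = 100.0 * (1.0 - np.exp(-delta_g * t))
        traj = Trajectory(t, np.zeros_like(t), np.zeros_like(t), g)
        assert response_time(traj, 0.95) == pytest.approx(math.log(20) / delta_g, rel=1e-3)

    def test_criterion_monotonicity(self):
        t = np.linspace(0.0, 240.0, 2401)
        g = 10.0 * (1.0 - np.exp(-0.05 * t))
        traj = Trajectory(t, np.zeros_like(t), np.zeros_like(t), g)
        assert response_time(traj, 0.5) < response_time(traj, 0.95)

    def test_copy_number_moves_level_not_dynamics(self):
        """10x transcription rate scales G* ~10x but shifts the 95% response
        time by < 1% (below translation saturation)."""
        profile = build_signal_profile("step", level=25.0)
        t = np.linspace(0.0, 400.0, 2001)
        lo = CascadeParams(beta_R=0.1)
        hi = CascadeParams(beta_R=1.0)
        g_lo = steady_state(lo, 25.0)[2]
        g_hi = steady_state(hi, 25.0)[2]
        assert g_hi / g_lo == pytest.approx(10.0, rel=0.02)
        rt_lo = response_time(simulate_cascade(lo, profile, t))
        rt_hi = response_time(simulate_cascade(hi, profile, t))
        assert abs(rt_hi - rt_lo) / rt_lo < 0.01

    def test_no_plateau_rejected(self):
        t = np.linspace(0.0, 10.0, 101)
        g = t.copy()  # still rising linearly
        traj = Trajectory(t, np.zeros_like(t), np.zeros_like(t), g)
        with pytest.raises(ValueError):
            response_time(traj)


class TestLimits:
    def test_qss_protein_dominant_limit(self):
        """Fast RNA turnover reduces the reporter to exponential rise with
        production: sup-norm error below 1% of G*."""
        params = CascadeParams(delta_R=35.0, beta_R=350.0, k_cat=5.0, k_leak=0.0)
        profile = build_signal_profile("step", level=1e6)
        t = np.linspace(0.0, 120.0, 241)
        traj = simulate_cascade(params, profile, t, y0=(params.beta_R / 40.0, 0.0, 0.0))
        g_star = steady_state(params, 1e6)[2]
        expected = g_star * (1.0 - np.exp(-params.delta_G * t))
        assert np.max(np.abs(traj.G - expected)) < 1e-2 * g_star

    def test_slow_degradation_linear_growth(self):
        """When reporter degradation vanishes, G grows linearly at long times."""
        params = CascadeParams(delta_G=1e-6)
        profile = build_signal_profile("step", level=25.0)
        t = np.linspace(0.0, 600.0, 601)
        traj = simulate_cascade(params, profile, t)
        inc1 = traj.G[400] - traj.G[300]
        inc2 = traj.G[500] - traj.G[400]
        assert inc2 == pytest.approx(inc1, rel=0.01)
        assert inc2 > 0


class TestEnsemble:
    def test_zero_cv_identical_cells(self):
        params = CascadeParams()
        profile = build_signal_profile("step", level=25.0)
        t = np.linspace(0.0, 60.0, 61)
        cells = single_cell_ensemble(params, profile, t, 5, 0.0, rng=0)
        for traj in cells[1:]:
            assert np.array_equal(traj.G, cells[0].G)
        assert population_cv(cells, (40.0, 60.0)) == 0.0

    def test_seeded_reproducibility(self):
        params = CascadeParams()
        profile = build_signal_profile("step", level=25.0)
        t = np.linspace(0.0, 30.0, 31)
        a = single_cell_ensemble(params, profile, t, 4, 0.3, rng=11)
        b = single_cell_ensemble(params, profile, t, 4, 0.3, rng=11)
        for x, y in zip(a, b):
            assert np.array_equal(x.G, y.G)

    def test_ensemble_mean_tracks_nominal(self):
        """Small extrinsic noise: the ensemble mean reporter stays within a
        few percent of the nominal trajectory."""
        params = CascadeParams()
        profile = build_signal_profile("step", level=25.0)
        t = np.linspace(0.0, 120.0, 41)
        cells = single_cell_ensemble(params, profile, t, 200, 0.05, rng=5)
        mean_g = np.mean([c.G for c in cells], axis=0)
        nominal = simulate_cascade(params, profile, t).G
        late = t >= 30.0
        assert np.allclose(mean_g[late], nominal[late], rtol=0.03)

    def test_population_cv_linear_propagation(self):
        """With alpha_G-only lognormal noise the reporter CV equals the
        parameter CV (G* is exactly linear in alpha_G)."""
        params = CascadeParams()
        profile = build_signal_profile("step", level=25.0)
        t = np.linspace(0.0, 150.0, 31)
        cv_in = 0.1
        cells = single_cell_ensemble(
            params, profile, t, 300, cv_in, rng=42, noisy_params=("alpha_G",)
        )
        cv_out = population_cv(cells, (120.0, 150.0))
        assert cv_out == pytest.approx(cv_in, rel=0.2)

    def test_cv_scale_invariance(self):
        t = np.linspace(0.0, 10.0, 11)
        mk = lambda level: Trajectory(t, np.zeros_like(t), np.zeros_like(t),
                                      np.full_like(t, level))
        cells = [mk(8.0), mk(10.0), mk(12.0)]
        scaled = [mk(80.0), mk(100.0), mk(120.0)]
        assert population_cv(cells, (0.0, 10.0)) == pytest.approx(
            population_cv(scaled, (0.0, 10.0))
        )

    def test_window_validation(self):
        t = np.linspace(0.0, 10.0, 11)
        traj = Trajectory(t, np.zeros_like(t), np.zeros_like(t), np.ones_like(t))
        with pytest.raises(ValueError):
            population_cv([traj], (20.0, 30.0))
        with pytest.raises(ValueError):
            population_cv([traj], (5.0, 5.0))
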