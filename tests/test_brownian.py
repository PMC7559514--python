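"""Stochastic integrator: reflections, moments, transport coefficients."""

import math

import numpy as np
import pytest
from scipy import stats as sps

from dldsim import (
    ParticleSpec,
    SimulationConfig,
    advance_particles,
    first_passage_exit_positions,
    fit_transport_coefficients,
    gaussian_exit_distribution,
    run_ensemble,
    uniform_flow_field,
)
from dldsim.brownian import EnsembleStats, StepRejectionError
from dldsim.core import EffectiveObstacle, InvalidParameterError


def _free_obstacle():
    return EffectiveObstacle((4.0, 4.0), 0.0)


class TestAdvance:
    def test_deterministic_limit(self):
        """D = 0 far from obstacles: x' = x + v(x)·Δt exactly."""
        theta = math.atan2(1, 10)
        flow = uniform_flow_field(8.0, 40.0, theta, resolution=16)
        x0 = np.array([[1.0, 2.0]])
        out = advance_particles(x0, flow, _free_obstacle(), 0.0, 1e-3,
                                np.zeros((1, 2)))
        v = 40.0 * np.array([-math.sin(theta), math.cos(theta)])
        np.testing.assert_allclose(out[0], x0[0] + v * 1e-3, rtol=1e-12)

    def test_free_brownian_msd(self):
        """v ≡ 0, no obstacles: MSD(t) = 4·D·t in two dimensions."""
        flow = uniform_flow_field(8.0, 0.0, 0.0, resolution=8)
        d_p = 0.7
        dt = 1e-3
        n, steps = 4000, 200
        rng = np.random.default_rng(5)
        pos = np.zeros((n, 2))
        for _ in range(steps):
            pos = advance_particles(pos, flow, _free_obstacle(), d_p, dt,
                                    rng.standard_normal((n, 2)))
        msd = (pos ** 2).sum(axis=1).mean()
        expect = 4.0 * d_p * steps * dt
        # sampling error of MSD ~ expect·sqrt(2/n)
        assert msd == pytest.approx(expect, rel=4 * math.sqrt(2.0 / n))

    def test_radial_reflection_oracle(self):
        """A step aimed at the post centre from distance s ends at the
        mirror distance outside, preserving path length."""
        r_eff = 3.54
        flow = uniform_flow_field(8.0, 40.0, -math.pi / 2, resolution=16)
        # velocity (40, 0): aim at the post at (4, 4) from the left
        d0 = 0.2          # start distance from the effective surface
        step = 0.35       # v·dt
        x0 = np.array([[4.0 - r_eff - d0, 4.0]])
        obs = EffectiveObstacle((4.0, 4.0), r_eff)
        out = advance_particles(x0, flow, obs, 0.0, step / 40.0,
                                np.zeros((1, 2)))
        final_dist = 4.0 - r_eff - (step - d0)   # mirrored overshoot
        assert out[0, 1] == pytest.approx(4.0, abs=1e-12)
        assert out[0, 0] == pytest.approx(final_dist, abs=1e-6)

    def test_tangential_step_untouched(self):
        r_eff = 3.0
        flow = uniform_flow_field(8.0, 40.0, 0.0, resolution=16)  # v=(0,40)
        x0 = np.array([[4.0 - r_eff - 0.5, 4.0]])
        obs = EffectiveObstacle((4.0, 4.0), r_eff)
        out = advance_particles(x0, flow, obs, 0.0, 1e-3, np.zeros((1, 2)))
        np.testing.assert_allclose(out[0], x0[0] + [0.0, 0.04], rtol=1e-12)

    def test_reflection_overflow_raises(self):
        """A step far larger than the pore space exhausts the reflection
        budget and is rejected with advice to shrink Δt."""
        r_eff = 3.9   # pore nearly closed
        flow = uniform_flow_field(8.0, 4000.0, -math.pi / 2, resolution=16)
        obs = EffectiveObstacle((4.0, 4.0), r_eff)
        x0 = np.array([[0.05, 4.0]])
        with pytest.raises(StepRejectionError):
            advance_particles(x0, flow, obs, 0.0, 1.0, np.zeros((1, 2)),
                              max_reflections=10, on_overflow="raise")


class TestEnsemble:
    def test_same_seed_bitwise_identical(self, flow_transport):
        obs = EffectiveObstacle((4.0, 4.0), 3.5)
        p = ParticleSpec(radius=0.3, diffusivity=0.7)
        cfg = SimulationConfig(n_particles=200, time_step=2e-4, n_steps=400,
                               record_every=40, seed=9)
        s1 = run_ensemble(cfg, flow_transport, obs, p)
        s2 = run_ensemble(cfg, flow_transport, obs, p)
        assert np.array_equal(s1.e_x, s2.e_x)
        assert np.array_equal(s1.e_xx, s2.e_xx)

    def test_single_deterministic_trajectory_has_zero_variance(
            self, flow_transport):
        obs = EffectiveObstacle((4.0, 4.0), 3.4)
        p = ParticleSpec(radius=0.2, diffusivity=1e-30)
        cfg = SimulationConfig(n_particles=1, time_step=2e-4, n_steps=2000,
                               record_every=100, seed=3)
        s = run_ensemble(cfg, flow_transport, obs, p)
        np.testing.assert_allclose(s.var_x, 0.0, atol=1e-12)

    def test_release_inside_obstacle_snapped_with_warning(
            self, flow_transport):
        obs = EffectiveObstacle((4.0, 4.0), 3.5)
        p = ParticleSpec(radius=0.3, diffusivity=0.7)
        cfg = SimulationConfig(n_particles=10, time_step=2e-4, n_steps=10,
                               record_every=1, seed=0)
        with pytest.warns(UserWarning, match="snapped"):
            run_ensemble(cfg, flow_transport, obs, p, release=(4.5, 4.0))

    def test_impenetrability_of_recorded_states(self, flow_transport,
                                                transport_lattice):
        """No stored particle position may lie inside an effective disc."""
        r_eff_obs = transport_lattice.obstacle_radius + 0.34
        obs = EffectiveObstacle((4.0, 4.0), r_eff_obs)
        p = ParticleSpec(radius=0.3, diffusivity=0.73,
                         electrostatic_displacement=0.04,
                         displacement_provenance="calibrated")
        cfg = SimulationConfig(n_particles=300, time_step=2e-4, n_steps=3000,
                               record_every=150, seed=11)
        s = run_ensemble(cfg, flow_transport, obs, p, store_positions=True)
        ell = flow_transport.cell_edge
        pts = s.positions.reshape(-1, 2)
        ctr = (np.floor(pts / ell) + 0.5) * ell
        dist = np.linalg.norm(pts - ctr, axis=1)
        assert dist.min() >= r_eff_obs - 1e-7 * ell


class TestRegression:
    def _stats(self, times, ex, var):
        n = len(times)
        return EnsembleStats(
            times=np.asarray(times), e_x=np.asarray(ex),
            e_y=2.0 * np.asarray(times),
            e_xx=np.asarray(var) + np.asarray(ex) ** 2,
            e_yy=np.zeros(n), n_particles=100,
            release=np.zeros(2),
            config=SimulationConfig(n_particles=100, time_step=1e-3,
                                    n_steps=100, record_every=1),
        )

    def test_slope_identities(self):
        """x_c = 3t gives W_x = 3; Var = 2·0.7·t gives D_xx = 0.7."""
        t = np.linspace(0, 10, 101)
        s = self._stats(t, 3.0 * t, 2.0 * 0.7 * t)
        co = fit_transport_coefficients(s)
        assert co.w_x == pytest.approx(3.0, rel=1e-12)
        assert co.w_y == pytest.approx(2.0, rel=1e-12)
        assert co.d_xx == pytest.approx(0.7, rel=1e-12)

    def test_short_series_rejected(self):
        t = np.linspace(0, 1, 12)
        s = self._stats(t, t, t)
        with pytest.raises(InvalidParameterError):
            fit_transport_coefficients(s, transient_fraction=0.9)

    def test_nonlinear_variance_warns(self):
        t = np.linspace(0, 10, 101)
        s = self._stats(t, 3 * t, 1.0 - np.exp(-3 * t))   # saturated growth
        with pytest.warns(UserWarning, match="asymptotic"):
            fit_transport_coefficients(s)

    def test_free_advection_diffusion_recovery(self, fluid):
        """Empty lattice: the fitted W equals the mean flow vector and
        D_xx the bare diffusivity, within 3 regression SE."""
        theta = math.atan2(1, 10)
        flow = uniform_flow_field(8.0, 40.0, theta, resolution=16)
        p = ParticleSpec.from_radius(0.3, fluid)
        cfg = SimulationConfig(n_particles=4000, time_step=2e-4,
                               n_steps=2000, record_every=25, seed=21)
        s = run_ensemble(cfg, flow, _free_obstacle(), p)
        co = fit_transport_coefficients(s)
        assert abs(co.w_x) < 3 * co.stderr_w_x + 1e-6
        assert abs(co.w_y - 40.0) < 3 * co.stderr_w_y + 1e-6
        assert abs(co.d_xx - p.diffusivity) < 3 * co.stderr_d_xx


class TestExitDistribution:
    def test_aligned_velocity_centres_at_zero(self):
        ed = gaussian_exit_distribution((0.0, 40.0), 0.7, 11000.0)
        assert ed.mean == 0.0

    def test_lattice_axis_velocity_recovers_kinematic_limit(self):
        """W along the lattice axis at tilt 1/10 puts the mean at
        L·tan Θ_L = 1100 μm for L = 11 mm."""
        w = np.array([math.sin(math.atan2(1, 10)), math.cos(math.atan2(1, 10))])
        ed = gaussian_exit_distribution(40.0 * w, 0.7, 11000.0)
        assert ed.mean == pytest.approx(1100.0, rel=1e-12)

    def test_sigma_scaling_with_dispersion(self):
        e1 = gaussian_exit_distribution((0.0, 40.0), 0.7, 11000.0)
        e2 = gaussian_exit_distribution((0.0, 40.0), 1.4, 11000.0)
        assert e2.sigma == pytest.approx(math.sqrt(2.0) * e1.sigma, rel=1e-12)

    def test_profile_normalized(self):
        ed = gaussian_exit_distribution((3.0, 40.0), 0.7, 11000.0)
        assert np.trapezoid(ed.pdf, ed.x) == pytest.approx(1.0, abs=1e-4)

    def test_no_transit_error(self):
        with pytest.raises(InvalidParameterError):
            gaussian_exit_distribution((1.0, 0.0), 0.7, 100.0)


class TestFirstPassage:
    def test_deterministic_exits_have_zero_spread(self, flow_transport):
        """D = 0: every realization follows the same path, so all exits
        coincide."""
        obs = EffectiveObstacle((4.0, 4.0), 3.4)
        p = ParticleSpec(radius=0.2, diffusivity=1e-30)
        cfg = SimulationConfig(n_particles=50, time_step=2e-4, n_steps=8000,
                               record_every=100, seed=2)
        exits, censored = first_passage_exit_positions(
            cfg, flow_transport, obs, p, (0.0, 0.0), 80.0)
        assert censored == 0
        assert exits.std() < 1e-9

    def test_mean_matches_moment_prediction(self, fluid):
        """Free advection–diffusion: the empirical first-passage mean and
        the coefficient-based prediction agree within 3 SE."""
        theta = math.atan2(1, 10)
        flow = uniform_flow_field(8.0, 40.0, theta, resolution=16)
        p = ParticleSpec.from_radius(0.3, fluid)
        length = 160.0
        cfg = SimulationConfig(n_particles=3000, time_step=2e-4,
                               n_steps=40000, record_every=100, seed=13)
        exits, censored = first_passage_exit_positions(
            cfg, flow, _free_obstacle(), p, (0.0, 0.0), length)
        assert censored == 0
        # coefficient route: W = (0, V), D_xx = D_p
        ed = gaussian_exit_distribution((0.0, 40.0), p.diffusivity, length)
        se = exits.std() / math.sqrt(len(exits))
        assert abs(exits.mean() - ed.mean) < 3 * se
        assert exits.std() == pytest.approx(ed.sigma, rel=0.1)

    def test_exits_gaussian_by_ks(self, fluid):
        """The empirical exit sample is consistent with the fitted
        Gaussian (small Kolmogorov–Smirnov distance at large N_s)."""
        theta = math.atan2(1, 10)
        flow = uniform_flow_field(8.0, 40.0, theta, resolution=16)
        p = ParticleSpec.from_radius(0.3, fluid)
        cfg = SimulationConfig(n_particles=3000, time_step=2e-4,
                               n_steps=30000, record_every=100, seed=17)
        exits, _ = first_passage_exit_positions(
            cfg, flow, _free_obstacle(), p, (0.0, 0.0), 120.0)
        ks = sps.kstest(exits, "norm",
                        args=(exits.mean(), exits.std())).statistic
        assert ks < 0.03
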