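"""Lanes, critical streamlines, critical radius and gliding trajectories."""

import math

import numpy as np
import pytest

from dldsim import (
    LatticeSpec,
    ParticleSpec,
    kinematic_exit_distribution,
    kinematic_trajectory,
    lane_decomposition,
    trace_streamline,
    uniform_flow_field,
)
from dldsim.core import EffectiveObstacle
from dldsim.kinematics import find_stagnation_points, streamline_periodicity


class TestStreamlines:
    def test_uniform_flow_streamline_is_straight(self):
        theta = math.atan2(1, 10)
        flow = uniform_flow_field(8.0, 40.0, theta, resolution=16)
        pts, status = trace_streamline(flow, (0.0, 0.0), "forward",
                                       max_length=50.0)
        assert status == "length"
        # all points on the line through the origin with direction
        # (-sinθ, cosθ)
        d = np.array([-math.sin(theta), math.cos(theta)])
        cross = pts[:, 0] * d[1] - pts[:, 1] * d[0]
        assert np.abs(cross).max() < 1e-6

    def test_periodic_image_congruence(self, flow_benchmark):
        """Streamlines through a point and its periodic image are
        translated copies of each other."""
        ell = flow_benchmark.cell_edge
        p1, _ = trace_streamline(flow_benchmark, (0.4, 0.0), "forward",
                                 max_length=2 * ell)
        p2, _ = trace_streamline(flow_benchmark, (0.4 + ell, 0.0), "forward",
                                 max_length=2 * ell)
        m = min(len(p1), len(p2))
        np.testing.assert_allclose(p2[:m] - np.array([ell, 0.0]), p1[:m],
                                   atol=1e-3)

    def test_stagnation_points_found_on_post(self, flow_benchmark):
        stag = find_stagnation_points(flow_benchmark)
        kinds = sorted(s["kind"] for s in stag)
        assert "attachment" in kinds and "detachment" in kinds

    def test_critical_streamline_repeats_every_tenth_row(
            self, flow_benchmark, benchmark_lattice):
        """At tilt 1/10 the critical streamline terminates on the post one
        column across and ten rows downstream, and its phase-matched
        transverse drift stays below one interpolation-grid spacing."""
        rep = streamline_periodicity(flow_benchmark, benchmark_lattice)
        assert rep["rows"] == 10
        assert abs(rep["columns"]) == 1
        assert rep["offset_error"] < flow_benchmark.spacing


class TestLaneDecomposition:
    def test_ten_lanes_each_tenth_of_flux(self, flow_benchmark,
                                          benchmark_lattice):
        dec = lane_decomposition(flow_benchmark, benchmark_lattice)
        assert dec.n_lanes == 10
        np.testing.assert_allclose(dec.flux_fractions, 0.1, atol=1e-3)

    def test_four_lanes_at_tilt_quarter(self, flow_tilt4, lattice_tilt4):
        dec = lane_decomposition(flow_tilt4, lattice_tilt4)
        assert dec.n_lanes == 4
        np.testing.assert_allclose(dec.flux_fractions, 0.25, atol=2.5e-3)

    def test_fractions_partition_total_flux(self, flow_benchmark,
                                            benchmark_lattice):
        dec = lane_decomposition(flow_benchmark, benchmark_lattice)
        assert dec.flux_fractions.sum() == pytest.approx(1.0, rel=1e-12)

    def test_critical_radius_within_gap(self, flow_benchmark,
                                        benchmark_lattice):
        dec = lane_decomposition(flow_benchmark, benchmark_lattice)
        assert 0.0 < dec.critical_radius < dec.gap_width / 2
        # the near-wall lane is wider than the gap/N mid-gap share because
        # the velocity vanishes at the wall
        assert dec.critical_radius > dec.gap_width / 10


class TestGlidingTrajectories:
    def test_free_streaming_matches_streamline(self):
        """With no obstacle in reach the hard-contact path is a streamline."""
        theta = math.atan2(1, 10)
        flow = uniform_flow_field(8.0, 40.0, theta, resolution=16)
        obs = EffectiveObstacle((4.0, 4.0), 0.0)
        path = kinematic_trajectory(flow, obs, start=(0.0, 0.0), span=40.0)
        d = np.array([-math.sin(theta), math.cos(theta)])
        cross = path.points[:, 0] * d[1] - path.points[:, 1] * d[0]
        assert np.abs(cross).max() < 1e-6
        assert path.classification == "zig-zag"

    def test_dichotomy_single_transition(self, flow_benchmark,
                                         benchmark_lattice):
        """Sweeping r_p^eff across R_crit flips zig-zag -> displaced once."""
        dec = lane_decomposition(flow_benchmark, benchmark_lattice)
        r_crit = dec.critical_radius
        sweep = [0.4 * r_crit, 0.8 * r_crit, 1.3 * r_crit, 2.0 * r_crit]
        classes = []
        for r_eff in sweep:
            obs = EffectiveObstacle(
                (4.0, 4.0), benchmark_lattice.obstacle_radius + r_eff)
            path = kinematic_trajectory(flow_benchmark, obs,
                                        start=(0.0, 0.0), span=8.0 * 30)
            classes.append(path.classification)
        assert classes == ["zig-zag", "zig-zag", "displaced", "displaced"]

    def test_points_never_inside_effective_obstacle(self, flow_benchmark,
                                                    benchmark_lattice):
        ell = benchmark_lattice.cell_edge
        r_eff_obs = benchmark_lattice.obstacle_radius + 0.2
        obs = EffectiveObstacle((4.0, 4.0), r_eff_obs)
        path = kinematic_trajectory(flow_benchmark, obs, start=(0.0, 0.0),
                                    span=8.0 * 20)
        centers = (np.floor(path.points / ell) + 0.5) * ell
        dist = np.linalg.norm(path.points - centers, axis=1)
        assert dist.min() >= r_eff_obs - 1e-5 * ell

    def test_supercritical_contacts_every_row(self, flow_benchmark,
                                              benchmark_lattice):
        obs = EffectiveObstacle((4.0, 4.0),
                                benchmark_lattice.obstacle_radius + 0.25)
        path = kinematic_trajectory(flow_benchmark, obs, start=(0.0, 0.0),
                                    span=8.0 * 20)
        rows = (path.points[-1, 1] - path.points[0, 1]) / 8.0
        assert path.classification == "displaced"
        # one glide per row once the particle locks onto the post column
        # (the lead-in rows before first contact carry none)
        assert rows - 4 <= len(path.contacts) <= rows + 1


class TestKinematicExit:
    def _decomp(self, flow, lattice):
        return lane_decomposition(flow, lattice)

    def test_subcritical_exits_at_zero(self, flow_benchmark,
                                       benchmark_lattice):
        dec = self._decomp(flow_benchmark, benchmark_lattice)
        p = ParticleSpec(radius=dec.critical_radius * 0.3, diffusivity=1.0)
        kin = kinematic_exit_distribution(p, dec, benchmark_lattice)
        assert kin.exit_position == 0.0
        assert not kin.displaced

    def test_supercritical_exit_position(self, flow_benchmark,
                                         benchmark_lattice):
        """L = 11 mm at tilt 1/10 puts displaced particles at 1100 μm."""
        dec = self._decomp(flow_benchmark, benchmark_lattice)
        p = ParticleSpec(radius=0.3, diffusivity=1.0)
        kin = kinematic_exit_distribution(p, dec, benchmark_lattice)
        assert kin.displaced
        assert kin.exit_position == pytest.approx(1100.0, rel=1e-12)

    def test_marginal_band_flagged(self, flow_benchmark, benchmark_lattice):
        dec = self._decomp(flow_benchmark, benchmark_lattice)
        p = ParticleSpec(radius=dec.critical_radius + 0.2 * dec.grid_spacing,
                         diffusivity=1.0)
        kin = kinematic_exit_distribution(p, dec, benchmark_lattice)
        assert kin.marginal

    def test_independent_of_flowrate(self, benchmark_lattice, fluid):
        """The exit prediction involves no velocity scale: doubling the
        flowrate leaves the lane geometry, hence the prediction, unchanged."""
        from dldsim import FluidSpec, solve_unit_cell_flow
        f2 = solve_unit_cell_flow(benchmark_lattice,
                                  FluidSpec(mean_flow_speed=80.0),
                                  resolution=200, solver_resolution=64)
        f1 = solve_unit_cell_flow(benchmark_lattice,
                                  FluidSpec(mean_flow_speed=40.0),
                                  resolution=200, solver_resolution=64)
        d1 = lane_decomposition(f1, benchmark_lattice)
        d2 = lane_decomposition(f2, benchmark_lattice)
        assert d1.critical_radius == pytest.approx(d2.critical_radius,
                                                   rel=1e-9)
        p = ParticleSpec(radius=0.3, diffusivity=1.0)
        k1 = kinematic_exit_distribution(p, d1, benchmark_lattice)
        k2 = kinematic_exit_distribution(p, d2, benchmark_lattice)
        assert k1.exit_position == k2.exit_position
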