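"""End-to-end prediction workflows: predict, calibrate, sweep, fixtures.

The full prediction chain for one particle size runs:

1. solve the unit-cell Stokes flow at the device tilt and flowrate;
2. obtain the electrostatic displacement d_F−EDL — from the double-layer
   force balance when the buffer is characterized, or from a calibration
   value — and form the effective radius r_p^eff = r_p + d_F−EDL;
3. build the effective obstacle (rejecting blocking geometries);
4. integrate the stochastic ensemble from a point release;
5. fit the macroscopic coefficients (W_x, W_y, D_xx) from the moment
   time scalings;
6. evaluate the Gaussian exit distribution at the outlet distance L.

When no buffer data are available, :func:`calibrate_displacement` tunes
d_F−EDL on a single reference particle size so the predicted mean exit
position matches a measured value; because the displacement is independent
of particle radius, the calibrated value is then reused unchanged for every
other size (:func:`size_sweep`), making the sweep a parameter-free
prediction.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .brownian import (
    EnsembleStats,
    ExitDistribution,
    SimulationConfig,
    TransportCoefficients,
    fit_transport_coefficients,
    gaussian_exit_distribution,
    run_ensemble,
)
from .core import (
    BlockingGeometryError,
    EffectiveObstacle,
    FluidSpec,
    InvalidParameterError,
    LatticeSpec,
    NumericalFailureError,
    ParticleSpec,
    build_effective_obstacle,
)
from .electrostatics import ElectrostaticParams, electrostatic_displacement
from .kinematics import (
    LaneDecomposition,
    kinematic_exit_distribution,
    lane_decomposition,
)
from .stokes import FlowField, solve_unit_cell_flow

__all__ = [
    "ConfigError",
    "RunManifest",
    "PredictionResult",
    "CalibrationResult",
    "load_config",
    "build_specs",
    "run_prediction",
    "calibrate_displacement",
    "size_sweep",
    "generate_fixture",
]

logger = logging.getLogger("dldsim")


class ConfigError(InvalidParameterError):
    """The run configuration is malformed or inconsistent."""


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

_DEFAULT_CONFIG = {
    "flow": {"resolution": 600, "solver_resolution": 160},
    "simulation": {
        "n_particles": 100_000,
        "steps_per_cell": 1000,
        "n_cells_span": 50,
        "record_every": 200,
        "seed": 0,
        "transient_fraction": 0.5,
    },
}


def load_config(path) -> dict:
    """Read a YAML run configuration and validate its section structure."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ConfigError(f"configuration root must be a mapping: {path}")
    validate_config(cfg)
    return cfg


def validate_config(cfg: dict) -> None:
    for section in ("lattice", "fluid"):
        if section not in cfg:
            raise ConfigError(f"missing required config section {section!r}")
    es = cfg.get("electrostatics")
    if es is not None:
        has_value = "displacement" in es
        has_params = "debye_length" in es
        if has_value == has_params:
            raise ConfigError(
                "electrostatics section must contain exactly one of "
                "'displacement' (calibrated mode) or the force-balance "
                "parameters starting with 'debye_length' (compute mode)"
            )


def build_specs(cfg: dict) -> tuple[LatticeSpec, FluidSpec]:
    try:
        lattice = LatticeSpec(**cfg["lattice"])
        fluid = FluidSpec(**cfg.get("fluid", {}))
    except (TypeError, KeyError) as exc:
        raise ConfigError(f"bad lattice/fluid section: {exc}") from exc
    return lattice, fluid


def resolve_displacement(cfg: dict, fluid: FluidSpec) -> tuple[float, str]:
    """Displacement value and its provenance from the electrostatics section."""
    es = cfg.get("electrostatics")
    if es is None:
        return 0.0, "none"
    if "displacement" in es:
        d = float(es["displacement"])
        if d < 0:
            raise ConfigError("calibrated displacement must be >= 0")
        return d, "calibrated"
    params = ElectrostaticParams(
        debye_length=es["debye_length"],
        particle_charge_density=es["particle_charge_density"],
        obstacle_charge_density=es["obstacle_charge_density"],
        relative_permittivity=es.get("relative_permittivity",
                                     fluid.relative_permittivity),
        viscosity=es.get("viscosity", fluid.viscosity),
        velocity=es.get("velocity", fluid.mean_flow_speed),
    )
    return electrostatic_displacement(params), "computed"


def simulation_config(cfg: dict, lattice: LatticeSpec, fluid: FluidSpec,
                      seed: int | None = None) -> SimulationConfig:
    """Build a :class:`SimulationConfig` from the config's simulation section.

    The time step follows the cell-crossing heuristic: ``steps_per_cell``
    steps (default 1000) for a mean-flow particle to traverse one cell;
    ``n_cells_span`` sets the total integrated time in cell crossings.
    """
    sim = {**_DEFAULT_CONFIG["simulation"], **cfg.get("simulation", {})}
    t_cell = lattice.cell_edge / fluid.mean_flow_speed
    dt = sim.get("time_step") or t_cell / sim["steps_per_cell"]
    n_steps = sim.get("n_steps") or int(sim["n_cells_span"] * t_cell / dt)
    return SimulationConfig(
        n_particles=sim["n_particles"],
        time_step=dt,
        n_steps=n_steps,
        record_every=sim["record_every"],
        seed=sim["seed"] if seed is None else seed,
        transient_fraction=sim["transient_fraction"],
    )


# ---------------------------------------------------------------------------
# Manifest
# ---------------------------------------------------------------------------

@dataclass
class RunManifest:
    """Provenance record of one workflow run."""

    config: dict
    seed: int
    displacement_provenance: str = "none"
    solver_residuals: dict = field(default_factory=dict)
    timings: dict = field(default_factory=dict)
    outputs: dict = field(default_factory=dict)

    def add_output(self, path) -> None:
        p = Path(path)
        digest = hashlib.sha256(p.read_bytes()).hexdigest()
        self.outputs[str(p)] = digest

    def write(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, default=str))


@dataclass(frozen=True)
class PredictionResult:
    """Outcome of the full stochastic prediction for one particle size."""

    particle: ParticleSpec
    obstacle: EffectiveObstacle
    coefficients: TransportCoefficients
    exit_distribution: ExitDistribution
    stats: EnsembleStats
    manifest: RunManifest


@dataclass(frozen=True)
class CalibrationResult:
    displacement: float
    bracket: tuple[float, float]
    achieved_mean: float
    target_mean: float
    evaluations: tuple


# ---------------------------------------------------------------------------
# Workflows
# ---------------------------------------------------------------------------

def run_prediction(cfg: dict, seed: int | None = None,
                   flow: FlowField | None = None,
                   particle: ParticleSpec | None = None) -> PredictionResult:
    """Execute the full prediction chain for the configured particle.

    ``flow`` may be passed to reuse an already-solved field (the flow
    geometry does not depend on the particle); ``particle`` overrides the
    config's particle section, e.g. inside sweeps.  Deterministic for fixed
    config and seed.
    """
    validate_config(cfg)
    lattice, fluid = build_specs(cfg)
    timings = {}
    t0 = time.perf_counter()
    if flow is None:
        fl = {**_DEFAULT_CONFIG["flow"], **cfg.get("flow", {})}
        flow = solve_unit_cell_flow(lattice, fluid,
                                    resolution=fl["resolution"],
                                    solver_resolution=fl["solver_resolution"])
    timings["flow_solve_s"] = time.perf_counter() - t0

    if particle is None:
        pcfg = cfg.get("particle")
        if not pcfg or "radius" not in pcfg:
            raise ConfigError("config needs a particle section with a radius")
        d, provenance = resolve_displacement(cfg, fluid)
        particle = ParticleSpec.from_radius(
            pcfg["radius"], fluid, electrostatic_displacement=d,
            displacement_provenance=provenance)

    obstacle = build_effective_obstacle(lattice, particle)
    sim = simulation_config(cfg, lattice, fluid, seed=seed)

    t0 = time.perf_counter()
    stats = run_ensemble(sim, flow, obstacle, particle)
    timings["ensemble_s"] = time.perf_counter() - t0
    coeffs = fit_transport_coefficients(stats)
    exit_dist = gaussian_exit_distribution(coeffs.w, coeffs.d_xx,
                                           lattice.device_length)
    manifest = RunManifest(
        config=cfg, seed=sim.seed,
        displacement_provenance=particle.displacement_provenance,
        solver_residuals={k: flow.meta.get(k) for k in
                          ("divergence_max", "boundary_slip_rel",
                           "achieved_tilt_tan")},
        timings=timings,
    )
    logger.info("prediction r_p=%.3g μm: mean=%.1f μm sigma=%.1f μm",
                particle.radius, exit_dist.mean, exit_dist.sigma)
    return PredictionResult(particle=particle, obstacle=obstacle,
                            coefficients=coeffs, exit_distribution=exit_dist,
                            stats=stats, manifest=manifest)


def _predicted_mean(cfg, flow, lattice, fluid, radius, displacement, seed):
    particle = ParticleSpec.from_radius(radius, fluid,
                                        electrostatic_displacement=displacement,
                                        displacement_provenance="calibrated")
    res = run_prediction(cfg, seed=seed, flow=flow, particle=particle)
    return res.exit_distribution.mean


def calibrate_displacement(cfg: dict, reference_radius: float,
                           target_mean: float,
                           tolerance: float = 2.0e-3,
                           max_iterations: int = 40,
                           seed: int | None = None,
                           flow: FlowField | None = None) -> CalibrationResult:
    """Find d_F−EDL so the predicted mean exit position hits a measurement.

    Scalar bisection on ``d ↦ x̄_L(d; reference_radius) − target_mean`` over
    the feasible interval [0, d_max), d_max the largest displacement that
    still leaves a gap for the particle centre.  Every objective evaluation
    uses the *same* seed (common random numbers), which makes the noisy
    objective quasi-deterministic and monotone, so bisection is reliable.
    ``tolerance`` is the bracket width in μm at which iteration stops.

    Raises an infeasible-target error when the target lies outside the range
    achievable between d = 0 and d = d_max, and reports the full endpoint
    scan if the response fails to be monotone between the endpoints.
    """
    validate_config(cfg)
    lattice, fluid = build_specs(cfg)
    if not (0.0 <= target_mean <= lattice.device_length * lattice.tilt_ratio):
        raise InvalidParameterError(
            f"target mean {target_mean} μm outside the achievable range "
            f"[0, {lattice.device_length * lattice.tilt_ratio}] μm")
    if flow is None:
        fl = {**_DEFAULT_CONFIG["flow"], **cfg.get("flow", {})}
        flow = solve_unit_cell_flow(lattice, fluid,
                                    resolution=fl["resolution"],
                                    solver_resolution=fl["solver_resolution"])
    seed = cfg.get("simulation", {}).get("seed", 0) if seed is None else seed
    d_max = lattice.cell_edge / 2.0 - lattice.obstacle_radius \
        - reference_radius - 1e-3 * lattice.cell_edge
    if d_max <= 0:
        raise BlockingGeometryError(
            "reference particle already blocks the gap at zero displacement")

    evaluations = []

    def f(d):
        m = _predicted_mean(cfg, flow, lattice, fluid, reference_radius, d, seed)
        evaluations.append((d, m))
        logger.info("calibration eval d=%.4f μm -> mean=%.1f μm", d, m)
        return m - target_mean

    f_lo = f(0.0)
    if abs(f_lo) <= 1e-9 or target_mean == 0.0:
        return CalibrationResult(0.0, (0.0, 0.0), f_lo + target_mean,
                                 target_mean, tuple(evaluations))
    f_hi = f(d_max)
    if f_lo > 0 or f_hi < 0:
        if f_lo > f_hi:
            raise NumericalFailureError(
                "non-monotone calibration response between endpoints; "
                f"scan: {evaluations}")
        raise InvalidParameterError(
            f"target mean {target_mean} μm not achievable: model range is "
            f"[{f_lo + target_mean:.1f}, {f_hi + target_mean:.1f}] μm "
            f"for d in [0, {d_max:.3f}]")
    lo, hi = 0.0, d_max
    for _ in range(max_iterations):
        if hi - lo <= tolerance:
            break
        mid = 0.5 * (lo + hi)
        if f(mid) < 0:
            lo = mid
        else:
            hi = mid
    d_star = 0.5 * (lo + hi)
    achieved = _predicted_mean(cfg, flow, lattice, fluid, reference_radius,
                               d_star, seed)
    return CalibrationResult(displacement=d_star, bracket=(lo, hi),
                             achieved_mean=achieved, target_mean=target_mean,
                             evaluations=tuple(evaluations))


def size_sweep(cfg: dict, radii, displacement: float,
               variants=("kinematic", "hindrance", "hindrance+ED"),
               seed: int | None = None,
               flow: FlowField | None = None) -> pd.DataFrame:
    """Predict exit statistics across particle sizes at one displacement.

    Runs the requested model variants per radius with the *same*
    displacement for every size (it is radius independent):

    * ``"kinematic"`` — diffusion-free delta prediction (0 or L·tanΘ_L);
    * ``"hindrance"`` — stochastic model with d = 0 (steric only);
    * ``"hindrance+ED"`` — stochastic model with the given displacement.

    Returns a tidy DataFrame with one row per (radius, variant); radii are
    processed in increasing order and failures (e.g. blocking geometries)
    are recorded as rows with a ``status`` message, partial results being
    retained.
    """
    validate_config(cfg)
    lattice, fluid = build_specs(cfg)
    radii = sorted(float(r) for r in radii)
    if flow is None:
        fl = {**_DEFAULT_CONFIG["flow"], **cfg.get("flow", {})}
        flow = solve_unit_cell_flow(lattice, fluid,
                                    resolution=fl["resolution"],
                                    solver_resolution=fl["solver_resolution"])
    decomposition = lane_decomposition(flow, lattice) \
        if "kinematic" in variants else None

    rows = []
    for r_p in radii:
        for variant in variants:
            d = {"kinematic": displacement, "hindrance": 0.0,
                 "hindrance+ED": displacement}[variant]
            provenance = "none" if d == 0.0 else "calibrated"
            row = {"radius": r_p, "variant": variant,
                   "effective_radius": r_p + d, "displacement": d,
                   "status": "ok"}
            try:
                particle = ParticleSpec.from_radius(
                    r_p, fluid, electrostatic_displacement=d,
                    displacement_provenance=provenance)
                if variant == "kinematic":
                    kin = kinematic_exit_distribution(particle, decomposition,
                                                      lattice)
                    row.update(mean=kin.exit_position, sigma=0.0,
                               marginal=kin.marginal)
                else:
                    res = run_prediction(cfg, seed=seed, flow=flow,
                                         particle=particle)
                    row.update(
                        mean=res.exit_distribution.mean,
                        sigma=res.exit_distribution.sigma,
                        w_x=res.coefficients.w_x,
                        w_y=res.coefficients.w_y,
                        d_xx=res.coefficients.d_xx,
                    )
            except (BlockingGeometryError, NumericalFailureError) as exc:
                row["status"] = f"{type(exc).__name__}: {exc}"
            rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Fixtures
# ---------------------------------------------------------------------------

def generate_fixture(kind: str, **params) -> tuple[dict, dict]:
    """Ready-to-run configurations with analytic reference values.

    Kinds
    -----
    ``"uniform-flow"``
        Obstacle-free cell: free advection–diffusion, for which the exit
        distribution is exactly Gaussian with mean 0 and
        σ_L = sqrt(2·D_p·L/V).
    ``"single-circle"``
        A periodic cell with one post and the analytic specular-reflection
        oracle for a radial step against a circle.
    ``"huang-like"``
        The microfluidic benchmark device: tilt 1/10, cell edge 8 μm,
        device length L = 11 mm, mean flow speed 40 or 400 μm/s, particle
        radii 0.3–0.5 μm.  The post radius (not published with the rest of
        the geometry) defaults to 3.2 μm — a 1.6 μm gap, wide enough for
        every radius in the sweep to transit.

    Returns ``(config, reference)``.
    """
    if kind == "uniform-flow":
        ell = params.get("cell_edge", 8.0)
        v = params.get("mean_flow_speed", 40.0)
        length = params.get("device_length", 1000.0)
        radius = params.get("particle_radius", 0.3)
        cfg = {
            "lattice": {"cell_edge": ell, "obstacle_radius": 0.0,
                        "tilt_numerator": 1, "tilt_denominator": 10,
                        "device_length": length},
            "fluid": {"mean_flow_speed": v},
            "particle": {"radius": radius},
            "flow": {"resolution": 64, "solver_resolution": 0},
        }
        fluid = FluidSpec(mean_flow_speed=v)
        d_p = ParticleSpec.from_radius(radius, fluid).diffusivity
        ref = {"mean": 0.0, "sigma": math.sqrt(2.0 * d_p * length / v),
               "diffusivity": d_p}
        return cfg, ref
    if kind == "single-circle":
        ell = params.get("cell_edge", 8.0)
        r_o = params.get("obstacle_radius", 3.0)
        r_eff = params.get("effective_radius", r_o)
        start_distance = params.get("start_distance", r_eff + 0.1)
        step = params.get("step", 0.3)
        cfg = {
            "lattice": {"cell_edge": ell, "obstacle_radius": r_o,
                        "tilt_numerator": 1, "tilt_denominator": 10,
                        "device_length": 1000.0},
            "fluid": {},
        }
        # radial approach: travel (d0 − R) to the wall, mirror the rest
        pen = step - (start_distance - r_eff)
        final = start_distance if pen <= 0 else r_eff + pen
        ref = {"final_distance": final,
               "touches": pen > 0,
               "path_length": step}
        return cfg, ref
    if kind == "huang-like":
        v = params.get("mean_flow_speed", 40.0)
        if v not in (40.0, 400.0):
            logger.warning("huang-like fixture normally runs at 40 or 400 μm/s")
        ell = params.get("cell_edge", 8.0)
        r_o = params.get("obstacle_radius", 3.2)
        radii = list(params.get("radii", (0.3, 0.35, 0.4, 0.45, 0.5)))
        cfg = {
            "lattice": {"cell_edge": ell, "obstacle_radius": r_o,
                        "tilt_numerator": 1, "tilt_denominator": 10,
                        "device_length": 11_000.0},
            "fluid": {"mean_flow_speed": v},
            "particle": {"radius": radii[0]},
            "sweep": {"radii": radii},
        }
        ref = {"supercritical_exit": 11_000.0 / 10.0, "radii": radii}
        return cfg, ref
    raise InvalidParameterError(f"unknown fixture kind {kind!r}")
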