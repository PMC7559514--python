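"""Electric-double-layer standoff between charged particle and post surfaces.

Both the particle and the posts acquire a surface charge when wetted by the
buffer.  When the two charges have the same sign the overlap of the electric
double layers produces a repulsive force that keeps the particle surface a
finite distance away from the post even "in contact".  Following the lumped
description of this effect, that equilibrium distance — the *electrostatic
displacement* d_F−EDL — is where double-layer repulsion balances the viscous
drag pressing the particle against the post, and it is independent of the
particle radius: for a sphere, both the Derjaguin double-layer force and the
Stokes drag scale linearly with radius, so the radius cancels from the
balance.  The displacement acts as a hard-core shell: it is simply added to
the particle radius to form the effective radius r_p^eff = r_p + d_F−EDL.

With λ_D the Debye length, ρ_p and ρ_s the particle/post surface charge
densities, ε_r ε₀ the buffer permittivity, μ the viscosity and V the
characteristic flow speed, the balance gives

    d_F−EDL = −λ_D ln[ (−ρ_p²ρ_s² + sqrt(ρ_p⁴ρ_s⁴ +
                        (ρ_p²+ρ_s²)³ μ ε_r ε₀ V / λ_D)) / (ρ_p²+ρ_s²)² ]

clamped below at zero: when the argument of the logarithm reaches one —
drag strong enough to dominate the repulsion at every separation — the
standoff vanishes, a physically meaningful high-flowrate regime rather than
an error.  Properties that pin the expression down: the result does not
depend on r_p, is non-increasing in V and continuous at the clamp, and
d/λ_D depends on (V, λ_D) only through V/λ_D.

The formula is evaluated in SI units (m, Pa·s, C/m², m/s) and converted at
the boundary, because it mixes ε₀ with surface charge densities; lengths
going in and out of this module are μm as everywhere else in the package.

When buffer composition is unknown (so λ_D and the charge densities cannot
be estimated), the displacement can instead be *calibrated*: fixed so that
the predicted mean exit position of one reference particle size matches a
measurement, then reused unchanged for every other size — see
:func:`displacement_from_calibration` and
:func:`dldsim.pipeline.calibrate_displacement`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .core import (
    VACUUM_PERMITTIVITY,
    FluidSpec,
    InvalidParameterError,
    ParticleSpec,
)

__all__ = [
    "ElectrostaticParams",
    "electrostatic_displacement",
    "displacement_from_calibration",
    "UnsupportedConfigurationError",
]


class UnsupportedConfigurationError(InvalidParameterError):
    """Raised for attractive (opposite-sign) surface-charge configurations."""


@dataclass(frozen=True)
class ElectrostaticParams:
    """Inputs of the double-layer force balance.

    Attributes
    ----------
    debye_length:
        λ_D in nm (set by the ionic strength of the buffer; accepted as an
        input, not computed from composition).
    particle_charge_density, obstacle_charge_density:
        ρ_el,p and ρ_el,s in C/m².  Must share the same sign (repulsive
        double-layer overlap); the attractive case is out of scope.
    relative_permittivity:
        ε_r of the buffer (≈ 78.5 for water at 25 °C).
    viscosity:
        μ in Pa·s.
    velocity:
        Characteristic flow speed V in μm/s (the mean flow speed of the
        device).
    """

    debye_length: float
    particle_charge_density: float
    obstacle_charge_density: float
    relative_permittivity: float = 78.5
    viscosity: float = 1.0e-3
    velocity: float = 40.0

    def __post_init__(self) -> None:
        if self.debye_length <= 0:
            raise InvalidParameterError("debye_length must be positive")
        if self.relative_permittivity <= 0 or self.viscosity <= 0:
            raise InvalidParameterError(
                "permittivity and viscosity must be positive")
        if self.velocity < 0:
            raise InvalidParameterError("velocity must be non-negative")
        if self.particle_charge_density == 0 or self.obstacle_charge_density == 0:
            raise InvalidParameterError("surface charge densities must be nonzero")
        if self.particle_charge_density * self.obstacle_charge_density < 0:
            raise UnsupportedConfigurationError(
                "opposite-sign surface charges give an attractive double "
                "layer; only the repulsive (equal-sign) case is modelled"
            )


def electrostatic_displacement(params: ElectrostaticParams) -> float:
    """Equilibrium standoff d_F−EDL in μm, clamped below at zero.

    Evaluates the drag/double-layer force balance described in the module
    docstring.  The output is independent of the particle radius by
    construction; it decreases monotonically with the flow speed V until the
    clamp is reached, and vanishes (continuously) beyond it.
    """
    lam = params.debye_length * 1e-9          # nm -> m
    v = params.velocity * 1e-6                # μm/s -> m/s
    if v == 0.0:
        # no drag: the repulsion pushes the particle out to the range of the
        # double layer; the balance has no finite root.  Treat as invalid.
        raise InvalidParameterError(
            "velocity must be positive for a finite standoff")
    rp2 = params.particle_charge_density ** 2
    rs2 = params.obstacle_charge_density ** 2
    s = rp2 + rs2
    drag = (params.viscosity * params.relative_permittivity
            * VACUUM_PERMITTIVITY * v / lam)
    arg = (-rp2 * rs2 + math.sqrt(rp2 ** 2 * rs2 ** 2 + s ** 3 * drag)) / s ** 2
    if arg >= 1.0:
        return 0.0  # drag dominates at every separation: no standoff
    d_m = -lam * math.log(arg)
    return d_m * 1e6  # m -> μm


def displacement_from_calibration(particle: ParticleSpec,
                                  value: float) -> ParticleSpec:
    """Install a calibration-supplied displacement into a particle spec.

    Bypasses the force balance: ``value`` (μm, must be >= 0) is typically the
    output of :func:`dldsim.pipeline.calibrate_displacement` on a reference
    particle size.  Because the displacement is radius independent, the same
    value is reused unchanged for every other size.  The returned spec
    records ``"calibrated"`` provenance so run manifests can distinguish
    calibrated from computed predictions.

    Installing ``0`` recovers the pure hindrance (steric-only) model.
    """
    if value < 0:
        raise InvalidParameterError("calibrated displacement must be >= 0")
    return particle.with_displacement(value, "calibrated")
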