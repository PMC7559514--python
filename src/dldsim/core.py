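"""Shared physical types, unit conventions and constants for DLD transport models.

Unit system
-----------
Lengths are expressed in micrometres (μm), times in seconds, velocities in
μm/s and diffusivities in μm²/s throughout the package — the natural scales
of a microfluidic obstacle array.  SI units appear only inside the
electric-double-layer force balance (:mod:`dldsim.electrostatics`), which
mixes surface charge densities (C/m²) with the vacuum permittivity; the
conversion happens at that module's boundary.

Frames
------
Two Cartesian frames are used:

* the *channel frame*: mean flow along +y, transverse (separation) coordinate
  x — the frame in which exit distributions are reported;
* the *lattice frame*: axes aligned with the square obstacle array.  The
  array is tilted by the angle ``Θ_L = atan(M/N)`` relative to the channel,
  so in the lattice frame the mean flow direction is ``(-sin Θ_L, cos Θ_L)``.

All microscale computation (flow solve, particle stepping) happens in the
lattice frame, where the geometry is a simple axis-aligned periodic cell;
:func:`frame_transform` converts between the two.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "BOLTZMANN_CONSTANT",
    "VACUUM_PERMITTIVITY",
    "DLDError",
    "InvalidParameterError",
    "BlockingGeometryError",
    "NumericalFailureError",
    "LatticeSpec",
    "FluidSpec",
    "ParticleSpec",
    "EffectiveObstacle",
    "stokes_einstein_diffusivity",
    "effective_particle_radius",
    "build_effective_obstacle",
    "frame_transform",
    "rotation_matrix",
]

#: Boltzmann constant, J/K (CODATA 2018 exact value).
BOLTZMANN_CONSTANT = 1.380649e-23

#: Vacuum permittivity ε₀, F/m (CODATA 2018).
VACUUM_PERMITTIVITY = 8.8541878128e-12


class DLDError(Exception):
    """Base class for all errors raised by dldsim."""


class InvalidParameterError(DLDError, ValueError):
    """A physical parameter is out of its admissible range."""


class BlockingGeometryError(DLDError):
    """The effective obstacle closes the inter-obstacle gap: the particle
    centre has no path through the array."""


class NumericalFailureError(DLDError):
    """A numerical procedure failed to converge; carries diagnostics."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LatticeSpec:
    """Geometry of the periodic obstacle array.

    Parameters
    ----------
    cell_edge:
        Edge length ℓ of the square unit cell, μm.
    obstacle_radius:
        Radius R_o of the cylindrical posts, μm.  Must satisfy
        ``0 <= R_o < ℓ/2`` so that neighbouring posts do not touch.
    tilt_numerator, tilt_denominator:
        Integers M < N defining the array tilt ``tan Θ_L = M/N`` relative to
        the channel axis.  At this tilt the flow through the cell decomposes
        into N flux tubes ("lanes").
    device_length:
        Streamwise distance L from the injection point to the outlet
        cross-section, μm.
    frame:
        Tag recording the frame convention of coordinates attached to this
        lattice; ``"lattice"`` (axis-aligned posts) is the computational
        default.
    """

    cell_edge: float
    obstacle_radius: float
    tilt_numerator: int
    tilt_denominator: int
    device_length: float
    frame: str = "lattice"

    def __post_init__(self) -> None:
        if self.cell_edge <= 0:
            raise InvalidParameterError("cell_edge must be positive")
        if not (0 <= self.obstacle_radius < self.cell_edge / 2):
            raise InvalidParameterError(
                "obstacle_radius must lie in [0, cell_edge/2): got "
                f"{self.obstacle_radius} for cell_edge {self.cell_edge}"
            )
        if not (1 <= self.tilt_numerator < self.tilt_denominator):
            raise InvalidParameterError(
                "tilt must satisfy 1 <= M < N, got "
                f"M={self.tilt_numerator}, N={self.tilt_denominator}"
            )
        if self.device_length <= 0:
            raise InvalidParameterError("device_length must be positive")
        if self.frame not in ("lattice", "channel"):
            raise InvalidParameterError(f"unknown frame tag {self.frame!r}")

    @property
    def tilt_angle(self) -> float:
        """Tilt angle Θ_L = atan(M/N), radians."""
        return math.atan2(self.tilt_numerator, self.tilt_denominator)

    @property
    def tilt_ratio(self) -> float:
        """tan Θ_L = M/N."""
        return self.tilt_numerator / self.tilt_denominator

    @property
    def gap(self) -> float:
        """Clear gap between neighbouring posts, ℓ − 2 R_o, μm."""
        return self.cell_edge - 2.0 * self.obstacle_radius


@dataclass(frozen=True)
class FluidSpec:
    """Properties of the suspending buffer and the imposed mean flow.

    viscosity in Pa·s, temperature in K, mean_flow_speed V in μm/s.
    ``relative_permittivity`` is used only by the electrostatics module.
    """

    viscosity: float = 1.0e-3
    temperature: float = 298.0
    relative_permittivity: float = 78.5
    mean_flow_speed: float = 40.0

    def __post_init__(self) -> None:
        for name in ("viscosity", "temperature", "relative_permittivity",
                     "mean_flow_speed"):
            if getattr(self, name) <= 0:
                raise InvalidParameterError(f"{name} must be strictly positive")


@dataclass(frozen=True)
class ParticleSpec:
    """A spherical particle: physical radius, bare diffusivity and the
    electric-double-layer standoff distance that dilates it.

    Attributes
    ----------
    radius:
        Physical radius r_p, μm.
    diffusivity:
        Bare Brownian diffusivity D_p, μm²/s (Stokes–Einstein unless
        supplied directly).
    electrostatic_displacement:
        Standoff distance d_F−EDL at which double-layer repulsion balances
        viscous drag, μm.  Independent of particle radius.
    displacement_provenance:
        ``"computed"`` (from the double-layer force balance),
        ``"calibrated"`` (matched to a measured mean exit position) or
        ``"none"`` (pure steric model, d = 0).
    """

    radius: float
    diffusivity: float
    electrostatic_displacement: float = 0.0
    displacement_provenance: str = "none"

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise InvalidParameterError("particle radius must be positive")
        if self.diffusivity <= 0:
            raise InvalidParameterError("diffusivity must be positive")
        if self.electrostatic_displacement < 0:
            raise InvalidParameterError(
                "electrostatic displacement must be non-negative"
            )
        if self.displacement_provenance not in ("computed", "calibrated", "none"):
            raise InvalidParameterError(
                f"unknown provenance {self.displacement_provenance!r}"
            )

    @property
    def effective_radius(self) -> float:
        """r_p^eff = r_p + d_F−EDL, μm."""
        return self.radius + self.electrostatic_displacement

    def with_displacement(self, d: float, provenance: str) -> "ParticleSpec":
        """Return a copy with a new electrostatic displacement installed."""
        if d < 0:
            raise InvalidParameterError("displacement must be non-negative")
        return replace(self, electrostatic_displacement=d,
                       displacement_provenance=provenance)

    @classmethod
    def from_radius(cls, radius: float, fluid: FluidSpec,
                    electrostatic_displacement: float = 0.0,
                    displacement_provenance: str = "none") -> "ParticleSpec":
        """Build a spec with the Stokes–Einstein diffusivity for ``fluid``."""
        d_p = stokes_einstein_diffusivity(radius, fluid.temperature,
                                          fluid.viscosity)
        return cls(radius=radius, diffusivity=d_p,
                   electrostatic_displacement=electrostatic_displacement,
                   displacement_provenance=displacement_provenance)


@dataclass(frozen=True)
class EffectiveObstacle:
    """The obstacle as seen by the particle centre: the physical post
    dilated by the particle's effective radius.

    ``center`` is in the lattice frame (μm); ``radius`` is
    R_eff = R_o + r_p^eff (μm).  The particle centre can never enter the
    disc of radius ``radius`` around ``center`` (nor around any of its
    lattice translates).
    """

    center: tuple[float, float]
    radius: float


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def stokes_einstein_diffusivity(radius: float, temperature: float,
                                viscosity: float) -> float:
    """Bare diffusivity of a sphere, D_p = k_B T / (6 π r_p μ), in μm²/s.

    Parameters are in package units: ``radius`` in μm, ``temperature`` in K,
    ``viscosity`` in Pa·s.
    """
    if radius <= 0 or temperature <= 0 or viscosity <= 0:
        raise InvalidParameterError(
            "radius, temperature and viscosity must all be strictly positive"
        )
    r_m = radius * 1e-6
    d_si = BOLTZMANN_CONSTANT * temperature / (6.0 * math.pi * r_m * viscosity)
    return d_si * 1e12  # m²/s -> μm²/s


def effective_particle_radius(radius: float, displacement: float) -> float:
    """Effective (hard-core) radius r_p^eff = r_p + d_F−EDL, μm.

    The electrostatic standoff acts as a shell of thickness d_F−EDL around
    the particle; it does not depend on the particle radius.
    """
    if radius <= 0:
        raise InvalidParameterError("radius must be positive")
    if displacement < 0:
        raise InvalidParameterError(
            "displacement must be non-negative (the force balance clamps "
            "negative equilibrium distances to zero upstream)"
        )
    return radius + displacement


def build_effective_obstacle(lattice: LatticeSpec,
                             particle: ParticleSpec) -> EffectiveObstacle:
    """Dilate the physical post by the particle's effective radius.

    Raises
    ------
    BlockingGeometryError
        If ``R_eff >= ℓ/2``: the discs around neighbouring posts touch or
        overlap and no gap remains for the particle centre.
    """
    r_eff = particle.effective_radius
    radius = lattice.obstacle_radius + r_eff
    if radius >= lattice.cell_edge / 2.0:
        raise BlockingGeometryError(
            f"effective obstacle radius {radius:.4g} μm >= half cell edge "
            f"{lattice.cell_edge / 2:.4g} μm: particle of effective radius "
            f"{r_eff:.4g} μm cannot pass the gap"
        )
    half = lattice.cell_edge / 2.0
    return EffectiveObstacle(center=(half, half), radius=radius)


def rotation_matrix(angle: float) -> np.ndarray:
    """Counter-clockwise rotation matrix by ``angle`` (radians)."""
    c, s = math.cos(angle), math.sin(angle)
    return np.array([[c, -s], [s, c]])


def frame_transform(vec, tilt_angle: float, direction: str) -> np.ndarray:
    """Rotate points/vectors between the channel and lattice frames.

    The lattice frame is rotated counter-clockwise by Θ_L relative to the
    channel frame, so ``channel→lattice`` applies R(+Θ_L) to components and
    ``lattice→channel`` applies R(−Θ_L).  Round-tripping is the identity to
    machine precision; norms are preserved.

    Parameters
    ----------
    vec:
        Array of shape (2,) or (..., 2).
    tilt_angle:
        Θ_L in radians.
    direction:
        ``"channel_to_lattice"`` or ``"lattice_to_channel"``.
    """
    if direction == "channel_to_lattice":
        rot = rotation_matrix(tilt_angle)
    elif direction == "lattice_to_channel":
        rot = rotation_matrix(-tilt_angle)
    else:
        raise InvalidParameterError(
            "direction must be 'channel_to_lattice' or 'lattice_to_channel'"
        )
    v = np.asarray(vec, dtype=float)
    return v @ rot.T
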