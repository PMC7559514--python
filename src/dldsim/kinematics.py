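"""Deterministic (diffusion-free) particle transport: lanes and gliding.

At tilt tan Θ_L = M/N the flow through one unit cell splits into N flux
tubes ("lanes") delimited by the *critical streamlines* — streamlines that
originate from and terminate on post surfaces.  Because the stream function
is constant on each post and posts of successive rows sit on ψ levels spaced
by exactly ``<u>·ℓ`` (one M/N-th of the per-cell flowrate), the critical
levels partition the gap cross-section into N lanes each carrying 1/N of the
flowrate, and the lane pattern repeats every N rows.  The thickness of the
lane adjacent to the post, measured across the gap, is the critical radius
R_crit: a particle whose effective radius exceeds it is bumped across one
lane at every post and travels along the lattice axis (displaced mode),
while a smaller particle stays in its lane and follows the mean flow
(zig-zag mode).  The resulting diffusion-free exit distribution is an
all-or-nothing delta: transverse exit position 0 for subcritical particles,
L·tan Θ_L for supercritical ones, independent of flowrate.

In the hard-contact picture a finite-size particle follows the unperturbed
velocity evaluated at its centre until the centre touches the *effective*
post (radius R_o + r_p^eff); there the normal velocity component is
annihilated and the tangential one preserved, so the particle glides around
the post and detaches where the flow pulls away from the surface.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp

from .core import (
    EffectiveObstacle,
    InvalidParameterError,
    LatticeSpec,
    NumericalFailureError,
    ParticleSpec,
)
from .stokes import FlowField, stream_function_at, velocity_at

__all__ = [
    "LaneDecomposition",
    "KinematicPath",
    "KinematicExit",
    "trace_streamline",
    "find_stagnation_points",
    "lane_decomposition",
    "kinematic_trajectory",
    "kinematic_exit_distribution",
]


@dataclass(frozen=True)
class LaneDecomposition:
    """Lane structure of the unit-cell flow at tilt M/N.

    ``boundary_positions`` are distances (μm) from the left post surface
    along the gap cross-section at which the critical ψ levels are crossed;
    position 0 is the post surface itself.  ``flux_fractions`` are the lane
    flowrates as fractions of the per-cell total (they sum to 1);
    ``critical_radius`` is the thickness of the lane adjacent to the post.
    """

    n_lanes: int
    psi_levels: np.ndarray
    boundary_positions: np.ndarray
    flux_fractions: np.ndarray
    critical_radius: float
    total_flux: float
    gap_width: float
    grid_spacing: float
    meta: dict = field(default_factory=dict, compare=False)

    @property
    def first_lane_width(self) -> float:
        return self.critical_radius


@dataclass(frozen=True)
class KinematicPath:
    """A hard-contact gliding trajectory.

    ``points`` is the (n, 2) lattice-frame polyline of the particle centre;
    ``contacts`` lists (entry_index, exit_index) pairs of glide intervals.
    ``classification`` is ``"zig-zag"`` (net motion along the mean flow),
    ``"displaced"`` (net motion along the lattice axis) or ``"stalled"``.
    ``lateral_displacement_per_row`` is the channel-frame transverse advance
    per obstacle row crossed.
    """

    points: np.ndarray
    contacts: list
    lateral_displacement_per_row: float
    classification: str
    status: str = "ok"


@dataclass(frozen=True)
class KinematicExit:
    """Dirac-delta exit prediction of the diffusion-free model."""

    exit_position: float      # channel-frame x at the outlet, μm
    displaced: bool
    marginal: bool            # |r_eff − R_crit| below the resolution band
    effective_radius: float
    critical_radius: float


# ---------------------------------------------------------------------------
# Streamlines
# ---------------------------------------------------------------------------

def _nearest_post_center(points: np.ndarray, ell: float) -> np.ndarray:
    """Centre of the post nearest to each point (posts at cell centres)."""
    return (np.floor(np.asarray(points) / ell) + 0.5) * ell


def trace_streamline(flow: FlowField, start, direction: str = "forward",
                     max_length: float | None = None,
                     contact_offset: float | None = None,
                     speed_threshold_rel: float = 1e-4,
                     rtol: float = 1e-8) -> tuple[np.ndarray, str]:
    """Trace a streamline by arclength integration of dx/ds = v/|v|.

    Terminates at ``max_length`` (default 3 N ℓ / cos Θ), on close approach
    to a post surface (distance below ``contact_offset``, default half a
    grid spacing) or at a stagnation point (speed below
    ``speed_threshold_rel`` times the mean speed).

    Returns the polyline and a status string:
    ``"length"``, ``"contact"`` or ``"stagnation"``.
    """
    start = np.asarray(start, dtype=float)
    ell = flow.cell_edge
    if max_length is None:
        max_length = 3.0 * ell / max(math.cos(flow.tilt_angle), 0.1) * 10
    if contact_offset is None:
        contact_offset = 0.5 * flow.spacing
    sgn = {"forward": 1.0, "backward": -1.0}.get(direction)
    if sgn is None:
        raise InvalidParameterError("direction must be 'forward' or 'backward'")
    v_floor = speed_threshold_rel * flow.mean_speed
    r_o = flow.obstacle_radius

    v0 = velocity_at(flow, start)
    if np.hypot(*v0) < v_floor:
        return start[None, :], "stagnation"

    def rhs(_s, xy):
        v = velocity_at(flow, xy)
        speed = math.hypot(v[0], v[1])
        if speed < v_floor:
            return np.zeros(2)
        return sgn * v / speed

    def ev_contact(_s, xy):
        if r_o == 0.0:
            return 1.0
        c = _nearest_post_center(xy, ell)
        return math.hypot(xy[0] - c[0], xy[1] - c[1]) - r_o - contact_offset

    ev_contact.terminal = True
    ev_contact.direction = -1

    def ev_stagnation(_s, xy):
        v = velocity_at(flow, xy)
        return math.hypot(v[0], v[1]) - v_floor

    ev_stagnation.terminal = True
    ev_stagnation.direction = -1

    sol = solve_ivp(rhs, (0.0, max_length), start, method="RK45",
                    rtol=rtol, atol=rtol * ell,
                    max_step=flow.spacing * 4.0,
                    events=[ev_contact, ev_stagnation],
                    dense_output=False)
    pts = sol.y.T
    if sol.status == 1:
        status = "contact" if len(sol.t_events[0]) else "stagnation"
    else:
        status = "length"
    return pts, status


def find_stagnation_points(flow: FlowField, post_center=None,
                           offset: float | None = None,
                           n_samples: int = 1440) -> list[dict]:
    """Locate the surface stagnation points of one post.

    The tangential velocity component is sampled on a circle a small offset
    outside the post surface; its sign changes bracket the points where the
    critical streamlines leave (detachment, radial velocity outward) or
    arrive at (attachment) the surface.  Returns a list of dicts with keys
    ``angle``, ``point`` and ``kind`` ("attachment"/"detachment").
    """
    ell = flow.cell_edge
    if post_center is None:
        post_center = flow.obstacle_center
    if offset is None:
        # clear of the staircase-boundary error band of the solver grid
        n_solver = flow.meta.get("solver_resolution", flow.resolution) or flow.resolution
        offset = max(2.0 * ell / n_solver, 1e-4 * ell)
    r = flow.obstacle_radius + offset
    ang = np.linspace(0.0, 2.0 * math.pi, n_samples, endpoint=False)
    pts = np.stack([post_center[0] + r * np.cos(ang),
                    post_center[1] + r * np.sin(ang)], axis=-1)
    vel = velocity_at(flow, pts)
    tang = -vel[:, 0] * np.sin(ang) + vel[:, 1] * np.cos(ang)
    rad = vel[:, 0] * np.cos(ang) + vel[:, 1] * np.sin(ang)
    out = []
    for k in range(n_samples):
        k1 = (k + 1) % n_samples
        if tang[k] == 0.0 or tang[k] * tang[k1] >= 0:
            continue
        # linear root of the tangential component in angle
        a0, a1 = ang[k], ang[k] + (ang[1] - ang[0])
        t0, t1 = tang[k], tang[k1]
        a_root = a0 + (a1 - a0) * (0.0 - t0) / (t1 - t0)
        p = np.array([post_center[0] + r * math.cos(a_root),
                      post_center[1] + r * math.sin(a_root)])
        v_rad = float(np.interp(a_root, [a0, a1], [rad[k], rad[k1]]))
        out.append({"angle": a_root % (2 * math.pi), "point": p,
                    "kind": "detachment" if v_rad > 0 else "attachment"})
    return out


def streamline_periodicity(flow: FlowField, lattice: LatticeSpec) -> dict:
    """Periodicity check of a traced critical streamline.

    Traces the critical streamline leaving the detachment stagnation point
    of the central post.  At tilt M/N it must terminate on the post M
    columns across and N rows downstream, whereupon the lane pattern —
    continued by the exactly periodic flow field — repeats with transverse
    offset M·ℓ.  Returns the integer cell displacement ``(columns, rows)``
    of the terminal post and ``offset_error``: the stream-function drift
    accumulated along the trace between the first and last open-flow row
    crossings, converted to a transverse length through the local speed.
    That drift is the only way the traced curve can fail to return to the
    same transverse offset, so it bounds the periodicity error of the
    trace.
    """
    ell = lattice.cell_edge
    stag = find_stagnation_points(flow)
    det = [s for s in stag if s["kind"] == "detachment"]
    if not det:
        raise NumericalFailureError("no detachment stagnation point found")
    start = det[0]["point"]
    max_len = (lattice.tilt_denominator + 4) * ell / math.cos(flow.tilt_angle)
    pts, status = trace_streamline(flow, start, "forward", max_length=max_len)
    if status != "contact":
        raise NumericalFailureError(
            f"critical streamline did not terminate on a post ({status})")
    c_start = _nearest_post_center(start, ell)
    c_end = _nearest_post_center(pts[-1], ell)
    cells = np.round((c_end - c_start) / ell).astype(int)

    # phase-matched stream-function drift between open-flow row crossings
    y_levels = np.arange(math.ceil(pts[0, 1] / ell) * ell,
                         pts[-1, 1], ell)
    crossings = []
    for ylev in y_levels:
        idx = np.where((pts[:-1, 1] < ylev) & (pts[1:, 1] >= ylev))[0]
        if len(idx):
            i = idx[0]
            f = (ylev - pts[i, 1]) / (pts[i + 1, 1] - pts[i, 1])
            crossings.append(pts[i] + f * (pts[i + 1] - pts[i]))
    if len(crossings) < 2:
        raise NumericalFailureError("trace crossed fewer than two rows")
    p_first, p_last = crossings[0], crossings[-1]
    psi = stream_function_at(flow, np.asarray([p_first, p_last]))
    speed = float(np.linalg.norm(velocity_at(flow, p_first)))
    offset_error = abs(float(psi[1] - psi[0])) / speed
    return {"columns": int(cells[0]), "rows": int(cells[1]),
            "offset_error": offset_error, "status": status,
            "n_points": len(pts)}


# ---------------------------------------------------------------------------
# Lane decomposition
# ---------------------------------------------------------------------------

def lane_decomposition(flow: FlowField, lattice: LatticeSpec,
                       n_profile: int = 4000,
                       dedupe_tol: float = 1e-6) -> LaneDecomposition:
    """Split the per-cell flowrate into lanes bounded by critical ψ levels.

    The gap cross-section joining two neighbouring posts of one row is
    sampled; the critical levels are the stream-function values of the posts
    0..N−1 rows downstream, which by the quasi-periodicity of ψ are spaced by
    ``<u>·ℓ`` — the numerically achieved tilt, not the nominal ratio, so the
    computed lane fluxes genuinely test the flow solve.  Lane boundaries are
    located where ψ crosses each level along the gap; the flux fractions are
    the normalized ψ increments between consecutive boundaries.

    Raises :class:`NumericalFailureError` when fewer than N distinct
    boundaries are resolvable at the current grid resolution.
    """
    big_n = lattice.tilt_denominator
    ell = lattice.cell_edge
    r_o = lattice.obstacle_radius
    cx = cy = ell / 2.0
    if flow.cell_edge != ell:
        raise InvalidParameterError("flow field and lattice cell edge differ")

    # gap cut from the right surface of the post to the left surface of its
    # +x neighbour, slightly inset to stay clear of the staircase band
    x0, x1 = cx + r_o, cx + ell - r_o
    xs = np.linspace(x0, x1, n_profile)
    pts = np.stack([xs, np.full_like(xs, cy)], axis=-1)
    psi = stream_function_at(flow, pts)
    psi_left, psi_right = psi[0], psi[-1]
    total_flux = psi_right - psi_left   # = −<v>·ℓ, negative for flow toward +y

    mu, mv = flow.mean_velocity
    row_increment = mu * ell            # ψ difference between successive rows
    ratio = row_increment / total_flux  # numerically ≈ M/N
    if not np.isfinite(ratio) or total_flux == 0:
        raise NumericalFailureError("degenerate flux through the gap")

    fracs = np.mod(np.arange(big_n) * ratio, 1.0)
    order = np.argsort(fracs)
    fracs_sorted = fracs[order]
    # count distinct levels
    circ_gaps = np.diff(np.concatenate([fracs_sorted, [fracs_sorted[0] + 1.0]]))
    n_distinct = int(np.sum(circ_gaps > dedupe_tol))
    levels = psi_left + fracs_sorted * total_flux

    # locate boundaries along the (monotone) gap profile
    if not (np.all(np.diff(psi) < 0) or np.all(np.diff(psi) > 0)):
        # tolerate small non-monotone wiggles near the surfaces
        trend = np.sign(total_flux)
        psi = trend * np.maximum.accumulate(trend * psi)
    x_of_psi = np.interp(levels, psi[::-1], xs[::-1]) if total_flux < 0 \
        else np.interp(levels, psi, xs)
    positions = x_of_psi - x0

    sep = np.diff(np.sort(positions))
    if n_distinct < big_n or (len(sep) and sep.min() < flow.spacing):
        raise NumericalFailureError(
            f"only {n_distinct} of {big_n} lane boundaries resolvable at "
            f"grid spacing {flow.spacing:.3g} μm; increase the resolution"
        )

    # lane fluxes: circular gaps between sorted critical levels
    fractions = circ_gaps
    # first lane: between the post surface (fraction 0) and the smallest
    # positive critical fraction
    pos_sorted = np.sort(positions)
    nonzero = pos_sorted[pos_sorted > flow.spacing * 0.5]
    critical_radius = float(nonzero[0]) if len(nonzero) else float(pos_sorted[-1])

    return LaneDecomposition(
        n_lanes=n_distinct,
        psi_levels=levels,
        boundary_positions=positions,
        flux_fractions=fractions,
        critical_radius=critical_radius,
        total_flux=float(total_flux),
        gap_width=x1 - x0,
        grid_spacing=flow.spacing,
        meta={"achieved_tilt_ratio": float(ratio),
              "nominal_tilt_ratio": lattice.tilt_ratio},
    )


# ---------------------------------------------------------------------------
# Hard-contact gliding trajectories
# ---------------------------------------------------------------------------

def _inside_effective(points: np.ndarray, ell: float, r_eff: float):
    """Signed distance of points to the nearest effective post surface."""
    c = _nearest_post_center(points, ell)
    d = np.linalg.norm(np.asarray(points) - c, axis=-1)
    return d - r_eff, c


def kinematic_trajectory(flow: FlowField, obstacle: EffectiveObstacle,
                         start, span: float,
                         step_fraction: float = 2e-3,
                         contact_tol_rel: float = 1e-6,
                         max_steps: int = 2_000_000) -> KinematicPath:
    """Integrate the zero-diffusion hard-contact dynamics of one particle.

    The particle centre follows the unperturbed flow until it reaches the
    effective post surface (radius ``obstacle.radius`` around every lattice
    post).  Contact is located by interval halving on the signed distance to
    the circle (tolerance ``contact_tol_rel``·ℓ); during the glide only the
    tangential velocity component is kept and the particle detaches as soon
    as the local velocity points away from the surface.  Integration stops
    once the streamwise (lattice +y) span is covered.

    Free flight uses midpoint (RK2) steps of arc length
    ``step_fraction``·ℓ, so the step size adapts to the local speed — the
    velocity varies by an order of magnitude between the gap jets and the
    open cell interior.
    """
    ell = flow.cell_edge
    r_eff = obstacle.radius
    v_mean = flow.mean_speed
    contact_tol = contact_tol_rel * ell
    arc = step_fraction * ell
    v_floor = 1e-4 * v_mean
    x = np.asarray(start, dtype=float).copy()
    d0, _ = _inside_effective(x, ell, r_eff)
    if d0 < 0:
        raise InvalidParameterError("start point lies inside an effective obstacle")

    pts = [x.copy()]
    contacts: list[tuple[int, int]] = []
    y_start = x[1]
    in_contact = False
    contact_entry = 0
    stall_count = 0
    status = "ok"

    step = 0
    while x[1] - y_start < span and step < max_steps:
        step += 1
        v = velocity_at(flow, x)
        speed = math.hypot(v[0], v[1])
        if speed < v_floor:
            status = "stalled"
            break
        dt = arc / speed
        if not in_contact:
            v_mid = velocity_at(flow, x + 0.5 * dt * v)
            sp_mid = math.hypot(v_mid[0], v_mid[1])
            if sp_mid < v_floor:
                status = "stalled"
                break
            dt = arc / sp_mid
            x_new = x + v_mid * dt
            d_new, c = _inside_effective(x_new, ell, r_eff)
            if d_new < 0.0:
                # interval halving on the signed distance along the step
                lo, hi = 0.0, 1.0
                while (hi - lo) * arc > contact_tol:
                    mid = 0.5 * (lo + hi)
                    d_mid, _ = _inside_effective(x + v_mid * (mid * dt),
                                                 ell, r_eff)
                    if d_mid < 0:
                        hi = mid
                    else:
                        lo = mid
                x = x + v_mid * (lo * dt)
                # snap exactly onto the surface
                _, c = _inside_effective(x, ell, r_eff)
                n_hat = (x - c) / np.linalg.norm(x - c)
                x = c + n_hat * r_eff
                in_contact = True
                contact_entry = len(pts)
            else:
                x = x_new
        else:
            _, c = _inside_effective(x, ell, r_eff)
            n_hat = (x - c) / np.linalg.norm(x - c)
            v_n = float(v @ n_hat)
            if v_n > 0.0:
                in_contact = False
                contacts.append((contact_entry, len(pts)))
                x = c + n_hat * (r_eff + contact_tol)
                continue
            t_hat = np.array([-n_hat[1], n_hat[0]])
            v_t = float(v @ t_hat)
            if abs(v_t) < 1e-6 * v_mean:
                stall_count += 1
                if stall_count > 50:
                    status = "stalled"
                    break
            else:
                stall_count = 0
            # advance along the circle by one arc-length step
            dphi = math.copysign(min(abs(v_t) * dt, arc), v_t) / r_eff
            phi = math.atan2(n_hat[1], n_hat[0]) + dphi
            x = c + r_eff * np.array([math.cos(phi), math.sin(phi)])
        pts.append(x.copy())
    if in_contact:
        contacts.append((contact_entry, len(pts) - 1))
    if step >= max_steps and status == "ok":
        status = "max-steps"

    pts_arr = np.asarray(pts)
    dy = pts_arr[-1, 1] - pts_arr[0, 1]
    dx = pts_arr[-1, 0] - pts_arr[0, 0]
    theta = flow.tilt_angle
    if dy <= 0:
        classification = "stalled"
        lateral_per_row = 0.0
    else:
        rows = dy / ell
        # channel-frame transverse advance per row: 0 for a flow follower,
        # ℓ·tanΘ·cosΘ-ish for a lattice-axis follower; classify by the
        # lattice-frame drift angle relative to Θ_L/2
        drift_tan = dx / dy            # lattice frame; flow follower ≈ −tanΘ
        follow_flow = abs(drift_tan + math.tan(theta))
        follow_axis = abs(drift_tan)
        classification = "displaced" if follow_axis < follow_flow else "zig-zag"
        # transverse (channel x) displacement per row
        ch = np.array([dx, dy]) @ np.array(
            [[math.cos(-theta), -math.sin(-theta)],
             [math.sin(-theta), math.cos(-theta)]]).T
        lateral_per_row = float(ch[0] / rows)
    if status == "stalled":
        classification = "stalled"
    return KinematicPath(points=pts_arr, contacts=contacts,
                         lateral_displacement_per_row=lateral_per_row,
                         classification=classification, status=status)


def kinematic_exit_distribution(particle: ParticleSpec,
                                decomposition: LaneDecomposition,
                                lattice: LatticeSpec) -> KinematicExit:
    """All-or-nothing exit prediction of the diffusion-free model.

    Subcritical particles (r_p^eff < R_crit) exit at channel-frame x = 0;
    supercritical ones at x = L·tan Θ_L.  Independent of the flowrate: the
    Stokes flow geometry, and with it the lane structure, does not change
    with the velocity magnitude.  Sizes within one grid spacing of R_crit
    are flagged marginal rather than trusted to either side.
    """
    r_eff = particle.effective_radius
    r_crit = decomposition.critical_radius
    displaced = r_eff > r_crit
    marginal = abs(r_eff - r_crit) < decomposition.grid_spacing
    exit_x = lattice.device_length * lattice.tilt_ratio if displaced else 0.0
    return KinematicExit(exit_position=exit_x, displaced=displaced,
                         marginal=marginal, effective_radius=r_eff,
                         critical_radius=r_crit)
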