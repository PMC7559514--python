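# Methods

This note records the model equations as implemented, the numerical
choices behind them, and the limits of what the test fixtures demonstrate.

## Model

### Geometry and frames

The device is a square lattice of cylindrical posts (cell edge ℓ, post
radius R_o) whose axis is tilted by Θ_L = atan(M/N), M < N coprime,
relative to the channel's mean-flow direction. Two frames are used:
the *channel frame* (mean flow along +y, separation coordinate x, the frame
of exit distributions) and the *lattice frame* (posts on an axis-aligned
square grid), related by a rigid rotation by Θ_L. All field and particle
computations run in the lattice frame, where the periodic unit cell is a
simple square; moments and exit statistics are reported in the channel
frame.

Internal units: μm, s, μm/s, μm²/s; Pa·s for viscosity and K for
temperature. SI units are used only inside the double-layer force balance,
which mixes surface charge densities (C/m²) with ε₀.

### Unit-cell Stokes flow

The single-phase creeping flow satisfies the steady Stokes equations in the
periodic cell with no slip on the *physical* post (the effective obstacle
enters only particle dynamics, never the flow). The mean pressure drop is
modelled by a uniform body force. Because the centred circular post in a
square cell has the full symmetry group of the square, the cell's
permeability tensor is isotropic, so the mean velocity is collinear with
the body force; directing the force at Θ_L to the lattice axis therefore
realizes the channel-frame constraint exactly. The discrete achieved tilt
is part of the solver diagnostics and agrees with M/N to ~1e-7 at the
default resolution.

Discretization: staggered (MAC) finite differences with Brinkman volume
penalization of the post (friction coefficient 1e8 in nondimensional
units), plus a tiny pseudo-compressibility ε = 1e-9 that removes the
pressure nullspace while keeping the sparse matrix local; the saddle system
is factorized with SuperLU. Consequences, measured at the default
160-cell solve of the benchmark geometry:

* divergence residual < 1e-6 of the peak speed;
* velocity inside the solid < 2e-4 of the peak speed;
* interpolated speed *on* the staircase post boundary up to ~0.1 of the
  peak speed — the O(h) price of the un-fitted boundary. This band is the
  reason surface-adjacent quantities (stagnation points, streamline seeds)
  are evaluated a couple of solver cells off the surface.

The solved cell is resampled onto a uniform node grid (1000×1000 by
default, 600×600 in the test suite) and continued periodically; velocity
and stream function anywhere are bilinear interpolants. The stream
function is integrated exactly from the discrete fluxes (path independent
because the discrete field is divergence-free), and split as
ψ = ψ_per + ⟨u⟩y − ⟨v⟩x into a periodic part plus the mean-flow ramp.

### Lanes and the critical radius

ψ is constant on each post; posts k rows downstream sit on levels spaced by
⟨u⟩ℓ, which is M/N of the per-cell flux. The N distinct levels (mod the
per-column flux) partition the gap cross-section into N lanes; boundaries
are located where the sampled ψ profile across the gap crosses each level.
The lane fluxes therefore test the *numerically achieved* tilt, not the
nominal ratio. R_crit is the distance from the post surface to the first
boundary. The lane adjacent to the wall is wider than gap/N because the
velocity vanishes at the wall (for the benchmark gap of 0.8 μm,
R_crit ≈ 0.14 μm ≈ 0.18 gap).

Critical-streamline tracing: stagnation points are located by sign changes
of the tangential velocity sampled on a circle two solver cells outside the
post; streamlines integrate dx/ds = v/|v| with RK45 and terminate on post
contact, stagnation, or arc-length budget. The periodicity check verifies
(i) the traced critical streamline terminates on the post exactly M columns
across and N rows downstream, and (ii) the stream-function drift between
phase-matched row crossings, converted to transverse length through the
local speed, stays below one interpolation-grid spacing (measured:
~1e-3 μm against a 0.013 μm spacing).

### Electrostatic displacement

For equally charged surfaces the double-layer repulsion balances the
viscous drag pressing the particle onto the post at a standoff

    d_F−EDL = −λ_D ln[ (−ρ_p²ρ_s² + √(ρ_p⁴ρ_s⁴ + (ρ_p²+ρ_s²)³ μ ε_r ε₀ V/λ_D))
                       / (ρ_p²+ρ_s²)² ],

clamped below at zero and independent of the particle radius (both the
Derjaguin double-layer force and the Stokes drag scale linearly with
radius, so it cancels). This transcription was fixed by dimensional
analysis — it is the unique grouping of the balance in which the log
argument is dimensionless — and is pinned by the property suite: monotone
non-increasing in V, continuous at the clamp, d/λ_D a function of the
charges and V/λ_D only. With charge densities of order 0.1 mC/m² and
λ_D ~ 10 nm, the standoff is tens of nm at V = 40 μm/s and clamps to zero
in the few-hundred-μm/s range — the regime ordering the model is built
around. When buffer data are missing entirely, the calibrated path
replaces the formula: bisection on the predicted mean exit position of one
reference size (common random numbers across evaluations make the noisy
objective quasi-deterministic), and the single calibrated value is reused
for all sizes.

### Stochastic microdynamics

Euler–Maruyama with Δt set so a mean-flow particle crosses one cell in
~1000 steps (2e-4 s at ℓ = 8 μm, V = 40 μm/s). Wiener increments have
variance Δt per component; the noise amplitude is √(2 D_p). A displacement
segment entering an effective disc (radius R_o + r_p^eff around every
post) is specularly reflected about the tangent at the entry point —
located exactly by the segment–circle quadratic against the 3×3
neighbourhood of candidate posts — iterating up to 10 times; overflow
either rejects the step (strict mode) or truncates at the wall (ensemble
mode, counted and reported). In the Δt → 0 limit this realizes the
hard-wall rule: tangential velocity preserved, normal component
annihilated. The deterministic (D_p → 0) integrator and the explicit
gliding trajectory (contact by interval halving at 1e-6 ℓ, detachment when
v·n̂ > 0) agree on mode and per-row drift away from the critical size.

### Macroscopic coefficients and exit distribution

Channel-frame moments are recorded along the ensemble; W_x, W_y, D_xx are
OLS slopes of E[x], E[y], Var[x] over the trailing half of the recorded
window (the transient fraction is configurable; an R² < 0.99 variance fit
raises a non-asymptotic warning). Because a single ensemble's moment
series is itself a random walk, naive OLS standard errors are
anti-conservative; the reported errors are therefore block standard errors
over 10 independent particle blocks. The exit distribution is Gaussian
with x̄_L = L·W_x/W_y and σ_L = √(2 D_xx L / W_y), the variance accumulated
over the traversal time L/W_y. (D_xx stands in for the full
flow-direction-projected dispersion coefficient; at small tilt,
tan Θ_L ≤ 1/10 here, the difference is negligible.) A first-passage
sampler provides the empirical cross-check: transverse positions at the
first crossing of streamwise distance L, linearly interpolated within the
crossing step.

## Default parameters

| parameter | default | rationale |
|---|---|---|
| cell edge ℓ | 8 μm | benchmark array pitch |
| post radius R_o | 3.6 μm (lane benchmarks) / 3.2 μm (transport) | gap ℓ/10 for the lane-structure benchmarks; 1.6 μm gap for particle transport, the only gap under which the 0.3–0.5 μm sweep radii can transit (gap ℓ/10 blocks r_p^eff ≥ 0.4 μm) |
| tilt M/N | 1/10 | benchmark tilt; 1/4 exercised for the 4-lane structure |
| device length L | 11 mm | benchmark outlet distance (displaced exit L·tanΘ_L = 1100 μm) |
| V | 40 μm/s (low-flowrate regime), 400 μm/s available | two-phase/3-D effects grow with flowrate and are out of scope |
| T, μ, ε_r | 298 K, 1e-3 Pa·s, 78.5 | aqueous buffer at room temperature |
| Δt | cell-crossing time / 1000 | resolves gap jets ~14× the mean speed |
| N_s | 1e5 production / 1e2–1e4 in tests | moment noise ∝ 1/√N_s |
| penalization, ε_p | 1e8, 1e-9 | solid speed ≤ 2e-4 peak; local matrix |

## What the fixtures do and do not show

The synthetic fixtures are the device geometries themselves (the
obstacle-free cell, a single post, and the benchmark lattice); there is no
synthetic "data" beyond seeded noise realizations. Passing tests
demonstrate internal consistency (analytic limits, conservation laws,
cross-route agreement between independent estimators) and the structural
numbers of the benchmark geometry. They do not demonstrate agreement with
measurements on physical devices, which would additionally probe two-phase
particle–flow coupling, particle inertia, and the 3-D velocity profile
between channel floor and ceiling — all outside this model. The model is
expected to degrade at high flowrate (hundreds of μm/s), where unsteady
and three-dimensional effects grow.

## Numerical edge cases

* R_o = 0 returns the exact uniform flow (no solve).
* R_o + r_p^eff ≥ ℓ/2 is a blocking geometry: rejected with a dedicated
  error; sweeps record the failure per radius and keep partial results.
* Effective radii within one grid spacing of R_crit are flagged
  "marginal" by the kinematic classifier rather than hard-classified.
* Calibration targets outside [0, L·tanΘ_L] are rejected as infeasible;
  a non-monotone endpoint response aborts with the full scan attached.
* Release points inside an effective disc are snapped to the surface with
  a warning.

## Test problem sizes

The suite runs ensembles of 3e2–1e4 particles over 2e3–4e4 steps and
solves the unit cell at 160 cells per edge (48–96 in the cheapest checks),
resampled to a 600-node interpolation grid — sizes chosen so the full
suite completes in minutes on one core while leaving every statistical
assertion at ≥3 estimated standard errors of slack. Production settings
(1e5 realizations, 1000×1000 grid) differ only in cost.

## Known limitations

* The staircase (penalized) post boundary limits near-surface field
  accuracy to first order in the grid spacing; R_crit inherits an O(h)
  bias. A boundary-fitted solver would sharpen both.
* Transport coefficients assume the pre-asymptotic transient is contained
  in the discarded half-window; strongly subcritical/supercritical
  particles converge fast, near-critical sizes are the slowest.
* The time step is uniform; the step-rejection guard (not adaptivity)
  handles the rare deep-gap excursions.
* Single master seed, single stream: reproducibility is per-run, and
  trajectory-level parallel decomposition is not implemented.
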