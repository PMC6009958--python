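# Methods

`crosslimb` models pulsatile blood flow through idealized "crossed-limb"
(ballerina) bifurcated aortic stent grafts and evaluates the hemodynamic
indicators used to compare graft configurations: outlet helicity, TAWSS,
OSI, RRT, and the displacement (drag) force on the device. This note
records the model, the numerical choices, and what the synthetic study
conditions do and do not represent.

## Geometry

A graft instance is a trunk tube (diameter 17 mm, length 71 mm) and two
iliac limb tubes (diameter 10 mm) that end on the distal plane so the
total axial device length is 154.64 mm. The limbs leave ostia offset
laterally by (trunk − iliac)/2 = 3.5 mm, follow a cubic Hermite arc to
the cross point on the axis at axial distance `l` below the bifurcation,
and continue straight toward their outlets. Writing `h` for the axial
cross-to-outlet distance (`l + h = 83.64 mm`), the configuration is set
by any two of:

* the cross angle `alpha` between the limbs at the crossing,
* the cross-position ratio `r = l/h`,
* the outlet-center separation `g`,

linked by `tan(alpha/2) = g/(2h)` because the below-cross leg is
straight. The cross-angle series varies `alpha` in {30…90}° at fixed
`l = 42 mm`; the cross-position series varies `r` in {0.48…1.92} at fixed
`g = 41 mm`. We read the fixed "side length" parameter of the position
series as the outlet-center separation: any reading of it as a limb
*segment length* is geometrically infeasible (every bifurcation-to-outlet
path spans ≥ 83.64 mm axially), while the separation reading yields
feasible angles (39.9°–71.2°) that grow with `r`, consistent with the
projected-area mechanism by which lower cross positions raise the
displacement force.

Two coplanar 10-mm limbs crossing would interpenetrate, so each limb
carries an equal-and-opposite out-of-plane excursion in `y` of amplitude
(iliac diameter + clearance)/2 with a flat top around the cross point
(default clearance 1 mm); the surface-to-surface gap at the crossing is
exactly the clearance. Near the bifurcation the limb lumens merge at the
flow divider, as in the physical modular device; disjointness is enforced
(and checked by a flood-fill test) in a window around the crossing.

The lumen is an implicit surface: signed distance to each centerline
capsule minus the tube radius, trunk and limbs blended by a polynomial
smooth-minimum over one iliac radius, limbs combined by a hard minimum.
Walls are triangulated from the zero level set by marching cubes; sample
points are triangle centroids with area weights, labeled by nearest
centerline (trunk / left / right iliac), by outer/inner side, and by
on-graft arc length. The solver domain extends the limbs ~1.5–2 diameters
past the distal plane as a numerical outflow extension; extension wall is
excluded from device metrics. Outlet sections for helicity are discs of
the iliac radius perpendicular to the limb tangent at the distal
centerline endpoint (area exactly pi R^2 by the quadrature construction).

## Rheology

Blood is a generalized Newtonian Carreau fluid,
`eta(gd) = eta_inf + (eta_0 − eta_inf) [1 + (lambda gd)^2]^((n−1)/2)` with
`eta_inf = 3.45e-3 Pa s`, `eta_0 = 5.6e-2 Pa s`, `lambda = 3.313 s`,
`n = 0.3568`, density 1050 kg/m^3; `gd = sqrt(2 D:D)`. A Newtonian
shortcut (`eta_0 = eta_inf`) switches the solver to constant viscosity
for the analytic verification fixtures.

## Flow solver

Incompressible Navier–Stokes on a uniform staggered (MAC) Cartesian grid
with a mask-based direct-forcing immersed boundary:

* cells with negative signed distance are fluid; faces are open when both
  neighbor cells are fluid *and* the face midpoint is inside the lumen
  (the extra check prevents leaks through the ~1 mm inter-limb gap at
  coarse spacings); closed faces are forced to zero velocity;
* advection: explicit second-order upwind-biased differences with a
  first-order fallback within two cells of the inflow/outflow boundaries;
* diffusion: `div(eta grad u)` treated with a theta scheme
  (Crank–Nicolson for pulsatile runs, backward Euler for pseudo-time
  steady marches), solved per velocity family on the open faces only by
  Jacobi-preconditioned conjugate gradients; at wall neighbors the
  operator uses a linear reflection ghost, which places the no-slip plane
  on the face and is globally second order for face-aligned walls
  (observed order 2.00 on plane Poiseuille); the remaining
  `div(eta (grad u)^T)` part of the stress is added explicitly;
* viscosity is evaluated at cell centers from strain rates computed on a
  velocity field mirror-extended into solid border cells (a plain zero
  there underestimates near-wall strain rates and inflates the Carreau
  viscosity); face viscosities are arithmetic averages;
* pressure projection: the Poisson system over fluid cells (Neumann at
  walls and at the velocity inlet, Dirichlet via ghost elimination at the
  outlet plane, gauge-pinned for closed/periodic fixtures) is factorized
  once per geometry with SuperLU, so the discrete divergence of every
  fluid cell is zero to direct-solver round-off after each step;
* boundary conditions: spatially flat (plug) inlet velocity waveform on
  the trunk inlet face; time-dependent uniform pressure on the outlet
  plane apertures; rigid no-slip walls. Periodic axes and a uniform body
  acceleration support the verification fixtures.

The scheme is first order in time for the splitting (second order for the
diffusion term under Crank–Nicolson) and second order in space away from
immersed walls. Pulsatile runs substep each retained output interval to
an advective CFL of 0.4, so the 40-snapshot/cycle cadence never controls
stability; Carreau coefficients are refreshed once per output step
(they vary on the cardiac timescale). Steady solves pseudo-march with
CFL-limited steps capped at 0.5 s and stop when the L2 velocity change
per step, scaled by the inlet velocity, falls below tolerance
(default 1e-5; coarse tiers use relaxed values listed below).

## Wall shear extraction

At each wall sample the tangential velocity is probed at 1 and 2 grid
spacings along the inward normal (trilinear interpolation on the
mirror-extended field). The wall traction is recovered by fitting the
generalized-Newtonian near-wall profile: assume the tangential traction
varies linearly with wall distance, `tau(x) = tau_w + s x`, and the
velocity is the flux profile `u(d) = ∫_0^d g(tau(x)) dx` with `g` the
inverse Carreau law; `(tau_w, s)` solve the two probe equations by a
damped Newton iteration. The fit is exact for fully developed Carreau
tube/channel flow and reduces to the standard one-sided quadratic fit in
the Newtonian limit. Probe depths are a compromise: deeper probes escape
staircase interpolation noise but lose the thin oscillatory Stokes layer.
Samples whose first probe falls outside the fluid are flagged, zeroed,
and excluded from all averages (counts reported). Wall pressure is the
one-sided interpolation at the first probe.

## Metrics

* Helicity density `H_d = u · (curl u)` by second-order central
  differences at cell centers; the outlet trace is the area-weighted
  section mean, reported both signed (`|<H_d>|`, sensitive to the balance
  of the two counter-rotating structures) and unsigned (`<|H_d|>`, the
  total local swirl intensity). Sweep trend evaluation uses the unsigned
  cycle trace: the signed mean measures cancellation between the
  left- and right-handed helices rather than helical-flow strength, and
  is not monotone across the series.
* TAWSS, OSI, RRT per sample with trapezoidal time quadrature over the
  retained final cycle; OSI is clamped to [0, 0.5]; RRT poles
  (OSI → 0.5 or TAWSS → 0) map to an infinity sentinel and are excluded
  from area means with reported counts. Area means are computed on
  per-sample indicator values over the bilateral iliac wall (averaging
  the indicator, not the WSS, so the mean RRT is *not* the RRT of the
  mean TAWSS/OSI — the two do not commute).
* Displacement force `F(t) = Σ (p n̂ + tau_wss) dA` over the device wall
  (pressure part always on the full sample set; at coarse tiers the WSS
  maps may use a stride-2 sample subset with area rescaling of the small
  viscous force part). The vector magnitude maximum over the cycle is the
  primary scalar; the axial component is logged alongside.
* Outer-surface enrichment: the ratio of the outer-surface area fraction
  among top-quartile OSI (or RRT) samples to that among all iliac
  samples; values > 1 quantify the high-OSI/RRT strips on the outer
  surface of the crossed limbs.

## Study conditions and synthetic waveforms

The boundary waveforms are parametric stand-ins anchored to the printed
values: inlet cycle mean 0.044 m/s, outlet cycle mean 13 300 Pa
(100 mmHg), period 1.0 s, systolic peak at t = 0.1 s. Shapes are
truncated (8-harmonic) Fourier pulses with the cycle mean enforced
exactly; defaults are a pulsatility index of 4 for the inlet (peak
~4.7× mean, no retrograde flow) and a 5 320 Pa (40 mmHg) peak-to-peak
pulse pressure — rest-state aortic-like choices, not digitized clinical
curves. Consequences: absolute pulsatile numbers (helicity in m/s^2,
TAWSS/OSI/RRT, force maxima in N) are comparable in order of magnitude
but not in value to runs driven by a measured waveform, and the OSI level
is low because the stand-in inlet never reverses. Cross-configuration
*trends* at matched conditions are the meaningful output, and those are
what the test suite asserts.

## Resolution tiers and problem sizes

Solver fidelity is organized in tiers (grid spacing, snapshots/cycle,
cycles, steady tolerance):

* `desk` — 10/24 mm (24 cells per iliac diameter), 40 snapshots/cycle,
  3 cycles, steady tolerance 1e-5. Full-fidelity runs; a 10-run sweep
  takes many hours on one CPU.
* `test` — 1.4 mm (~7 cells/diameter), 40 snapshots/cycle, 2 cycles,
  steady tolerance 1e-3, stride-2 WSS sampling. One graft run takes
  about 1–2 minutes; the automated test suite and the acceptance script
  run the sweep series at this scale.
* `smoke` — 2.0 mm, fastest contract checks.

The analytic verification cases run at their own canonical resolutions
(channel 16/32/64 cells across; tubes at 32 cells per diameter).

## Verification summary (computed by the test suite)

* Carreau law: exact plateau limits; value at 1 s^-1 matches a 20-digit
  symbolic evaluation.
* Plane Poiseuille: centerline error < 2%, observed spatial order 2.0.
* Womersley tube flow (alpha ≈ 6.9): wall-shear amplitude and phase
  within 5% / 5° of the Bessel solution at 32 cells/diameter, starting
  from the exact profile (the homogeneous start-up transient decays far
  more slowly than the few simulated cycles).
* Generalized Carreau Poiseuille: wall shear within 10% of a
  high-precision 1-D radial inversion/quadrature oracle.
* Metric identities: OSI ∈ {0, 0.5, 0.25} fixtures, TAWSS of a rectified
  sine = 2 tau_0/pi, RRT identity to 1e-12, helicity = 2 Omega w0 on the
  solid-body helix, pointwise sign flip under mirror reflection.
* Conservation: inlet/outlet flux mismatch at direct-solver round-off;
  left/right outlet flux symmetry to < 1% on symmetric configurations.

## Known limitations

* The immersed wall is a staircase at the grid scale: local WSS on the
  curved graft wall carries O(h) geometric noise; area-averaged values
  and cross-configuration trends are the reliable quantities.
* Coarse-tier sweeps (~7 cells per iliac diameter) resolve the bulk flow
  split, the pressure load, and the large-scale helical structures, but
  under-resolve secondary-flow detail; desk-tier runs exist for fidelity
  at the cost of hours.
* Under the stand-in inlet waveform (no reverse-flow phase), the
  high-OSI/RRT strips concentrate on the *companion-facing* limb
  surfaces near the crossing at small cross angles, and favor the outer
  surface only toward the large-angle end of the series. Outer-surface
  concentration across all configurations, as seen in device studies
  driven by measured triphasic aortic waveforms, likely requires the
  diastolic reverse-flow phase that the nonnegative default waveform
  deliberately omits; the outer-enrichment ratio is therefore reported
  per run rather than assumed.
* Rigid walls, no fluid–structure interaction, no turbulence model
  (peak Reynolds number ~ a few hundred), idealized planar-with-bump
  centerlines rather than patient anatomy.
* The fractional-step fixed point depends weakly (O(dt^2)) on the pseudo
  step size, so steady and pulsatile-with-constant-forcing solutions
  agree to ~1%, not to solver tolerance.
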