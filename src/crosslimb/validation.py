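"""Analytic verification cases for the flow solver and wall-shear chain.

Each case builds a small fixture (plane channel or straight tube, driven
by a body force so the streamwise direction can be periodic), runs the
actual production solver, and compares against a closed-form or
high-precision one-dimensional oracle:

* plane Poiseuille (Newtonian)       — parabolic profile, grid-refinement
  order of accuracy;
* Womersley oscillatory tube flow    — wall-shear amplitude and phase
  against the Bessel-function solution;
* generalized Carreau Poiseuille     — steady tube wall shear against a
  high-precision 1-D radial quadrature oracle;
* Poiseuille tube drag               — axial viscous drag versus the exact
  momentum balance dp/dz * pi R^2 per unit length.

The oracles are computed independently of the solver discretization.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import integrate, optimize

from .geometry import SignedDistanceField, WallSurface, _FixtureEvaluator
from .rheology import RheologyParams, newtonian, carreau_viscosity
from .solver import (GridSpec, BoundaryConditions, IBSolver, FlowState,
                     initial_state, solve_steady, solve_pulsatile)
from .waveforms import womersley_field
from .metrics import wall_shear_vectors

__all__ = [
    "channel_fixture",
    "tube_fixture",
    "cylinder_surface",
    "plane_poiseuille_case",
    "poiseuille_refinement",
    "carreau_poiseuille_oracle",
    "carreau_tube_case",
    "womersley_case",
    "tube_drag_case",
]

BLOOD_NU_VISC = 3.45e-3  # Pa s, high-shear blood plateau used for
# Newtonian fixtures


def channel_fixture(ny: int, half_width: float = 5e-3,
                    viscosity: float = BLOOD_NU_VISC, rho: float = 1050.0):
    """Plane channel of half-width H: walls at y = +/-H aligned with cell
    faces (one solid cell layer each side), periodic in x and z."""
    h = 2.0 * half_width / ny
    dims = (4, ny + 2, 4)
    origin = np.array([0.0, -half_width - h, 0.0])

    def ev(points):
        pts = np.atleast_2d(points)
        return np.abs(pts[:, 1]) - half_width

    sdf = SignedDistanceField(origin=origin, spacing=h,
                              values=np.zeros((2, 2, 2)),
                              evaluator=_FixtureEvaluator(ev))
    grid = GridSpec(origin=origin, spacing=h, dims=dims)
    rheo = newtonian(viscosity, rho=rho)
    return grid, sdf, rheo


def plane_poiseuille_case(ny: int = 32, half_width: float = 5e-3,
                          viscosity: float = BLOOD_NU_VISC,
                          rho: float = 1050.0, u_max: float = 2e-3,
                          tol: float = 1e-8):
    """Steady body-force-driven plane Poiseuille flow.

    Returns centerline error, discrete L2 profile error, and the profile
    itself.  The exact solution is u(y) = u_max (1 - (y/H)^2) for the
    body force G = 2 eta u_max / H^2.
    """
    grid, sdf, rheo = channel_fixture(ny, half_width, viscosity, rho)
    H = half_width
    G = 2.0 * viscosity * u_max / (H * H)
    bc = BoundaryConditions(body_accel=(G / rho, 0.0, 0.0),
                            periodic=(True, False, True))
    solver = IBSolver(grid, sdf, rheo, bc)
    state, hist = solve_steady(solver, tol=tol, max_iter=2000, u_ref=u_max)
    yc = grid.cell_centers_1d()[1]
    prof = state.u[2, :, 2]  # u at an interior x-face, along y
    fluid = np.abs(yc) < H
    exact = u_max * (1.0 - (yc[fluid] / H) ** 2)
    num = prof[fluid]
    l2 = math.sqrt(float(np.mean((num - exact) ** 2))) / u_max
    centerline = float(np.max(num))
    mean = float(np.mean(num))
    return {
        "centerline_error": centerline / u_max - 1.0,
        "centerline_over_mean": centerline / mean,
        "l2_error": l2,
        "profile": num, "exact": exact, "y": yc[fluid],
        "steady": hist,
    }


def poiseuille_refinement(nys=(16, 32, 64), **kw):
    """Observed spatial order of accuracy from an L2-error refinement."""
    errs = [plane_poiseuille_case(ny, **kw)["l2_error"] for ny in nys]
    orders = [math.log2(errs[i] / errs[i + 1]) for i in range(len(errs) - 1)]
    return {"ny": tuple(nys), "errors": errs, "orders": orders}


def tube_fixture(cells_per_diameter: int, radius: float = 5e-3,
                 rheology: RheologyParams | None = None, nz: int = 4):
    """Straight tube along z (periodic), walls immersed in the x-y plane."""
    h = 2.0 * radius / cells_per_diameter
    n = cells_per_diameter + 4
    if n % 2:
        n += 1  # keep the axis midway between cell centers, symmetric grid
    dims = (n, n, nz)
    origin = np.array([-n / 2.0 * h, -n / 2.0 * h, 0.0])

    def ev(points):
        pts = np.atleast_2d(points)
        return np.hypot(pts[:, 0], pts[:, 1]) - radius

    sdf = SignedDistanceField(origin=origin, spacing=h,
                              values=np.zeros((2, 2, 2)),
                              evaluator=_FixtureEvaluator(ev))
    grid = GridSpec(origin=origin, spacing=h, dims=dims)
    return grid, sdf, rheology or RheologyParams()


def cylinder_surface(radius: float, grid: GridSpec, n_theta: int = 64,
                     margin_cells: float = 1.0) -> WallSurface:
    """Analytic cylinder wall samples for WSS probing on tube fixtures.

    Rings of samples at every interior z cell center; outward normals are
    radial; per-sample area weights tile the lateral surface exactly.
    """
    zc = grid.cell_centers_1d()[2]
    ang = 2.0 * np.pi * (np.arange(n_theta) + 0.5) / n_theta
    ca, sa = np.cos(ang), np.sin(ang)
    pts, nrm = [], []
    for z in zc:
        pts.append(np.column_stack([radius * ca, radius * sa,
                                    np.full(n_theta, z)]))
        nrm.append(np.column_stack([ca, sa, np.zeros(n_theta)]))
    pts = np.vstack(pts)
    nrm = np.vstack(nrm)
    n = len(pts)
    area = 2.0 * np.pi * radius * grid.spacing / n_theta
    return WallSurface(points=pts, normals=nrm,
                       areas=np.full(n, area),
                       region=np.full(n, "trunk"), side=np.ones(n),
                       arclength=pts[:, 2].copy(),
                       on_graft=np.ones(n, bool))


def carreau_poiseuille_oracle(radius: float, params: RheologyParams,
                              G: float | None = None,
                              v_mean: float | None = None, n_r: int = 4000):
    """Fully developed Carreau tube flow by exact radial force balance.

    tau(r) = G r / 2, so the strain rate solves eta(gd) gd = G r / 2 at
    every radius (inverted by bisection); the profile follows by inward
    quadrature and the wall shear is exactly G R / 2.  Give either the
    pressure gradient ``G`` (Pa/m) or the target ``v_mean`` (solved for G).
    """
    R = radius

    def profile_for(Gval):
        r = np.linspace(0.0, R, n_r)
        tau = Gval * r / 2.0

        def gd_of_tau(tv):
            if tv == 0.0:
                return 0.0
            f = lambda g: carreau_viscosity(g, params) * g - tv
            hi = tv / params.eta_inf
            return optimize.brentq(f, 0.0, hi * 1.001, xtol=1e-15,
                                   rtol=8.9e-16)

        gd = np.array([gd_of_tau(tv) for tv in tau])
        # u(r) = int_r^R gd dr'
        u = integrate.cumulative_trapezoid(gd[::-1], r[::-1], initial=0.0)
        u = u[::-1] * -1.0
        vm = 2.0 / (R * R) * integrate.trapezoid(u * r, r)
        return r, u, gd, vm

    if G is None:
        if v_mean is None:
            raise ValueError("give G or v_mean")
        eta_hi = carreau_viscosity(8.0 * v_mean / (2 * R), params)
        G0 = 8.0 * params.eta_inf * v_mean / (R * R)
        G1 = 8.0 * params.eta_0 * v_mean / (R * R)
        G = optimize.brentq(lambda g: profile_for(g)[3] - v_mean,
                            0.5 * G0, 2.0 * G1, xtol=1e-12, rtol=1e-13)
    r, u, gd, vm = profile_for(G)
    return {
        "G": G, "r": r, "u": u, "gamma_dot": gd, "v_mean": vm,
        "u_center": float(u[0]), "tau_wall": G * R / 2.0,
        "gamma_dot_wall": float(gd[-1]),
    }


def carreau_tube_case(cells_per_diameter: int = 32, radius: float = 5e-3,
                      v_mean: float = 0.0636,
                      params: RheologyParams | None = None,
                      tol: float = 2e-6, max_iter: int = 8000):
    """Steady Carreau tube flow versus the 1-D oracle.

    Drives the tube with the body force the oracle associates with the
    requested mean velocity and compares the probed wall shear stress and
    the bulk mean velocity.
    """
    params = params or RheologyParams()
    oracle = carreau_poiseuille_oracle(radius, params, v_mean=v_mean)
    G = oracle["G"]
    grid, sdf, _ = tube_fixture(cells_per_diameter, radius, params)
    bc = BoundaryConditions(body_accel=(0.0, 0.0, G / params.rho),
                            periodic=(False, False, True))
    solver = IBSolver(grid, sdf, params, bc)
    state, hist = solve_steady(solver, tol=tol, max_iter=max_iter,
                               u_ref=v_mean, strict=False)
    wall = cylinder_surface(radius, grid)
    wss, excl = wall_shear_vectors(state, wall, params, grid,
                                   sdf_evaluator=sdf.evaluator)
    tau_meas = float(np.mean(np.linalg.norm(wss[~excl], axis=1)))
    # discrete mean velocity over the lumen
    xc, yc, _ = grid.cell_centers_1d()
    X, Y = np.meshgrid(xc, yc, indexing="ij")
    inside = np.hypot(X, Y) < radius
    wc = 0.5 * (state.w[:, :, 1] + state.w[:, :, 2])
    v_meas = float(np.mean(wc[inside]))
    return {
        "oracle": oracle, "tau_wall": tau_meas,
        "tau_error": tau_meas / oracle["tau_wall"] - 1.0,
        "v_mean": v_meas, "v_error": v_meas / oracle["v_mean"] - 1.0,
        "steady": hist, "state": state, "grid": grid,
    }


def womersley_case(cells_per_diameter: int = 32, radius: float = 5e-3,
                   frequency: float = 1.0, grad_amplitude: float = 130.0,
                   viscosity: float = BLOOD_NU_VISC, rho: float = 1050.0,
                   steps_per_cycle: int = 40, n_cycles: int = 3):
    """Pulsatile tube flow versus the Womersley Bessel solution.

    The run starts from the exact profile at t = 0 (removing the slow
    start-up transient, whose decay time far exceeds a few cycles) and is
    marched the requested cycles; the retained final cycle's wall-shear
    trace is fit at the driving frequency and compared in amplitude and
    phase with the analytic complex wall shear.
    """
    field = womersley_field(radius, viscosity, rho, grad_amplitude,
                            frequency)
    omega = field.extras["omega"]
    rheo = newtonian(viscosity, rho=rho)
    grid, sdf, _ = tube_fixture(cells_per_diameter, radius, rheo)
    accel = lambda t: (0.0, 0.0,
                       grad_amplitude * math.cos(omega * t) / rho)
    bc = BoundaryConditions(body_accel=accel, periodic=(False, False, True))
    solver = IBSolver(grid, sdf, rheo, bc, theta=0.5)
    # exact initial condition on the w faces
    state = initial_state(grid)
    xc, yc, _ = grid.cell_centers_1d()
    X, Y = np.meshgrid(xc, yc, indexing="ij")
    r = np.hypot(X, Y)
    w0 = field.extras["axial_velocity"](np.clip(r, 0, radius), 0.0)
    w0[r >= radius] = 0.0
    state.w[:, :, :] = w0[:, :, None]
    solver.apply_bc(state, 0.0)
    wall = cylinder_surface(radius, grid)
    taus, times = [], []

    def hook(st, sv):
        wss, excl = wall_shear_vectors(st, wall, rheo, grid,
                                       sdf_evaluator=sdf.evaluator)
        taus.append(float(np.mean(wss[~excl, 2])))
        times.append(st.t)

    solve_pulsatile(solver, steps_per_cycle=steps_per_cycle,
                    n_cycles=n_cycles, init=state, period=1.0 / frequency,
                    snapshot_hook=hook, keep_snapshots=False)
    t = np.asarray(times)
    tau = np.asarray(taus)
    # single-frequency complex fit over exactly one period
    ph = np.exp(-1j * omega * t)
    amp = 2.0 * np.mean(tau * ph)
    ref = field.extras["wall_shear_complex"]
    amp_err = abs(amp) / abs(ref) - 1.0
    phase_err = math.degrees(math.atan2(np.imag(amp / ref),
                                        np.real(amp / ref)))
    return {
        "amplitude": abs(amp), "amplitude_ref": abs(ref),
        "amplitude_error": amp_err, "phase_error_deg": phase_err,
        "womersley_number": field.extras["womersley_number"],
        "trace": tau, "times": t,
    }


def tube_drag_case(cells_per_diameter: int = 32, radius: float = 5e-3,
                   viscosity: float = BLOOD_NU_VISC, rho: float = 1050.0,
                   u_max: float = 2e-3):
    """Axial viscous drag on a Poiseuille tube wall vs the momentum balance.

    For fully developed flow the wall drag per unit length equals
    (-dp/dz) pi R^2 exactly; the case integrates the probed WSS over the
    lateral wall and compares.
    """
    rheo = newtonian(viscosity, rho=rho)
    G = 4.0 * viscosity * u_max / (radius * radius)
    grid, sdf, _ = tube_fixture(cells_per_diameter, radius, rheo)
    bc = BoundaryConditions(body_accel=(0.0, 0.0, G / rho),
                            periodic=(False, False, True))
    solver = IBSolver(grid, sdf, rheo, bc)
    state, _ = solve_steady(solver, tol=1e-8, max_iter=4000, u_ref=u_max)
    wall = cylinder_surface(radius, grid)
    wss, excl = wall_shear_vectors(state, wall, rheo, grid,
                                   sdf_evaluator=sdf.evaluator)
    L = grid.dims[2] * grid.spacing
    drag = float(np.sum(wss[~excl, 2] * wall.areas[~excl]))
    expected = G * math.pi * radius * radius * L
    return {"drag": drag, "expected": expected,
            "error": drag / expected - 1.0}
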