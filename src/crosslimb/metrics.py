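"""Hemodynamic quantities of interest.

* Helicity density H_d = u . (curl u)  — signed measure of corkscrew
  motion; positive = right-handed alignment of velocity and vorticity.
* TAWSS = (1/T) int_0^T |WSS| dt       — time-averaged wall shear stress.
* OSI = 0.5 (1 - |int WSS dt| / int |WSS| dt) — oscillatory shear index,
  0 for unidirectional shear, 0.5 for perfectly reversing shear.
* RRT = 1 / ((1 - 2 OSI) * TAWSS)      — relative residence time.
* Displacement force F(t) = sum over wall samples of (p n + tau_wss) dA —
  the pressure-plus-viscous load that drives stent-graft migration.

Wall shear vectors are extracted from the immersed-boundary solution by
probing the tangential velocity at one and two grid spacings along the
inward wall normal and Richardson-extrapolating the one-sided gradient to
the wall; the Carreau viscosity is evaluated at the extracted wall strain
rate.  Time quadrature is trapezoidal over the retained final cycle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import RegularGridInterpolator

from .rheology import RheologyParams, carreau_viscosity
from .geometry import WallSurface, OutletSection

__all__ = [
    "WssHistory",
    "MetricsTable",
    "helicity_density",
    "section_mean_helicity",
    "wall_shear_vectors",
    "wall_pressure",
    "tawss",
    "osi",
    "rrt",
    "area_weighted_mean",
    "surface_force",
    "displacement_force",
    "outer_surface_enrichment",
    "MetricsAccumulator",
]

RRT_INF = np.inf


def _shift0(a, axis, n):
    out = np.zeros_like(a)
    src = [slice(None)] * a.ndim
    dst = [slice(None)] * a.ndim
    if n > 0:
        src[axis], dst[axis] = slice(n, None), slice(None, -n)
    else:
        src[axis], dst[axis] = slice(None, n), slice(-n, None)
    out[tuple(dst)] = a[tuple(src)]
    return out


def extend_into_solid(fields, fluid):
    """Reflect cell-centered velocity into solid cells bordering the fluid.

    Solid neighbors get minus the mean of their fluid face-neighbors, so
    interpolation and finite differences across the immersed wall see the
    no-slip condition at the interface instead of a smeared zero.
    """
    fl = fluid.astype(float)
    cnt = np.zeros_like(fl)
    sums = [np.zeros_like(fl) for _ in fields]
    for a in range(3):
        for s in (-1, +1):
            nb_fl = _shift0(fl, a, s)
            cnt += nb_fl
            for k, f in enumerate(fields):
                sums[k] += _shift0(f * fl, a, s)
    cnt = np.maximum(cnt, 1.0)
    return tuple(np.where(fluid, f, -s / cnt)
                 for f, s in zip(fields, sums))


def _interp(field3, grid, points, fill=0.0):
    """Trilinear interpolation of a cell-centered field at points."""
    axes = grid.cell_centers_1d()
    it = RegularGridInterpolator(axes, field3, bounds_error=False,
                                 fill_value=fill)
    return it(points)


def _fluid_mask(grid, sdf_evaluator):
    xc, yc, zc = grid.cell_centers_1d()
    X, Y, Z = np.meshgrid(xc, yc, zc, indexing="ij")
    pts = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])
    return np.asarray(sdf_evaluator(pts)).reshape(grid.dims) < 0.0


def helicity_density(uc, vc, wc, spacing):
    """H_d = u . (curl u) at cell centers, second-order central curl."""
    h = float(spacing)
    _, duy, duz = np.gradient(uc, h, h, h)
    dvx, _, dvz = np.gradient(vc, h, h, h)
    dwx, dwy, _ = np.gradient(wc, h, h, h)
    cx = dwy - dvz
    cy = duz - dwx
    cz = dvx - duy
    return uc * cx + vc * cy + wc * cz


def section_mean_helicity(state, grid, section: OutletSection):
    """Area-weighted mean of H_d over an outlet section (signed), plus the
    area-weighted mean of |H_d| (the alternate unsigned variant)."""
    if len(section.points) == 0:
        raise ValueError("empty outlet section")
    uc, vc, wc = state.cell_velocity()
    H = helicity_density(uc, vc, wc, grid.spacing)
    vals = _interp(H, grid, section.points)
    wsum = float(np.sum(section.weights))
    signed = float(np.sum(vals * section.weights) / wsum)
    unsigned = float(np.sum(np.abs(vals) * section.weights) / wsum)
    return signed, unsigned


@dataclass
class WssHistory:
    """WSS vector time series per wall sample over one retained cycle.

    ``wss`` has shape (n_samples, n_times, 3); ``times`` spans exactly one
    period and is strictly increasing; ``excluded`` flags samples with no
    valid fluid probes (reported, left out of area averages).
    """

    times: np.ndarray
    wss: np.ndarray
    excluded: np.ndarray

    def __post_init__(self):
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.wss.shape[1] != len(self.times):
            raise ValueError("wss/time shape mismatch")

    @property
    def n_excluded(self) -> int:
        return int(np.sum(self.excluded))


#: probe depths (in grid spacings) for wall-shear extraction: close enough
#: to the wall to resolve oscillatory (Stokes-layer) shear, far enough
#: that trilinear interpolation is not dominated by the immersed-wall
#: staircase.
PROBE_DEPTHS = (1.0, 2.0)


def wall_probe_points(wall: WallSurface, spacing: float,
                      depths=PROBE_DEPTHS):
    """Probe locations along the inward wall normal."""
    n_in = -wall.normals
    return tuple(wall.points + d * spacing * n_in for d in depths)


def _carreau_tau(g, p: RheologyParams):
    lg2 = (p.lambda_relax * g) ** 2
    return p.eta_inf * g + (p.eta_0 - p.eta_inf) * g * (1.0 + lg2) ** (
        (p.n_index - 1.0) / 2.0)


def _carreau_dtau(g, p: RheologyParams):
    lg2 = (p.lambda_relax * g) ** 2
    return p.eta_inf + (p.eta_0 - p.eta_inf) * (1.0 + lg2) ** (
        (p.n_index - 3.0) / 2.0) * (1.0 + p.n_index * lg2)


def _carreau_invert(tau, p: RheologyParams, iters: int = 14):
    """Strain rate g >= 0 with eta(g) g = tau (tau >= 0), vectorized."""
    tau = np.asarray(tau, float)
    # seed with the effective-viscosity estimate; Newton is then a few
    # quadratically convergent steps
    g = tau / np.asarray(carreau_viscosity(tau / p.eta_inf, p))
    for _ in range(iters):
        g = np.maximum(g - (_carreau_tau(g, p) - tau) / _carreau_dtau(g, p),
                       0.0)
    return g


# 4-point Gauss-Legendre on [0, 1]
_GX = np.array([0.06943184420297371, 0.33000947820757187,
                0.6699905217924281, 0.9305681557970262])
_GW = np.array([0.17392742256872693, 0.32607257743127305,
                0.32607257743127305, 0.17392742256872693])


def _fit_wall_shear(u1, u2, d1, d2, p: RheologyParams, iters: int = 14):
    """Signed wall traction tau_w from two near-wall tangential speeds.

    Model: the tangential traction varies linearly with wall distance,
    tau(x) = tau_w + s x, and the velocity follows the generalized
    Newtonian flux profile u(d) = int_0^d g(tau(x)) dx with g the inverse
    of the Carreau law.  Exact for fully developed tube/channel flow of a
    Carreau fluid; reduces to the one-sided quadratic fit for a Newtonian
    fluid.  Solved per sample by a damped Newton iteration.
    """
    a0 = (u1 * d2 * d2 - u2 * d1 * d1) / (d1 * d2 * (d2 - d1))
    if p.is_newtonian:
        # closed form: u(d) = (tau_w d + s d^2/2)/eta -> quadratic fit
        return p.eta_0 * a0
    # quadrature nodes on [0, d1] and [d1, d2]
    xa = d1 * _GX[None, :]
    wa = d1 * _GW[None, :]
    xb = d1 + (d2 - d1) * _GX[None, :]
    wb = (d2 - d1) * _GW[None, :]
    tw = np.asarray(carreau_viscosity(np.abs(a0), p)) * a0
    s = np.zeros_like(tw)

    def seg(tw, s, x, w):
        tau = tw[:, None] + s[:, None] * x
        sign = np.sign(tau)
        g = _carreau_invert(np.abs(tau), p) * sign
        gp = 1.0 / _carreau_dtau(np.abs(g), p)
        I = np.sum(g * w, axis=1)
        dI_dtw = np.sum(gp * w, axis=1)
        dI_ds = np.sum(gp * x * w, axis=1)
        return I, dI_dtw, dI_ds

    for _ in range(iters):
        Ia, Ja_t, Ja_s = seg(tw, s, xa, wa)
        Ib, Jb_t, Jb_s = seg(tw, s, xb, wb)
        F1 = Ia - u1
        F2 = Ia + Ib - u2
        J11, J12 = Ja_t, Ja_s
        J21, J22 = Ja_t + Jb_t, Ja_s + Jb_s
        det = J11 * J22 - J12 * J21
        det = np.where(np.abs(det) < 1e-300, 1e-300, det)
        dtw = (F1 * J22 - F2 * J12) / det
        ds = (F2 * J11 - F1 * J21) / det
        tw = tw - np.clip(dtw, -10 * np.abs(tw) - 1.0, 10 * np.abs(tw) + 1.0)
        s = s - np.clip(ds, -1e8, 1e8)
    return tw


def wall_shear_vectors(state, wall: WallSurface, rheology: RheologyParams,
                       grid, sdf_evaluator=None, depths=PROBE_DEPTHS,
                       fluid_mask=None):
    """Tangential wall shear stress vector (Pa) at every wall sample.

    The tangential velocity is probed at two depths along the inward
    normal and the wall traction is recovered by the generalized-
    Newtonian near-wall profile fit (see _fit_wall_shear).  When a fluid
    mask is available the probed field is first mirror-extended into the
    solid so the interpolation respects the no-slip interface.  Returns
    (wss, excluded): flagged samples (first probe outside the fluid)
    carry zeros and are excluded from averages.
    """
    h = grid.spacing
    p1, p2 = wall_probe_points(wall, h, depths)
    uc, vc, wc = state.cell_velocity()
    if fluid_mask is None and sdf_evaluator is not None:
        fluid_mask = _fluid_mask(grid, sdf_evaluator)
    if fluid_mask is not None:
        uc, vc, wc = extend_into_solid((uc, vc, wc), fluid_mask)
    u1 = np.column_stack([_interp(f, grid, p1) for f in (uc, vc, wc)])
    u2 = np.column_stack([_interp(f, grid, p2) for f in (uc, vc, wc)])
    n = wall.normals
    ut1 = u1 - np.sum(u1 * n, axis=1, keepdims=True) * n
    ut2 = u2 - np.sum(u2 * n, axis=1, keepdims=True) * n
    speed1 = np.linalg.norm(ut1, axis=1)
    ehat = np.divide(ut1, speed1[:, None],
                     out=np.zeros_like(ut1), where=speed1[:, None] > 0)
    s2 = np.sum(ut2 * ehat, axis=1)
    d1, d2 = depths[0] * h, depths[1] * h
    tw = _fit_wall_shear(speed1, s2, d1, d2, rheology)
    wss = tw[:, None] * ehat
    excluded = np.zeros(len(wall), bool)
    if sdf_evaluator is not None:
        excluded = np.asarray(sdf_evaluator(p1)) > 0.0
        wss[excluded] = 0.0
    return wss, excluded


def wall_pressure(state, wall: WallSurface, grid):
    """Pressure extrapolated to wall samples one-sided from the fluid."""
    p1, _ = wall_probe_points(wall, grid.spacing)
    return np.asarray(_interp(state.p, grid, p1))


def tawss(history: WssHistory):
    """Per-sample time-averaged |WSS| (Pa), trapezoidal over the cycle."""
    if len(history.times) < 2:
        raise ValueError("need at least two time steps for TAWSS")
    T = history.times[-1] - history.times[0]
    mag = np.linalg.norm(history.wss, axis=2)
    return np.trapezoid(mag, history.times, axis=1) / T


def osi(history: WssHistory):
    """Per-sample oscillatory shear index in [0, 0.5].

    Never-loaded samples (zero shear all cycle) get OSI = 0 and are
    flagged; returns (osi_values, flagged).
    """
    if len(history.times) < 2:
        raise ValueError("need at least two time steps for OSI")
    vec = np.trapezoid(history.wss, history.times, axis=1)
    mag = np.trapezoid(np.linalg.norm(history.wss, axis=2), history.times,
                       axis=1)
    flagged = mag <= 0.0
    num = np.linalg.norm(vec, axis=1)
    out = np.zeros(len(mag))
    ok = ~flagged
    out[ok] = 0.5 * (1.0 - np.clip(num[ok] / mag[ok], 0.0, 1.0))
    return out, flagged


def rrt(tawss_value, osi_value):
    """Relative residence time 1 / ((1 - 2 OSI) * TAWSS), Pa^-1.

    Scalar or arrays; returns (rrt, flagged) where flagged marks poles
    (OSI -> 0.5 or TAWSS -> 0, mapped to +inf and excluded from means).
    """
    t = np.asarray(tawss_value, float)
    o = np.asarray(osi_value, float)
    if np.any(t < 0.0):
        raise ValueError("TAWSS must be non-negative")
    if np.any((o < 0.0) | (o > 0.5)):
        raise ValueError("OSI must lie in [0, 0.5]")
    denom = (1.0 - 2.0 * o) * t
    flagged = denom <= 0.0
    out = np.full(np.broadcast_shapes(t.shape, o.shape), RRT_INF)
    out[~flagged] = 1.0 / denom[~flagged]
    if out.ndim == 0:
        return float(out), bool(flagged)
    return out, flagged


def area_weighted_mean(values, wall: WallSurface, regions=None,
                       exclude=None, graft_only: bool = True) -> float:
    """Area-weighted mean of a per-sample field over selected wall regions."""
    mask = wall.select(regions=regions, graft_only=graft_only)
    if exclude is not None:
        mask &= ~np.asarray(exclude, bool)
    vals = np.asarray(values, float)
    mask &= np.isfinite(vals)
    if not np.any(mask):
        raise ValueError("no wall samples selected")
    return float(np.sum(vals[mask] * wall.areas[mask])
                 / np.sum(wall.areas[mask]))


def outer_surface_enrichment(values, wall: WallSurface,
                             regions=("left_iliac", "right_iliac"),
                             exclude=None, quantile: float = 0.75) -> float:
    """How strongly high values of a wall metric favor the outer surface.

    Returns the ratio of the outer-surface area fraction among the
    top-quantile samples to the outer-surface area fraction among all
    selected samples; > 1 means high values (e.g. OSI, RRT strips)
    concentrate on the outer surface of the limbs.
    """
    mask = wall.select(regions=regions, graft_only=True)
    vals = np.asarray(values, float)
    if exclude is not None:
        mask &= ~np.asarray(exclude, bool)
    mask &= np.isfinite(vals)
    if not np.any(mask):
        raise ValueError("no wall samples selected")
    thr = np.quantile(vals[mask], quantile)
    top = mask & (vals >= thr)
    outer = wall.side > 0
    area = wall.areas
    frac_top = np.sum(area[top & outer]) / np.sum(area[top])
    frac_all = np.sum(area[mask & outer]) / np.sum(area[mask])
    return float(frac_top / frac_all)


def surface_force(pressure, wss, wall: WallSurface, mask=None):
    """Net force vector (N) on the wall: sum of (p n + tau_wss) dA.

    ``pressure`` per sample (Pa), ``wss`` (n, 3) tangential traction the
    fluid exerts on the wall, normals point from fluid into wall.
    """
    if mask is None:
        mask = np.ones(len(wall), bool)
    dA = wall.areas[mask][:, None]
    n = wall.normals[mask]
    p = np.asarray(pressure, float)[mask][:, None]
    tau = np.asarray(wss, float)[mask]
    return np.sum((p * n + tau) * dA, axis=0)


def displacement_force(states, wall: WallSurface, rheology: RheologyParams,
                       grid, sdf_evaluator=None):
    """Displacement-force trace over a snapshot sequence.

    Returns (times, F) with F of shape (nt, 3): the net pressure-plus-
    viscous load on the device wall at each snapshot.  The maximum of
    |F(t)| is expected at the overall outlet-pressure peak (checked as a
    diagnostic by the sweep pipeline).
    """
    fluid = (_fluid_mask(grid, sdf_evaluator)
             if sdf_evaluator is not None else None)
    mask = wall.select(graft_only=True)
    times, forces = [], []
    for st in states:
        wss, excl = wall_shear_vectors(st, wall, rheology, grid,
                                       sdf_evaluator, fluid_mask=fluid)
        p = wall_pressure(st, wall, grid)
        forces.append(surface_force(p, wss, wall, mask & ~excl))
        times.append(st.t)
    return np.asarray(times), np.vstack(forces)


@dataclass
class MetricsTable:
    """Tidy per-run record of the hemodynamic indicators."""

    config: dict
    times: np.ndarray
    helicity_signed_trace: np.ndarray
    helicity_unsigned_trace: np.ndarray
    force_trace: np.ndarray          # (nt, 3)
    tawss_map: np.ndarray
    osi_map: np.ndarray
    rrt_map: np.ndarray
    excluded: np.ndarray
    wall: WallSurface | None = None
    diagnostics: dict = field(default_factory=dict)

    @property
    def helicity_abs_trace(self):
        """|area-averaged H_d| at the outlet, the primary reported trace."""
        return np.abs(self.helicity_signed_trace)

    @property
    def helicity_cycle_mean(self) -> float:
        t = self.times
        return float(np.trapezoid(self.helicity_abs_trace, t) / (t[-1] - t[0]))

    @property
    def helicity_peak(self) -> float:
        return float(np.max(self.helicity_abs_trace))

    @property
    def helicity_unsigned_peak(self) -> float:
        """Peak of the <|H_d|> (unsigned-variant) outlet trace."""
        return float(np.max(self.helicity_unsigned_trace))

    @property
    def helicity_unsigned_cycle_mean(self) -> float:
        t = self.times
        return float(np.trapezoid(self.helicity_unsigned_trace, t)
                     / (t[-1] - t[0]))

    @property
    def force_magnitude_trace(self):
        return np.linalg.norm(self.force_trace, axis=1)

    @property
    def force_max(self) -> float:
        return float(np.max(self.force_magnitude_trace))

    @property
    def force_axial_max(self) -> float:
        return float(np.max(np.abs(self.force_trace[:, 2])))

    def area_means(self, regions=("left_iliac", "right_iliac")) -> dict:
        w = self.wall
        out = {}
        out["tawss"] = area_weighted_mean(self.tawss_map, w, regions,
                                          exclude=self.excluded)
        out["osi"] = area_weighted_mean(self.osi_map, w, regions,
                                        exclude=self.excluded)
        rrt_excl = self.excluded | ~np.isfinite(self.rrt_map)
        out["rrt"] = area_weighted_mean(self.rrt_map, w, regions,
                                        exclude=rrt_excl)
        return out

    def enrichment(self, which: str = "osi") -> float:
        """Outer-surface enrichment ratio of the high-OSI/RRT strips."""
        vals = {"osi": self.osi_map, "rrt": self.rrt_map,
                "tawss": self.tawss_map}[which]
        excl = self.excluded | ~np.isfinite(np.asarray(vals, float))
        return outer_surface_enrichment(vals, self.wall, exclude=excl)

    def to_row(self) -> dict:
        row = dict(self.config)
        row.update({f"iliac_{k}": v for k, v in self.area_means().items()})
        for which in ("osi", "rrt"):
            try:
                row[f"{which}_outer_enrichment"] = self.enrichment(which)
            except ValueError:
                row[f"{which}_outer_enrichment"] = float("nan")
        row.update({
            "helicity_peak": self.helicity_peak,
            "helicity_cycle_mean": self.helicity_cycle_mean,
            "helicity_unsigned_peak": self.helicity_unsigned_peak,
            "helicity_unsigned_cycle_mean": self.helicity_unsigned_cycle_mean,
            "force_max": self.force_max,
            "force_axial_max": self.force_axial_max,
            "n_excluded": int(np.sum(self.excluded)),
        })
        row.update(self.diagnostics)
        return row


class MetricsAccumulator:
    """Collects per-snapshot wall and outlet data during a pulsatile solve.

    Use as the ``snapshot_hook`` of ``solve_pulsatile`` so full 3-D fields
    never need to be stored; ``finalize`` assembles the MetricsTable.
    """

    def __init__(self, grid, wall: WallSurface, rheology: RheologyParams,
                 section: OutletSection, sdf_evaluator=None,
                 config: dict | None = None, wall_stride: int = 1):
        self.grid = grid
        self.full_wall = wall
        # WSS maps may run on a strided sample subset at coarse tiers; the
        # pressure force always integrates over the full wall (the vector
        # area of a thinned closed-ish surface would not cancel properly)
        idx = np.arange(0, len(wall), max(1, int(wall_stride)))
        self.wall = wall.subset(idx) if wall_stride > 1 else wall
        self._area_scale = (wall.total_area / self.wall.total_area
                            if wall_stride > 1 else 1.0)
        self.rheology = rheology
        self.section = section
        self.sdf_evaluator = sdf_evaluator
        self.config = dict(config or {})
        self.times = []
        self._wss = []
        self._forces = []
        self._hel_signed = []
        self._hel_unsigned = []
        self._excluded = np.zeros(len(self.wall), bool)
        self._graft_mask = self.wall.select(graft_only=True)
        self._full_graft = wall.select(graft_only=True)
        self._fluid = (_fluid_mask(grid, sdf_evaluator)
                       if sdf_evaluator is not None else None)

    def __call__(self, state, solver=None):
        wss, excl = wall_shear_vectors(state, self.wall, self.rheology,
                                       self.grid, self.sdf_evaluator,
                                       fluid_mask=self._fluid)
        p = wall_pressure(state, self.full_wall, self.grid)
        self._excluded |= excl
        mask = self._graft_mask & ~excl
        F = surface_force(p, np.zeros((len(self.full_wall), 3)),
                          self.full_wall, self._full_graft)
        F = F + self._area_scale * surface_force(
            np.zeros(len(self.wall)), wss, self.wall, mask)
        self._forces.append(F)
        s, u = section_mean_helicity(state, self.grid, self.section)
        self._hel_signed.append(s)
        self._hel_unsigned.append(u)
        self._wss.append(wss)
        self.times.append(state.t)

    def finalize(self, diagnostics: dict | None = None) -> MetricsTable:
        times = np.asarray(self.times)
        times = times - times[0]
        hist = WssHistory(times=times,
                          wss=np.stack(self._wss, axis=1),
                          excluded=self._excluded)
        ta = tawss(hist)
        os_, os_flag = osi(hist)
        rr, rr_flag = rrt(ta, os_)
        excluded = self._excluded | os_flag
        return MetricsTable(
            config=self.config,
            times=times,
            helicity_signed_trace=np.asarray(self._hel_signed),
            helicity_unsigned_trace=np.asarray(self._hel_unsigned),
            force_trace=np.vstack(self._forces),
            tawss_map=ta, osi_map=os_, rrt_map=rr,
            excluded=excluded, wall=self.wall,
            diagnostics=dict(diagnostics or {}),
        )
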