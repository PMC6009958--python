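"""Parametric crossed-limb bifurcated stent-graft (BSG) geometry.

A BSG consists of a straight trunk tube and two iliac limb tubes that leave
the bifurcation, cross each other ("ballerina position"), and end on the
distal outlet plane.  The configuration is controlled by the cross angle
``alpha`` between the limbs at the crossing and the cross position, either
as the axial bifurcation-to-cross distance ``l`` or as the ratio
``r = l/h`` with ``h`` the axial cross-to-outlet distance.

Construction conventions (all geometry is mirror symmetric):

* z is the trunk axis pointing distal (flow direction), the x-z plane is
  the symmetry plane, y is out of plane; the origin is the trunk inlet
  center.  Config lengths are mm, all returned objects are SI meters.
* Each limb starts at an ostium offset laterally by
  (trunk_diameter - iliac_diameter)/2 from the axis, follows a cubic
  Hermite arc to the cross point on the axis, and continues straight from
  the cross point toward its outlet; the straight distal leg fixes the
  relation tan(alpha/2) = g / (2 h) between the cross angle and the
  outlet-center separation ``g`` (the limb "side length" parameter), so a
  sweep may prescribe either one.
* Truly coplanar 10 mm limbs would interpenetrate at the crossing, so each
  limb carries an equal-and-opposite smooth out-of-plane excursion in y of
  amplitude (iliac_diameter + clearance)/2, flat-topped around the cross
  point so the surface-to-surface gap there is exactly ``clearance``.

The lumen is represented implicitly as a signed distance field (negative
inside the fluid) built from capsule distances to the three centerlines
with a smooth-minimum blend at the bifurcation; walls are extracted from
the zero level set by marching cubes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "GeometryError",
    "BSGConfig",
    "Centerline",
    "SignedDistanceField",
    "WallSurface",
    "build_centerlines",
    "LumenSDF",
    "sample_sdf",
    "extract_wall_surface",
    "outlet_section",
    "straight_tube_sdf",
    "sphere_surface",
    "default_grid",
]

MM = 1e-3


class GeometryError(ValueError):
    """Raised for geometrically infeasible configurations."""


@dataclass(frozen=True)
class BSGConfig:
    """All geometric parameters of one crossed-limb graft instance (mm/deg).

    Exactly one of (``cross_angle_deg``, ``side_length_mm``) and one of
    (``cross_length_mm``, ``position_ratio``) must be given; the other
    member of each pair is derived through tan(alpha/2) = g/(2h) and
    r = l/h.  The angle sweep fixes l = 42 mm and varies alpha; the
    position sweep fixes g = 41 mm and varies r.
    """

    trunk_diameter: float = 17.0
    iliac_diameter: float = 10.0
    total_length: float = 154.64
    trunk_length: float = 71.0
    cross_angle_deg: float | None = 60.0
    cross_length_mm: float | None = 42.0
    position_ratio: float | None = None
    side_length_mm: float | None = None
    clearance_mm: float = 1.0
    ostium_offset_mm: float | None = None

    def __post_init__(self):
        errs = []
        for name in ("trunk_diameter", "iliac_diameter", "total_length",
                     "trunk_length", "clearance_mm"):
            if getattr(self, name) <= 0:
                errs.append(f"{name} must be positive")
        if self.trunk_length >= self.total_length:
            errs.append("trunk_length must be smaller than total_length")
        if self.cross_angle_deg is not None and not 0 < self.cross_angle_deg < 180:
            errs.append("cross_angle_deg must lie in (0, 180)")
        if self.cross_length_mm is None and self.position_ratio is None:
            errs.append("one of cross_length_mm / position_ratio is required")
        if self.cross_angle_deg is None and self.side_length_mm is None:
            errs.append("one of cross_angle_deg / side_length_mm is required")
        if self.position_ratio is not None and self.position_ratio <= 0:
            errs.append("position_ratio must be positive")
        if self.side_length_mm is not None and self.side_length_mm <= 0:
            errs.append("side_length_mm must be positive")
        if errs:
            raise GeometryError("; ".join(errs))

    # ---- resolved quantities (mm / radians) -------------------------------
    @property
    def limb_axial_mm(self) -> float:
        """Axial span of the limbs, l + h."""
        return self.total_length - self.trunk_length

    @property
    def l_mm(self) -> float:
        """Axial distance from bifurcation point to cross point."""
        if self.cross_length_mm is not None:
            l = float(self.cross_length_mm)
        else:
            r = self.position_ratio
            l = self.limb_axial_mm * r / (1.0 + r)
        if not 0.0 < l < self.limb_axial_mm:
            raise GeometryError(
                f"cross point at l = {l:g} mm does not lie between the "
                f"bifurcation and the distal plane (0, {self.limb_axial_mm:g})"
            )
        return l

    @property
    def h_mm(self) -> float:
        """Axial distance from cross point to the distal outlet plane."""
        return self.limb_axial_mm - self.l_mm

    @property
    def ratio(self) -> float:
        """Cross position ratio r = l/h."""
        return self.l_mm / self.h_mm

    @property
    def half_angle_rad(self) -> float:
        if self.cross_angle_deg is not None:
            return math.radians(self.cross_angle_deg) / 2.0
        theta = math.atan2(self.side_length_mm / 2.0, self.h_mm)
        return theta

    @property
    def alpha_deg(self) -> float:
        return math.degrees(2.0 * self.half_angle_rad)

    @property
    def outlet_separation_mm(self) -> float:
        """Distance g between the two outlet centers on the distal plane."""
        return 2.0 * self.h_mm * math.tan(self.half_angle_rad)

    @property
    def ostium_offset(self) -> float:
        if self.ostium_offset_mm is not None:
            return float(self.ostium_offset_mm)
        return (self.trunk_diameter - self.iliac_diameter) / 2.0

    @property
    def bump_amplitude_mm(self) -> float:
        return (self.iliac_diameter + self.clearance_mm) / 2.0

    def validate(self) -> None:
        """Raise GeometryError for infeasible resolved geometry."""
        _ = self.l_mm
        if not 0.0 < self.alpha_deg < 180.0:
            raise GeometryError(f"resolved cross angle {self.alpha_deg:g} deg "
                                "outside (0, 180)")
        # the out-of-plane excursion must fit between ostium and outlet
        if min(self.l_mm, self.h_mm) < 1.2 * self.bump_amplitude_mm:
            raise GeometryError(
                "cross point too close to bifurcation or outlet for the "
                "out-of-plane clearance excursion "
                f"(min(l, h) = {min(self.l_mm, self.h_mm):g} mm)"
            )


@dataclass(frozen=True)
class Centerline:
    """Ordered 3-D polyline (meters) with unit tangents and arc length."""

    points: np.ndarray
    tangents: np.ndarray
    arclength: np.ndarray
    label: str = ""

    def __post_init__(self):
        t = np.linalg.norm(self.tangents, axis=1)
        if not np.allclose(t, 1.0, atol=1e-9):
            raise GeometryError("tangents must be unit vectors")
        if np.any(np.diff(self.arclength) <= 0):
            raise GeometryError("arc length must be strictly increasing")

    @property
    def length(self) -> float:
        return float(self.arclength[-1])

    def max_tangent_kink_deg(self) -> float:
        dots = np.clip(np.sum(self.tangents[:-1] * self.tangents[1:], axis=1),
                       -1.0, 1.0)
        return float(np.degrees(np.max(np.arccos(dots))))

    def to_csv(self, path) -> None:
        arr = np.column_stack([self.points, self.arclength])
        np.savetxt(path, arr, delimiter=",", comments="",
                   header="x,y,z,arclength", fmt="%.12g")


def _polyline(points: np.ndarray, label: str) -> Centerline:
    seg = np.diff(points, axis=0)
    ds = np.linalg.norm(seg, axis=1)
    s = np.concatenate([[0.0], np.cumsum(ds)])
    tan = np.empty_like(points)
    tan[1:-1] = points[2:] - points[:-2]
    tan[0] = seg[0]
    tan[-1] = seg[-1]
    tan /= np.linalg.norm(tan, axis=1, keepdims=True)
    return Centerline(points=points, tangents=tan, arclength=s, label=label)


def _bump_profile(u: np.ndarray, plateau: float = 0.35) -> np.ndarray:
    """C^1 flat-topped unit bump on |u| <= 1: 1 on |u|<=plateau, cos^2 taper."""
    out = np.zeros_like(u)
    au = np.abs(u)
    out[au <= plateau] = 1.0
    taper = (au > plateau) & (au < 1.0)
    out[taper] = np.cos(0.5 * np.pi * (au[taper] - plateau) / (1.0 - plateau)) ** 2
    return out


def _limb_points(cfg: BSGConfig, side: int, n: int, extension_mm: float):
    """In-plane limb polyline for side=+1 (left, crosses to +x) or -1.

    Returns (n_pts, 3) array in mm, including the out-of-plane bump.
    """
    theta = cfg.half_angle_rad
    z_bif, z_end = cfg.trunk_length, cfg.total_length
    l, h = cfg.l_mm, cfg.h_mm
    x0 = -side * cfg.ostium_offset
    # proximal cubic Hermite: ostium (axial tangent) -> cross point (tangent
    # at half-angle); tangent magnitudes equal to the chord length
    p0 = np.array([x0, 0.0, z_bif])
    p1 = np.array([0.0, 0.0, z_bif + l])
    d = np.array([side * math.sin(theta), 0.0, math.cos(theta)])
    chord = np.linalg.norm(p1 - p0)
    m0 = np.array([0.0, 0.0, 1.0]) * chord
    m1 = d * chord
    n_prox = max(8, int(round(n * l / (l + h))))
    t = np.linspace(0.0, 1.0, n_prox)[:, None]
    h00 = 2 * t**3 - 3 * t**2 + 1
    h10 = t**3 - 2 * t**2 + t
    h01 = -2 * t**3 + 3 * t**2
    h11 = t**3 - t**2
    prox = h00 * p0 + h10 * m0 + h01 * p1 + h11 * m1
    # distal straight leg from the cross point to (and optionally past) the
    # outlet plane; the centerline ends exactly at z = total_length
    leg = (h + extension_mm) / math.cos(theta)
    n_dist = max(8, int(round(n * (h + extension_mm) / (l + h))))
    s = np.linspace(0.0, leg, n_dist + 1)[1:, None]
    dist = p1 + s * d
    pts = np.vstack([prox, dist])
    # out-of-plane clearance excursion, flat-topped around the cross point
    w = 0.85 * min(l, h)
    u = (pts[:, 2] - (z_bif + l)) / w
    pts[:, 1] = side * cfg.bump_amplitude_mm * _bump_profile(u)
    return pts


def build_centerlines(cfg: BSGConfig, n: int = 400, extension_mm: float = 0.0):
    """Trunk, left and right limb centerlines (SI meters).

    The trunk is the straight axial segment of length ``trunk_length``; the
    limbs are mirror images through the symmetry plane (up to the sign of
    the out-of-plane excursion) ending on the distal plane, extended
    ``extension_mm`` further downstream when a numerical outflow extension
    is requested.
    """
    cfg.validate()
    nz = max(32, n // 2)
    ztrunk = np.linspace(0.0, cfg.trunk_length, nz)
    trunk_pts = np.column_stack([np.zeros(nz), np.zeros(nz), ztrunk])
    trunk = _polyline(trunk_pts * MM, "trunk")
    left = _polyline(_limb_points(cfg, +1, n, extension_mm) * MM, "left_iliac")
    right = _polyline(_limb_points(cfg, -1, n, extension_mm) * MM, "right_iliac")
    for cl in (left, right):
        if cl.max_tangent_kink_deg() > 5.0:
            raise GeometryError(
                f"{cl.label} centerline is not C1 within tolerance "
                f"(max kink {cl.max_tangent_kink_deg():.2f} deg)")
    _check_clearance(cfg, left, right)
    return trunk, left, right


def _check_clearance(cfg: BSGConfig, left: Centerline, right: Centerline):
    """Limb lumens must keep the clearance gap around the crossing.

    Proximal to the crossing the limbs legitimately merge into the trunk
    at the flow divider, so the check covers the out-of-plane plateau
    window centered on the cross point.
    """
    z_c = (cfg.trunk_length + cfg.l_mm) * MM
    w = 0.85 * min(cfg.l_mm, cfg.h_mm) * MM
    sel_l = np.abs(left.points[:, 2] - z_c) <= 0.34 * w
    sel_r = np.abs(right.points[:, 2] - z_c) <= 0.5 * w
    tree = cKDTree(right.points[sel_r])
    dmin = float(np.min(tree.query(left.points[sel_l])[0]))
    gap = dmin / MM - cfg.iliac_diameter
    if gap < 0.98 * cfg.clearance_mm:
        raise GeometryError(
            "limb lumens interpenetrate at the crossing: surface gap "
            f"{gap:.3f} mm < clearance {cfg.clearance_mm:g} mm")


# ---------------------------------------------------------------------------
# signed distance field


def _smin(a: np.ndarray, b: np.ndarray, k: float) -> np.ndarray:
    """Polynomial smooth minimum with blend radius k (exact min for k=0)."""
    if k <= 0.0:
        return np.minimum(a, b)
    h = np.clip(0.5 + 0.5 * (b - a) / k, 0.0, 1.0)
    return b + (a - b) * h - k * h * (1.0 - h)


class LumenSDF:
    """Signed distance evaluator for the BSG lumen (negative inside).

    Distance to each tube is capsule distance to a densely sampled
    centerline minus the tube radius; trunk and limbs are joined by a
    smooth minimum over one iliac radius, while the two limbs combine by a
    hard minimum so their lumens stay disjoint at the crossing.
    """

    def __init__(self, cfg: BSGConfig, extension_mm: float = 0.0,
                 sample_ds_mm: float = 0.15, blend_mm: float | None = None):
        self.cfg = cfg
        self.extension_mm = float(extension_mm)
        n = int(max(400, 4 * cfg.total_length / sample_ds_mm))
        trunk, left, right = build_centerlines(cfg, n=n,
                                               extension_mm=extension_mm)
        self.centerlines = {"trunk": trunk, "left_iliac": left,
                            "right_iliac": right}
        self.radii = {"trunk": cfg.trunk_diameter / 2.0 * MM,
                      "left_iliac": cfg.iliac_diameter / 2.0 * MM,
                      "right_iliac": cfg.iliac_diameter / 2.0 * MM}
        self.blend = (cfg.iliac_diameter / 2.0 if blend_mm is None
                      else blend_mm) * MM
        self._trees = {k: cKDTree(cl.points)
                       for k, cl in self.centerlines.items()}

    def tube_distances(self, points: np.ndarray) -> dict:
        pts = np.atleast_2d(points)
        return {k: self._trees[k].query(pts)[0] - self.radii[k]
                for k in self._trees}

    def __call__(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        d = self.tube_distances(pts)
        k = self.blend
        out = np.minimum(_smin(d["trunk"], d["left_iliac"], k),
                         _smin(d["trunk"], d["right_iliac"], k))
        return out

    def nearest_region(self, points: np.ndarray):
        """Label, nearest-centerline arc length, and lateral side per point.

        side is +1 on the outer surface (facing away from the symmetry
        axis / the other limb) and -1 on the inner surface.
        """
        pts = np.atleast_2d(points)
        d = self.tube_distances(pts)
        labels = np.array(list(d.keys()))
        stack = np.vstack([d[k] for k in labels])
        idx = np.argmin(stack, axis=0)
        region = labels[idx]
        arcs = np.empty(len(pts))
        side = np.empty(len(pts))
        for j, k in enumerate(labels):
            sel = idx == j
            if not np.any(sel):
                continue
            _, near = self._trees[k].query(pts[sel])
            cl = self.centerlines[k]
            arcs[sel] = cl.arclength[near]
            clx = cl.points[near, 0]
            side[sel] = np.where(
                np.sign(clx) * (pts[sel, 0] - clx) > 0, 1.0, -1.0)
        return region, arcs, side

    def graft_end_arclength(self, limb: str) -> float:
        """Limb arc length at which the graft ends (distal plane crossing)."""
        cl = self.centerlines[limb]
        z = cl.points[:, 2]
        z_end = self.cfg.total_length * MM
        i = int(np.searchsorted(z, z_end - 1e-12))
        if i >= len(z):
            return cl.length
        return float(cl.arclength[min(i, len(z) - 1)])


@dataclass(frozen=True)
class SignedDistanceField:
    """Node-sampled signed distance on a uniform Cartesian grid (meters).

    ``values`` has shape ``dims`` (node counts per axis); negative values
    are inside the fluid lumen.
    """

    origin: np.ndarray
    spacing: float
    values: np.ndarray
    evaluator: Callable | None = field(default=None, compare=False)

    @property
    def dims(self):
        return self.values.shape

    def node_coords(self):
        o, h = self.origin, self.spacing
        return [o[a] + h * np.arange(self.dims[a]) for a in range(3)]


def default_grid(cfg: BSGConfig, spacing_mm: float, margin_mm: float = 3.0,
                 extension_mm: float = 0.0):
    """Origin (m), spacing (m) and node dims covering the graft lumen.

    The box is symmetric in x and y about the trunk axis so that mirror
    configurations land on mirrored grid nodes, and spans z in
    [0, total_length + extension].
    """
    theta = cfg.half_angle_rad
    r_i = cfg.iliac_diameter / 2.0
    xmax = max(cfg.trunk_diameter / 2.0,
               (cfg.h_mm + extension_mm) * math.tan(theta) + r_i / math.cos(theta),
               cfg.ostium_offset + r_i) + margin_mm
    ymax = cfg.bump_amplitude_mm + r_i + margin_mm
    h = spacing_mm * MM
    nx = 2 * int(math.ceil(xmax * MM / h)) + 1
    ny = 2 * int(math.ceil(ymax * MM / h)) + 1
    zlen = (cfg.total_length + extension_mm) * MM
    nz = int(math.ceil(zlen / h)) + 1
    origin = np.array([-(nx - 1) / 2.0 * h, -(ny - 1) / 2.0 * h, 0.0])
    return origin, h, (nx, ny, nz)


def sample_sdf(cfg: BSGConfig, grid_spec=None, spacing_mm: float = 1.0,
               extension_mm: float = 0.0) -> SignedDistanceField:
    """Sample the lumen SDF on grid nodes.

    ``grid_spec`` is an (origin, spacing, dims) triple in meters; when
    omitted a symmetric default box is built at ``spacing_mm`` resolution.
    Refuses spacings coarser than the iliac radius (lumen unresolvable).
    """
    if grid_spec is None:
        grid_spec = default_grid(cfg, spacing_mm, extension_mm=extension_mm)
    origin, h, dims = grid_spec
    origin = np.asarray(origin, dtype=float)
    if h > cfg.iliac_diameter / 2.0 * MM:
        raise GeometryError(
            f"grid spacing {h / MM:g} mm exceeds the iliac radius "
            f"{cfg.iliac_diameter / 2.0:g} mm; lumen would be unresolvable")
    ev = LumenSDF(cfg, extension_mm=extension_mm,
                  sample_ds_mm=min(0.2, h / MM / 2.0))
    xs, ys, zs = (origin[a] + h * np.arange(dims[a]) for a in range(3))
    X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
    pts = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])
    vals = ev(pts).reshape(dims)
    return SignedDistanceField(origin=origin, spacing=h, values=vals,
                               evaluator=ev)


# ---------------------------------------------------------------------------
# wall surface


@dataclass
class WallSurface:
    """Discrete wall samples: points, outward normals, areas, labels.

    Normals point from the fluid into the wall (along +grad SDF).  ``region``
    labels each sample trunk/left_iliac/right_iliac; ``on_graft`` is False
    on numerical outflow-extension wall beyond the distal device end;
    ``side`` is +1 on the outer (abluminal-facing) surface of a limb.
    """

    points: np.ndarray
    normals: np.ndarray
    areas: np.ndarray
    region: np.ndarray
    side: np.ndarray
    arclength: np.ndarray
    on_graft: np.ndarray
    triangles: np.ndarray | None = None
    vertices: np.ndarray | None = None

    def __len__(self):
        return len(self.points)

    @property
    def total_area(self) -> float:
        return float(np.sum(self.areas))

    def subset(self, idx) -> "WallSurface":
        """Sample subset (e.g. a stride thinning for coarse-tier metrics)."""
        return WallSurface(points=self.points[idx], normals=self.normals[idx],
                           areas=self.areas[idx], region=self.region[idx],
                           side=self.side[idx],
                           arclength=self.arclength[idx],
                           on_graft=self.on_graft[idx])

    def select(self, regions=None, graft_only: bool = True) -> np.ndarray:
        mask = np.ones(len(self), dtype=bool)
        if regions is not None:
            mask &= np.isin(self.region, list(regions))
        if graft_only:
            mask &= self.on_graft
        return mask


def extract_wall_surface(sdf: SignedDistanceField) -> WallSurface:
    """Triangulate the zero level set and build integration samples.

    Uses marching cubes on the node-sampled SDF; samples are triangle
    centroids weighted by triangle area.  Aperture faces at the domain
    boundary are naturally left open (no caps are generated).
    """
    from skimage import measure

    vals = sdf.values
    if not (vals.min() < 0.0 < vals.max()):
        raise GeometryError("SDF has no zero level set on this grid")
    h = sdf.spacing
    verts, faces, _, _ = measure.marching_cubes(
        vals, level=0.0, spacing=(h, h, h))
    verts = verts + sdf.origin[None, :]
    tri = verts[faces]
    cent = tri.mean(axis=1)
    cross = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
    area2 = np.linalg.norm(cross, axis=1)
    keep = area2 > 0.0
    faces, cent, cross, area2 = faces[keep], cent[keep], cross[keep], area2[keep]
    areas = 0.5 * area2
    if len(areas) == 0:
        raise GeometryError("empty wall surface")
    if sdf.evaluator is not None:
        normals = _sdf_gradient(sdf.evaluator, cent, 0.25 * h)
        region, arcs, side = sdf.evaluator.nearest_region(cent)
        on_graft = np.ones(len(cent), dtype=bool)
        for limb in ("left_iliac", "right_iliac"):
            s_end = sdf.evaluator.graft_end_arclength(limb)
            on_graft &= ~((region == limb) & (arcs > s_end))
    else:
        normals = _grid_gradient(sdf, cent)
        region = np.full(len(cent), "trunk")
        arcs = cent[:, 2].copy()
        side = np.ones(len(cent))
        on_graft = np.ones(len(cent), dtype=bool)
    return WallSurface(points=cent, normals=normals, areas=areas,
                       region=region, side=side, arclength=arcs,
                       on_graft=on_graft, triangles=faces, vertices=verts)


def _sdf_gradient(ev, points, eps):
    g = np.empty_like(points)
    for a in range(3):
        dp = np.zeros(3)
        dp[a] = eps
        g[:, a] = (ev(points + dp) - ev(points - dp)) / (2.0 * eps)
    n = np.linalg.norm(g, axis=1, keepdims=True)
    n[n == 0.0] = 1.0
    return g / n


def _grid_gradient(sdf: SignedDistanceField, points):
    from scipy.interpolate import RegularGridInterpolator

    axes = sdf.node_coords()
    grads = np.gradient(sdf.values, sdf.spacing, edge_order=1)
    g = np.empty_like(points)
    for a in range(3):
        it = RegularGridInterpolator(axes, grads[a], bounds_error=False,
                                     fill_value=None)
        g[:, a] = it(points)
    n = np.linalg.norm(g, axis=1, keepdims=True)
    n[n == 0.0] = 1.0
    return g / n


# ---------------------------------------------------------------------------
# outlet sections


@dataclass(frozen=True)
class OutletSection:
    """Lumen quadrature points on a limb outlet disc (meters)."""

    center: np.ndarray
    normal: np.ndarray
    points: np.ndarray
    weights: np.ndarray
    limb: str

    @property
    def area(self) -> float:
        return float(np.sum(self.weights))


def outlet_section(cfg: BSGConfig, limb: str, sdf=None,
                   n_rings: int = 12) -> OutletSection:
    """Quadrature over the outlet cross-section of one limb.

    The section is the disc of iliac radius centered on the limb centerline
    where it meets the distal plane, oriented normal to the limb tangent
    there (concentric-ring midpoint rule; weights sum to pi*R^2 exactly).
    """
    if limb not in ("left", "right", "left_iliac", "right_iliac"):
        raise GeometryError(f"unknown limb {limb!r}")
    key = limb if limb.endswith("_iliac") else limb + "_iliac"
    if sdf is not None and getattr(sdf, "evaluator", None) is not None:
        cl = sdf.evaluator.centerlines[key]
    else:
        trunk, left, right = build_centerlines(cfg)
        cl = {"left_iliac": left, "right_iliac": right}[key]
    z_end = cfg.total_length * MM
    i = int(np.argmin(np.abs(cl.points[:, 2] - z_end)))
    center, normal = cl.points[i], cl.tangents[i]
    R = cfg.iliac_diameter / 2.0 * MM
    if sdf is not None and getattr(sdf, "evaluator", None) is not None:
        if sdf.evaluator(center[None, :])[0] > 0.0:
            raise GeometryError("outlet plane misses the lumen")
    # orthonormal in-plane basis; e1 chosen deterministically
    e1 = np.cross(normal, [0.0, 1.0, 0.0])
    if np.linalg.norm(e1) < 1e-12:
        e1 = np.cross(normal, [1.0, 0.0, 0.0])
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(normal, e1)
    pts, wts = [], []
    dr = R / n_rings
    for j in range(n_rings):
        rj = (j + 0.5) * dr
        ring_area = np.pi * (((j + 1) * dr) ** 2 - (j * dr) ** 2)
        m = max(6, int(round(2.0 * np.pi * rj / dr)))
        ang = 2.0 * np.pi * (np.arange(m) + 0.5) / m
        pts.append(center[None, :] + rj * (np.outer(np.cos(ang), e1)
                                           + np.outer(np.sin(ang), e2)))
        wts.append(np.full(m, ring_area / m))
    return OutletSection(center=center, normal=normal,
                         points=np.vstack(pts), weights=np.concatenate(wts),
                         limb=key)


# ---------------------------------------------------------------------------
# analytic fixture geometries


def straight_tube_sdf(radius_m: float, origin, spacing_m: float, dims,
                      axis: int = 2) -> SignedDistanceField:
    """SDF of an infinite straight tube along one axis (fixture geometry)."""
    origin = np.asarray(origin, dtype=float)
    coords = np.meshgrid(*[origin[a] + spacing_m * np.arange(dims[a])
                           for a in range(3)], indexing="ij")
    trans = [coords[a] for a in range(3) if a != axis]
    vals = np.sqrt(trans[0] ** 2 + trans[1] ** 2) - radius_m

    def ev(points):
        pts = np.atleast_2d(points)
        tr = [pts[:, a] for a in range(3) if a != axis]
        return np.sqrt(tr[0] ** 2 + tr[1] ** 2) - radius_m

    return SignedDistanceField(origin=origin, spacing=spacing_m, values=vals,
                               evaluator=_FixtureEvaluator(ev))


def sphere_surface(radius_m: float, spacing_m: float) -> WallSurface:
    """Closed sphere wall surface (fluid inside), for force-closure tests."""
    n = 2 * int(math.ceil(1.3 * radius_m / spacing_m)) + 1
    origin = np.array([-(n - 1) / 2.0 * spacing_m] * 3)

    def ev(points):
        pts = np.atleast_2d(points)
        return np.linalg.norm(pts, axis=1) - radius_m

    xs = origin[0] + spacing_m * np.arange(n)
    X, Y, Z = np.meshgrid(xs, xs, xs, indexing="ij")
    vals = np.sqrt(X**2 + Y**2 + Z**2) - radius_m
    sdf = SignedDistanceField(origin=origin, spacing=spacing_m, values=vals,
                              evaluator=_FixtureEvaluator(ev))
    return extract_wall_surface(sdf)


class _FixtureEvaluator:
    """Wrap a plain callable so fixtures share the LumenSDF interface."""

    def __init__(self, fn, label: str = "trunk"):
        self._fn = fn
        self._label = label

    def __call__(self, points):
        return self._fn(points)

    def nearest_region(self, points):
        pts = np.atleast_2d(points)
        n = len(pts)
        return (np.full(n, self._label), pts[:, 2].copy(), np.ones(n))

    def graft_end_arclength(self, limb):
        return np.inf
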