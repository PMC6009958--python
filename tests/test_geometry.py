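"""Parametric crossed-limb geometry: centerlines, SDF, wall, sections."""

import math

import numpy as np
import pytest
from scipy import ndimage

from crosslimb.geometry import (BSGConfig, GeometryError, build_centerlines,
                                LumenSDF, sample_sdf, extract_wall_surface,
                                outlet_section, sphere_surface, default_grid)

MM = 1e-3

ANGLE_LEVELS = [30.0, 45.0, 60.0, 75.0, 90.0]
POSITION_LEVELS = [0.48, 0.72, 1.0, 1.4, 1.92]


def angle_cfg(a):
    return BSGConfig(cross_angle_deg=a, cross_length_mm=42.0)


def position_cfg(r):
    return BSGConfig(cross_angle_deg=None, cross_length_mm=None,
                     position_ratio=r, side_length_mm=41.0)


def measured_cross_angle(cfg):
    """Angle between limb tangent projections onto the symmetry plane at
    the cross point."""
    _, left, right = build_centerlines(cfg)
    zc = (cfg.trunk_length + cfg.l_mm) * MM
    tl = left.tangents[np.argmin(np.abs(left.points[:, 2] - zc))]
    tr = right.tangents[np.argmin(np.abs(right.points[:, 2] - zc))]
    pl = np.array([tl[0], 0.0, tl[2]])
    pr = np.array([tr[0], 0.0, tr[2]])
    c = np.dot(pl, pr) / (np.linalg.norm(pl) * np.linalg.norm(pr))
    return math.degrees(math.acos(np.clip(c, -1, 1)))


class TestConfig:
    def test_angle_series_ratio_near_unity(self):
        cfg = angle_cfg(60.0)
        assert cfg.l_mm == 42.0
        assert cfg.h_mm == pytest.approx(41.64)

    @pytest.mark.parametrize("r", POSITION_LEVELS)
    def test_position_series_reproduces_ratio(self, r):
        cfg = position_cfg(r)
        assert cfg.ratio == pytest.approx(r, rel=1e-2)
        assert 0.0 < cfg.alpha_deg < 180.0

    def test_ratio_one_means_equal_distances(self):
        cfg = BSGConfig(cross_angle_deg=60.0, cross_length_mm=None,
                        position_ratio=1.0)
        assert cfg.l_mm == pytest.approx(cfg.h_mm, rel=1e-9)

    def test_invalid_configs_rejected(self):
        with pytest.raises(GeometryError):
            BSGConfig(cross_angle_deg=200.0)
        with pytest.raises(GeometryError):
            BSGConfig(trunk_length=200.0)  # exceeds total length
        with pytest.raises(GeometryError):
            BSGConfig(cross_angle_deg=None, side_length_mm=None)

    def test_cross_point_outside_limb_span_rejected(self):
        cfg = BSGConfig(cross_angle_deg=60.0, cross_length_mm=100.0)
        with pytest.raises(GeometryError, match="cross point"):
            cfg.validate()


class TestCenterlines:
    @pytest.mark.parametrize("cfg", [angle_cfg(a) for a in ANGLE_LEVELS]
                             + [position_cfg(r) for r in POSITION_LEVELS],
                             ids=lambda c: f"a{c.alpha_deg:.0f}r{c.ratio:.2f}")
    def test_series_level_contracts(self, cfg):
        trunk, left, right = build_centerlines(cfg)
        # total axial extent equals the device length exactly
        allz = np.concatenate([c.points[:, 2] for c in (trunk, left, right)])
        assert (allz.max() - allz.min()) == pytest.approx(
            cfg.total_length * MM, rel=1e-12)
        # requested cross angle is realized at the crossing
        assert measured_cross_angle(cfg) == pytest.approx(cfg.alpha_deg,
                                                          abs=0.5)
        # mirror symmetry through the x-z plane up to the bump sign
        flip = left.points.copy()
        flip[:, 0] *= -1.0
        flip[:, 1] *= -1.0
        assert np.allclose(flip, right.points, atol=1e-12)
        # C1: no tangent kinks beyond tolerance
        assert left.max_tangent_kink_deg() < 2.0

    def test_trunk_is_straight_axial(self):
        trunk, _, _ = build_centerlines(angle_cfg(60.0))
        assert np.allclose(trunk.points[:, :2], 0.0)
        assert trunk.length == pytest.approx(71.0 * MM)

    def test_limb_clearance_at_crossing(self):
        cfg = angle_cfg(60.0)
        _, left, right = build_centerlines(cfg)
        zc = (cfg.trunk_length + cfg.l_mm) * MM
        sel = np.abs(left.points[:, 2] - zc) < 5 * MM
        from scipy.spatial import cKDTree
        d = cKDTree(right.points).query(left.points[sel])[0].min()
        gap = d / MM - cfg.iliac_diameter
        assert gap >= 0.98 * cfg.clearance_mm

    def test_arclength_strictly_increasing_unit_tangents(self):
        _, left, _ = build_centerlines(angle_cfg(30.0))
        assert np.all(np.diff(left.arclength) > 0)
        assert np.allclose(np.linalg.norm(left.tangents, axis=1), 1.0)


class TestSignedDistanceField:
    def test_trunk_axis_value_is_minus_radius(self):
        ev = LumenSDF(BSGConfig())
        val = ev(np.array([[0.0, 0.0, 35e-3]]))[0]
        # centerlines are sampled polylines, so the capsule distance is
        # accurate to about half the sampling step
        assert val == pytest.approx(-8.5 * MM, rel=3e-3)

    def test_limb_wall_is_zero_level(self):
        cfg = BSGConfig()
        ev = LumenSDF(cfg)
        # point on the left limb wall far from the bifurcation: centerline
        # point + radius along an in-plane normal
        cl = ev.centerlines["left_iliac"]
        i = np.argmin(np.abs(cl.points[:, 2] - 140e-3))
        t = cl.tangents[i]
        n = np.cross(t, [0.0, 1.0, 0.0])
        n /= np.linalg.norm(n)
        p = cl.points[i] + 5.0 * MM * n
        assert abs(ev(p[None, :])[0]) < 0.05 * MM

    def test_gradient_magnitude_near_unity(self):
        ev = LumenSDF(BSGConfig())
        rng = np.random.default_rng(7)
        pts = rng.uniform([-0.02, -0.01, 0.01], [0.02, 0.01, 0.15], (200, 3))
        eps = 1e-5
        g = np.zeros((200, 3))
        for a in range(3):
            d = np.zeros(3)
            d[a] = eps
            g[:, a] = (ev(pts + d) - ev(pts - d)) / (2 * eps)
        gn = np.linalg.norm(g, axis=1)
        # away from the medial axis / blend region the SDF is a distance
        near_wall = np.abs(ev(pts)) < 3 * MM
        assert np.all(np.abs(gn[near_wall] - 1.0) < 0.1)

    def test_coarse_spacing_refused(self):
        with pytest.raises(GeometryError, match="spacing"):
            sample_sdf(BSGConfig(), spacing_mm=6.0)

    def test_limb_lumens_disconnected_at_crossing(self):
        """Flood-fill oracle: voxelize a box around the cross point and
        verify the two limb lumens are separate components."""
        cfg = BSGConfig()
        ev = LumenSDF(cfg)
        zc = (cfg.trunk_length + cfg.l_mm) * MM
        h = 0.4 * MM
        half = 8 * MM
        ax = np.arange(-half, half + h / 2, h)
        az = zc + ax
        X, Y, Z = np.meshgrid(ax, ax, az, indexing="ij")
        pts = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])
        mask = (ev(pts) < 0).reshape(X.shape)
        lab, n = ndimage.label(mask)
        assert n >= 2  # left and right lumens are separate in this window
        # and the two largest components are both tube-sized
        sizes = np.sort(np.bincount(lab.ravel())[1:])[::-1]
        assert sizes[1] > 0.2 * sizes[0]

    def test_mirror_symmetry_of_field(self):
        ev = LumenSDF(BSGConfig())
        rng = np.random.default_rng(3)
        pts = rng.uniform([-0.03, -0.01, 0.0], [0.03, 0.01, 0.154], (100, 3))
        mirrored = pts * np.array([-1.0, -1.0, 1.0])
        assert np.allclose(ev(pts), ev(mirrored), atol=1e-10)


@pytest.fixture(scope="module")
def sdf():
    return sample_sdf(BSGConfig(), spacing_mm=1.4, extension_mm=0.0)


class TestWallSurface:

    def test_area_close_to_swept_tube_estimate(self, sdf):
        wall = extract_wall_surface(sdf)
        cfg = BSGConfig()
        trunk, left, right = build_centerlines(cfg)
        est = (2 * np.pi * 8.5 * MM * trunk.length
               + 2 * np.pi * 5 * MM * (left.length + right.length))
        assert wall.total_area == pytest.approx(est, rel=0.08)

    def test_every_sample_labeled_all_regions_present(self, sdf):
        wall = extract_wall_surface(sdf)
        for region in ("trunk", "left_iliac", "right_iliac"):
            assert np.sum(wall.region == region) > 0
        assert np.allclose(np.linalg.norm(wall.normals, axis=1), 1.0)

    def test_refinement_changes_area_little(self, sdf):
        fine = sample_sdf(BSGConfig(), spacing_mm=0.9, extension_mm=0.0)
        a0 = extract_wall_surface(sdf).total_area
        a1 = extract_wall_surface(fine).total_area
        assert abs(a1 - a0) / a1 < 0.02

    def test_cylinder_area_analytic(self):
        # degenerate single-tube config: straight tube fixture
        from crosslimb.validation import tube_fixture
        grid, sdf, _ = tube_fixture(16, 5e-3, nz=8)
        vals = sdf.evaluator(np.column_stack(
            [c.ravel() for c in np.meshgrid(
                *[grid.origin[a] + grid.spacing * np.arange(grid.dims[a] + 1)
                  for a in range(3)], indexing="ij")])).reshape(
            [d + 1 for d in grid.dims])
        from crosslimb.geometry import SignedDistanceField
        s = SignedDistanceField(origin=grid.origin, spacing=grid.spacing,
                                values=vals, evaluator=sdf.evaluator)
        wall = extract_wall_surface(s)
        L = (grid.dims[2]) * grid.spacing
        assert wall.total_area == pytest.approx(2 * np.pi * 5e-3 * L,
                                                rel=0.05)

    def test_sphere_closure(self):
        wall = sphere_surface(5e-3, 0.4e-3)
        # vector area of a closed surface vanishes
        va = np.sum(wall.normals * wall.areas[:, None], axis=0)
        assert np.linalg.norm(va) < 0.01 * np.pi * (5e-3) ** 2
        assert wall.total_area == pytest.approx(4 * np.pi * 25e-6, rel=0.02)


class TestOutletSection:
    def test_area_matches_iliac_lumen(self):
        cfg = BSGConfig()
        sec = outlet_section(cfg, "left")
        assert sec.area == pytest.approx(np.pi * 25e-6, rel=1e-12)
        assert np.linalg.norm(sec.normal) == pytest.approx(1.0)

    def test_left_right_congruent_under_reflection(self):
        cfg = BSGConfig()
        sl = outlet_section(cfg, "left")
        sr = outlet_section(cfg, "right")
        assert sl.center[0] == pytest.approx(-sr.center[0])
        assert sl.center[2] == pytest.approx(sr.center[2])
        assert sl.area == pytest.approx(sr.area)

    def test_unknown_limb_rejected(self):
        with pytest.raises(GeometryError):
            outlet_section(BSGConfig(), "middle")
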