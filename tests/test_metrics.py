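"""Hemodynamic metric kernels against closed-form oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from crosslimb.geometry import WallSurface, sphere_surface
from crosslimb.metrics import (WssHistory, helicity_density, tawss, osi, rrt,
                               area_weighted_mean, surface_force,
                               section_mean_helicity)
from crosslimb.waveforms import synthetic_wss_history, helical_fixture_field
from crosslimb.solver import GridSpec, FlowState


def history(pattern, samples=401, **kw):
    t, wss = synthetic_wss_history(pattern, samples=samples, **kw)
    return WssHistory(times=t, wss=wss[None, :, :],
                      excluded=np.zeros(1, bool))


class TestTawss:
    def test_constant_history(self):
        assert tawss(history("constant", magnitude=0.2))[0] == \
            pytest.approx(0.2, abs=1e-14)

    def test_rectified_sine_mean(self):
        # |sin| averages to 2/pi over the cycle
        h = history("reversing", samples=2001, magnitude=0.3)
        assert tawss(h)[0] == pytest.approx(0.3 * 2 / np.pi, rel=1e-5)

    def test_zero_history(self):
        h = history("constant", magnitude=0.0)
        assert tawss(h)[0] == 0.0

    def test_single_step_rejected(self):
        h = history("constant")
        bad = WssHistory(times=h.times[:1], wss=h.wss[:, :1],
                         excluded=h.excluded)
        with pytest.raises(ValueError):
            tawss(bad)


class TestOsi:
    def test_constant_direction_is_zero(self):
        o, fl = osi(history("constant"))
        assert o[0] == pytest.approx(0.0, abs=1e-12) and not fl[0]

    def test_reversing_approaches_half(self):
        o, _ = osi(history("reversing", samples=4001))
        assert o[0] == pytest.approx(0.5, abs=1e-6)

    def test_partial_ratio_half_gives_quarter(self):
        o, _ = osi(history("partial", samples=4001, ratio=0.5))
        assert o[0] == pytest.approx(0.25, abs=1e-4)

    def test_never_loaded_sample_flagged(self):
        o, fl = osi(history("constant", magnitude=0.0))
        assert o[0] == 0.0 and fl[0]

    @given(st.floats(min_value=0.02, max_value=0.98))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_osi_tracks_prescribed_ratio(self, ratio):
        o, _ = osi(history("partial", samples=2001, ratio=ratio))
        assert o[0] == pytest.approx(0.5 * (1 - ratio), abs=1e-3)


class TestRrt:
    def test_arithmetic_value(self):
        val, fl = rrt(0.2, 0.0)
        assert val == pytest.approx(5.0) and not fl

    def test_reported_iliac_means_value(self):
        # direct arithmetic on representative area-mean TAWSS/OSI values
        val, _ = rrt(0.128, 0.145)
        assert val == pytest.approx(11.00, abs=0.01)

    def test_pole_flagged_infinite(self):
        val, fl = rrt(0.2, 0.5)
        assert np.isinf(val) and fl

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            rrt(-0.1, 0.0)
        with pytest.raises(ValueError):
            rrt(0.1, 0.7)

    @given(st.floats(min_value=1e-3, max_value=10.0),
           st.floats(min_value=0.0, max_value=0.49))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_identity(self, ta, os_):
        val, fl = rrt(ta, os_)
        assert not fl
        assert val * (1.0 - 2.0 * os_) * ta == pytest.approx(1.0, rel=1e-12)


class TestHelicity:
    def grid_field(self, fn, n=16, h=0.05):
        x = (np.arange(n) + 0.5) * h - n * h / 2
        X, Y, Z = np.meshgrid(x, x, x, indexing="ij")
        u, v, w = fn(X, Y, Z)
        return (u, v, w), h

    def test_solid_body_helix(self):
        (u, v, w), h = self.grid_field(
            lambda X, Y, Z: (-Y, X, np.ones_like(X)))
        H = helicity_density(u, v, w, h)
        assert np.allclose(H[2:-2, 2:-2, 2:-2], 2.0, atol=1e-10)

    def test_left_handed_sign(self):
        (u, v, w), h = self.grid_field(
            lambda X, Y, Z: (-Y, X, -np.ones_like(X)))
        H = helicity_density(u, v, w, h)
        assert np.allclose(H[2:-2, 2:-2, 2:-2], -2.0, atol=1e-10)

    def test_swirl_free_axisymmetric_flow_zero(self):
        (u, v, w), h = self.grid_field(
            lambda X, Y, Z: (np.zeros_like(X), np.zeros_like(X),
                             1.0 - (X**2 + Y**2)))
        H = helicity_density(u, v, w, h)
        assert np.max(np.abs(H[1:-1, 1:-1, 1:-1])) < 1e-10

    def test_mirror_reflection_negates_pointwise(self):
        (u, v, w), h = self.grid_field(
            lambda X, Y, Z: (np.sin(Y) - Z, X * Z, np.cos(X * Y)))
        H = helicity_density(u, v, w, h)
        # reflect through the y=0 plane: y -> -y flips v and the y axis
        Hm = helicity_density(u[:, ::-1], -v[:, ::-1], w[:, ::-1], h)
        assert np.allclose(Hm, -H[:, ::-1], atol=1e-10)

    def test_velocity_scaling_is_quadratic(self):
        (u, v, w), h = self.grid_field(
            lambda X, Y, Z: (-Y, X, np.ones_like(X)))
        H1 = helicity_density(u, v, w, h)
        H3 = helicity_density(3 * u, 3 * v, 3 * w, h)
        assert np.allclose(H3, 9.0 * H1, atol=1e-9)


class TestSectionHelicity:
    def make_state(self, fn, n=24, h=1e-3):
        grid = GridSpec(origin=np.array([-n * h / 2, -n * h / 2, 0.0]),
                        spacing=h, dims=(n, n, 8))
        xs = grid.cell_centers_1d()
        X, Y, Z = np.meshgrid(*xs, indexing="ij")
        u, v, w = fn(X, Y, Z)

        def faces(cc, axis):
            pad = [(0, 0)] * 3
            pad[axis] = (1, 1)
            p = np.pad(cc, pad, mode="edge")
            sl0 = [slice(None)] * 3
            sl0[axis] = slice(None, -1)
            sl1 = [slice(None)] * 3
            sl1[axis] = slice(1, None)
            return 0.5 * (p[tuple(sl0)] + p[tuple(sl1)])

        state = FlowState(faces(u, 0), faces(v, 1), faces(w, 2),
                          np.zeros_like(u))
        return state, grid

    def section(self, grid, radius=8e-3):
        from crosslimb.geometry import OutletSection
        n_r = 10
        pts, wts = [], []
        dr = radius / n_r
        for j in range(n_r):
            rj = (j + 0.5) * dr
            m = max(6, int(round(2 * np.pi * rj / dr)))
            ang = 2 * np.pi * (np.arange(m) + 0.5) / m
            ring = np.pi * (((j + 1) * dr) ** 2 - (j * dr) ** 2)
            pts.append(np.column_stack([rj * np.cos(ang), rj * np.sin(ang),
                                        np.full(m, 4e-3)]))
            wts.append(np.full(m, ring / m))
        return OutletSection(center=np.array([0, 0, 4e-3]),
                             normal=np.array([0, 0, 1.0]),
                             points=np.vstack(pts),
                             weights=np.concatenate(wts), limb="left_iliac")

    def test_helical_core_value(self):
        state, grid = self.make_state(
            lambda X, Y, Z: (-Y, X, np.ones_like(X)))
        signed, unsigned = section_mean_helicity(state, grid,
                                                 self.section(grid))
        assert signed == pytest.approx(2.0, rel=0.05)
        assert unsigned == pytest.approx(2.0, rel=0.05)

    def test_counter_rotating_pair_cancels_signed_only(self):
        # right-handed swirl for x > 0, left-handed for x < 0: the signed
        # section mean cancels while the unsigned variant does not,
        # distinguishing |<H_d>| from <|H_d|>
        def fn(X, Y, Z):
            s = np.sign(X)
            return (-Y * s, np.abs(X), np.ones_like(X))

        state, grid = self.make_state(fn)
        signed, unsigned = section_mean_helicity(state, grid,
                                                 self.section(grid))
        assert abs(signed) < 0.15 * unsigned
        assert unsigned > 0.5


class TestAreaMean:
    def wall(self, n=10):
        pts = np.random.default_rng(0).uniform(size=(n, 3))
        return WallSurface(points=pts, normals=np.tile([1.0, 0, 0], (n, 1)),
                           areas=np.ones(n), region=np.array(
                               ["left_iliac"] * (n // 2)
                               + ["right_iliac"] * (n - n // 2)),
                           side=np.ones(n), arclength=np.zeros(n),
                           on_graft=np.ones(n, bool))

    def test_uniform_field(self):
        w = self.wall()
        assert area_weighted_mean(np.full(10, 3.3), w) == pytest.approx(3.3)

    def test_checkerboard_cancels(self):
        w = self.wall()
        vals = np.resize([1.0, -1.0], 10)
        assert area_weighted_mean(vals, w) == pytest.approx(0.0, abs=1e-14)

    def test_empty_selection_rejected(self):
        w = self.wall()
        with pytest.raises(ValueError):
            area_weighted_mean(np.ones(10), w, regions=["trunk"])


class TestSurfaceForce:
    def test_uniform_pressure_on_closed_sphere_cancels(self):
        wall = sphere_surface(5e-3, 0.4e-3)
        p0 = 13300.0
        F = surface_force(np.full(len(wall), p0), np.zeros((len(wall), 3)),
                          wall)
        assert np.linalg.norm(F) < 0.01 * p0 * np.pi * (5e-3) ** 2

    def test_pressure_scaling_linearity(self):
        wall = sphere_surface(5e-3, 0.6e-3)
        # truncate to a hemisphere so the net force is nonzero
        mask = wall.points[:, 2] > 0
        p = np.full(len(wall), 100.0)
        F1 = surface_force(p, np.zeros((len(wall), 3)), wall, mask)
        F3 = surface_force(3 * p, np.zeros((len(wall), 3)), wall, mask)
        assert np.allclose(F3, 3 * F1, rtol=1e-12)
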