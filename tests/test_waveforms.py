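"""Synthetic waveforms and analytic fixture fields."""

import numpy as np
import pytest
from scipy import integrate

from crosslimb.waveforms import (make_inlet_waveform, make_pressure_waveform,
                                 womersley_field, helical_fixture_field,
                                 synthetic_wss_history)


class TestInletWaveform:
    def test_zero_pulsatility_is_constant(self):
        wf = make_inlet_waveform(0.044, 0.0, 0.1, 1.0)
        t = np.linspace(0, 2, 50)
        assert np.allclose(wf(t), 0.044)

    def test_exact_mean_and_peak_location(self):
        wf = make_inlet_waveform(0.044, 4.0, 0.1, 1.0)
        mean, _ = integrate.quad(wf, 0.0, 1.0, limit=400)
        assert mean == pytest.approx(0.044, rel=1e-8)
        t = np.linspace(0, 1, 4001)
        assert t[np.argmax(wf(t))] == pytest.approx(0.1, abs=1.0 / 4000)

    def test_periodicity_exact(self):
        wf = make_inlet_waveform(0.044, 4.0, 0.1, 1.0)
        for t in (0.0, 0.123, 0.77):
            assert wf(t) == pytest.approx(wf(t + 1.0), abs=1e-14)

    def test_nonnegative_by_default(self):
        wf = make_inlet_waveform(0.044, 4.0, 0.1, 1.0)
        assert np.min(wf(np.linspace(0, 1, 4001))) >= 0.0

    def test_excessive_pulsatility_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            make_inlet_waveform(0.044, 40.0, 0.1, 1.0)

    def test_determinism(self):
        a = make_inlet_waveform(0.044, 4.0, 0.1, 1.0)
        b = make_inlet_waveform(0.044, 4.0, 0.1, 1.0)
        t = np.linspace(0, 1, 100)
        assert np.array_equal(a(t), b(t))


class TestPressureWaveform:
    def test_constant_outlet_pressure(self):
        wf = make_pressure_waveform(13300.0, 0.0)
        assert wf(0.42) == 13300.0

    def test_exact_mean_with_pulse(self):
        wf = make_pressure_waveform(13300.0, 2700.0, 0.1, 1.0)
        mean, _ = integrate.quad(wf, 0.0, 1.0, limit=400)
        assert mean == pytest.approx(13300.0, rel=1e-8)
        t = np.linspace(0, 1, 4001)
        assert t[np.argmax(wf(t))] == pytest.approx(0.1, abs=1.0 / 4000)

    def test_negative_mean_rejected(self):
        with pytest.raises(ValueError):
            make_pressure_waveform(-10.0, 0.0)


class TestWomersleyField:
    def test_low_frequency_approaches_quasi_steady_poiseuille(self):
        R, eta, rho, G = 5e-3, 5.6e-2, 1050.0, 100.0
        f = womersley_field(R, eta, rho, G, frequency=1e-3)
        assert f.extras["womersley_number"] < 0.3
        r = np.linspace(0, R * 0.99, 30)
        # at t=0 the gradient is maximal: compare to steady Poiseuille
        num = f.extras["axial_velocity"](r, 0.0)
        ref = G / (4 * eta) * (R**2 - r**2)
        assert np.max(np.abs(num - ref)) / np.max(ref) < 0.01

    def test_high_womersley_centerline_lags_ninety_degrees(self):
        R, eta, rho = 5e-3, 3.45e-3, 1050.0
        nu = eta / rho
        # alpha = 10 -> omega = (10/R)^2 nu
        omega = (10.0 / R) ** 2 * nu
        f = womersley_field(R, eta, rho, 1.0, omega / (2 * np.pi))
        assert f.extras["womersley_number"] == pytest.approx(10.0, rel=1e-12)
        W0 = f.extras["profile_complex"](0.0)
        # pressure gradient phase is 0 (cosine); velocity lags ~90 deg
        lag = -np.degrees(np.angle(W0))
        assert lag == pytest.approx(90.0, abs=5.0)

    def test_axisymmetry(self):
        f = womersley_field(5e-3, 3.45e-3, 1050.0, 100.0, 1.0)
        pts = np.array([[3e-3, 0, 0], [0, 3e-3, 0],
                        [3e-3 / np.sqrt(2), 3e-3 / np.sqrt(2), 0.0]])
        v = f.velocity(pts, 0.3)[:, 2]
        assert np.allclose(v, v[0])

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            womersley_field(0.0, 1e-3, 1000.0, 1.0, 1.0)


class TestHelicalFixture:
    @pytest.mark.parametrize("Om,w0,expected", [
        (1.0, 1.0, 2.0), (1.0, -1.0, -2.0), (0.0, 3.0, 0.0)])
    def test_helicity_density_value(self, Om, w0, expected):
        f = helical_fixture_field(Om, w0)
        assert f.extras["helicity_density"] == expected


class TestSyntheticWssHistory:
    def test_constant_pattern(self):
        t, wss = synthetic_wss_history("constant", 0.2, samples=11)
        assert wss.shape == (11, 3)
        assert np.allclose(np.linalg.norm(wss, axis=1), 0.2)

    def test_reversing_pattern_zero_mean(self):
        t, wss = synthetic_wss_history("reversing", 0.3, samples=401)
        assert np.abs(np.trapezoid(wss[:, 0], t)) < 1e-10

    def test_partial_ratio_contract(self):
        t, wss = synthetic_wss_history("partial", 0.2, samples=2001,
                                       ratio=0.5)
        num = np.abs(np.trapezoid(wss[:, 0], t))
        den = np.trapezoid(np.abs(wss[:, 0]), t)
        assert num / den == pytest.approx(0.5, abs=2e-4)

    def test_unknown_pattern(self):
        with pytest.raises(ValueError):
            synthetic_wss_history("wiggle", 0.1)
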