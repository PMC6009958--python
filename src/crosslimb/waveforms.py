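"""Synthetic boundary waveforms and analytic verification flow fields.

The pulsatile boundary conditions of the study are a flat (plug) inlet
velocity waveform with a prescribed cycle mean and a pressure waveform at
the outlets anchored to a prescribed cycle-mean pressure.  The exact curve
shapes are not tabulated anywhere, so this module builds parametric
stand-ins: smooth single-systolic-peak pulses represented as truncated
Fourier series with the cycle mean enforced exactly by construction.  The
printed anchors honoured by the defaults are: inlet mean velocity
0.044 m/s, outlet mean pressure 13 300 Pa, period T = 1.0 s, systolic peak
near t = 0.1 s.

The module also provides closed-form flow fields (Womersley oscillatory
tube flow, solid-body helical flow) and synthetic wall-shear histories
used as independent oracles for the solver and metric modules.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy import integrate, optimize, special

__all__ = [
    "Waveform",
    "make_inlet_waveform",
    "make_pressure_waveform",
    "AnalyticField",
    "womersley_field",
    "helical_fixture_field",
    "synthetic_wss_history",
]


@dataclass(frozen=True)
class Waveform:
    """Periodic scalar function of time as a truncated Fourier series.

    evaluate(t) = mean + sum_k 2*Re(c_k * exp(2j*pi*k*t/T)); the cycle
    average equals ``mean`` exactly because the k = 0 coefficient is stored
    separately and never touched by shaping.
    """

    period: float
    mean: float
    coeffs: np.ndarray = field(default_factory=lambda: np.zeros(0, complex))

    def __post_init__(self) -> None:
        if self.period <= 0.0:
            raise ValueError("period must be positive")
        object.__setattr__(self, "coeffs", np.asarray(self.coeffs, dtype=complex))

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        out = np.full(t.shape, self.mean)
        for k, ck in enumerate(self.coeffs, start=1):
            out = out + 2.0 * np.real(ck * np.exp(2j * np.pi * k * t / self.period))
        return out if out.ndim else float(out)

    evaluate = __call__

    def samples(self, n: int):
        """n uniform samples over one period, endpoints 0 and T inclusive."""
        t = np.linspace(0.0, self.period, n)
        return t, self(t)

    def to_csv(self, path, n: int = 201) -> None:
        t, v = self.samples(n)
        np.savetxt(path, np.column_stack([t, v]), delimiter=",",
                   header="t,value", comments="", fmt="%.17g")


def _pulse_coeffs(T: float, peak_time: float, kappa: float, n_harmonics: int):
    """Fourier coefficients (k >= 1) of a von-Mises-style periodic pulse
    exp(kappa*(cos(2*pi*(t - peak_time)/T) - 1)), peak-to-peak normalized.

    The pulse is even about the peak, so truncation keeps the maximum at
    ``peak_time`` exactly.
    """
    ks = np.arange(1, n_harmonics + 1)
    # Fourier coefficients of exp(kappa*cos(x)) are I_k(kappa); the exp(-kappa)
    # factor cancels in the normalization below.
    ck = special.ive(ks, kappa) / special.ive(0, kappa)
    # peak-to-peak of the truncated series evaluated densely
    x = np.linspace(0.0, 2.0 * np.pi, 4096, endpoint=False)
    shape = np.zeros_like(x)
    for k, c in zip(ks, ck):
        shape += 2.0 * c * np.cos(k * x)
    ptp = shape.max() - shape.min()
    phase = np.exp(-2j * np.pi * ks * peak_time / T)
    return (ck / ptp) * phase, shape.min() / ptp


def make_inlet_waveform(
    mean_velocity: float = 0.044,
    pulsatility_index: float = 4.0,
    peak_time: float = 0.1,
    T: float = 1.0,
    n_harmonics: int = 8,
    pulse_width: float = 20.0,
) -> Waveform:
    """Plug inlet-velocity waveform with exact cycle mean.

    ``pulsatility_index`` is (max - min)/mean; zero gives the constant
    steady inflow.  The single systolic peak sits at ``peak_time``.  The
    default index of 4 gives a rest-state aortic-like pulse (peak roughly
    4.7x the mean, weak diastolic flow); it is a documented stand-in, not a
    measured curve.  Raises if the requested pulsatility would drive the
    inlet velocity negative.
    """
    if mean_velocity <= 0.0:
        raise ValueError("mean_velocity must be positive")
    if not 0.0 < peak_time < T:
        raise ValueError("peak_time must lie inside (0, T)")
    if pulsatility_index < 0.0:
        raise ValueError("pulsatility_index must be >= 0")
    if pulsatility_index == 0.0:
        return Waveform(T, mean_velocity)
    if n_harmonics < 4:
        raise ValueError("need at least 4 harmonics for the systolic pulse")
    coeffs, shape_min = _pulse_coeffs(T, peak_time, pulse_width, n_harmonics)
    amp = pulsatility_index * mean_velocity
    vmin = mean_velocity + amp * shape_min
    if vmin < 0.0:
        raise ValueError(
            f"pulsatility_index {pulsatility_index} drives the inlet velocity "
            f"negative (min {vmin:.4g} m/s); reduce it below "
            f"{-mean_velocity / (amp * shape_min / pulsatility_index):.3g}"
        )
    return Waveform(T, mean_velocity, amp * coeffs)


def make_pressure_waveform(
    mean_pressure: float = 13300.0,
    pulse_amplitude: float = 5320.0,
    peak_time: float = 0.1,
    T: float = 1.0,
    n_harmonics: int = 8,
    pulse_width: float = 6.0,
) -> Waveform:
    """Outlet pressure waveform with exact cycle mean.

    ``pulse_amplitude`` is the peak-to-peak excursion in Pa; zero recovers
    the constant steady outlet pressure.  The default mean of 13 300 Pa is
    100 mmHg; the default 5 320 Pa pulse is a 40 mmHg pulse pressure
    (~120/80 mmHg), a documented stand-in.
    """
    if mean_pressure < 0.0:
        raise ValueError("mean_pressure must be non-negative")
    if pulse_amplitude < 0.0:
        raise ValueError("pulse_amplitude must be >= 0")
    if pulse_amplitude == 0.0:
        return Waveform(T, mean_pressure)
    coeffs, _ = _pulse_coeffs(T, peak_time, pulse_width, n_harmonics)
    return Waveform(T, mean_pressure, pulse_amplitude * coeffs)


@dataclass(frozen=True)
class AnalyticField:
    """Closed-form velocity (and optional pressure) field used as an oracle.

    ``velocity(points, t)`` takes an (n, 3) array of positions in meters and
    a time and returns an (n, 3) velocity array.  Extra fixture-specific
    callables are carried in ``extras``.
    """

    velocity: Callable
    domain: str
    pressure: Callable | None = None
    extras: dict = field(default_factory=dict)


def womersley_field(
    tube_radius: float,
    viscosity: float,
    rho: float,
    grad_amplitude: float,
    frequency: float,
) -> AnalyticField:
    """Oscillatory laminar tube flow driven by -dp/dz = G*cos(omega*t).

    Axial velocity  w(r, t) = Re[W(r) e^{i omega t}] with
    W(r) = (G / (i rho omega)) * (1 - J0(beta r)/J0(beta R)),
    beta^2 = -i omega / nu.  The wall shear the fluid exerts on the wall,
    in the flow direction, is tau(t) = Re[-eta W'(R) e^{i omega t}].

    extras: ``axial_velocity(r, t)``, ``wall_shear(t)``,
    ``wall_shear_complex`` (complex amplitude), ``womersley_number``.
    """
    if tube_radius <= 0.0 or viscosity <= 0.0 or rho <= 0.0:
        raise ValueError("radius, viscosity and density must be positive")
    if frequency <= 0.0:
        raise ValueError("frequency must be positive")
    R = tube_radius
    nu = viscosity / rho
    omega = 2.0 * np.pi * frequency
    G = grad_amplitude
    beta = np.sqrt(-1j * omega / nu)
    j0R = special.jv(0, beta * R)

    def W(r):
        return (G / (1j * rho * omega)) * (1.0 - special.jv(0, beta * np.asarray(r)) / j0R)

    # W'(r) = (G/(i rho omega)) * beta * J1(beta r) / J0(beta R)
    dWdr_R = (G / (1j * rho * omega)) * beta * special.jv(1, beta * R) / j0R
    tau_c = -viscosity * dWdr_R

    def axial_velocity(r, t):
        return np.real(W(r) * np.exp(1j * omega * t))

    def wall_shear(t):
        return np.real(tau_c * np.exp(1j * omega * np.asarray(t)))

    def velocity(points, t):
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        r = np.hypot(pts[:, 0], pts[:, 1])
        out = np.zeros_like(pts)
        inside = r <= R
        out[inside, 2] = axial_velocity(r[inside], t)
        return out

    alpha = R * np.sqrt(omega / nu)
    return AnalyticField(
        velocity=velocity,
        domain=f"tube r<={R}",
        extras={
            "axial_velocity": axial_velocity,
            "wall_shear": wall_shear,
            "wall_shear_complex": tau_c,
            "profile_complex": W,
            "womersley_number": alpha,
            "omega": omega,
        },
    )


def helical_fixture_field(Omega: float, w0: float) -> AnalyticField:
    """Solid-body rotation plus uniform axial flow: u = (-Om*y, Om*x, w0).

    curl u = (0, 0, 2*Om), so the helicity density is 2*Om*w0 everywhere;
    positive for a right-handed helix.
    """

    def velocity(points, t=0.0):
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        out = np.empty_like(pts)
        out[:, 0] = -Omega * pts[:, 1]
        out[:, 1] = Omega * pts[:, 0]
        out[:, 2] = w0
        return out

    return AnalyticField(
        velocity=velocity,
        domain="box",
        extras={"helicity_density": 2.0 * Omega * w0},
    )


def _partial_offset(ratio: float) -> float:
    """Offset c such that |mean(c + sin)| / mean|c + sin| = ratio."""

    def f(c):
        val, _ = integrate.quad(
            lambda x: abs(c + np.sin(x)), 0.0, 2.0 * np.pi, limit=200
        )
        return c / (val / (2.0 * np.pi)) - ratio

    return optimize.brentq(f, 0.0, 50.0, xtol=1e-14, rtol=1e-15)


def synthetic_wss_history(
    pattern: str,
    magnitude: float = 0.2,
    T: float = 1.0,
    samples: int = 201,
    ratio: float = 0.5,
    direction=(1.0, 0.0, 0.0),
):
    """Synthetic single-sample WSS-vector time series for metric oracles.

    patterns
    --------
    constant  : fixed vector of the given magnitude (OSI = 0).
    reversing : magnitude*sin(2*pi*t/T) along one direction (zero-mean,
                OSI -> 0.5 under refinement).
    partial   : magnitude*(c + sin(2*pi*t/T)) along one direction with c
                chosen so |int WSS| / int |WSS| equals ``ratio``, hence
                OSI = (1 - ratio)/2.

    Returns (times, wss) with times of length ``samples`` spanning [0, T]
    inclusive and wss of shape (samples, 3).
    """
    if samples < 2:
        raise ValueError("need at least 2 samples")
    e = np.asarray(direction, dtype=float)
    e = e / np.linalg.norm(e)
    t = np.linspace(0.0, T, samples)
    if pattern == "constant":
        scal = np.full(samples, magnitude)
    elif pattern == "reversing":
        scal = magnitude * np.sin(2.0 * np.pi * t / T)
    elif pattern == "partial":
        c = _partial_offset(ratio)
        scal = magnitude * (c + np.sin(2.0 * np.pi * t / T))
    else:
        raise ValueError(f"unknown pattern {pattern!r}")
    return t, scal[:, None] * e[None, :]
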