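"""Parametric sweep pipeline over cross angle and cross position series.

The two study series are the five-level cross-angle sweep
(alpha in {30, 45, 60, 75, 90} deg at fixed l = 42 mm) and the five-level
cross-position sweep (r = l/h in {0.48, 0.72, 1, 1.4, 1.92} at fixed limb
side parameter g = 41 mm).  Every level runs the same protocol: build the
geometry, converge a steady solution, use it to initialize a multi-cycle
pulsatile solve, and reduce the final cycle to the hemodynamic indicators.

Resolution tiers trade fidelity for runtime; ``desk`` is the full
verification tier (24 cells per iliac diameter, 3 cycles), while ``test``
and ``smoke`` are coarse surrogates sized so a sweep fits in an automated
test run on one CPU.  Trend conclusions (monotone behaviour of outlet
helicity and displacement force across the series) are evaluated by
``trend_report``; exact field values at coarse tiers are not meaningful.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats

from .geometry import (BSGConfig, GeometryError, sample_sdf,
                       extract_wall_surface, outlet_section, default_grid)
from .rheology import RheologyParams
from .waveforms import make_inlet_waveform, make_pressure_waveform
from .solver import (GridSpec, IBSolver, BoundaryConditions, solve_steady,
                     solve_pulsatile, SolverError)
from .metrics import MetricsAccumulator, MetricsTable

__all__ = [
    "TIERS",
    "SweepPlan",
    "TrendReport",
    "angle_series_config",
    "position_series_config",
    "build_case",
    "run_case",
    "run_sweep",
    "trend_report",
]

ANGLE_LEVELS = (30.0, 45.0, 60.0, 75.0, 90.0)
POSITION_LEVELS = (0.48, 0.72, 1.0, 1.4, 1.92)

#: resolution tiers: grid spacing (mm), retained steps per cycle, cycles,
#: steady tolerance / iteration cap.  ``desk`` mirrors the full protocol at
#: 24 cells per iliac diameter; the coarse tiers are scaled-down surrogates.
TIERS = {
    "smoke": dict(spacing_mm=2.0, steps_per_cycle=40, n_cycles=2,
                  steady_tol=2e-3, steady_max_iter=250, wall_stride=2),
    "test": dict(spacing_mm=1.4, steps_per_cycle=40, n_cycles=2,
                 steady_tol=1e-3, steady_max_iter=500, wall_stride=2),
    "desk": dict(spacing_mm=10.0 / 24.0, steps_per_cycle=40, n_cycles=3,
                 steady_tol=1e-5, steady_max_iter=20000, wall_stride=1),
}


def angle_series_config(alpha_deg: float, l_mm: float = 42.0) -> BSGConfig:
    """Cross-angle series member: alpha varies, l fixed at 42 mm."""
    return BSGConfig(cross_angle_deg=alpha_deg, cross_length_mm=l_mm,
                     position_ratio=None, side_length_mm=None)


def position_series_config(ratio: float, g_mm: float = 41.0) -> BSGConfig:
    """Cross-position series member: r = l/h varies, g fixed at 41 mm."""
    return BSGConfig(cross_angle_deg=None, cross_length_mm=None,
                     position_ratio=ratio, side_length_mm=g_mm)


@dataclass(frozen=True)
class SweepPlan:
    """One sweep series at one resolution tier."""

    series: str = "angle"
    levels: tuple = ()
    tier: str = "test"
    fixed_l_mm: float = 42.0
    fixed_g_mm: float = 41.0
    inlet_mean: float = 0.044
    pulsatility_index: float = 4.0
    outlet_mean_pressure: float = 13300.0
    pulse_amplitude: float = 5320.0
    peak_time: float = 0.1
    period: float = 1.0
    extension_mm: float = 20.0
    overrides: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.series not in ("angle", "position"):
            raise ValueError("series must be 'angle' or 'position'")
        levels = self.levels or (ANGLE_LEVELS if self.series == "angle"
                                 else POSITION_LEVELS)
        levels = tuple(float(x) for x in levels)
        if len(levels) < 2 or np.any(np.diff(levels) <= 0):
            raise ValueError("levels must be >= 2 and strictly increasing")
        object.__setattr__(self, "levels", levels)
        if self.tier not in TIERS:
            raise ValueError(f"unknown tier {self.tier!r}")

    @property
    def params(self) -> dict:
        p = dict(TIERS[self.tier])
        p.update(self.overrides)
        return p

    def config_for(self, level: float) -> BSGConfig:
        if self.series == "angle":
            return angle_series_config(level, self.fixed_l_mm)
        return position_series_config(level, self.fixed_g_mm)


def build_case(cfg: BSGConfig, spacing_mm: float, extension_mm: float = 20.0):
    """Geometry artifacts for one solver run: SDF, wall, grid, section."""
    sdf = sample_sdf(cfg, spacing_mm=spacing_mm, extension_mm=extension_mm)
    wall = extract_wall_surface(sdf)
    node_dims = sdf.values.shape
    grid = GridSpec(origin=sdf.origin, spacing=sdf.spacing,
                    dims=tuple(n - 1 for n in node_dims))
    section = outlet_section(cfg, "left", sdf)
    return dict(cfg=cfg, sdf=sdf, wall=wall, grid=grid, section=section)


def run_case(cfg: BSGConfig, plan: SweepPlan,
             rheology: RheologyParams | None = None) -> MetricsTable:
    """Steady-init pulsatile run of one configuration, reduced to metrics."""
    rheology = rheology or RheologyParams()
    p = plan.params
    case = build_case(cfg, p["spacing_mm"], plan.extension_mm)
    inlet = make_inlet_waveform(plan.inlet_mean, plan.pulsatility_index,
                                plan.peak_time, plan.period)
    outlet = make_pressure_waveform(plan.outlet_mean_pressure,
                                    plan.pulse_amplitude, plan.peak_time,
                                    plan.period)
    bc_steady = BoundaryConditions(inlet=plan.inlet_mean,
                                   outlet_pressure=plan.outlet_mean_pressure)
    solver = IBSolver(case["grid"], case["sdf"], rheology, bc_steady)
    steady, hist = solve_steady(solver, tol=p["steady_tol"],
                                max_iter=p["steady_max_iter"], strict=False)
    solver.bc = BoundaryConditions(inlet=inlet, outlet_pressure=outlet)
    acc = MetricsAccumulator(case["grid"], case["wall"], rheology,
                             case["section"],
                             sdf_evaluator=case["sdf"].evaluator,
                             wall_stride=p.get("wall_stride", 1),
                             config={"series": plan.series,
                                     "alpha_deg": cfg.alpha_deg,
                                     "ratio": cfg.ratio,
                                     "l_mm": cfg.l_mm,
                                     "g_mm": cfg.outlet_separation_mm})
    result = solve_pulsatile(solver, steps_per_cycle=p["steps_per_cycle"],
                             n_cycles=p["n_cycles"], init=steady,
                             period=plan.period, snapshot_hook=acc,
                             keep_snapshots=False)
    flux_in = solver.inlet_flux(steady)
    table_times = np.asarray(acc.times)
    fmag = np.linalg.norm(np.vstack(acc._forces), axis=1)
    t_peak_force = float(table_times[int(np.argmax(fmag))]
                         % plan.period)
    diag = {
        # diagnostic: the force maximum is expected at peak outlet pressure
        "force_peak_time": t_peak_force,
        "pressure_peak_time": plan.peak_time,
        "steady_residual": float(hist["residuals"][-1]),
        "steady_iterations": hist["iterations"],
        "periodicity": float(result.periodicity[-1])
        if len(result.periodicity) else math.nan,
        "mass_error": abs(solver.outlet_flux(steady) - flux_in)
        / abs(flux_in),
        "flux_left": solver.outlet_flux(steady, "left"),
        "flux_right": solver.outlet_flux(steady, "right"),
        "max_divergence": solver.last_divergence,
    }
    return acc.finalize(diagnostics=diag)


def run_sweep(plan: SweepPlan, rheology: RheologyParams | None = None,
              progress=None):
    """Run every level of a sweep plan.

    Returns (rows, tables): ``rows`` is a list of flat dicts (one per
    level, failed levels carry an ``error`` entry), ``tables`` maps level
    to the full MetricsTable.  A single failed level does not abort the
    sweep; if every level fails a SolverError is raised.
    """
    rows, tables = [], {}
    for level in plan.levels:
        try:
            cfg = plan.config_for(level)
            table = run_case(cfg, plan, rheology)
            row = {"level": level, **table.to_row()}
            tables[level] = table
        except (GeometryError, SolverError, ValueError) as exc:
            row = {"level": level, "error": str(exc)}
        rows.append(row)
        if progress is not None:
            progress(row)
    if not tables:
        raise SolverError("all sweep levels failed: "
                          + "; ".join(str(r.get("error")) for r in rows))
    return rows, tables


@dataclass(frozen=True)
class TrendReport:
    """Direction and monotonicity of one metric across sweep levels."""

    metric: str
    levels: tuple
    values: tuple
    spearman: float
    monotonic: bool
    direction: str
    expected: str | None = None

    @property
    def matches_expected(self) -> bool | None:
        if self.expected is None:
            return None
        return self.monotonic and self.direction == self.expected

    def to_dict(self) -> dict:
        return {
            "metric": self.metric, "levels": list(self.levels),
            "values": list(self.values), "spearman": self.spearman,
            "monotonic": self.monotonic, "direction": self.direction,
            "expected": self.expected,
            "matches_expected": self.matches_expected,
        }


def trend_report(rows, metric: str, expected: str | None = None
                 ) -> TrendReport:
    """Monotonicity assessment of ``metric`` versus sweep level.

    Rows are sorted by level first, so input order is irrelevant; failed
    rows are skipped.  ``expected`` is 'increasing' or 'decreasing'.
    Strict monotonicity is required for the monotone flag (ties break it).
    """
    ok = [r for r in rows if "error" not in r and metric in r]
    if len(ok) < 3:
        raise ValueError("need at least 3 successful rows for a trend")
    ok.sort(key=lambda r: r["level"])
    levels = tuple(r["level"] for r in ok)
    values = tuple(float(r[metric]) for r in ok)
    d = np.diff(values)
    if np.all(d > 0):
        direction, monotonic = "increasing", True
    elif np.all(d < 0):
        direction, monotonic = "decreasing", True
    else:
        monotonic = False
        direction = "increasing" if np.sum(d) > 0 else "decreasing"
    rho = float(stats.spearmanr(levels, values).statistic)
    return TrendReport(metric=metric, levels=levels, values=values,
                       spearman=rho, monotonic=monotonic,
                       direction=direction, expected=expected)
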