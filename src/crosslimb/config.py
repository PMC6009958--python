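"""Run configuration: TOML dialect, defaults, validation.

One structured-text dialect (TOML) with nested blocks ``[geometry]``,
``[rheology]``, ``[waveforms]``, ``[grid]``, ``[solver]``, ``[sweep]``,
``[output]``.  Defaults are the study's printed values wherever printed:
graft diameters 17/10 mm, lengths 154.64/71 mm, Carreau blood parameters,
rho = 1050 kg/m^3, cycle of 200 steps x 0.005 s, 6 cycles, residual
target 1e-5, inlet mean 0.044 m/s, outlet mean pressure 13 300 Pa.
Unknown keys are rejected and every violation is reported, not just the
first.
"""

from __future__ import annotations

import hashlib
import json
import tomllib
from dataclasses import dataclass, field, fields, asdict

from .geometry import BSGConfig, GeometryError
from .rheology import RheologyParams, newtonian

__all__ = ["RunConfig", "ConfigError", "load_config", "default_config"]


class ConfigError(ValueError):
    def __init__(self, problems):
        self.problems = list(problems)
        super().__init__("invalid configuration:\n  "
                         + "\n  ".join(self.problems))


_DEFAULTS = {
    "geometry": {
        "trunk_diameter": 17.0, "iliac_diameter": 10.0,
        "total_length": 154.64, "trunk_length": 71.0,
        "cross_angle_deg": 60.0, "cross_length_mm": 42.0,
        "position_ratio": None, "side_length_mm": None,
        "clearance_mm": 1.0, "ostium_offset_mm": None,
    },
    "rheology": {
        "eta_inf": 3.45e-3, "eta_0": 5.6e-2, "lambda_relax": 3.313,
        "n_index": 0.3568, "rho": 1050.0, "newtonian": None,
    },
    "waveforms": {
        "inlet_mean": 0.044, "pulsatility_index": 4.0,
        "outlet_mean_pressure": 13300.0, "pulse_amplitude": 5320.0,
        "peak_time": 0.1, "period": 1.0,
    },
    "grid": {"spacing_mm": 1.4, "margin_mm": 3.0, "extension_mm": 20.0},
    "solver": {
        "dt": 0.005, "steps_per_cycle": 200, "n_cycles": 6,
        "steady_tol": 1e-5, "steady_max_iter": 20000, "cfl": 0.4,
    },
    "sweep": {"series": "angle", "tier": "test", "levels": None},
    "output": {"directory": "runs", "write_vtk": False},
}


@dataclass(frozen=True)
class RunConfig:
    """Fully resolved nested configuration."""

    geometry: dict
    rheology: dict
    waveforms: dict
    grid: dict
    solver: dict
    sweep: dict
    output: dict

    def bsg_config(self) -> BSGConfig:
        g = dict(self.geometry)
        return BSGConfig(**g)

    def rheology_params(self) -> RheologyParams:
        r = dict(self.rheology)
        nw = r.pop("newtonian", None)
        if nw is not None:
            return newtonian(float(nw), rho=r["rho"])
        return RheologyParams(**r)

    def to_dict(self) -> dict:
        return asdict(self)

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:12]


def default_config() -> RunConfig:
    return RunConfig(**{k: dict(v) for k, v in _DEFAULTS.items()})


def load_config(source=None) -> RunConfig:
    """Build a RunConfig from a TOML path, TOML text, or nested dict.

    Missing keys take defaults; unknown blocks/keys and cross-field
    inconsistencies raise ConfigError listing every violation.
    """
    if source is None:
        data = {}
    elif isinstance(source, dict):
        data = source
    else:
        text = str(source)
        if "\n" in text or "=" in text:
            data = tomllib.loads(text)
        else:
            with open(text, "rb") as f:
                data = tomllib.load(f)
    problems = []
    merged = {}
    for block, defaults in _DEFAULTS.items():
        user = data.get(block, {})
        if not isinstance(user, dict):
            problems.append(f"[{block}] must be a table")
            user = {}
        for key in user:
            if key not in defaults:
                problems.append(f"unknown key [{block}] {key}")
        merged[block] = {**defaults,
                         **{k: v for k, v in user.items() if k in defaults}}
    for block in data:
        if block not in _DEFAULTS:
            problems.append(f"unknown block [{block}]")
    g = merged["geometry"]
    if g.get("cross_angle_deg") is not None and not \
            0.0 < g["cross_angle_deg"] < 180.0:
        problems.append("geometry.cross_angle_deg must lie in (0, 180)")
    # when the user pins the position pair, release the angle-pair defaults
    user_geo = data.get("geometry", {}) if isinstance(data, dict) else {}
    if "position_ratio" in user_geo and "cross_length_mm" not in user_geo:
        g["cross_length_mm"] = None
    if "side_length_mm" in user_geo and "cross_angle_deg" not in user_geo:
        g["cross_angle_deg"] = None
    for key in ("spacing_mm", "margin_mm", "extension_mm"):
        if merged["grid"][key] is not None and merged["grid"][key] < 0:
            problems.append(f"grid.{key} must be non-negative")
    s = merged["solver"]
    if s["steps_per_cycle"] < 40:
        problems.append("solver.steps_per_cycle must be >= 40")
    if s["steady_tol"] <= 0:
        problems.append("solver.steady_tol must be positive")
    w = merged["waveforms"]
    if w["inlet_mean"] <= 0:
        problems.append("waveforms.inlet_mean must be positive")
    if w["outlet_mean_pressure"] < 0:
        problems.append("waveforms.outlet_mean_pressure must be >= 0")
    if merged["sweep"]["series"] not in ("angle", "position"):
        problems.append("sweep.series must be 'angle' or 'position'")
    if not problems and g["cross_angle_deg"] is None \
            and g["side_length_mm"] is None:
        problems.append("geometry needs cross_angle_deg or side_length_mm")
    if not problems:
        try:
            cfg = BSGConfig(**g)
            cfg.validate()
        except (GeometryError, TypeError) as exc:
            problems.append(f"geometry: {exc}")
        # advective CFL advisory estimate: plug peak through iliac area
        try:
            area_ratio = (g["trunk_diameter"] / g["iliac_diameter"]) ** 2 / 2.0
            v_est = w["inlet_mean"] * (1 + w["pulsatility_index"]) * area_ratio
            h = merged["grid"]["spacing_mm"] * 1e-3
            if s["dt"] > 0.7 * h / max(v_est, 1e-12):
                pass  # informational only: the solver substeps to the CFL
        except Exception:
            pass
    if problems:
        raise ConfigError(problems)
    return RunConfig(**merged)
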