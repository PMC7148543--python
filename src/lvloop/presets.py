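"""Scenario presets, YAML configuration and override resolution.

Four named physiological presets are provided:

* ``control_basic`` / ``control_extended`` — a resting 1 Hz heart
  (PR = 9 mmHg and m0 = 70 mmHg for the basic variant; gamma = 0.6,
  k2 = 14 kPa, V0 = 96 mL, alpha_u = 5, mu1 = 0.0024, mu2 = 0), no pump.
* ``dcm_basic`` / ``dcm_extended`` — dilated cardiomyopathy: an enlarged,
  stiffer, weaker ventricle (V0 = 144 mL, k2 = 40 kPa, gamma = 0.45),
  all other parameters unchanged.

Pump settings are attached per run through overrides or the CLI
(``off``, constant speed, or an affine ramp).

Overrides use dotted keys into the scenario tree, e.g.
``circulation.m0 = 50`` or ``pump.delta_p = 1``; unknown keys are
rejected.  A scenario serialises to YAML and loads back identically.
"""

from __future__ import annotations

from dataclasses import asdict, fields as dc_fields
from pathlib import Path
from typing import Any, Mapping

import yaml

from .circulation import CirculationParams, PumpParams, PumpProtocol
from .electro import ElectricParams
from .engine import Scenario, SolverSettings
from .sarcomere import SarcomereParams

__all__ = [
    "preset_names",
    "make_preset",
    "load_scenario",
    "apply_overrides",
    "scenario_to_dict",
    "scenario_from_dict",
    "save_scenario",
]

#: exact control reference volume, stored as the ratio to avoid decimal drift
V0_CONTROL = 144.0 / 1.5
V0_DCM = 144.0

_DCM_SARC = {"k2": 40.0, "V0": V0_DCM, "gamma": 0.45}


def _control_sarc() -> SarcomereParams:
    return SarcomereParams()  # defaults are the control values


def make_preset(name: str) -> Scenario:
    """Build a named preset scenario (pump off; attach pump via overrides)."""
    if name == "control_basic":
        return Scenario(variant="basic", name=name)
    if name == "control_extended":
        return Scenario(variant="extended", name=name)
    if name == "dcm_basic":
        return Scenario(
            variant="basic",
            sarcomere=_control_sarc().with_overrides(**_DCM_SARC),
            name=name,
        )
    if name == "dcm_extended":
        return Scenario(
            variant="extended",
            sarcomere=_control_sarc().with_overrides(**_DCM_SARC),
            name=name,
        )
    raise KeyError(f"unknown preset {name!r}; available: {', '.join(preset_names())}")


def preset_names() -> tuple[str, ...]:
    return ("control_basic", "control_extended", "dcm_basic", "dcm_extended")


_SUBSECTIONS = {
    "sarcomere": SarcomereParams,
    "electric": ElectricParams,
    "circulation": CirculationParams,
    "pump": PumpParams,
    "protocol": PumpProtocol,
    "solver": SolverSettings,
}
_SCALARS = ("variant", "t_end", "output_dt", "v_floor", "name")


def scenario_to_dict(scenario: Scenario) -> dict:
    d = asdict(scenario)
    return d


def scenario_from_dict(data: Mapping[str, Any]) -> Scenario:
    """Reconstruct a Scenario from a nested mapping; unknown keys raise."""
    data = dict(data)
    kwargs: dict[str, Any] = {}
    for key, cls in _SUBSECTIONS.items():
        if key in data:
            sub = data.pop(key)
            if not isinstance(sub, Mapping):
                raise ValueError(f"section {key!r} must be a mapping")
            valid = {f.name for f in dc_fields(cls)}
            unknown = set(sub) - valid
            if unknown:
                raise KeyError(f"unknown keys in {key!r}: {sorted(unknown)}")
            kwargs[key] = cls(**sub)
    if "initial" in data:
        kwargs["initial"] = {str(k): float(v) for k, v in data.pop("initial").items()}
    for key in _SCALARS:
        if key in data:
            kwargs[key] = data.pop(key)
    if data:
        raise KeyError(f"unknown scenario keys: {sorted(data)}")
    return Scenario(**kwargs)


def apply_overrides(scenario: Scenario, overrides: Mapping[str, Any]) -> Scenario:
    """Apply dotted-key overrides, e.g. {"circulation.m0": 50.0}."""
    if not overrides:
        return scenario
    tree = scenario_to_dict(scenario)
    for dotted, value in overrides.items():
        parts = dotted.split(".")
        node = tree
        for p in parts[:-1]:
            if p not in node or not isinstance(node[p], dict):
                raise KeyError(f"unknown override key {dotted!r}")
            node = node[p]
        leaf = parts[-1]
        if parts[0] == "initial":
            # new initial-state entries are allowed; Scenario validates names
            node[leaf] = value
        elif leaf not in node:
            raise KeyError(f"unknown override key {dotted!r}")
        else:
            node[leaf] = value
    name = tree.get("name") or ""
    tree["name"] = f"{name}+overrides" if name else "custom"
    return scenario_from_dict(tree)


def load_scenario(source: str | Path, overrides: Mapping[str, Any] | None = None) -> Scenario:
    """Resolve a preset name or a YAML file into a Scenario, then apply
    dotted-key overrides.  Unknown presets, keys or sections raise."""
    source = str(source)
    if source in preset_names():
        scen = make_preset(source)
    else:
        path = Path(source)
        if not path.exists():
            raise KeyError(
                f"{source!r} is neither a preset ({', '.join(preset_names())}) nor a file"
            )
        with open(path) as fh:
            data = yaml.safe_load(fh)
        if not isinstance(data, dict):
            raise ValueError(f"scenario file {source!r} must contain a mapping")
        scen = scenario_from_dict(data)
    return apply_overrides(scen, overrides or {})


def save_scenario(scenario: Scenario, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(scenario_to_dict(scenario), fh, sort_keys=True)
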