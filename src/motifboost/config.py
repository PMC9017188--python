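"""Structured run configuration (YAML) for the end-to-end pipeline.

A config names a channel design (preset or explicit), the simulator's
study conditions, the acquisition model, the acceptance criteria, and the
analysis parameters.  Unknown keys are rejected, and a config round-trips
serialize -> parse -> serialize identically.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Any

import yaml

from .filters import ChannelDesign, FilterCriteria, ck2_design, py_design, titration_design
from .simulate import AcquisitionParams, SimulationConfig, TruthParams

DESIGN_PRESETS = {"ck2": ck2_design, "py": py_design, "titration": titration_design}


class ConfigError(ValueError):
    pass


def _build(cls, data: dict[str, Any], context: str):
    """Instantiate a dataclass from a dict, rejecting unknown keys."""
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ConfigError(f"unknown key(s) in {context}: {sorted(unknown)}")
    kwargs = {}
    for f in dataclasses.fields(cls):
        if f.name not in data:
            continue
        value = data[f.name]
        if f.name == "truth" and isinstance(value, dict):
            value = _build(TruthParams, value, "simulation.truth")
        if f.name in ("treated_conditions",) and isinstance(value, list):
            value = tuple(value)
        if f.name in ("class_priors",) and isinstance(value, dict):
            value = {k: tuple(v) for k, v in value.items()}
        if f.name in ("residue_ratio", "composition") and isinstance(value, list):
            value = tuple(value)
        kwargs[f.name] = value
    return cls(**kwargs)


@dataclass
class AnalysisConfig:
    alpha: float = 0.05
    control: str = ""
    treated: str = ""
    endo_condition: str = ""
    normalization: str = "none"
    equal_var: bool = True
    min_abs_log2_ratio: float = 0.0


@dataclass
class RunConfig:
    seed: int = 0
    outdir: str = "results/run"
    design: str | dict = "ck2"
    models_path: str | None = None
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    acquisition: AcquisitionParams = field(default_factory=AcquisitionParams)
    criteria: FilterCriteria = field(default_factory=FilterCriteria)
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)

    def build_design(self) -> ChannelDesign:
        if isinstance(self.design, str):
            try:
                return DESIGN_PRESETS[self.design]()
            except KeyError:
                raise ConfigError(
                    f"unknown design preset {self.design!r}; "
                    f"choose from {sorted(DESIGN_PRESETS)} or give an explicit mapping"
                ) from None
        d = dict(self.design)
        return ChannelDesign(
            channels=tuple(d["channels"]),
            roles=dict(d["roles"]),
            duplicate_sets=tuple(tuple(s) for s in d["duplicate_sets"]),
            boost_ratio_samples=(
                tuple(d["boost_ratio_samples"]) if d.get("boost_ratio_samples") else None
            ),
        )

    def to_dict(self) -> dict:
        def clean(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {k: clean(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, dict):
                return {k: clean(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [clean(v) for v in obj]
            if isinstance(obj, frozenset):
                return sorted(obj)
            return obj

        return clean(dataclasses.asdict(self))


def config_from_dict(data: dict[str, Any]) -> RunConfig:
    names = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(data) - names
    if unknown:
        raise ConfigError(f"unknown top-level key(s): {sorted(unknown)}")
    kwargs: dict[str, Any] = {}
    for key, value in data.items():
        if key == "simulation":
            kwargs[key] = _build(SimulationConfig, value, "simulation")
        elif key == "acquisition":
            kwargs[key] = _build(AcquisitionParams, value, "acquisition")
        elif key == "criteria":
            kwargs[key] = _build(FilterCriteria, value, "criteria")
        elif key == "analysis":
            kwargs[key] = _build(AnalysisConfig, value, "analysis")
        else:
            kwargs[key] = value
    return RunConfig(**kwargs)


def load_config(path) -> RunConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return config_from_dict(data)


def save_config(config: RunConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)
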