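"""Run configuration: validated, serializable experiment descriptions."""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .climate import ClimateSpec
from .models import ModelParams, table1

__all__ = ["RunConfig", "load_config"]

_EXPERIMENTS = ("simulate", "montecarlo", "bi-region", "bifurcate",
                "switch-map")


@dataclass(frozen=True)
class RunConfig:
    """One experiment: model, parameter overrides, forcing and seeding.

    Unknown keys and invalid values are rejected at load time;
    round-trips losslessly through to_dict/from_dict.
    """

    model: str
    experiment: str
    seed: int = 0
    overrides: dict = field(default_factory=dict)
    climate: dict = field(default_factory=dict)
    outdir: str = "."

    def __post_init__(self) -> None:
        if self.model not in ("rma", "may"):
            raise ValueError(f"unknown model {self.model!r}")
        if self.experiment not in _EXPERIMENTS:
            raise ValueError(f"unknown experiment {self.experiment!r}; "
                             f"expected one of {_EXPERIMENTS}")
        for key, val in self.overrides.items():
            if not isinstance(val, (int, float)) or val <= 0:
                raise ValueError(f"override {key}={val!r} must be a "
                                 "positive number")
        # constructing the params validates override names
        self.params()
        if self.climate:
            self.climate_spec()

    def params(self) -> ModelParams:
        try:
            return table1(self.model, **self.overrides)
        except TypeError as exc:
            raise ValueError(f"invalid parameter override: {exc}") from exc

    def climate_spec(self) -> ClimateSpec:
        allowed = {"r_low", "r_high", "rho", "horizon"}
        unknown = set(self.climate) - allowed
        if unknown:
            raise ValueError(f"unknown climate keys: {sorted(unknown)}")
        return ClimateSpec(seed=self.seed, **self.climate)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def save(self, path: str | Path) -> None:
        path = Path(path)
        text = (json.dumps(self.to_dict(), indent=2)
                if path.suffix == ".json"
                else yaml.safe_dump(self.to_dict(), sort_keys=False))
        path.write_text(text)

    def digest(self) -> str:
        import hashlib
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def load_config(path: str | Path) -> RunConfig:
    """Read a RunConfig from a JSON or YAML file (by extension)."""
    path = Path(path)
    text = path.read_text()
    data = (json.loads(text) if path.suffix == ".json"
            else yaml.safe_load(text))
    if not isinstance(data, dict):
        raise ValueError(f"config {path} must be a mapping")
    return RunConfig.from_dict(data)
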