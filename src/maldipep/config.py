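"""Pipeline configuration: one strict YAML file drives the whole workflow.

Sections mirror the stage configs (``simulation``, ``preprocessing``,
``peaks``, ``svm``, ``cv``) plus a top-level ``seed``.  Unknown keys are
rejected so typos cannot silently fall back to defaults, and a config
round-trips unchanged through serialization.
"""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .preprocessing import PreprocessConfig
from .peaks import PeakConfig
from .simulate import SimulationConfig, config_from_dict as _sim_from_dict, \
    config_to_dict as _sim_to_dict
from .svm import SVMConfig


class ConfigError(ValueError):
    """Raised for invalid or unknown pipeline configuration."""


@dataclass
class CVSettings:
    mode: str = "cv20"                 # "cv20" | "doublecv"
    k: int = 20
    outer_k: int = 10
    inner_k: int = 20

    def validate(self) -> None:
        if self.mode not in ("cv20", "doublecv"):
            raise ConfigError(f"unknown cv mode {self.mode!r}")
        if min(self.k, self.outer_k, self.inner_k) < 2:
            raise ConfigError("fold counts must be >= 2")


@dataclass
class PipelineConfig:
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    preprocessing: PreprocessConfig = field(default_factory=PreprocessConfig)
    peaks: PeakConfig = field(default_factory=PeakConfig)
    svm: SVMConfig = field(default_factory=SVMConfig)
    cv: CVSettings = field(default_factory=CVSettings)
    seed: int = 0

    def validate(self) -> "PipelineConfig":
        self.simulation.validate()
        self.preprocessing.validate()
        self.peaks.validate()
        self.svm.validate()
        self.cv.validate()
        return self

    def to_dict(self) -> dict:
        return {
            "simulation": _sim_to_dict(self.simulation),
            "preprocessing": asdict(self.preprocessing),
            "peaks": asdict(self.peaks),
            "svm": {**asdict(self.svm),
                    "gamma_grid": list(self.svm.gamma_grid),
                    "coef0_grid": list(self.svm.coef0_grid),
                    "cost_grid": list(self.svm.cost_grid)},
            "cv": asdict(self.cv),
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        data = dict(data or {})
        known = {"simulation", "preprocessing", "peaks", "svm", "cv", "seed"}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config section(s): {sorted(unknown)}")
        try:
            simulation = _sim_from_dict(data.get("simulation", {}))
            preprocessing = _strict(PreprocessConfig, data.get("preprocessing", {}))
            peaks = _strict(PeakConfig, data.get("peaks", {}))
            svm_data = dict(data.get("svm", {}))
            for key in ("gamma_grid", "coef0_grid", "cost_grid"):
                if key in svm_data:
                    svm_data[key] = tuple(svm_data[key])
            svm = _strict(SVMConfig, svm_data)
            cv = _strict(CVSettings, data.get("cv", {}))
        except ValueError as exc:
            raise ConfigError(str(exc)) from None
        cfg = cls(simulation=simulation, preprocessing=preprocessing,
                  peaks=peaks, svm=svm, cv=cv, seed=int(data.get("seed", 0)))
        return cfg.validate()

    @property
    def digest(self) -> str:
        """Stable hash stamped on every artifact for provenance."""
        text = yaml.safe_dump(self.to_dict(), sort_keys=True)
        return hashlib.sha256(text.encode()).hexdigest()[:12]


def _strict(cls, data: dict):
    allowed = set(cls.__dataclass_fields__)
    unknown = set(data) - allowed
    if unknown:
        raise ConfigError(
            f"unknown key(s) in {cls.__name__}: {sorted(unknown)}")
    obj = cls(**data)
    obj.validate()
    return obj


def load_config(path) -> PipelineConfig:
    with open(Path(path)) as fh:
        data = yaml.safe_load(fh)
    return PipelineConfig.from_dict(data)


def save_config(cfg: PipelineConfig, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=True)
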