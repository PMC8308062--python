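"""Pipeline configuration: YAML/JSON in, resolved defaults out.

Unknown keys are rejected anywhere in the tree; a run's effective
configuration (all defaults resolved) is serialized beside its outputs and
its hash stamped into every output file header.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from .errors import ConfigurationError
from .synthdata import DiseaseSpec, SimulationConfig


def _build(cls, raw: dict, where: str):
    known = {f.name for f in fields(cls)}
    unknown = set(raw) - known
    if unknown:
        raise ConfigurationError(f"unknown keys under {where}: {sorted(unknown)}")
    return cls(**raw)


@dataclass
class QCSettings:
    maf_min: float = 0.001
    snp_missing_max: float = 0.03
    sample_missing_max: float = 0.03


@dataclass
class SolverSettings:
    n_lambda: int = 100
    min_ratio: float = 1e-3
    tol: float = 1e-7
    max_sweeps: int = 10_000


@dataclass
class SplitSettings:
    n_folds: int = 5
    n_validation: int = 1000


@dataclass
class PredictorSettings:
    biomarkers: list[str] = field(default_factory=list)  # empty = all simulated
    conditions: list[str] = field(default_factory=list)  # empty = all simulated
    dropped_biomarkers: list[str] = field(default_factory=list)
    sex_stratified_bmrs: bool = True


@dataclass
class EvaluationSettings:
    percentiles: list[float] = field(default_factory=lambda: [50, 60, 70, 80, 90, 95, 99])
    sibling_thresholds: list[float] = field(default_factory=lambda: [0.5, 1.0, 1.5])
    n_boot: int = 100


@dataclass
class CalibrationSettings:
    n_bins: int = 40
    window: int = 5
    curve_bins: int = 20


@dataclass
class PipelineConfig:
    seed: int = 0
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    qc: QCSettings = field(default_factory=QCSettings)
    solver: SolverSettings = field(default_factory=SolverSettings)
    splits: SplitSettings = field(default_factory=SplitSettings)
    predictors: PredictorSettings = field(default_factory=PredictorSettings)
    evaluation: EvaluationSettings = field(default_factory=EvaluationSettings)
    calibration: CalibrationSettings = field(default_factory=CalibrationSettings)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        raw = dict(raw)
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown top-level keys: {sorted(unknown)}")
        sim_raw = dict(raw.pop("simulation", {}))
        specs = [
            _build(DiseaseSpec, dict(s), "simulation.disease_specs")
            for s in sim_raw.pop("disease_specs", [])
        ]
        if "maf_range" in sim_raw:
            sim_raw["maf_range"] = tuple(sim_raw["maf_range"])
        sim = _build(SimulationConfig, {**sim_raw, "disease_specs": specs}, "simulation")
        out = cls(
            seed=raw.pop("seed", 0),
            simulation=sim,
            qc=_build(QCSettings, dict(raw.pop("qc", {})), "qc"),
            solver=_build(SolverSettings, dict(raw.pop("solver", {})), "solver"),
            splits=_build(SplitSettings, dict(raw.pop("splits", {})), "splits"),
            predictors=_build(PredictorSettings, dict(raw.pop("predictors", {})), "predictors"),
            evaluation=_build(EvaluationSettings, dict(raw.pop("evaluation", {})), "evaluation"),
            calibration=_build(CalibrationSettings, dict(raw.pop("calibration", {})), "calibration"),
        )
        # a single master seed drives the simulation unless it set its own
        if "seed" not in sim_raw:
            out.simulation.seed = out.seed
        return out

    @classmethod
    def load(cls, path: str | Path) -> "PipelineConfig":
        text = Path(path).read_text()
        raw = yaml.safe_load(text) or {}
        if not isinstance(raw, dict):
            raise ConfigurationError(f"{path}: config must be a mapping")
        return cls.from_dict(raw)

    def to_dict(self) -> dict:
        # json round-trip turns tuples into lists so yaml.safe_dump accepts it
        return json.loads(json.dumps(asdict(self)))

    def dump(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @property
    def hash(self) -> str:
        canon = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(canon.encode()).hexdigest()[:12]
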