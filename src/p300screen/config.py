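"""Run configuration: one YAML-serializable object covering every stage."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from p300screen.errors import ConfigurationError
from p300screen.sequencer import DEFAULT_SEED, TimingConfig
from p300screen.synthetic import ERPComponent, SubjectProfile


@dataclass(frozen=True)
class PreprocessingConfig:
    filter_order: int = 40
    band: tuple[float, float] = (1.5, 10.0)
    window_attenuation_db: float = 60.0


@dataclass(frozen=True)
class ClassifierConfig:
    cv_folds: int = 5
    n_lambdas: int = 50
    lambda_min_ratio: float = 1e-4
    max_iter: int = 300


@dataclass(frozen=True)
class EvaluationConfig:
    l_values: tuple[int, ...] = tuple(range(1, 11))
    n_eval_reps: int = 9


@dataclass(frozen=True)
class RunConfig:
    """Everything needed to reproduce a multi-subject simulated study."""

    timing: TimingConfig = field(default_factory=TimingConfig)
    profile: SubjectProfile = field(default_factory=SubjectProfile)
    preprocessing: PreprocessingConfig = field(default_factory=PreprocessingConfig)
    classifier: ClassifierConfig = field(default_factory=ClassifierConfig)
    evaluation: EvaluationConfig = field(default_factory=EvaluationConfig)
    n_subjects: int = 20
    seed: int = DEFAULT_SEED
    sample_rate: float = 512.0
    output_dir: str = "runs"

    def to_dict(self) -> dict:
        def listify(obj):
            if isinstance(obj, dict):
                return {k: listify(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [listify(v) for v in obj]
            return obj

        return listify(asdict(self))

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        data = dict(data)
        try:
            timing = TimingConfig(
                **{
                    **data["timing"],
                    "isi_values": tuple(data["timing"]["isi_values"]),
                    "block_reps": tuple(data["timing"]["block_reps"]),
                }
            )
            prof = dict(data["profile"])
            prof["target_components"] = tuple(
                ERPComponent(**c) for c in prof["target_components"]
            )
            prof["nontarget_components"] = tuple(
                ERPComponent(**c) for c in prof["nontarget_components"]
            )
            prof["channel_gains"] = tuple(prof["channel_gains"])
            pre = dict(data["preprocessing"])
            pre["band"] = tuple(pre["band"])
            ev = dict(data["evaluation"])
            ev["l_values"] = tuple(ev["l_values"])
            return cls(
                timing=timing,
                profile=SubjectProfile(**prof),
                preprocessing=PreprocessingConfig(**pre),
                classifier=ClassifierConfig(**data["classifier"]),
                evaluation=EvaluationConfig(**ev),
                n_subjects=int(data["n_subjects"]),
                seed=int(data["seed"]),
                sample_rate=float(data["sample_rate"]),
                output_dir=str(data["output_dir"]),
            )
        except (KeyError, TypeError) as exc:
            raise ConfigurationError(f"malformed run config: {exc}") from exc

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def hash(self) -> str:
        """Short provenance hash; changes iff any config field changes."""
        canonical = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canonical.encode()).hexdigest()[:12]
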