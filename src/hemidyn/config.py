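"""Run configuration: a serializable description of a full analysis run."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from .synth import SimulationConfig

__all__ = ["RunConfig", "load_config", "save_config"]


def _check_keys(d: dict, cls) -> dict:
    known = {f.name for f in fields(cls)}
    unknown = set(d) - known
    if unknown:
        raise ValueError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    return d


@dataclass(frozen=True)
class TripletTaskConfig:
    """Latent mixing weights and size of one online triplet task."""

    w_image: float = 1.0
    w_concept: float = 0.3
    n_participants: int = 21
    n_trials: int = 400
    decision_noise: float = 0.15


@dataclass(frozen=True)
class RunConfig:
    """Everything needed to reproduce one end-to-end pipeline run.

    ``analyses`` toggles pipeline stages; decoding folds, the RSA delay grid
    and window, permutation counts and the Bayes-factor prior follow the
    study's defaults and are all overridable.  Round-trips losslessly through
    YAML/JSON; unknown keys are rejected on load.
    """

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    n_concepts: int = 6
    n_image_exemplars: int = 4
    n_word_variants: int = 2
    conditions: tuple[str, ...] = ("single", "dual")
    analyses: tuple[str, ...] = ("decoding", "rsa", "consistency", "behavior",
                                 "commonality", "stats")
    n_folds: int = 12
    shrinkage: str | float | None = "ledoit-wolf"
    delay_range: tuple[int, int] = (-100, 100)
    rsa_window: tuple[int, int] = (0, 500)
    n_permutations: int = 1000
    image_task: TripletTaskConfig = field(default_factory=TripletTaskConfig)
    concept_task: TripletTaskConfig = field(
        default_factory=lambda: TripletTaskConfig(w_image=0.3, w_concept=1.0))
    prior_scale: float = 0.707
    null_interval: tuple[float, float] = (-0.5, 0.5)
    onset_threshold: float = 10.0
    onset_run_ms: int = 10
    jackknife_leave_out: int = 2
    out_dir: str = "runs"
    seed: int = 0

    def to_dict(self) -> dict:
        d = asdict(self)
        d["simulation"] = self.simulation.to_dict()
        for key in ("conditions", "analyses", "delay_range", "rsa_window", "null_interval"):
            d[key] = list(d[key])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(_check_keys(d, cls))
        if "simulation" in d and isinstance(d["simulation"], dict):
            d["simulation"] = SimulationConfig.from_dict(d["simulation"])
        for key in ("image_task", "concept_task"):
            if key in d and isinstance(d[key], dict):
                d[key] = TripletTaskConfig(**_check_keys(d[key], TripletTaskConfig))
        for key in ("conditions", "analyses", "delay_range", "rsa_window", "null_interval"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha1(blob.encode()).hexdigest()[:12]


def save_config(config: RunConfig, path: str | Path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        if path.suffix in (".yaml", ".yml"):
            yaml.safe_dump(config.to_dict(), fh, sort_keys=False)
        else:
            json.dump(config.to_dict(), fh, indent=2)


def load_config(path: str | Path) -> RunConfig:
    path = Path(path)
    with open(path) as fh:
        if path.suffix in (".yaml", ".yml"):
            d = yaml.safe_load(fh)
        else:
            d = json.load(fh)
    return RunConfig.from_dict(d)
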