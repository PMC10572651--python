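"""Experiment configuration: explicit seeds, YAML round-trip, strict schema.

Every source of randomness has its own named seed (cohort, split, partition,
model init, training shuffle) so components can be varied independently in
ablations; a single ``seed`` key derives all five. No wall-clock seeding.
Unknown keys are rejected by name so a typo never silently falls back to a
default.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields, replace
from pathlib import Path

import numpy as np
import yaml

from .aggregation import ThresholdPolicy
from .cohort import GeneratorParams
from .model import Architecture, TrainingConfig


@dataclass(frozen=True)
class CohortConfig:
    n_cases: int = 300
    class_mix: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3)
    image_size: int = 64
    benign_radius: tuple[float, float] = (3.0, 6.0)
    benign_intensity: float = 0.6
    benign_spiculation: float = 0.0
    malignant_radius: tuple[float, float] = (5.0, 9.0)
    malignant_intensity: float = 0.8
    malignant_spiculation: float = 0.35
    spiculation_harmonics: tuple[int, ...] = (3, 5, 7)
    edge_blur_sd: float = 1.0
    slice_thickness_mm: float = 1.25

    def generator_params(self) -> GeneratorParams:
        return GeneratorParams(
            image_size=self.image_size,
            benign_radius=tuple(self.benign_radius),
            benign_intensity=self.benign_intensity,
            benign_spiculation=self.benign_spiculation,
            malignant_radius=tuple(self.malignant_radius),
            malignant_intensity=self.malignant_intensity,
            malignant_spiculation=self.malignant_spiculation,
            spiculation_harmonics=tuple(self.spiculation_harmonics),
            edge_blur_sd=self.edge_blur_sd,
            slice_thickness_mm=self.slice_thickness_mm,
        )


@dataclass(frozen=True)
class TopologyConfig:
    n_clients: int = 5
    n_routers: int | None = None  # None -> ceil(sqrt(n_clients))
    partition: str = "iid"
    skew_alpha: float = 0.5


@dataclass(frozen=True)
class Seeds:
    cohort_seed: int = 42
    split_seed: int = 1
    partition_seed: int = 2
    init_seed: int = 3
    train_seed: int = 4

    @classmethod
    def from_master(cls, seed: int) -> "Seeds":
        state = np.random.SeedSequence(seed).generate_state(5)
        names = [f.name for f in fields(cls)]
        return cls(**{n: int(s % (2**31)) for n, s in zip(names, state)})


@dataclass(frozen=True)
class ExperimentConfig:
    cohort: CohortConfig = field(default_factory=CohortConfig)
    topology: TopologyConfig = field(default_factory=TopologyConfig)
    training: TrainingConfig = field(default_factory=lambda: TrainingConfig(
        epochs=5, learning_rate=0.1, batch_size=16, l2=1e-4))
    policy: ThresholdPolicy = field(default_factory=ThresholdPolicy)
    architecture: Architecture = field(default_factory=Architecture)
    rounds: int = 30
    train_fraction: float = 0.6
    calibration_fraction: float = 0.2
    seeds: Seeds = field(default_factory=Seeds)
    output_dir: str = "runs"


_SECTION_TYPES = {
    "cohort": CohortConfig,
    "topology": TopologyConfig,
    "training": TrainingConfig,
    "policy": ThresholdPolicy,
    "architecture": Architecture,
    "seeds": Seeds,
}


def _build_section(cls, data: dict, path: str):
    if not isinstance(data, dict):
        raise ValueError(f"config section {path!r} must be a mapping")
    known = {f.name for f in fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config key(s) under {path!r}: {sorted(unknown)}")
    kwargs = {}
    for k, v in data.items():
        if isinstance(v, list):
            v = tuple(v)
        if k == "mode" and isinstance(v, bool):
            # YAML 1.1 reads a bare `off` as False; map it back
            v = "off" if v is False else "on"
        kwargs[k] = v
    return cls(**kwargs)


def config_from_dict(data: dict | None) -> ExperimentConfig:
    """Build a full config from a (possibly partial) plain dict.

    Missing keys take defaults; unknown keys raise with the offending name.
    A top-level ``seed`` derives all five component seeds.
    """
    data = dict(data or {})
    top_known = {f.name for f in fields(ExperimentConfig)} | {"seed"}
    unknown = set(data) - top_known
    if unknown:
        raise ValueError(f"unknown config key(s): {sorted(unknown)}")
    kwargs = {}
    master = data.pop("seed", None)
    for name, cls in _SECTION_TYPES.items():
        if name in data:
            kwargs[name] = _build_section(cls, data.pop(name), name)
    kwargs.update(data)
    cfg = ExperimentConfig(**kwargs)
    if master is not None:
        if "seeds" in kwargs:
            raise ValueError("give either 'seed' or 'seeds', not both")
        cfg = replace(cfg, seeds=Seeds.from_master(int(master)))
    return cfg


def config_to_dict(cfg: ExperimentConfig) -> dict:
    d = asdict(cfg)

    def tuples_to_lists(obj):
        if isinstance(obj, dict):
            return {k: tuples_to_lists(v) for k, v in obj.items()}
        if isinstance(obj, tuple):
            return [tuples_to_lists(v) for v in obj]
        return obj

    return tuples_to_lists(d)


def load_config(path: str | Path) -> ExperimentConfig:
    text = Path(path).read_text()
    return config_from_dict(yaml.safe_load(text) or {})


def save_config(cfg: ExperimentConfig, path: str | Path) -> None:
    Path(path).write_text(
        yaml.safe_dump(config_to_dict(cfg), sort_keys=False, default_flow_style=None)
    )
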