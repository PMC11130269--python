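"""Run configuration: one YAML document driving the whole pipeline.

A RunConfig bundles every sub-configuration (simulation grid, population,
integrator, emulator widths, training, baseline) plus a single master seed.
The master seed fans out deterministically to named sub-seeds (training
population, test population, per-architecture weight/holdout streams) that
are recorded in the run manifest.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import yaml

from .baseline_plsr import PLSRConfig
from .emulators import TrainConfig
from .params import SimConfig
from .population import ParameterDistributionConfig
from .scenarios import ScenarioGridConfig

__all__ = ["RunConfig", "load_run_config", "derive_seeds"]

_SEED_NAMES = ("population_train", "population_test", "weights_semimechanistic",
               "weights_blackbox", "plsr")


def derive_seeds(master_seed: int) -> dict[str, int]:
    """Fan a master seed out into named, independent sub-seeds (< 2^31)."""
    state = np.random.SeedSequence(master_seed).generate_state(
        len(_SEED_NAMES), dtype=np.uint32)
    return {name: int(s % (2 ** 31)) for name, s in zip(_SEED_NAMES, state)}


@dataclass(frozen=True)
class EmulatorWidths:
    recurrent_width: int = 16
    dense_width: int = 32

    def __post_init__(self) -> None:
        if self.recurrent_width < 1 or self.dense_width < 1:
            raise ValueError("widths must be >= 1")


@dataclass(frozen=True)
class RunConfig:
    seed: int = 0
    population_size: int = 100
    population_cv: float = 0.20
    grid: ScenarioGridConfig = field(default_factory=ScenarioGridConfig)
    sim: SimConfig = field(default_factory=SimConfig)
    widths: EmulatorWidths = field(default_factory=EmulatorWidths)
    train: TrainConfig = field(default_factory=TrainConfig)
    plsr: PLSRConfig = field(default_factory=PLSRConfig)

    @property
    def seeds(self) -> dict[str, int]:
        return derive_seeds(self.seed)

    def population_config(self, role: str) -> ParameterDistributionConfig:
        return ParameterDistributionConfig(
            size=self.population_size,
            cv=self.population_cv,
            seed=self.seeds[f"population_{role}"],
        )

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _build(cls, doc: dict | None):
    doc = doc or {}
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(doc) - names
    if unknown:
        raise ValueError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    if cls is ScenarioGridConfig:
        doc = {k: tuple(v) if isinstance(v, list) else v for k, v in doc.items()}
    return cls(**doc)


def load_run_config(path) -> RunConfig:
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    return RunConfig(
        seed=int(doc.get("seed", 0)),
        population_size=int(doc.get("population", {}).get("size", 100)),
        population_cv=float(doc.get("population", {}).get("cv", 0.20)),
        grid=_build(ScenarioGridConfig, doc.get("scenario_grid")),
        sim=_build(SimConfig, doc.get("sim")),
        widths=_build(EmulatorWidths, doc.get("emulator")),
        train=_build(TrainConfig, doc.get("train")),
        plsr=_build(PLSRConfig, doc.get("plsr")),
    )
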