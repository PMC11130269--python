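"""Virtual-population generation.

A virtual subject is one draw of all kinetic parameters (binding for both
ligands, both PK blocks, biophase equilibration).  The reference study built
its population from bootstrap/literature joint distributions that are not
redistributable, so this module samples each parameter independently from a
log-normal distribution centred on the shipped stand-in defaults with a
configurable coefficient of variation.  Log-scale sampling guarantees
positivity by construction; bounded parameters (bioavailability f, agonism
alpha) are clipped into their domains after sampling.

Seeding: a single master seed spawns one independent child stream per
subject via numpy's SeedSequence, so populations are reproducible and can be
extended without disturbing earlier draws.
"""

from __future__ import annotations

import dataclasses
import importlib.resources
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml

from .params import (
    LigandBindingParams,
    NaloxonePKParams,
    OpioidPKParams,
    VirtualSubject,
)

__all__ = [
    "ParameterDistributionConfig",
    "default_subject",
    "sample_population",
    "population_to_frame",
    "population_from_frame",
    "save_population_csv",
    "load_population_csv",
]

# flattened parameter layout: (block, field) pairs in canonical column order
_BLOCKS = {
    "opioid_binding": ("k_on", "k_off", "n"),
    "naloxone_binding": ("k_on", "k_off", "n"),
    "opioid_pk": ("k_out", "k12", "k21", "k13", "k31", "v_c",
                  "molar_mass", "k1_biophase", "alpha"),
    "naloxone_pk": ("k_tr", "k_in", "v", "c_l", "f",
                    "molar_mass", "k1_biophase"),
}
# parameters that are structural constants rather than biological variability
_FIXED = {("opioid_pk", "molar_mass"), ("naloxone_pk", "molar_mass"),
          ("opioid_pk", "alpha")}

_BLOCK_TYPES = {
    "opioid_binding": LigandBindingParams,
    "naloxone_binding": LigandBindingParams,
    "opioid_pk": OpioidPKParams,
    "naloxone_pk": NaloxonePKParams,
}


def _load_defaults() -> dict:
    ref = importlib.resources.files("naloxsim.data") / "default_parameters.yaml"
    return yaml.safe_load(ref.read_text())


def default_subject() -> VirtualSubject:
    """The shipped stand-in parameter set (documented non-fitted values)."""
    doc = _load_defaults()
    return VirtualSubject(**{
        block: cls(**doc[block]) for block, cls in _BLOCK_TYPES.items()
    })


@dataclass(frozen=True)
class ParameterDistributionConfig:
    """Independent log-normal distributions around per-parameter locations.

    locations : flat dict ``{"block.field": value}``; missing entries fall
        back to the shipped defaults.
    cv : coefficient of variation shared by all sampled parameters, or a
        per-parameter override dict merged over the shared value.
    size : population size.
    seed : master seed for the per-subject random streams.
    """

    size: int = 2000
    cv: float = 0.20
    locations: dict = field(default_factory=dict)
    cv_overrides: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.size < 1:
            raise ValueError("population size must be >= 1")
        if self.cv < 0 or any(v < 0 for v in self.cv_overrides.values()):
            raise ValueError("coefficients of variation must be >= 0")


def _flat_locations(config: ParameterDistributionConfig) -> dict:
    defaults = _load_defaults()
    flat = {
        f"{block}.{name}": float(defaults[block][name])
        for block, names in _BLOCKS.items()
        for name in names
    }
    for key, value in config.locations.items():
        if key not in flat:
            raise ValueError(f"unknown parameter '{key}'")
        flat[key] = float(value)
    return flat


def sample_population(config: ParameterDistributionConfig) -> list[VirtualSubject]:
    """Draw ``config.size`` virtual subjects.

    Each parameter is log-normal with median equal to its configured
    location and log-scale sigma = sqrt(log(1 + cv^2)); structural constants
    (molar masses, alpha) are held fixed unless given an explicit override.
    """
    flat = _flat_locations(config)
    streams = np.random.SeedSequence(config.seed).spawn(config.size)
    subjects = []
    for ss in streams:
        rng = np.random.default_rng(ss)
        blocks = {}
        for block, names in _BLOCKS.items():
            values = {}
            for name in names:
                key = f"{block}.{name}"
                loc = flat[key]
                cv = config.cv_overrides.get(
                    key, 0.0 if (block, name) in _FIXED else config.cv
                )
                if cv > 0:
                    sigma = np.sqrt(np.log1p(cv * cv))
                    values[name] = float(loc * np.exp(rng.normal(0.0, sigma)))
                else:
                    values[name] = loc
            if block == "naloxone_pk":
                values["f"] = min(values["f"], 1.0)
            if block == "opioid_pk":
                values["alpha"] = min(max(values["alpha"], 0.0), 1.0)
            blocks[block] = _BLOCK_TYPES[block](**values)
        subjects.append(VirtualSubject(**blocks))
    return subjects


# ---------------------------------------------------------------------------
# CSV round trip: one row per subject, columns "block.field"


def population_to_frame(subjects: list[VirtualSubject]) -> pd.DataFrame:
    rows = []
    for s in subjects:
        row = {}
        for block, names in _BLOCKS.items():
            comp = getattr(s, block)
            for name in names:
                row[f"{block}.{name}"] = getattr(comp, name)
        rows.append(row)
    return pd.DataFrame(rows)


def population_from_frame(frame: pd.DataFrame) -> list[VirtualSubject]:
    subjects = []
    for _, row in frame.iterrows():
        blocks = {
            block: _BLOCK_TYPES[block](
                **{name: float(row[f"{block}.{name}"]) for name in names}
            )
            for block, names in _BLOCKS.items()
        }
        subjects.append(VirtualSubject(**blocks))
    return subjects


def save_population_csv(subjects: list[VirtualSubject], path) -> None:
    population_to_frame(subjects).to_csv(path, index=False, float_format="%.17g")


def load_population_csv(path) -> list[VirtualSubject]:
    return population_from_frame(pd.read_csv(path, float_precision="round_trip"))
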