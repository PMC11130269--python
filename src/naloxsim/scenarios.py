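"""Dosing-scenario grid, feature encoding, and training-set construction.

The study design crosses four dosing factors — opioid dose level, number of
naloxone administrations, the ventilation threshold that triggers rescue,
and the delay between administrations — into a full factorial grid (the
default 12 x 5 x 3 x 3 = 540 cells).  Each (virtual subject, scenario) pair
is one training record: the input is a min-max-normalized feature vector
split into three blocks (opioid PK + dose, naloxone PK + dosing factors,
receptor binding), the target is the mechanistic occupancy trajectory.
"""

from __future__ import annotations

import dataclasses
import hashlib
import itertools
import json
import logging
from dataclasses import dataclass, field
from typing import Sequence

import h5py
import numpy as np

from .mechanistic import SimulationError, simulate_subject
from .params import DosingScenario, SimConfig, VirtualSubject

logger = logging.getLogger(__name__)

__all__ = [
    "ScenarioGridConfig",
    "FeatureBounds",
    "FeatureEncoding",
    "EmulatorDataset",
    "build_scenario_grid",
    "encode_inputs",
    "build_dataset",
    "dataset_index",
]

OPIOID_FEATURES = ("k_out", "k12", "k21", "k13", "k31", "v_c", "k1_biophase")
NALOXONE_FEATURES = ("k_tr", "k_in", "v", "c_l", "f", "k1_biophase")
SCENARIO_NALOXONE_FEATURES = (
    "n_naloxone_doses", "naloxone_dose_per_admin", "threshold_frac",
    "inter_dose_delay",
)
BINDING_FEATURES = ("op.k_on", "op.k_off", "op.n", "nx.k_on", "nx.k_off", "nx.n")


@dataclass(frozen=True)
class ScenarioGridConfig:
    """Factor levels of the dosing grid.

    Defaults reproduce the 540-cell design: 12 opioid dose levels evenly
    spaced over 0.013-0.157 mg, 0-4 naloxone doses, rescue thresholds of
    40/25/10% of baseline ventilation, inter-dose delays of 2/3/5 min, with
    4 mg naloxone per administration.
    """

    opioid_doses: tuple = tuple(np.round(np.linspace(0.013, 0.157, 12), 6))
    naloxone_counts: tuple = (0, 1, 2, 3, 4)
    thresholds: tuple = (0.40, 0.25, 0.10)
    delays: tuple = (2.0, 3.0, 5.0)
    naloxone_dose_per_admin: float = 4.0

    def __post_init__(self) -> None:
        for name in ("opioid_doses", "naloxone_counts", "thresholds", "delays"):
            if len(getattr(self, name)) == 0:
                raise ValueError(f"factor list '{name}' must be non-empty")

    @property
    def n_scenarios(self) -> int:
        return (len(self.opioid_doses) * len(self.naloxone_counts)
                * len(self.thresholds) * len(self.delays))


def build_scenario_grid(config: ScenarioGridConfig | None = None) -> list[DosingScenario]:
    """Full Cartesian product of the factor lists, lexicographic in
    (dose, count, threshold, delay) order."""
    config = config or ScenarioGridConfig()
    return [
        DosingScenario(
            opioid_dose=dose,
            n_naloxone_doses=count,
            naloxone_dose_per_admin=config.naloxone_dose_per_admin,
            threshold_frac=thr,
            inter_dose_delay=delay,
        )
        for dose, count, thr, delay in itertools.product(
            config.opioid_doses, config.naloxone_counts,
            config.thresholds, config.delays,
        )
    ]


# ---------------------------------------------------------------------------
# Feature extraction and normalization


def _raw_blocks(subject: VirtualSubject, scenario: DosingScenario):
    op = subject.opioid_pk
    nx = subject.naloxone_pk
    opioid = np.array([getattr(op, f) for f in OPIOID_FEATURES]
                      + [scenario.opioid_dose])
    naloxone = np.array(
        [getattr(nx, f) for f in NALOXONE_FEATURES]
        + [float(scenario.n_naloxone_doses), scenario.naloxone_dose_per_admin,
           scenario.threshold_frac, scenario.inter_dose_delay]
    )
    ob, nb = subject.opioid_binding, subject.naloxone_binding
    binding = np.array([ob.k_on, ob.k_off, ob.n, nb.k_on, nb.k_off, nb.n])
    return opioid, naloxone, binding


FEATURE_NAMES = {
    "opioid_block": OPIOID_FEATURES + ("opioid_dose",),
    "naloxone_block": NALOXONE_FEATURES + SCENARIO_NALOXONE_FEATURES,
    "binding_block": BINDING_FEATURES,
}


@dataclass
class FeatureBounds:
    """Per-feature min-max normalization bounds, one (lo, hi) pair per block
    feature.  Features with zero span encode to 0."""

    opioid: np.ndarray    # shape (2, 8)
    naloxone: np.ndarray  # shape (2, 10)
    binding: np.ndarray   # shape (2, 6)

    def __post_init__(self) -> None:
        self._warned: set = set()

    @classmethod
    def from_data(
        cls,
        subjects: Sequence[VirtualSubject],
        scenarios: Sequence[DosingScenario],
    ) -> "FeatureBounds":
        """Bounds covering the empirical range of the provided subjects and
        scenario factor levels."""
        subj_raw = [_raw_blocks(s, scenarios[0]) for s in subjects]
        scen_raw = [_raw_blocks(subjects[0], sc) for sc in scenarios]
        blocks = []
        for i in range(3):
            stacked = np.array([r[i] for r in subj_raw] + [r[i] for r in scen_raw])
            blocks.append(np.array([stacked.min(axis=0), stacked.max(axis=0)]))
        return cls(*blocks)

    def _norm(self, raw: np.ndarray, bounds: np.ndarray, block: str) -> np.ndarray:
        lo, hi = bounds
        span = hi - lo
        if block not in self._warned and (
                np.any(raw < lo - 1e-12) or np.any(raw > hi + 1e-12)):
            self._warned.add(block)
            logger.warning(
                "feature(s) outside bounds in %s block; clipping "
                "(reported once per block)", block)
        clipped = np.clip(raw, lo, hi)
        out = np.zeros_like(raw)
        nz = span > 0
        out[nz] = (clipped[nz] - lo[nz]) / span[nz]
        return out

    def encode(self, subject: VirtualSubject, scenario: DosingScenario) -> "FeatureEncoding":
        op_raw, nx_raw, bind_raw = _raw_blocks(subject, scenario)
        return FeatureEncoding(
            opioid_block=self._norm(op_raw, self.opioid, "opioid"),
            naloxone_block=self._norm(nx_raw, self.naloxone, "naloxone"),
            binding_block=self._norm(bind_raw, self.binding, "binding"),
        )


@dataclass
class FeatureEncoding:
    """Normalized feature vector, partitioned into the three input blocks."""

    opioid_block: np.ndarray
    naloxone_block: np.ndarray
    binding_block: np.ndarray

    @property
    def concatenated(self) -> np.ndarray:
        """Single flat vector (the black-box network's input layout)."""
        return np.concatenate(
            [self.opioid_block, self.naloxone_block, self.binding_block]
        )


def encode_inputs(
    subject: VirtualSubject, scenario: DosingScenario, bounds: FeatureBounds
) -> FeatureEncoding:
    """Min-max normalize one (subject, scenario) pair into the three blocks."""
    return bounds.encode(subject, scenario)


# ---------------------------------------------------------------------------
# Dataset construction


def dataset_index(
    subjects: Sequence[VirtualSubject], scenarios: Sequence[DosingScenario]
) -> list[tuple[int, int]]:
    """The (subject index, scenario index) pairs a dataset will contain:
    the full cross product, subjects outermost."""
    return [(i, j) for i in range(len(subjects)) for j in range(len(scenarios))]


@dataclass
class EmulatorDataset:
    """Materialized training/evaluation set.

    Arrays are aligned row-wise: inputs_* have one row per record, targets
    holds the occupancy trajectory on the shared output grid, and index maps
    each row back to its (subject, scenario) pair.
    """

    inputs_opioid: np.ndarray
    inputs_naloxone: np.ndarray
    inputs_binding: np.ndarray
    targets: np.ndarray
    index: np.ndarray          # (n, 2) int
    times: np.ndarray
    bounds: FeatureBounds
    metadata: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return self.targets.shape[0]

    @property
    def inputs_concat(self) -> np.ndarray:
        return np.concatenate(
            [self.inputs_opioid, self.inputs_naloxone, self.inputs_binding], axis=1
        )

    def save(self, path) -> None:
        with h5py.File(path, "w") as fh:
            grp = fh.create_group("inputs")
            grp.create_dataset("opioid_block", data=self.inputs_opioid)
            grp.create_dataset("naloxone_block", data=self.inputs_naloxone)
            grp.create_dataset("binding_block", data=self.inputs_binding)
            fh.create_dataset("targets", data=self.targets)
            fh.create_dataset("index", data=self.index)
            fh.create_dataset("times", data=self.times)
            b = fh.create_group("bounds")
            b.create_dataset("opioid", data=self.bounds.opioid)
            b.create_dataset("naloxone", data=self.bounds.naloxone)
            b.create_dataset("binding", data=self.bounds.binding)
            fh.attrs["metadata"] = json.dumps(self.metadata)

    @classmethod
    def load(cls, path) -> "EmulatorDataset":
        with h5py.File(path, "r") as fh:
            return cls(
                inputs_opioid=fh["inputs/opioid_block"][:],
                inputs_naloxone=fh["inputs/naloxone_block"][:],
                inputs_binding=fh["inputs/binding_block"][:],
                targets=fh["targets"][:],
                index=fh["index"][:],
                times=fh["times"][:],
                bounds=FeatureBounds(
                    opioid=fh["bounds/opioid"][:],
                    naloxone=fh["bounds/naloxone"][:],
                    binding=fh["bounds/binding"][:],
                ),
                metadata=json.loads(fh.attrs["metadata"]),
            )


def config_hash(obj) -> str:
    """Stable short hash of a (nested) configuration for cache manifests."""
    def default(o):
        if dataclasses.is_dataclass(o):
            return dataclasses.asdict(o)
        if isinstance(o, (np.ndarray,)):
            return o.tolist()
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        return str(o)

    blob = json.dumps(obj, sort_keys=True, default=default).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def build_dataset(
    subjects: Sequence[VirtualSubject],
    scenarios: Sequence[DosingScenario],
    config: SimConfig | None = None,
    bounds: FeatureBounds | None = None,
    metadata: dict | None = None,
) -> EmulatorDataset:
    """Simulate every (subject, scenario) pair and assemble the dataset.

    Targets are the mechanistic occupancy trajectories on the output grid.
    Records whose simulation fails are excluded, with the offending pair
    logged; the returned index always refers to the original positions.
    """
    if not subjects or not scenarios:
        raise ValueError("subjects and scenarios must be non-empty")
    config = config or SimConfig()
    bounds = bounds or FeatureBounds.from_data(subjects, scenarios)
    pairs = dataset_index(subjects, scenarios)
    rows_op, rows_nx, rows_bind, rows_y, kept = [], [], [], [], []
    for i, j in pairs:
        try:
            tc = simulate_subject(subjects[i], scenarios[j], config)
        except SimulationError as err:
            logger.warning("excluding failed record subject=%d scenario=%d: %s",
                           i, j, err)
            continue
        enc = bounds.encode(subjects[i], scenarios[j])
        rows_op.append(enc.opioid_block)
        rows_nx.append(enc.naloxone_block)
        rows_bind.append(enc.binding_block)
        rows_y.append(tc.r_op)
        kept.append((i, j))
    times = SimConfig(horizon=config.horizon, output_step=config.output_step).grid
    meta = dict(metadata or {})
    meta.setdefault("sim_config", dataclasses.asdict(config))
    meta.setdefault("n_subjects", len(subjects))
    meta.setdefault("n_scenarios", len(scenarios))
    return EmulatorDataset(
        inputs_opioid=np.array(rows_op),
        inputs_naloxone=np.array(rows_nx),
        inputs_binding=np.array(rows_bind),
        targets=np.array(rows_y),
        index=np.array(kept, dtype=int),
        times=times,
        bounds=bounds,
        metadata=meta,
    )
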