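"""Parameter containers for the opioid-naloxone PK-PD system.

The mechanistic model couples four parameter blocks per virtual subject:
competitive receptor binding for the agonist (opioid) and antagonist
(naloxone), a three-compartment IV-bolus opioid pharmacokinetic block, and a
transit-compartment intranasal naloxone pharmacokinetic block.  Rate-constant
units follow pharmacometric convention: PK rates in 1/min, receptor binding
rates on the seconds time scale used by the binding kinetics (k_on in
pM^-n s^-1, k_off in s^-1).  The simulator converts everything to a common
seconds axis internally.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import yaml

__all__ = [
    "LigandBindingParams",
    "NaloxonePKParams",
    "OpioidPKParams",
    "VirtualSubject",
    "DosingScenario",
    "SimConfig",
    "TimeCourse",
    "load_subject_yaml",
    "dump_subject_yaml",
]


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise ValueError(msg)


@dataclass(frozen=True)
class LigandBindingParams:
    """Receptor association/dissociation kinetics for one ligand.

    k_on : association rate, per pM^n per second.
    k_off : dissociation rate, per second.
    n : Hill-type slope of the concentration-effect relationship.
    """

    k_on: float
    k_off: float
    n: float = 1.0

    def __post_init__(self) -> None:
        _require(self.k_on > 0, f"k_on must be > 0, got {self.k_on}")
        _require(self.k_off > 0, f"k_off must be > 0, got {self.k_off}")
        _require(self.n > 0, f"n must be > 0, got {self.n}")

    @property
    def kd(self) -> float:
        """Equilibrium constant k_off/k_on (pM^n)."""
        return self.k_off / self.k_on


@dataclass(frozen=True)
class NaloxonePKParams:
    """Intranasal naloxone PK: two transit compartments feeding a central one.

    k_tr, k_in : transit and absorption rate constants (1/min).
    v : volume of distribution (L).
    c_l : total clearance (L/min).
    f : bioavailability fraction of the intranasal dose.
    molar_mass : g/mol, used to convert central concentration to pM.
    k1_biophase : effect-site equilibration rate (1/min).
    """

    k_tr: float
    k_in: float
    v: float
    c_l: float
    f: float
    molar_mass: float
    k1_biophase: float

    def __post_init__(self) -> None:
        for name in ("k_tr", "k_in", "v", "c_l", "molar_mass", "k1_biophase"):
            _require(getattr(self, name) > 0, f"{name} must be > 0")
        _require(0 < self.f <= 1, f"bioavailability f must be in (0, 1], got {self.f}")


@dataclass(frozen=True)
class OpioidPKParams:
    """IV-bolus opioid PK: three compartments (one central, two peripheral).

    k_out : elimination rate from the central compartment (1/min).
    k12, k21, k13, k31 : inter-compartment transfer rates (1/min).
    v_c : central compartment volume (L).
    molar_mass : g/mol.
    k1_biophase : effect-site equilibration rate (1/min).
    alpha : agonism coefficient in the ventilation map v_f = 1 - alpha * r_op.
    """

    k_out: float
    k12: float
    k21: float
    k13: float
    k31: float
    v_c: float
    molar_mass: float
    k1_biophase: float
    alpha: float = 1.0

    def __post_init__(self) -> None:
        for name in ("k_out", "k12", "k21", "k13", "k31", "v_c", "molar_mass", "k1_biophase"):
            _require(getattr(self, name) > 0, f"{name} must be > 0")
        _require(0 <= self.alpha <= 1, f"alpha must be in [0, 1], got {self.alpha}")

    def rate_matrix_per_s(self) -> np.ndarray:
        """3x3 rate matrix (1/s) of the linear compartment system.

        d/dt [p_f, p_f2, p_f3] = A @ [p_f, p_f2, p_f3] with amounts in mg.
        """
        k_out, k12, k21, k13, k31 = (
            x / 60.0 for x in (self.k_out, self.k12, self.k21, self.k13, self.k31)
        )
        return np.array(
            [
                [-(k12 + k13 + k_out), k21, k31],
                [k12, -k21, 0.0],
                [k13, 0.0, -k31],
            ]
        )


@dataclass(frozen=True)
class VirtualSubject:
    """One sampled kinetic parameter set defining a simulated individual."""

    opioid_binding: LigandBindingParams
    naloxone_binding: LigandBindingParams
    opioid_pk: OpioidPKParams
    naloxone_pk: NaloxonePKParams


@dataclass(frozen=True)
class DosingScenario:
    """One cell of the dosing grid.

    opioid_dose : IV bolus dose (mg).
    n_naloxone_doses : number of intranasal naloxone administrations (0-4).
    naloxone_dose_per_admin : mg per administration.
    threshold_frac : fraction of baseline minute ventilation that triggers
        the first naloxone administration.
    inter_dose_delay : minutes between consecutive administrations.
    """

    opioid_dose: float
    n_naloxone_doses: int
    naloxone_dose_per_admin: float
    threshold_frac: float
    inter_dose_delay: float

    def __post_init__(self) -> None:
        _require(self.opioid_dose >= 0, "opioid_dose must be >= 0")
        _require(
            int(self.n_naloxone_doses) == self.n_naloxone_doses and self.n_naloxone_doses >= 0,
            "n_naloxone_doses must be a non-negative integer",
        )
        _require(self.naloxone_dose_per_admin >= 0, "naloxone_dose_per_admin must be >= 0")
        _require(0 < self.threshold_frac < 1, "threshold_frac must be in (0, 1)")
        _require(self.inter_dose_delay > 0, "inter_dose_delay must be > 0")


@dataclass(frozen=True)
class SimConfig:
    """Numerical settings for one simulation.

    horizon and output_step in seconds; rtol/atol are integrator tolerances;
    event_tol bounds the localization error of the threshold crossing.
    """

    horizon: float = 3600.0
    output_step: float = 10.0
    rtol: float = 1e-8
    atol: float = 1e-10
    event_tol: float = 1.0

    def __post_init__(self) -> None:
        _require(self.horizon > 0, "horizon must be > 0")
        _require(self.output_step > 0, "output_step must be > 0")
        _require(self.rtol > 0 and self.atol > 0 and self.event_tol > 0,
                 "tolerances must be > 0")

    @property
    def grid(self) -> np.ndarray:
        """Fixed output time grid in seconds (inclusive of both endpoints)."""
        n = int(round(self.horizon / self.output_step))
        return np.linspace(0.0, n * self.output_step, n + 1)


@dataclass
class TimeCourse:
    """Simulated (or predicted) trajectories on a fixed time grid."""

    times: np.ndarray
    r_op: np.ndarray
    v_f: np.ndarray
    naloxone_admin_times: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.r_op = np.asarray(self.r_op, dtype=float)
        self.v_f = np.asarray(self.v_f, dtype=float)
        self.naloxone_admin_times = np.asarray(self.naloxone_admin_times, dtype=float)
        _require(self.times.ndim == 1 and np.all(np.diff(self.times) > 0),
                 "times must be strictly increasing")
        _require(self.r_op.shape == self.times.shape, "r_op/times length mismatch")
        _require(self.v_f.shape == self.times.shape, "v_f/times length mismatch")

    def to_csv(self, path) -> None:
        """Write time_s, r_op, v_f columns; administration times go in a
        commented metadata header."""
        admins = ",".join(f"{t:.6f}" for t in self.naloxone_admin_times)
        with open(path, "w") as fh:
            fh.write(f"# naloxone_admin_times_s: {admins}\n")
            fh.write("time_s,r_op,v_f\n")
            for t, r, v in zip(self.times, self.r_op, self.v_f):
                fh.write(f"{t:.6f},{r:.10g},{v:.10g}\n")

    @classmethod
    def from_csv(cls, path) -> "TimeCourse":
        admins: list[float] = []
        rows: list[tuple[float, float, float]] = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if line.startswith("# naloxone_admin_times_s:"):
                    payload = line.split(":", 1)[1].strip()
                    if payload:
                        admins = [float(x) for x in payload.split(",")]
                elif line and not line.startswith("#") and not line.startswith("time_s"):
                    t, r, v = line.split(",")
                    rows.append((float(t), float(r), float(v)))
        arr = np.array(rows)
        return cls(arr[:, 0], arr[:, 1], arr[:, 2], np.array(admins))


# ---------------------------------------------------------------------------
# YAML parameter files: named blocks matching the four parameter components.

_BLOCK_TYPES = {
    "opioid_binding": LigandBindingParams,
    "naloxone_binding": LigandBindingParams,
    "opioid_pk": OpioidPKParams,
    "naloxone_pk": NaloxonePKParams,
}


def load_subject_yaml(path) -> VirtualSubject:
    """Read a VirtualSubject from a YAML file with blocks opioid_binding,
    naloxone_binding, opioid_pk, naloxone_pk."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    kwargs = {}
    for block, cls in _BLOCK_TYPES.items():
        if block not in doc:
            raise ValueError(f"parameter file missing block '{block}'")
        fields = {f.name for f in dataclasses.fields(cls)}
        kwargs[block] = cls(**{k: v for k, v in doc[block].items() if k in fields})
    return VirtualSubject(**kwargs)


def dump_subject_yaml(subject: VirtualSubject, path) -> None:
    doc = {
        block: dataclasses.asdict(getattr(subject, block))
        for block in _BLOCK_TYPES
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)
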