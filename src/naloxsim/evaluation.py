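"""Population-level summaries and model-comparison metrics.

A virtual-population run produces one minute-ventilation trajectory per
subject; the population is summarized by the pointwise median and the
2.5th/97.5th percentiles (the 95% population band).  Emulators are scored
by the RMSE of each summary curve against the mechanistic one, per scenario
and pooled over all scenarios.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .params import TimeCourse

__all__ = [
    "PopulationSummary",
    "population_percentiles",
    "rmse_summary",
    "compare_models",
]

_CURVES = ("median", "p2_5", "p97_5")


@dataclass
class PopulationSummary:
    """Pointwise median and 95% band of v_f across a virtual population."""

    times: np.ndarray
    median: np.ndarray
    p2_5: np.ndarray
    p97_5: np.ndarray

    def __post_init__(self) -> None:
        for name in _CURVES:
            arr = np.asarray(getattr(self, name), dtype=float)
            setattr(self, name, arr)
            if arr.shape != np.shape(self.times):
                raise ValueError(f"{name} length does not match times")
        if np.any(self.p2_5 > self.median + 1e-12) or np.any(
                self.median > self.p97_5 + 1e-12):
            raise ValueError("percentile ordering violated")


def _vf_matrix(timecourses) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(timecourses, np.ndarray):
        raise TypeError("pass a list of TimeCourse or (times, matrix)")
    if not timecourses:
        raise ValueError("need at least one time course")
    if isinstance(timecourses[0], TimeCourse):
        times = timecourses[0].times
        for tc in timecourses[1:]:
            if tc.times.shape != times.shape or not np.allclose(tc.times, times):
                raise ValueError("time courses are not on a common grid")
        return times, np.array([tc.v_f for tc in timecourses])
    times, mat = timecourses
    return np.asarray(times), np.asarray(mat)


def population_percentiles(timecourses) -> PopulationSummary:
    """Pointwise 2.5/50/97.5 percentiles of v_f across subjects.

    Accepts a list of TimeCourse on a common grid, or a (times, matrix)
    pair with one row per subject.
    """
    times, mat = _vf_matrix(timecourses)
    p = np.percentile(mat, [2.5, 50.0, 97.5], axis=0)
    return PopulationSummary(times=times, median=p[1], p2_5=p[0], p97_5=p[2])


def rmse_summary(pred: PopulationSummary, ref: PopulationSummary) -> dict:
    """RMSE over all time points, separately for each summary curve."""
    if pred.times.shape != ref.times.shape or not np.allclose(pred.times, ref.times):
        raise ValueError("summaries are not on a common grid")
    return {
        name: float(np.sqrt(np.mean(
            (getattr(pred, name) - getattr(ref, name)) ** 2)))
        for name in _CURVES
    }


def compare_models(
    mechanistic: dict,
    model_summaries: dict,
) -> pd.DataFrame:
    """Consolidated RMSE table.

    mechanistic : {scenario_key: PopulationSummary} reference summaries.
    model_summaries : {model_name: {scenario_key: PopulationSummary}}.

    Returns one row per (model, scenario) plus an 'overall' row per model
    pooling squared errors over every time point of every scenario.  A
    scenario missing from a model is reported with NaN RMSEs, never dropped.
    """
    rows = []
    for model_name, per_scenario in model_summaries.items():
        pooled = {name: [] for name in _CURVES}
        for key, ref in mechanistic.items():
            pred = per_scenario.get(key)
            if pred is None:
                rows.append({"model": model_name, "scenario": key,
                             **{f"rmse_{n}": np.nan for n in _CURVES},
                             "missing": True})
                continue
            errs = rmse_summary(pred, ref)
            for name in _CURVES:
                pooled[name].append(
                    (getattr(pred, name) - getattr(ref, name)) ** 2)
            rows.append({"model": model_name, "scenario": key,
                         **{f"rmse_{n}": errs[n] for n in _CURVES},
                         "missing": False})
        overall = {
            f"rmse_{name}": float(np.sqrt(np.mean(np.concatenate(vals))))
            if vals else np.nan
            for name, vals in pooled.items()
        }
        rows.append({"model": model_name, "scenario": "overall",
                     **overall, "missing": False})
    return pd.DataFrame(rows)
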