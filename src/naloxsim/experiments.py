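"""Reduced-scale emulation experiments.

The full study design (2000 subjects x 540 scenarios, multi-day training)
is summarized here by a desk-scale version that keeps the structure intact:
a 36-cell scenario sub-grid (4 opioid dose levels x 3 naloxone counts x
3 thresholds x 1 delay), populations of 100 virtual subjects, a 61-point
output grid (60 s steps over 1 h), and narrow networks (16 recurrent units,
32 dense units for the black-box).  Both architectures get the same epoch
budget, matched initialization/holdout seeds, and a cosine-annealed Adam
schedule.  The default budget of 80 epochs sits past the point where both
architectures' holdout errors have flattened under this schedule, so the
final-epoch error reflects plateau performance rather than mid-descent
ordering.

BLAS is pinned to one thread during training so runs reproduce bit-for-bit
regardless of host parallelism.
"""

from __future__ import annotations

import contextlib
from dataclasses import dataclass, field

import numpy as np

from .baseline_plsr import PLSRConfig, fit_plsr, predict_plsr
from .emulators import EmulatorSpec, TrainConfig, build_emulator, train
from .evaluation import compare_models, population_percentiles
from .params import SimConfig
from .population import ParameterDistributionConfig, sample_population
from .scenarios import (
    EmulatorDataset,
    ScenarioGridConfig,
    build_dataset,
    build_scenario_grid,
)

__all__ = [
    "reduced_scenario_config",
    "reduced_sim_config",
    "generate_reduced_datasets",
    "HeadToHeadResult",
    "head_to_head",
    "single_thread_blas",
]


def single_thread_blas():
    """Context manager pinning BLAS to one thread for exact reproducibility."""
    try:
        from threadpoolctl import threadpool_limits
        return threadpool_limits(limits=1)
    except ImportError:  # pragma: no cover
        return contextlib.nullcontext()


def reduced_scenario_config() -> ScenarioGridConfig:
    """36-cell sub-grid spanning the factor ranges of the full design."""
    return ScenarioGridConfig(
        opioid_doses=tuple(np.round(np.linspace(0.013, 0.157, 4), 6)),
        naloxone_counts=(0, 1, 2),
        thresholds=(0.40, 0.25, 0.10),
        delays=(3.0,),
    )


def reduced_sim_config() -> SimConfig:
    """One-hour horizon on a 60 s grid with tolerances adequate for
    occupancy targets accurate to ~1e-5."""
    return SimConfig(horizon=3600.0, output_step=60.0, rtol=1e-6, atol=1e-9)


def _derive_seeds(master_seed: int, n: int) -> list[int]:
    state = np.random.SeedSequence(master_seed).generate_state(n, dtype=np.uint32)
    return [int(s % (2 ** 31)) for s in state]


def generate_reduced_datasets(
    master_seed: int = 0,
    n_subjects: int = 100,
    scenario_config: ScenarioGridConfig | None = None,
    sim_config: SimConfig | None = None,
) -> tuple[EmulatorDataset, EmulatorDataset]:
    """Simulate matched train/test datasets from two disjoint populations.

    The test population is sampled with an independent seed (a new virtual
    population never seen in training); its features are normalized with the
    training bounds, as they would be in deployment.
    """
    scenario_config = scenario_config or reduced_scenario_config()
    sim_config = sim_config or reduced_sim_config()
    scenarios = build_scenario_grid(scenario_config)
    train_seed, test_seed = _derive_seeds(master_seed, 2)
    pop_train = sample_population(
        ParameterDistributionConfig(size=n_subjects, seed=train_seed))
    pop_test = sample_population(
        ParameterDistributionConfig(size=n_subjects, seed=test_seed))
    ds_train = build_dataset(pop_train, scenarios, sim_config,
                             metadata={"population_seed": train_seed,
                                       "role": "train"})
    ds_test = build_dataset(pop_test, scenarios, sim_config,
                            bounds=ds_train.bounds,
                            metadata={"population_seed": test_seed,
                                      "role": "test"})
    return ds_train, ds_test


@dataclass
class HeadToHeadResult:
    """Outcome of one reduced head-to-head comparison."""

    final_holdout: dict = field(default_factory=dict)   # (arch, seed) -> error
    holdout_curves: dict = field(default_factory=dict)  # (arch, seed) -> list
    overall_rmse: dict = field(default_factory=dict)    # model -> {curve: rmse}
    plsr_components: int = 0
    report = None  # full compare_models DataFrame

    def semi_wins_every_seed(self) -> bool:
        seeds = {s for (_, s) in self.final_holdout}
        return all(
            self.final_holdout[("semimechanistic", s)]
            < self.final_holdout[("blackbox", s)]
            for s in seeds
        )


def head_to_head(
    ds_train: EmulatorDataset,
    ds_test: EmulatorDataset,
    seeds: tuple[int, ...] = (0, 1, 2),
    epochs: int = 80,
    recurrent_width: int = 16,
    dense_width: int = 32,
    learning_rate: float = 3e-3,
    batch_size: int = 64,
    plsr_config: PLSRConfig | None = None,
) -> HeadToHeadResult:
    """Train both architectures at matched budgets across seeds, then score
    every model (plus the PLSR baseline) by population-summary RMSE on the
    test population.

    RMSE is computed per scenario from the pointwise median/2.5th/97.5th
    percentile curves of predicted vs mechanistic minute ventilation, pooled
    over scenarios; emulator predictions use the first seed's models.
    """
    dims = (ds_train.inputs_opioid.shape[1], ds_train.inputs_naloxone.shape[1],
            ds_train.inputs_binding.shape[1])
    T = ds_train.targets.shape[1]
    result = HeadToHeadResult()
    first_models = {}
    with single_thread_blas():
        for seed in seeds:
            for arch in ("semimechanistic", "blackbox"):
                spec = EmulatorSpec(arch, T, dims, dense_width=dense_width,
                                    recurrent_width=recurrent_width, seed=seed)
                model = build_emulator(spec)
                rec = train(model, ds_train,
                            TrainConfig(epochs=epochs, batch_size=batch_size,
                                        learning_rate=learning_rate, seed=seed))
                result.final_holdout[(arch, seed)] = rec.holdout_errors[-1]
                result.holdout_curves[(arch, seed)] = list(rec.holdout_errors)
                if seed == seeds[0]:
                    first_models[arch] = model
        plsr = fit_plsr(ds_train, plsr_config
                        or PLSRConfig(max_components=10, folds=15, seed=seeds[0]))
        result.plsr_components = plsr.n_components

        blocks = (ds_test.inputs_opioid, ds_test.inputs_naloxone,
                  ds_test.inputs_binding)
        preds = {arch: m.predict_occupancy(blocks)
                 for arch, m in first_models.items()}
        preds["plsr"] = predict_plsr(plsr, ds_test)

    alpha = 1.0  # full agonist; occupancy maps to v_f = 1 - r_op
    def to_vf(r):
        return np.clip(1.0 - alpha * r, 0.0, 1.0)

    scen_ids = ds_test.index[:, 1]
    mech, per_model = {}, {name: {} for name in preds}
    for sc in np.unique(scen_ids):
        mask = scen_ids == sc
        mech[int(sc)] = population_percentiles(
            (ds_test.times, to_vf(ds_test.targets[mask])))
        for name, p in preds.items():
            per_model[name][int(sc)] = population_percentiles(
                (ds_test.times, to_vf(p[mask])))
    report = compare_models(mech, per_model)
    result.report = report
    overall = report[report.scenario == "overall"]
    for _, row in overall.iterrows():
        result.overall_rmse[row["model"]] = {
            "median": row["rmse_median"],
            "p2_5": row["rmse_p2_5"],
            "p97_5": row["rmse_p97_5"],
        }
    return result
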