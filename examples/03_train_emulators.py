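"""Train both emulator architectures on a small simulated dataset.

Builds a 20-subject x 12-scenario dataset from the mechanistic simulator,
trains the black-box and semi-mechanistic networks for the same number of
epochs, and prints their per-epoch holdout errors (squared occupancy error
summed over time points, averaged over records).
"""

import numpy as np

from naloxsim import SimConfig
from naloxsim.emulators import EmulatorSpec, TrainConfig, build_emulator, train
from naloxsim.population import ParameterDistributionConfig, sample_population
from naloxsim.scenarios import ScenarioGridConfig, build_dataset, build_scenario_grid

scenarios = build_scenario_grid(ScenarioGridConfig(
    opioid_doses=(0.013, 0.085, 0.157),
    naloxone_counts=(0, 1),
    thresholds=(0.40, 0.10),
    delays=(3.0,),
))
population = sample_population(ParameterDistributionConfig(size=20, seed=1))
dataset = build_dataset(population, scenarios,
                        SimConfig(output_step=120.0, rtol=1e-6, atol=1e-9))
print(f"dataset: {len(dataset)} records, {dataset.targets.shape[1]} time points")

dims = (dataset.inputs_opioid.shape[1], dataset.inputs_naloxone.shape[1],
        dataset.inputs_binding.shape[1])
for arch in ("blackbox", "semimechanistic"):
    spec = EmulatorSpec(arch, dataset.targets.shape[1], dims,
                        dense_width=16, recurrent_width=8, seed=0)
    model = build_emulator(spec)
    record = train(model, dataset, TrainConfig(epochs=10, batch_size=16,
                                               learning_rate=5e-3, seed=0))
    errs = " ".join(f"{e:.3f}" for e in record.holdout_errors)
    print(f"{arch:16s} holdout errors per epoch: {errs}")

# Each epoch withholds a fresh random 10% of the records; falling numbers
# mean the network is learning the simulator's parameter-to-trajectory map.
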