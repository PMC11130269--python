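import numpy as np
import pytest

from naloxsim import DosingScenario, SimConfig
from naloxsim.population import default_subject


@pytest.fixture(scope="session")
def subject():
    return default_subject()


@pytest.fixture
def rescue_scenario():
    """0.11 mg IV opioid, one 4 mg intranasal naloxone dose at the 25%
    ventilation threshold."""
    return DosingScenario(
        opioid_dose=0.11,
        n_naloxone_doses=1,
        naloxone_dose_per_admin=4.0,
        threshold_frac=0.25,
        inter_dose_delay=3.0,
    )


@pytest.fixture
def fast_sim():
    """Coarse, cheap integration settings for tests that only need shape."""
    return SimConfig(horizon=1800.0, output_step=30.0, rtol=1e-6, atol=1e-9)


@pytest.fixture(scope="session")
def reduced_experiment():
    """The scaled-down head-to-head experiment shared by the training-order
    and baseline-order acceptance checks: 100-subject train/test populations
    on a 36-cell scenario sub-grid, both architectures trained for the same
    epoch budget across three seeds, plus the PLSR baseline.

    Expensive (several minutes); computed once per session.
    """
    from naloxsim.experiments import generate_reduced_datasets, head_to_head

    ds_train, ds_test = generate_reduced_datasets(master_seed=0, n_subjects=100)
    return head_to_head(ds_train, ds_test, seeds=(0, 1, 2), epochs=80)
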