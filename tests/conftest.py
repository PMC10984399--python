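import numpy as np
import pytest

from evofit.study_design import load_packaged_design
from evofit.synthetic_assays import SimulationConfig, TrueParameters, simulate_experiment


@pytest.fixture(scope="session")
def design():
    return load_packaged_design()


@pytest.fixture(scope="session")
def null_truth():
    """All fixed effects zero, variance components at realistic magnitudes."""
    return TrueParameters()


@pytest.fixture(scope="session")
def simulated_dataset(design, null_truth):
    """One full simulated experiment (raw counts + truth) under the null."""
    cfg = SimulationConfig(design=design, truth=null_truth, seed=1234)
    counts, truth_table, info = simulate_experiment(cfg)
    return counts, truth_table, info


@pytest.fixture(scope="session")
def effect_frame(design, simulated_dataset):
    """Scored effect-size table for the simulated dataset (80 rows)."""
    from evofit.effect_sizes import effect_size_table, effects_to_frame
    from evofit.fitness_scores import score_dataset

    counts, _, _ = simulated_dataset
    scores = score_dataset(counts)
    effects, missing = effect_size_table(scores, design)
    assert not missing
    return effects_to_frame(effects)


@pytest.fixture
def rng():
    return np.random.default_rng(2026)
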