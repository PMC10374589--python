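import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for helpers.py

from refdecode.pipeline import (
    PipelineConfig,
    fit_participant_betas,
    simulate_cohort_in_memory,
)


@pytest.fixture(scope="session")
def tiny_config():
    """Desk-scale cohort: 12^3 grid, 6 runs of 17 trials."""
    return PipelineConfig(
        seed=11,
        n_participants=2,
        n_runs=6,
        n_trials=17,
        grid_shape=(12, 12, 12),
        effect_size=1.0,
        error_rate=0.0,
        saccade_rate=0.0,
    )


@pytest.fixture(scope="session")
def tiny_cohort(tiny_config):
    geometry, cohort = simulate_cohort_in_memory(tiny_config)
    return geometry, cohort


@pytest.fixture(scope="session")
def tiny_betas(tiny_config, tiny_cohort):
    """Run-wise GLM betas for the first participant of the tiny cohort."""
    geometry, cohort = tiny_cohort
    part = cohort[0]
    betas = fit_participant_betas(
        part["design"], part["runs"], geometry.brain_mask
    )
    return geometry, part, betas


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
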