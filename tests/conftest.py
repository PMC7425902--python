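import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from risky_defaults.experiment_simulator import (
    DesignSpec,
    ScenarioSpec,
    simulate_experiment,
)
from risky_defaults.lottery_model import ModelParams

#: mean preliminary-experiment estimates used to generate stimuli
GEN_PARAMS = ModelParams(beta=4.38, u=0.56)

#: reduced design used by most analysis tests (fast, keeps the 3x3 balance)
SMALL_DESIGN = DesignSpec(
    n_subjects=8, n_blocks=9, trials_per_block=12, priming_trials=24
)


@pytest.fixture(scope="session")
def learned_trials():
    return simulate_experiment(
        SMALL_DESIGN, ScenarioSpec(hypothesis="learned"), seed=101
    )


@pytest.fixture(scope="session")
def null_trials():
    return simulate_experiment(SMALL_DESIGN, ScenarioSpec(hypothesis="none"), seed=202)


@pytest.fixture(scope="session")
def natural_trials():
    return simulate_experiment(
        SMALL_DESIGN, ScenarioSpec(hypothesis="natural"), seed=303
    )
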