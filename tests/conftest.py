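import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import ewalearn as ew

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def tiny_fixture():
    return ew.make_fixture("tiny")


@pytest.fixture(scope="session")
def payoff_fixture():
    return ew.make_fixture("payoff-biased")


@pytest.fixture(scope="session")
def tiny_learner(tiny_fixture):
    """Realized generating parameters of the tiny fixture's simulation run."""
    cfg, _ = tiny_fixture
    info = ew.RosterInfo(cfg.roster)
    rng = np.random.default_rng(cfg.seed)
    return cfg.true_params.draw_individuals(info.ages_std, rng, info.ids)
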