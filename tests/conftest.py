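import warnings

import pytest
from hypothesis import HealthCheck, settings

import dancedsp as d

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def base_pair():
    return (
        d.DanceSequence.from_string("LRUDRL"),
        d.DanceSequence.from_string("RULURD"),
    )


@pytest.fixture(scope="session")
def novel_pair():
    return (
        d.DanceSequence.from_string("LRDURL"),
        d.DanceSequence.from_string("DRULUR"),
    )


@pytest.fixture(scope="session")
def tiny_session(base_pair, novel_pair):
    """One short simulated block (3 Go per sequence + 1 NoGo, 4 channels)."""
    schedule = d.schedule_session(
        base_pair, novel_pair, n_training=1, n_test=0, seed=3,
        n_go_per_seq=3, n_nogo=1,
    )
    params = d.SimParams(n_channels=4, seed=7)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return d.simulate_session(schedule, params)


@pytest.fixture(scope="session")
def tiny_config():
    """Pipeline config small enough for repeated end-to-end runs."""
    cfg = d.default_config()
    cfg["task"].update(
        n_training_blocks=1, n_test_blocks=0, n_go_per_seq=2, n_nogo=1
    )
    cfg["simulate"].update(n_channels=3)
    cfg["seed"] = 11
    return cfg
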