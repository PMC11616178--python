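import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=100,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def pairs():
    from ctxbind import build_context_pairs

    return build_context_pairs()


@pytest.fixture(scope="session")
def basic_set():
    from ctxbind import build_basic_trial_set

    return build_basic_trial_set()


@pytest.fixture(scope="session")
def schedules(pairs, basic_set):
    """One schedule per group, fixed seed."""
    from ctxbind import GROUPS, build_group_schedule

    return {g: build_group_schedule(g, basic_set, pairs, seed=123) for g in GROUPS}


@pytest.fixture()
def rng():
    return np.random.default_rng(20240)
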