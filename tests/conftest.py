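import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import implearn as il

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=30,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def rate1_session() -> il.Session:
    """A rate-1 pure Rescorla-Wagner threshold agent on 300 random trials."""
    seq = il.generate_random_sequence(300, 0.5, seed=11)
    params = il.AgentParams(r_learn=1.0, r_gf=0.0, p_mix=1.0, policy="threshold", seed=12)
    return il.simulate_session(seq, params)


@pytest.fixture
def gf1_session() -> il.Session:
    """A pure gambler's-fallacy rate-1 threshold agent (anti-copies lag 1)."""
    seq = il.generate_random_sequence(300, 0.5, seed=21)
    params = il.AgentParams(r_learn=0.0, r_gf=1.0, p_mix=0.0, policy="threshold", seed=22)
    return il.simulate_session(seq, params)


def random_session(rng: np.random.Generator, n: int = 60) -> il.Session:
    """A session with unstructured random stimuli and responses."""
    return il.Session(
        stimuli=rng.integers(0, 2, n),
        responses=rng.integers(0, 2, n),
    )
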