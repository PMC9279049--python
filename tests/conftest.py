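import numpy as np
import pytest

from deeppsy import CohortConfig, simulate_cohort

EFFECT_CHANNELS = tuple(CohortConfig().effect_sizes)


def make_config(n=210, effects=1.0, seed=1, **kw):
    """Cohort config with a uniform effect size on every channel."""
    per = n // 3
    per_level = {"primary": per, "junior": per, "senior": n - 2 * per}
    if isinstance(effects, (int, float)):
        effects = {k: float(effects) for k in EFFECT_CHANNELS}
    return CohortConfig(
        n_students=n, per_level=per_level, effect_sizes=effects, seed=seed, **kw
    )


@pytest.fixture(scope="session")
def default_config():
    return CohortConfig(seed=1)


@pytest.fixture(scope="session")
def default_cohort(default_config):
    return simulate_cohort(default_config)


@pytest.fixture(scope="session")
def strong_config():
    """Strong planted multimodal effects on the standard 210-student design."""
    return make_config(n=210, effects=2.0, seed=1)


@pytest.fixture(scope="session")
def strong_cohort(strong_config):
    return simulate_cohort(strong_config)


@pytest.fixture(scope="session")
def null_large_cohort():
    """Zero effect sizes at n=2000: MD and non-MD channels exchangeable."""
    return simulate_cohort(make_config(n=2000, effects=0.0, seed=2))


@pytest.fixture(scope="session")
def small_strong_cohort():
    """A 60-student strong-effect cohort for fast model tests."""
    return simulate_cohort(make_config(n=60, effects=2.0, seed=3))
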