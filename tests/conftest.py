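import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from deactdyn.synthgen import PatternSpec, gen_beta_patterns

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def separable_trials():
    """Strongly separable two-condition patterns (5 runs x 5 trials/cond)."""
    return gen_beta_patterns(
        PatternSpec(
            n_trials_per_condition=25,
            n_runs=5,
            n_features=40,
            condition_separation=10.0,
            feature_coupling=0.0,
            noise_sd=1.0,
            seed=7,
        )
    )


@pytest.fixture
def null_trials():
    """Pure-noise patterns: no condition or feature structure."""
    return gen_beta_patterns(
        PatternSpec(
            n_trials_per_condition=25,
            n_runs=5,
            n_features=40,
            condition_separation=0.0,
            feature_coupling=0.0,
            noise_sd=1.0,
            seed=11,
        )
    )
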