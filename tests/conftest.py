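import numpy as np
import pytest

from socialsampling import ModelConfig, preset_config, run_experiment


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def exp1_bayes_result():
    """One Experiment-1-layout run under Bayesian social sampling."""
    cfg = preset_config(
        "exp1", ModelConfig("social_sampling_bayes", social_proportion=0.19), seed=7
    )
    return run_experiment(cfg)
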