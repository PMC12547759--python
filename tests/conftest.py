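import numpy as np
import pytest

from icbtpred import GeneratorConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """60-patient complete cohort with short texts and a clear text signal."""
    cfg = GeneratorConfig(n_patients=60, seed=5, text_signal_strength=2.0,
                          wordcount_log_mean=4.0, wordcount_log_sd=0.4)
    cohort, messages = generate_cohort(cfg)
    return cfg, cohort, messages


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
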