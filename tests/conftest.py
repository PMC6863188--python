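import numpy as np
import pytest

from krecout import pipeline, synthetic
from krecout.synthetic import NoiseModel, ZERO_NOISE, cwc_design


@pytest.fixture(scope="session")
def healthy_cohort_default_noise():
    """CWC-like cohort at generator defaults (n=288, seed 0), annotated."""
    samples, truth = synthetic.simulate_cohort(cwc_design(288), noise=NoiseModel(seed=0))
    annotated = pipeline.annotate_samples(samples)
    return annotated, truth


@pytest.fixture(scope="session")
def healthy_cohort_zero_noise():
    """Small noiseless cohort: every record internally consistent."""
    samples, truth = synthetic.simulate_cohort(cwc_design(120), noise=ZERO_NOISE)
    annotated = pipeline.annotate_samples(samples)
    return annotated, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
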