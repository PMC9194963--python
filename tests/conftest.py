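import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def gusto_dgp():
    from riskvoi import gusto_like

    return gusto_like()


@pytest.fixture(scope="session")
def small_sample(gusto_dgp):
    """A 600-row gusto-like development sample with its true risks."""
    from riskvoi import generate_sample

    sample, truth = generate_sample(gusto_dgp, 600, 20250901)
    return sample, truth


@pytest.fixture(scope="session")
def fitted_small(small_sample):
    """Proposed logistic model and its predicted risks on small_sample."""
    from riskvoi import LogisticDeveloper

    sample, _ = small_sample
    dev = LogisticDeveloper()
    model = dev.fit(sample)
    pi = np.clip(model.predict_risk(sample.covariates), 0.0, 1.0)
    return dev, model, pi
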