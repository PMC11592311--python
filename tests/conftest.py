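import numpy as np
import pytest

from lifsens import ExpectationContext, NeuronParams


def make_ctx(n=20, lam=64.0, tau=50.0, weight_seed=101, theta_fraction=0.4, approx=None):
    """Standard study-condition context: uniform [0,1] weights, threshold at
    a fixed fraction of the total weight."""
    w = np.random.default_rng(weight_seed).uniform(0.0, 1.0, n)
    params = NeuronParams(w, tau, theta_fraction * w.sum())
    if approx is None:
        return ExpectationContext(params, lam)
    return ExpectationContext(params, lam, approx)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
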