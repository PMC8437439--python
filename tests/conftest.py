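import numpy as np
import pytest

from mcugate import synthetic as syn


@pytest.fixture(scope="session")
def gating_default():
    return syn.default_gating_model()


@pytest.fixture(scope="session")
def ramp_default():
    return syn.default_ramp_model()


@pytest.fixture(scope="session")
def short_wt_trace(gating_default):
    """A 20-s WT trace at saturating symmetric Ca2+ with ground truth."""
    model = gating_default.potentiated(105e6, "WT")
    rec, states = syn.simulate_single_channel(model, duration=20.0, seed=11)
    return model, rec, states


def power_iteration_stationary(trans: np.ndarray, n_iter: int = 20000) -> np.ndarray:
    """Brute-force stationary distribution oracle: repeated left-multiplication."""
    pi = np.full(trans.shape[0], 1.0 / trans.shape[0])
    for _ in range(n_iter):
        new = pi @ trans
        if np.abs(new - pi).max() < 1e-15:
            return new
        pi = new
    return pi
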