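import numpy as np
import pytest

from chromocg.dynamics import LangevinParams, make_control_ensemble


@pytest.fixture(scope="session")
def small_saw_ensemble():
    """A modest equilibrated SAW ensemble shared across test modules."""
    return make_control_ensemble(
        "saw", n_beads=100, n_samples=12,
        params=LangevinParams(n_steps=8000, sample_every=200, seed=101),
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
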