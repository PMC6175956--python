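import numpy as np
import pytest

from curvsense import (ExclusionShell, HSMCConfig, SAWModel, StepClass,
                       Substrate)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def cubic_model():
    """Plain site-exclusion SAW on the cubic lattice (6 directions)."""
    return SAWModel(StepClass(0, 0, 1), ExclusionShell(0))


@pytest.fixture
def stiff_model():
    """24-direction walk with a 2-shell exclusion."""
    return SAWModel(StepClass(1, 1, 2), ExclusionShell(2))


@pytest.fixture
def ideal_model():
    """Exclusion-free test-mode walk with exactly known entropy."""
    return SAWModel(StepClass(0, 0, 1), ExclusionShell(0), self_avoiding=False)


@pytest.fixture
def desk_hsmc():
    """Desk-scale entropy settings used throughout the tests."""
    return HSMCConfig(n_bar=50, n_bar_prime=10, n_recon=24, seed=3)


@pytest.fixture
def flat_substrate():
    return Substrate("plane")
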