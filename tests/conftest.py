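import pytest

from seedgerm.validation import recovery_study


@pytest.fixture(scope="session")
def noisy_recovery():
    """20 virtual species, 25 seeds x 4 replicates, binomial counts."""
    return recovery_study(n_species=20, seed=1, noise=True)


@pytest.fixture(scope="session")
def noiseless_recovery():
    """Same design in the noiseless (expected-curve) limit."""
    return recovery_study(n_species=20, seed=1, noise=False)
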