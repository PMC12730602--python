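"""Shared fixtures: small synthetic datasets generated once per session."""

import numpy as np
import pytest

from fbcspts import generate_synthetic_mi

# sklearn deprecation chatter from dependencies is irrelevant to the suite
import warnings

warnings.filterwarnings("ignore", category=FutureWarning)


@pytest.fixture(scope="session")
def separable_4class():
    """High-SNR 4-class MI data: 20 trials/class, 22 channels, 250 Hz."""
    return generate_synthetic_mi(n_trials_per_class=20, n_channels=22,
                                 n_classes=4, snr=50.0, seed=11)


@pytest.fixture(scope="session")
def small_binary():
    """Cheap binary problem for pipeline plumbing tests: 10 trials/class,
    8 channels, 128 Hz, 2 s trials."""
    return generate_synthetic_mi(n_trials_per_class=10, n_channels=8,
                                 n_classes=2, sfreq=128.0, trial_length=2.0,
                                 snr=5.0, seed=3)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2026)
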