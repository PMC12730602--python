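"""Synthetic motor-imagery EEG with known ground truth.

The generator emulates the covariance structure that CSP-family methods
exploit: each class owns one band-limited oscillatory source (a narrowband
mu- or beta-band random process, not a sinusoid) whose variance is
amplified inside an activation interval only on trials of that class.
Sources are mixed into the channels through a random orthonormal-column
mixing matrix and buried in spatially white Gaussian noise at a stated
SNR. Class information therefore lives exclusively in band- and
time-localized spatial variance, exactly what the filter bank, CSP and
time segmentation are designed to recover.

Event-related modulation is modeled as variance amplification rather than
suppression; CSP is contrast-based, so the direction is immaterial.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .csp import CSPModel
from .epochs import BandSpec, EpochSet

#: default per-class source bands, one per filter-bank subband in the
#: mu/beta range (cycled when n_classes > 4)
DEFAULT_SOURCE_BANDS = (
    BandSpec(9.0, 11.0),    # mu
    BandSpec(13.0, 15.0),   # low beta
    BandSpec(21.0, 23.0),   # mid beta
    BandSpec(29.0, 31.0),   # high beta
)


@dataclass
class SyntheticGroundTruth:
    """Everything needed to score recovery of the generating model."""

    mixing: np.ndarray            # (n_channels, n_sources), orthonormal columns
    source_bands: list[BandSpec]  # band of each source
    class_of_source: np.ndarray   # class index per source
    active_interval: tuple[float, float]
    snr: float
    modulation: float
    seed: int


def _band_limited_noise(rng: np.random.Generator, band: BandSpec,
                        sfreq: float, n_samples: int, n_series: int) -> np.ndarray:
    """Unit-variance Gaussian noise band-passed to ``band`` (order-4
    zero-phase Butterworth), generated with padding to suppress edge
    transients."""
    pad = n_samples // 2
    white = rng.standard_normal((n_series, n_samples + 2 * pad))
    sos = signal.butter(4, (band.low_hz, band.high_hz), btype="bandpass",
                        fs=sfreq, output="sos")
    x = signal.sosfiltfilt(sos, white, axis=-1)[:, pad:pad + n_samples]
    x = x - x.mean(axis=-1, keepdims=True)
    return x / x.std(axis=-1, keepdims=True)


def generate_synthetic_mi(n_trials_per_class: int = 25, n_channels: int = 22,
                          n_classes: int = 4, sfreq: float = 250.0,
                          trial_length: float = 4.0, snr: float = 2.0,
                          active_interval: tuple[float, float] | None = None,
                          seed: int = 0, modulation: float = 6.0,
                          source_bands: list[BandSpec] | None = None,
                          ) -> tuple[EpochSet, SyntheticGroundTruth]:
    """Generate an MI-like EpochSet plus its generating ground truth.

    Parameters
    ----------
    snr : linear ratio of mean signal power (mixed sources) to noise power
        per channel. The default 2.0 gives a clearly learnable but not
        saturated problem; use ~50 for near-noise-free data.
    modulation : variance amplification factor of a class's source inside
        the activation interval on that class's trials (6.0 by default, a
        strong event-related modulation).
    active_interval : (start, end) seconds of the class-specific
        modulation; None means the whole trial.
    """
    if n_channels < n_classes + 1:
        raise ValueError("need n_channels >= n_classes + 1")
    if sfreq <= 64:
        raise ValueError("sfreq must exceed 64 Hz to contain the beta band")
    n_samples = int(round(sfreq * trial_length))
    if active_interval is None:
        active_interval = (0.0, trial_length)
    a0, a1 = active_interval
    if not 0.0 <= a0 < a1 <= trial_length + 1e-9:
        raise ValueError(f"invalid active_interval {active_interval}")

    if source_bands is None:
        source_bands = [DEFAULT_SOURCE_BANDS[c % len(DEFAULT_SOURCE_BANDS)]
                        for c in range(n_classes)]
    rng = np.random.default_rng(seed)
    n_sources = n_classes
    # orthonormal-column mixing (full column rank by construction)
    mixing, _ = np.linalg.qr(rng.standard_normal((n_channels, n_sources)))

    n_trials = n_trials_per_class * n_classes
    labels = np.repeat(np.arange(n_classes), n_trials_per_class)
    labels = labels[rng.permutation(n_trials)]

    i0, i1 = int(round(a0 * sfreq)), int(round(a1 * sfreq))
    gain = np.sqrt(modulation)
    data = np.empty((n_trials, n_channels, n_samples))
    signal_power = 0.0
    for t in range(n_trials):
        sources = np.vstack([
            _band_limited_noise(rng, source_bands[s], sfreq, n_samples, 1)
            for s in range(n_sources)
        ])
        sources[labels[t], i0:i1] *= gain
        clean = mixing @ sources
        data[t] = clean
        signal_power += clean.var()
    signal_power /= n_trials
    noise_sd = np.sqrt(signal_power / snr)
    data += noise_sd * rng.standard_normal(data.shape)

    epochs = EpochSet(data=data, sfreq=sfreq, labels=labels,
                      window=(0.0, trial_length))
    truth = SyntheticGroundTruth(
        mixing=mixing, source_bands=list(source_bands),
        class_of_source=np.arange(n_sources), active_interval=(a0, a1),
        snr=snr, modulation=modulation, seed=seed,
    )
    return epochs, truth


def pattern_recovery_score(truth: SyntheticGroundTruth,
                           csp_models: list[CSPModel]) -> np.ndarray:
    """Per class, the maximum |Pearson r| between any fitted CSP pattern
    column of that class's one-vs-rest model and the true mixing column.

    The score is sign-invariant (CSP patterns have arbitrary sign)."""
    scores = np.zeros(len(csp_models))
    for c, model in enumerate(csp_models):
        true_col = truth.mixing[:, c]
        best = 0.0
        for j in range(model.patterns.shape[1]):
            r = np.corrcoef(true_col, model.patterns[:, j])[0, 1]
            best = max(best, abs(float(r)))
        scores[c] = best
    return scores
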