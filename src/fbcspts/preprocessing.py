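"""Band-pass filtering and frequency-domain resampling.

Preprocessing follows standard motor-imagery practice: a zero-phase
Butterworth band-pass (default 8-32 Hz, covering the mu and beta rhythms)
applied to each epoch, followed - in degradation experiments - by
FFT-based resampling to a lower rate. The resampled length obeys the
contract ``n_out = round(n_in * f_target / f_original)``.

At strongly degraded rates a requested band may collide with the Nyquist
frequency. The policy is: the high edge is clipped to 0.95 x Nyquist (with
a logged warning); a band whose low edge reaches the clipped high edge is
inadmissible and dropped by filter-bank callers. This keeps the pipeline
defined at every sweep rate down to 10 Hz.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
from scipy import signal

from .epochs import BandSpec, EpochSet

logger = logging.getLogger(__name__)

#: Fraction of Nyquist at which a band's high edge is clipped.
NYQUIST_MARGIN = 0.95


@dataclass(frozen=True)
class ResampleSpec:
    """Original and target sampling rates of a degradation step."""

    f_original: float
    f_target: float

    def __post_init__(self) -> None:
        if self.f_original <= 0 or self.f_target <= 0:
            raise ValueError("sampling rates must be > 0")

    def output_length(self, n_original: int) -> int:
        """Resampled sample count: round(N * f_target / f_original)."""
        return int(round(n_original * self.f_target / self.f_original))


def clip_band(band: BandSpec, sfreq: float) -> BandSpec | None:
    """Clip a band to the admissible range below Nyquist.

    Returns the (possibly clipped) band, or None if the band lies wholly
    at/above the clipped Nyquist limit and must be dropped.
    """
    limit = NYQUIST_MARGIN * sfreq / 2.0
    if band.low_hz >= limit:
        return None
    if band.high_hz <= limit:
        return band
    logger.warning(
        "band (%g, %g) Hz exceeds Nyquist at sfreq=%g Hz; high edge clipped to %g Hz",
        band.low_hz, band.high_hz, sfreq, limit,
    )
    return BandSpec(band.low_hz, limit)


def bandpass_filter(epochs: EpochSet, band: BandSpec, order: int = 4) -> EpochSet:
    """Zero-phase Butterworth band-pass of every trial.

    The filter is applied forward-backward (``sosfiltfilt``), so the
    effective attenuation is twice the one-pass Butterworth roll-off and
    the group delay is zero. Raises if the high edge reaches Nyquist;
    callers running degraded rates should pass bands through
    :func:`clip_band` first.
    """
    nyq = epochs.sfreq / 2.0
    if band.high_hz >= nyq:
        raise ValueError(
            f"band edge {band.high_hz} Hz is at/above Nyquist ({nyq} Hz) "
            f"for sfreq={epochs.sfreq} Hz"
        )
    sos = signal.butter(order, (band.low_hz, band.high_hz), btype="bandpass",
                        fs=epochs.sfreq, output="sos")
    filtered = signal.sosfiltfilt(sos, epochs.data, axis=-1)
    return replace(epochs, data=np.ascontiguousarray(filtered))


def resample_epochs(epochs: EpochSet, f_target: float) -> EpochSet:
    """Resample every trial to ``f_target`` Hz with the FFT (Fourier) method.

    Fourier resampling interpolates in the frequency domain and is
    intrinsically anti-aliasing: spectral content above the new Nyquist is
    discarded, no extra low-pass is needed. The output length is
    ``round(n_samples * f_target / sfreq)``. ``f_target == sfreq`` returns
    an identical copy.
    """
    spec = ResampleSpec(epochs.sfreq, f_target)
    if f_target == epochs.sfreq:
        return epochs.copy()
    n_out = spec.output_length(epochs.n_samples)
    if n_out < 1:
        raise ValueError(f"resampling to {f_target} Hz leaves no samples")
    data = signal.resample(epochs.data, n_out, axis=-1)
    t0 = epochs.window[0]
    return replace(epochs, data=np.ascontiguousarray(data), sfreq=float(f_target),
                   window=(t0, t0 + n_out / f_target))


def sweep_rates(start_hz: float = 10.0, stop_hz: float = 250.0,
                step_hz: float = 10.0) -> list[float]:
    """Inclusive arithmetic sequence of sampling rates for the degradation
    sweep; the default is the 25-point grid 10, 20, ..., 250 Hz."""
    if step_hz <= 0:
        raise ValueError("step_hz must be > 0")
    if stop_hz < start_hz:
        raise ValueError("stop_hz must be >= start_hz")
    n = int(np.floor((stop_hz - start_hz) / step_hz + 1e-9)) + 1
    return [start_hz + i * step_hz for i in range(n)]
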