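"""Epoch container and I/O for motor-imagery EEG.

The universal data structure is :class:`EpochSet`: a dense trial tensor
(n_trials x n_channels x n_samples) in microvolts, integer class labels,
a sampling frequency and the epoch window in seconds relative to cue onset.
Readers exist for BCI Competition IV Dataset 2a (GDF, via MNE) and
Dataset 1 (MATLAB .mat, via scipy.io); a portable NumPy ``.npz`` archive
serves as the native fixture format so the full pipeline is testable
without any download.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: GDF event codes of the four cue classes in BCI Competition IV Dataset 2a
#: (left hand, right hand, foot, tongue), mapped to labels 0..3.
DATASET_2A_EVENT_CODES = {"769": 0, "770": 1, "771": 2, "772": 3}


@dataclass(frozen=True)
class BandSpec:
    """A frequency band [low_hz, high_hz] in Hz."""

    low_hz: float
    high_hz: float

    def __post_init__(self) -> None:
        if not (0 < self.low_hz < self.high_hz):
            raise ValueError(
                f"invalid band: need 0 < low < high, got ({self.low_hz}, {self.high_hz})"
            )

    def admissible(self, sfreq: float) -> bool:
        """Whether both edges lie strictly below the Nyquist frequency."""
        return self.high_hz < sfreq / 2.0

    def __iter__(self):
        return iter((self.low_hz, self.high_hz))


@dataclass
class EpochSet:
    """Epoched multichannel EEG with one integer class label per trial.

    Parameters
    ----------
    data : ndarray, shape (n_trials, n_channels, n_samples)
        Trial tensor in microvolts. Must be finite.
    sfreq : float
        Sampling frequency in Hz, > 0.
    labels : ndarray of int, shape (n_trials,)
        Class per trial; values must form a contiguous set {0..K-1}, K >= 2.
    channel_names : list of str
        One identifier per channel.
    window : (float, float)
        Epoch limits (t_start, t_end) in seconds relative to cue onset,
        half-open [t_start, t_end). n_samples must equal
        round(sfreq * (t_end - t_start)).
    """

    data: np.ndarray
    sfreq: float
    labels: np.ndarray
    channel_names: list[str] = field(default_factory=list)
    window: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.data.ndim != 3:
            raise ValueError(f"data must be 3-D (trials, channels, samples), got ndim={self.data.ndim}")
        if self.data.shape[0] == 0:
            raise ValueError("EpochSet must contain at least one trial")
        if not np.isfinite(self.data).all():
            raise ValueError("data contains non-finite values")
        if self.sfreq <= 0:
            raise ValueError(f"sfreq must be > 0, got {self.sfreq}")
        if self.labels.shape != (self.data.shape[0],):
            raise ValueError(
                f"labels shape {self.labels.shape} does not match n_trials={self.data.shape[0]}"
            )
        classes = np.unique(self.labels)
        if classes.size < 2 or not np.array_equal(classes, np.arange(classes.size)):
            raise ValueError(
                f"labels must form a contiguous set {{0..K-1}} with K >= 2, got {classes.tolist()}"
            )
        if not self.channel_names:
            self.channel_names = [f"ch{i}" for i in range(self.data.shape[1])]
        if len(self.channel_names) != self.data.shape[1]:
            raise ValueError("channel_names length does not match n_channels")
        t0, t1 = self.window
        if t1 <= t0:
            # derive a nominal window from the sample count
            self.window = (0.0, self.data.shape[2] / self.sfreq)
            t0, t1 = self.window
        expected = int(round(self.sfreq * (t1 - t0)))
        if expected != self.data.shape[2]:
            raise ValueError(
                f"n_samples={self.data.shape[2]} inconsistent with window {self.window} "
                f"at sfreq={self.sfreq} (expected {expected})"
            )

    # -- shape accessors -------------------------------------------------
    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    @property
    def n_classes(self) -> int:
        return int(self.labels.max()) + 1

    @property
    def trial_length(self) -> float:
        """Epoch duration in seconds."""
        return self.window[1] - self.window[0]

    def copy(self) -> "EpochSet":
        return replace(self, data=self.data.copy(), labels=self.labels.copy(),
                       channel_names=list(self.channel_names))

    def select_trials(self, index: np.ndarray) -> "EpochSet":
        """Subset trials; labels are NOT re-coded (caller keeps class meaning)."""
        sub = replace(self, data=self.data[index], labels=self.labels[index])
        return sub

    def crop(self, t_start: float, t_end: float) -> "EpochSet":
        """Slice samples in the half-open interval [t_start, t_end) seconds
        measured from the epoch start. Sample indices are round(t * sfreq)."""
        i0 = int(round(t_start * self.sfreq))
        i1 = int(round(t_end * self.sfreq))
        if not (0 <= i0 < i1 <= self.n_samples):
            raise ValueError(
                f"crop [{t_start}, {t_end}) s -> samples [{i0}, {i1}) outside "
                f"0..{self.n_samples}"
            )
        if i1 - i0 < 2:
            raise ValueError(
                f"crop [{t_start}, {t_end}) s yields {i1 - i0} sample(s) at "
                f"sfreq={self.sfreq} Hz; need at least 2"
            )
        w0 = self.window[0] + t_start
        return replace(self, data=self.data[:, :, i0:i1],
                       window=(w0, w0 + (i1 - i0) / self.sfreq))


# ---------------------------------------------------------------------------
# Native fixture archive (.npz)
# ---------------------------------------------------------------------------

def save_fixture(epochs: EpochSet, path) -> None:
    """Write an EpochSet to a single ``.npz`` archive."""
    np.savez(
        path,
        data=epochs.data,
        labels=epochs.labels,
        sfreq=np.float64(epochs.sfreq),
        channel_names=np.array(epochs.channel_names, dtype=object),
        window=np.asarray(epochs.window, dtype=np.float64),
    )


def load_fixture(path) -> EpochSet:
    """Read an EpochSet from the native ``.npz`` archive."""
    with np.load(path, allow_pickle=True) as z:
        return EpochSet(
            data=z["data"],
            sfreq=float(z["sfreq"]),
            labels=z["labels"],
            channel_names=[str(c) for c in z["channel_names"]],
            window=tuple(z["window"].tolist()),
        )


# ---------------------------------------------------------------------------
# Competition dataset readers (optional downloads)
# ---------------------------------------------------------------------------

def load_epochs_gdf(path, event_codes: dict[str, int] | None = None,
                    window: tuple[float, float] = (2.0, 6.0),
                    drop_eog: bool = True) -> EpochSet:
    """Epoch a BCI Competition IV Dataset 2a GDF recording.

    Cue onset is at t = 0 of each event; the default window (2.0, 6.0) s
    relative to trial start corresponds to the cued imagery period of the
    2a paradigm (cue at 2 s, imagery until 6 s). Requires ``mne``.

    Trials whose window runs past the end of the recording are dropped with
    a logged count. Missing event codes raise a ValueError naming the code.
    """
    import mne  # optional dependency; only needed for GDF input

    event_codes = dict(DATASET_2A_EVENT_CODES if event_codes is None else event_codes)
    if not event_codes:
        raise ValueError("event_codes must be non-empty")
    raw = mne.io.read_raw_gdf(path, preload=True, verbose="error")
    if drop_eog:
        eog = [ch for ch in raw.ch_names if "EOG" in ch.upper()]
        if eog:
            raw.drop_channels(eog)
    events, event_id = mne.events_from_annotations(raw, verbose="error")
    missing = [c for c in event_codes if c not in event_id]
    if missing:
        raise ValueError(f"event code(s) {missing} not present in {path}")
    sfreq = float(raw.info["sfreq"])
    sig = raw.get_data()  # (n_channels, n_total_samples), volts
    i_lo = int(round(window[0] * sfreq))
    n_samp = int(round(sfreq * (window[1] - window[0])))

    trials, labels = [], []
    n_dropped = 0
    for onset, _, code in events:
        label = None
        for name, lab in event_codes.items():
            if event_id.get(name) == code:
                label = lab
        if label is None:
            continue
        start = onset + i_lo
        if start < 0 or start + n_samp > sig.shape[1]:
            n_dropped += 1
            continue
        trials.append(sig[:, start:start + n_samp])
        labels.append(label)
    if n_dropped:
        logger.warning("dropped %d truncated trial(s) from %s", n_dropped, path)
    if not trials:
        raise ValueError(f"no complete trials found in {path} for codes {list(event_codes)}")
    data = np.stack(trials) * 1e6  # volts -> microvolts
    return EpochSet(data=data, sfreq=sfreq, labels=np.array(labels),
                    channel_names=list(raw.ch_names), window=window)


def load_epochs_mat(path, window: tuple[float, float] = (0.0, 4.0)) -> EpochSet:
    """Epoch a BCI Competition IV Dataset 1 calibration ``.mat`` file (100 Hz).

    The archive stores a continuous recording ``cnt`` (int16, 0.1 uV units),
    cue markers ``mrk`` (positions in samples, class labels in {-1, +1})
    and metadata ``nfo``. Labels are mapped to {0, 1}. The default window
    (0.0, 4.0) s after the cue covers the 4 s imagery period.
    """
    from scipy.io import loadmat

    m = loadmat(path, squeeze_me=True, struct_as_record=False)
    cnt = np.asarray(m["cnt"], dtype=np.float64) * 0.1  # -> microvolts
    mrk = m["mrk"]
    nfo = m["nfo"]
    sfreq = float(nfo.fs)
    pos = np.atleast_1d(np.asarray(mrk.pos, dtype=np.int64))
    y = np.atleast_1d(np.asarray(mrk.y, dtype=np.int64))
    if pos.size == 0:
        raise ValueError(f"no cue markers in {path}")
    i_lo = int(round(window[0] * sfreq))
    n_samp = int(round(sfreq * (window[1] - window[0])))
    trials, labels = [], []
    n_dropped = 0
    for p, cls in zip(pos, y):
        start = p + i_lo
        if start < 0 or start + n_samp > cnt.shape[0]:
            n_dropped += 1
            continue
        trials.append(cnt[start:start + n_samp, :].T)
        labels.append(0 if cls < 0 else 1)
    if n_dropped:
        logger.warning("dropped %d truncated trial(s) from %s", n_dropped, path)
    data = np.stack(trials)
    names = [str(c) for c in np.atleast_1d(nfo.clab)]
    return EpochSet(data=data, sfreq=sfreq, labels=np.array(labels),
                    channel_names=names, window=window)


# ---------------------------------------------------------------------------
# Results tables
# ---------------------------------------------------------------------------

def save_results(table: pd.DataFrame, path) -> None:
    """Write a per-condition metrics table to CSV (one row per record).

    A round-trip through :func:`load_results` returns an equal table.
    """
    table.to_csv(path, index=False)


def load_results(path) -> pd.DataFrame:
    return pd.read_csv(path)
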