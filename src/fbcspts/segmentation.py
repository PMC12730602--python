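"""Overlapping time segmentation and the soft-voting segment ensemble.

FBCSP-TS refits the whole FBCSP feature pipeline, plus a
probability-emitting classifier, on each of a family of overlapping time
segments of the trial, then fuses the per-segment class probabilities by
averaging (soft voting). Segments are defined in seconds, so a fixed
(window, step) configuration yields the same member count at every
sampling rate; slicing maps seconds to samples via round(t * sfreq).

A window length equal to the trial length reduces the ensemble to a
single member, i.e. plain FBCSP: predictions are then bitwise identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from sklearn.calibration import CalibratedClassifierCV
from sklearn.svm import SVC

from .epochs import BandSpec, EpochSet
from .fbcsp import FBCSPModel, fbcsp_transform, fit_fbcsp

#: temporal grid of the configuration search: 0.5-4.0 s in 0.5 s steps on
#: both axes, 64 (window, step) combinations.
DEFAULT_GRID_VALUES = tuple(0.5 * i for i in range(1, 9))


@dataclass(frozen=True)
class SegmentConfig:
    """Window length, moving (step) length and trial length, in seconds."""

    window_length: float
    moving_length: float
    trial_length: float

    def __post_init__(self) -> None:
        if not 0 < self.window_length <= self.trial_length:
            raise ValueError(
                f"need 0 < window_length <= trial_length, got "
                f"w={self.window_length}, T={self.trial_length}"
            )
        if self.moving_length <= 0:
            raise ValueError("moving_length must be > 0")

    @property
    def n_segments(self) -> int:
        return int(np.floor((self.trial_length - self.window_length)
                            / self.moving_length + 1e-9)) + 1


def enumerate_segments(config: SegmentConfig) -> list[tuple[float, float]]:
    """Half-open segment windows [i*s, i*s + w) for i = 0..floor((T-w)/s)."""
    w, s = config.window_length, config.moving_length
    return [(i * s, i * s + w) for i in range(config.n_segments)]


def build_grid(w_values: Sequence[float] = DEFAULT_GRID_VALUES,
               s_values: Sequence[float] = DEFAULT_GRID_VALUES,
               trial_length: float = 4.0) -> list[SegmentConfig]:
    """Cartesian product of window and step values (step-major order)."""
    if not w_values or not s_values:
        raise ValueError("w_values and s_values must be non-empty")
    return [SegmentConfig(w, s, trial_length)
            for s in s_values for w in w_values]


def default_classifier(seed: int = 0) -> CalibratedClassifierCV:
    """RBF-kernel SVM (C=1, gamma=scale) with Platt-calibrated probabilities.

    Calibration uses sigmoid scaling on unshuffled 3-fold out-of-fold
    decision values of the member's training data only, then refits the
    SVM on all of it — deterministic regardless of ``seed`` (kept in the
    signature so custom factories can consume it).
    """
    return CalibratedClassifierCV(
        SVC(C=1.0, kernel="rbf", gamma="scale"),
        method="sigmoid", cv=3, ensemble=False,
    )


@dataclass
class SegmentEnsemble:
    """Per-segment (FBCSPModel, classifier) members and their fusion rule."""

    config: SegmentConfig
    segments: list[tuple[float, float]]
    members: list[tuple[FBCSPModel, object]]
    classes: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))

    @property
    def n_members(self) -> int:
        return len(self.members)


def fit_segment_ensemble(epochs: EpochSet, labels: np.ndarray | None = None,
                         config: SegmentConfig | None = None, k: int = 4,
                         bands: list[BandSpec] | None = None,
                         n_pairs: int = 2, n_bins: int = 4,
                         filter_order: int = 4, select: bool = True,
                         seed: int = 0,
                         classifier_factory: Callable[[int], object] | None = None,
                         ) -> SegmentEnsemble:
    """Fit one FBCSP model and one probability classifier per time segment.

    The default configuration is the (3.5 s window, 0.5 s step) optimum of
    the temporal grid search. Member classifiers receive deterministic
    seeds derived from ``seed``.
    """
    if labels is None:
        labels = epochs.labels
    labels = np.asarray(labels)
    if config is None:
        config = SegmentConfig(min(3.5, epochs.trial_length), 0.5,
                               epochs.trial_length)
    if config.window_length > epochs.trial_length + 1e-9:
        raise ValueError(
            f"window_length {config.window_length} s exceeds trial length "
            f"{epochs.trial_length} s"
        )
    if classifier_factory is None:
        classifier_factory = default_classifier
    members = []
    segments = enumerate_segments(config)
    for i, (t0, t1) in enumerate(segments):
        cropped = epochs.crop(t0, t1)
        model = fit_fbcsp(cropped, labels, k=k, bands=bands, n_pairs=n_pairs,
                          n_bins=n_bins, filter_order=filter_order,
                          select=select)
        clf = classifier_factory(seed + i)
        clf.fit(fbcsp_transform(model, cropped), labels)
        members.append((model, clf))
    return SegmentEnsemble(config=config, segments=segments, members=members,
                           classes=np.unique(labels))


def soft_vote(prob_stacks: Sequence[np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
    """Average per-segment probability matrices and take the argmax.

    All stacks must share shape (n_trials, n_classes) with rows summing to
    one (tolerance 1e-6). Ties in the argmax go to the lowest class index.
    Returns (labels, fused probabilities).
    """
    stacks = [np.asarray(p, dtype=np.float64) for p in prob_stacks]
    if not stacks:
        raise ValueError("no probability stacks to fuse")
    shape = stacks[0].shape
    if any(p.shape != shape for p in stacks):
        raise ValueError("probability stacks differ in shape")
    for p in stacks:
        if np.max(np.abs(p.sum(axis=1) - 1.0)) > 1e-6:
            raise ValueError("probability rows must sum to 1")
    fused = np.mean(stacks, axis=0)
    return fused.argmax(axis=1), fused


def predict(ensemble: SegmentEnsemble,
            epochs: EpochSet) -> tuple[np.ndarray, np.ndarray]:
    """Fused labels and probabilities for new epochs.

    Epochs must match the training trial length; each member scores its
    own segment and the per-segment probabilities are soft-voted.
    """
    if abs(epochs.trial_length - ensemble.config.trial_length) > 0.5 / epochs.sfreq:
        raise ValueError(
            f"epoch length {epochs.trial_length} s does not match training "
            f"trial length {ensemble.config.trial_length} s"
        )
    stacks = []
    for (t0, t1), (model, clf) in zip(ensemble.segments, ensemble.members):
        cropped = epochs.crop(t0, t1)
        stacks.append(clf.predict_proba(fbcsp_transform(model, cropped)))
    labels, fused = soft_vote(stacks)
    return ensemble.classes[labels], fused
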