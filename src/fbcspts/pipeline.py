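"""Method presets: CSP baseline, FBCSP, and FBCSP-TS.

All three methods share one implementation path — a segment ensemble — so
their comparison isolates what each stage adds:

* ``csp``      — a single broad 7-35 Hz band, whole-trial window, all CSP
                 features (no filter bank, no selection, no segmentation);
* ``fbcsp``    — the 7-band 4-32 Hz filter bank with MI feature selection,
                 whole-trial window (a single-segment ensemble);
* ``fbcsp-ts`` — FBCSP refitted on overlapping segments (default 3.5 s
                 window, 0.5 s step) fused by soft voting.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .epochs import BandSpec, EpochSet
from .segmentation import (SegmentConfig, SegmentEnsemble,
                           fit_segment_ensemble, predict)

METHODS = ("csp", "fbcsp", "fbcsp-ts")


@dataclass(frozen=True)
class PipelineSpec:
    """Declarative description of one decoding pipeline."""

    method: str = "fbcsp-ts"
    window_length: float = 3.5
    moving_length: float = 0.5
    k: int = 4
    n_pairs: int = 2
    n_bins: int = 4
    filter_order: int = 4
    bands: tuple[BandSpec, ...] | None = None  # None -> method default

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"method must be one of {METHODS}, got {self.method!r}")

    def with_segments(self, window_length: float,
                      moving_length: float) -> "PipelineSpec":
        return replace(self, window_length=window_length,
                       moving_length=moving_length)


def _segment_config(spec: PipelineSpec, trial_length: float) -> SegmentConfig:
    if spec.method == "fbcsp-ts":
        w = min(spec.window_length, trial_length)
        return SegmentConfig(w, spec.moving_length, trial_length)
    return SegmentConfig(trial_length, trial_length, trial_length)


@dataclass
class Pipeline:
    """A fitted decoding pipeline (spec + segment ensemble)."""

    spec: PipelineSpec
    ensemble: SegmentEnsemble = field(default=None, repr=False)

    def predict(self, epochs: EpochSet) -> np.ndarray:
        labels, _ = predict(self.ensemble, epochs)
        return labels

    def predict_proba(self, epochs: EpochSet) -> np.ndarray:
        _, proba = predict(self.ensemble, epochs)
        return proba


def fit_pipeline(spec: PipelineSpec, epochs: EpochSet,
                 labels: np.ndarray | None = None, seed: int = 0) -> Pipeline:
    """Fit the pipeline a spec describes on training epochs."""
    if spec.bands is not None:
        bands = list(spec.bands)
        select = True
    elif spec.method == "csp":
        bands = [BandSpec(7.0, 35.0)]
        select = False  # baseline keeps all CSP features, no MI selection
    else:
        bands = None  # default 7-band filter bank
        select = True
    config = _segment_config(spec, epochs.trial_length)
    ensemble = fit_segment_ensemble(
        epochs, labels, config=config, k=spec.k, bands=bands,
        n_pairs=spec.n_pairs, n_bins=spec.n_bins,
        filter_order=spec.filter_order, select=select, seed=seed,
    )
    return Pipeline(spec=spec, ensemble=ensemble)
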