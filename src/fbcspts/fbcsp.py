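"""Filter-bank CSP (FBCSP) with mutual-information feature selection.

The epoch is filtered into seven contiguous 4 Hz subbands spanning
4-32 Hz; CSP is fitted independently in each band (one-vs-rest for
multiclass); the concatenated log-variance features are ranked by the
mutual information (MI) between each feature and the class label, and the
top-k features are kept together with their CSP eigenvector partners.

The MI estimator discretizes each feature into equal-frequency bins
(default 4) and evaluates the plug-in discrete MI in bits. It is
deterministic and adequate for ranking; it is not a consistent estimator
of the continuous MI.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .csp import (CSPModel, fit_csp_multiclass, multiclass_features,
                  multiclass_partners)
from .epochs import BandSpec, EpochSet
from .preprocessing import bandpass_filter, clip_band


def build_filter_bank(low_hz: float = 4.0, high_hz: float = 32.0,
                      width_hz: float = 4.0) -> list[BandSpec]:
    """Contiguous filter bank; the default is the seven 4 Hz bands
    4-8, 8-12, ..., 28-32 Hz."""
    edges = np.arange(low_hz, high_hz + width_hz / 2, width_hz)
    return [BandSpec(float(a), float(b)) for a, b in zip(edges[:-1], edges[1:])]


def _equal_frequency_bins(x: np.ndarray, n_bins: int) -> np.ndarray:
    """Discretize a feature into (at most) n_bins equal-frequency bins."""
    qs = np.quantile(x, np.linspace(0, 1, n_bins + 1)[1:-1])
    return np.searchsorted(qs, x, side="right")


def mutual_information(feature: np.ndarray, labels: np.ndarray,
                       n_bins: int = 4) -> float:
    """Plug-in discrete MI (bits) between a binned feature and the labels.

    The feature is discretized into equal-frequency bins; MI is the
    exhaustive sum over the joint histogram,
    sum_{f,c} p(f,c) log2[ p(f,c) / (p(f) p(c)) ]. A constant feature has
    MI 0. Bounded by log2(min(n_bins, n_classes)).
    """
    feature = np.asarray(feature, dtype=np.float64)
    labels = np.asarray(labels)
    if feature.shape != labels.shape:
        raise ValueError("feature and labels must have equal length")
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    bins = _equal_frequency_bins(feature, n_bins)
    _, bins = np.unique(bins, return_inverse=True)
    _, labs = np.unique(labels, return_inverse=True)
    n = feature.size
    joint = np.zeros((bins.max() + 1, labs.max() + 1))
    np.add.at(joint, (bins, labs), 1.0)
    joint /= n
    pf = joint.sum(axis=1, keepdims=True)
    pc = joint.sum(axis=0, keepdims=True)
    mask = joint > 0
    mi = float(np.sum(joint[mask] * np.log2(joint[mask] / (pf @ pc)[mask])))
    return max(mi, 0.0)


def select_features(features: np.ndarray, labels: np.ndarray, k: int,
                    partners: np.ndarray | None = None,
                    n_bins: int = 4) -> tuple[np.ndarray, np.ndarray]:
    """Top-k features by MI with paired inclusion of CSP partners.

    Returns (selected indices, MI score per candidate feature). The top k
    features by MI (ties broken by lower index) are taken; whenever a
    selected feature has a CSP eigenvector partner, the partner joins the
    set too, so |selected| <= 2k. Selected indices are ordered by MI
    descending, ties by index ascending. k exceeding the number of
    features selects everything.
    """
    features = np.asarray(features, dtype=np.float64)
    n_feat = features.shape[1]
    if k < 1:
        raise ValueError("k must be >= 1")
    scores = np.array([mutual_information(features[:, j], labels, n_bins)
                       for j in range(n_feat)])
    order = np.lexsort((np.arange(n_feat), -scores))  # MI desc, index asc
    top = order[:min(k, n_feat)]
    chosen = set(top.tolist())
    if partners is not None:
        partners = np.asarray(partners)
        for j in top:
            chosen.add(int(partners[j]))
    rank = {int(j): i for i, j in enumerate(order)}
    selected = np.array(sorted(chosen, key=lambda j: rank[j]), dtype=int)
    return selected, scores


@dataclass
class FBCSPModel:
    """Fitted filter-bank CSP with selected features.

    bands hold the admissible (possibly Nyquist-clipped) bands actually
    fitted; csp_models[i] is the list of one-vs-rest CSP models for
    bands[i]; selected indexes the concatenated (band-major, class-major)
    feature vector; mi_scores is the MI of every candidate feature.
    """

    bands: list[BandSpec]
    csp_models: list[list[CSPModel]]
    selected: np.ndarray
    mi_scores: np.ndarray
    partners: np.ndarray
    n_pairs: int
    filter_order: int
    sfreq: float
    classes: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))

    @property
    def n_candidate_features(self) -> int:
        return int(self.mi_scores.size)


def _candidate_features(epochs: EpochSet, bands: list[BandSpec],
                        csp_models: list[list[CSPModel]],
                        order: int) -> np.ndarray:
    blocks = []
    for band, models in zip(bands, csp_models):
        filtered = bandpass_filter(epochs, band, order=order)
        blocks.append(multiclass_features(models, filtered))
    return np.hstack(blocks)


def admissible_bands(bands: list[BandSpec], sfreq: float) -> list[BandSpec]:
    """Clip each band to Nyquist; drop bands wholly above it."""
    kept = []
    for band in bands:
        clipped = clip_band(band, sfreq)
        if clipped is not None:
            kept.append(clipped)
    return kept


def fit_fbcsp(epochs: EpochSet, labels: np.ndarray | None = None, k: int = 4,
              bands: list[BandSpec] | None = None, n_pairs: int = 2,
              n_bins: int = 4, filter_order: int = 4,
              select: bool = True) -> FBCSPModel:
    """Fit the filter bank, per-band CSP and the MI feature selection.

    ``select=False`` keeps every candidate feature (used by the plain-CSP
    baseline preset); MI scores are still computed for inspection. Raises
    when no filter-bank band is admissible at the epoch's sampling rate.
    """
    if labels is None:
        labels = epochs.labels
    labels = np.asarray(labels)
    if bands is None:
        bands = build_filter_bank()
    usable = admissible_bands(bands, epochs.sfreq)
    if not usable:
        raise ValueError(
            f"no filter-bank band admissible at sfreq={epochs.sfreq} Hz"
        )
    csp_models = []
    for band in usable:
        filtered = bandpass_filter(epochs, band, order=filter_order)
        csp_models.append(
            fit_csp_multiclass(filtered.data, labels, n_pairs=n_pairs, band=band)
        )
    partners = _stack_partners(csp_models)
    feats = _candidate_features(epochs, usable, csp_models, filter_order)
    if select:
        selected, scores = select_features(feats, labels, k,
                                           partners=partners, n_bins=n_bins)
    else:
        scores = np.array([mutual_information(feats[:, j], labels, n_bins)
                           for j in range(feats.shape[1])])
        selected = np.arange(feats.shape[1])
    return FBCSPModel(bands=usable, csp_models=csp_models, selected=selected,
                      mi_scores=scores, partners=partners, n_pairs=n_pairs,
                      filter_order=filter_order, sfreq=epochs.sfreq,
                      classes=np.unique(labels))


def _stack_partners(csp_models: list[list[CSPModel]]) -> np.ndarray:
    parts, offset = [], 0
    for models in csp_models:
        block = multiclass_partners(models)
        parts.append(block + offset)
        offset += block.size
    return np.concatenate(parts)


def fbcsp_transform(model: FBCSPModel, epochs: EpochSet) -> np.ndarray:
    """Selected FBCSP features for new epochs, (n_trials, |selected|).

    Rows are independent: transforming trials one at a time gives the same
    result as a batch transform.
    """
    if not math.isclose(epochs.sfreq, model.sfreq, rel_tol=1e-9):
        raise ValueError(
            f"model fitted at {model.sfreq} Hz, epochs at {epochs.sfreq} Hz"
        )
    feats = _candidate_features(epochs, model.bands, model.csp_models,
                                model.filter_order)
    return feats[:, model.selected]
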