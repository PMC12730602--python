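"""Common spatial patterns: spatial-filter estimation and log-variance features.

CSP finds spatial filters w maximizing the variance ratio between two
classes of multichannel EEG. With trace-normalized class covariance means
Sigma_a and Sigma_b, filters solve the generalized eigenproblem

    Sigma_a w = lambda (Sigma_a + Sigma_b) w,

whose eigenvalues lie in [0, 1]: lambda near 1 means the component carries
almost all its variance in class a, near 0 in class b, and 0.5 is
uninformative. The filters simultaneously diagonalize both covariances.
The n_pairs most extreme eigenvalues from each end of the spectrum are
retained; features are the log of each component's normalized variance.

The 4-class task is handled one-vs-rest: one CSP model per class, feature
vectors concatenated in class-index order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg

from .epochs import BandSpec, EpochSet

#: condition-number threshold beyond which shrinkage is escalated
_COND_LIMIT = 1e10


@dataclass
class CSPModel:
    """Fitted CSP filters for one two-class contrast in one band.

    filters : (n_components, n_channels) — rows project channels to components.
    patterns : (n_channels, n_components) — forward-model columns mapping
        components back to channel topographies ((Sigma_a+Sigma_b) w per
        component, the dual basis of the filters).
    eigenvalues : per-component lambda in [0, 1], ordered by discriminability
        (|lambda - 0.5| descending, ties by eigenvalue rank).
    partners : per-component index of the opposite-end eigenvector it was
        selected with; used by paired feature selection.
    target_class : the "a" class of the contrast (one-vs-rest index, or a
        (a, b) tuple for an explicit binary contrast).
    """

    filters: np.ndarray
    patterns: np.ndarray
    eigenvalues: np.ndarray
    partners: np.ndarray
    band: BandSpec | None = None
    target_class: object = None

    @property
    def n_components(self) -> int:
        return self.filters.shape[0]


def trial_covariance(trial: np.ndarray) -> np.ndarray:
    """Trace-normalized spatial covariance (X X^T)/trace(X X^T) of one trial.

    Trace normalization removes per-trial global amplitude so that the class
    mean is not dominated by high-power trials. An all-zero trial has no
    defined normalization and raises.
    """
    X = np.asarray(trial, dtype=np.float64)
    if X.ndim != 2 or X.shape[1] < 2:
        raise ValueError(f"trial must be (channels, samples>=2), got {X.shape}")
    C = X @ X.T
    tr = np.trace(C)
    if tr <= 0:
        raise ValueError("all-zero trial: covariance normalization undefined")
    return C / tr


def class_covariance(data: np.ndarray, shrinkage: float = 0.0) -> np.ndarray:
    """Mean of trace-normalized per-trial covariances, optionally shrunk
    toward the scaled identity: (1-g) C + g (trace(C)/n) I."""
    covs = np.stack([trial_covariance(t) for t in data])
    C = covs.mean(axis=0)
    if shrinkage > 0:
        n = C.shape[0]
        C = (1.0 - shrinkage) * C + shrinkage * (np.trace(C) / n) * np.eye(n)
    return C


def _as_data(epochs) -> np.ndarray:
    if isinstance(epochs, EpochSet):
        return epochs.data
    arr = np.asarray(epochs, dtype=np.float64)
    if arr.ndim != 3:
        raise ValueError("expected EpochSet or (trials, channels, samples) array")
    return arr


def csp_from_covariances(cov_a: np.ndarray, cov_b: np.ndarray, n_pairs: int = 2,
                         band: BandSpec | None = None,
                         target_class=None) -> CSPModel:
    """Solve the CSP generalized eigenproblem on two class covariances.

    Retains the n_pairs largest- and n_pairs smallest-eigenvalue filters
    (2*n_pairs components). If the composite covariance is poorly
    conditioned, shrinkage toward the scaled identity is escalated
    automatically; a covariance that stays singular raises LinAlgError.
    """
    cov_a = np.asarray(cov_a, dtype=np.float64)
    cov_b = np.asarray(cov_b, dtype=np.float64)
    n_ch = cov_a.shape[0]
    if cov_a.shape != cov_b.shape or cov_a.shape != (n_ch, n_ch):
        raise ValueError("covariances must be square and same shape")
    if n_ch < 2 or n_pairs < 1 or 2 * n_pairs > n_ch:
        raise ValueError(f"n_pairs={n_pairs} invalid for {n_ch} channels")

    evals = None
    for gamma in (0.0, 1e-10, 1e-6, 1e-2):
        a, b = cov_a, cov_b
        if gamma > 0:
            eye = np.eye(n_ch)
            a = (1 - gamma) * a + gamma * (np.trace(a) / n_ch) * eye
            b = (1 - gamma) * b + gamma * (np.trace(b) / n_ch) * eye
        comp = a + b
        if np.linalg.cond(comp) > _COND_LIMIT:
            continue
        try:
            evals, evecs = scipy.linalg.eigh(a, comp)
            break
        except scipy.linalg.LinAlgError:
            continue
    if evals is None:
        raise np.linalg.LinAlgError(
            "composite covariance singular even after shrinkage"
        )
    # eigh returns ascending eigenvalues; eigenvectors satisfy
    # v^T (a+b) v = 1, hence v^T a v + v^T b v = 1 componentwise.
    order = np.concatenate([
        np.arange(n_ch - 1, n_ch - 1 - n_pairs, -1),  # largest first
        np.arange(0, n_pairs),                         # smallest, ascending
    ])
    lam = evals[order]
    W = evecs[:, order].T  # (2*n_pairs, n_channels)
    # patterns from the full eigenbasis: A = (a+b) V, the forward-model
    # columns dual to the filters (inv(V)^T restricted to kept components)
    patterns = (comp @ evecs)[:, order]
    m = n_pairs
    partners = np.array([(i + m) % (2 * m) for i in range(2 * m)])

    # reorder by discriminability: distance from 0.5, descending
    rank = np.lexsort((np.arange(2 * m), -np.abs(lam - 0.5)))
    inv = np.empty_like(rank)
    inv[rank] = np.arange(2 * m)
    lam = lam[rank]
    W = W[rank]
    patterns = patterns[:, rank]
    partners = inv[partners[rank]]
    return CSPModel(filters=W, patterns=patterns, eigenvalues=lam,
                    partners=partners, band=band, target_class=target_class)


def fit_csp(epochs_a, epochs_b, n_pairs: int = 2, band: BandSpec | None = None,
            target_class=None) -> CSPModel:
    """Fit binary CSP from two sets of trials (EpochSet or 3-D arrays)."""
    data_a = _as_data(epochs_a)
    data_b = _as_data(epochs_b)
    if data_a.shape[0] == 0 or data_b.shape[0] == 0:
        raise ValueError("both classes must contain at least one trial")
    if data_a.shape[1] != data_b.shape[1]:
        raise ValueError("classes must share the channel set")
    cov_a = class_covariance(data_a)
    cov_b = class_covariance(data_b)
    return csp_from_covariances(cov_a, cov_b, n_pairs=n_pairs, band=band,
                                target_class=target_class)


def csp_features(model: CSPModel, epochs) -> np.ndarray:
    """Normalized log-variance features, (n_trials, n_components).

    feature_ij = log( var(w_j x_i) / sum_k var(w_k x_i) ). Invariant to a
    global scaling of the trial. A trial with zero total projected
    variance raises.
    """
    data = _as_data(epochs)
    if data.shape[1] != model.filters.shape[1]:
        raise ValueError(
            f"model fitted on {model.filters.shape[1]} channels, data has {data.shape[1]}"
        )
    # (trials, components, samples)
    projected = np.einsum("ck,tks->tcs", model.filters, data)
    variances = projected.var(axis=-1)
    totals = variances.sum(axis=-1, keepdims=True)
    if np.any(totals <= 0):
        raise ValueError("zero-variance projected trial; features undefined")
    return np.log(variances / totals)


def fit_csp_multiclass(epochs, labels=None, n_pairs: int = 2,
                       band: BandSpec | None = None) -> list[CSPModel]:
    """One-vs-rest CSP: K models for K > 2 classes, one model for K == 2.

    Feature concatenation across models follows class-index order. Every
    class needs at least 2 trials.
    """
    data = _as_data(epochs)
    if labels is None:
        labels = epochs.labels
    labels = np.asarray(labels)
    classes = np.unique(labels)
    counts = {int(c): int((labels == c).sum()) for c in classes}
    small = [c for c, n in counts.items() if n < 2]
    if small:
        raise ValueError(f"class(es) {small} have fewer than 2 trials")
    if classes.size == 2:
        a, b = classes
        return [fit_csp(data[labels == a], data[labels == b], n_pairs=n_pairs,
                        band=band, target_class=(int(a), int(b)))]
    return [
        fit_csp(data[labels == c], data[labels != c], n_pairs=n_pairs,
                band=band, target_class=int(c))
        for c in classes
    ]


def multiclass_features(models: list[CSPModel], epochs) -> np.ndarray:
    """Concatenate per-model log-variance features in class-index order."""
    return np.hstack([csp_features(m, epochs) for m in models])


def multiclass_partners(models: list[CSPModel]) -> np.ndarray:
    """Partner map over the concatenated feature vector of several models."""
    parts, offset = [], 0
    for m in models:
        parts.append(m.partners + offset)
        offset += m.n_components
    return np.concatenate(parts) if parts else np.empty(0, dtype=int)
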