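"""Metrics, cross-validation, the sampling-rate degradation sweep and the
temporal-grid search.

Evaluation follows the paired design used for degradation studies: the
stratified 5-fold split is computed once from the labels and reused at
every sampling rate, so per-fold accuracies are comparable and the
t-test against the reference rate is genuinely paired. Family-wise error
over the non-reference rates is controlled by Bonferroni correction at
alpha = 0.05.

Conventions for degenerate paired t-tests (needed when a rate is compared
with itself): all-zero differences give p = 1; zero-variance differences
with nonzero mean give p = 0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import StratifiedKFold

from .epochs import EpochSet
from .pipeline import PipelineSpec, fit_pipeline
from .preprocessing import bandpass_filter, clip_band, resample_epochs, sweep_rates
from .segmentation import DEFAULT_GRID_VALUES, SegmentConfig, enumerate_segments
from .epochs import BandSpec

logger = logging.getLogger(__name__)

ALPHA = 0.05


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

def accuracy(y_true, y_pred) -> float:
    """Fraction of correctly classified trials (trace of the confusion
    matrix over its total, for any number of classes)."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.size == 0 or y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must be equal-length and non-empty")
    return float(np.mean(y_true == y_pred))


def confusion_matrix(y_true, y_pred, n_classes: int | None = None) -> np.ndarray:
    """K x K count matrix; rows are true classes, columns predictions."""
    y_true = np.asarray(y_true, dtype=np.int64)
    y_pred = np.asarray(y_pred, dtype=np.int64)
    if n_classes is None:
        n_classes = int(max(y_true.max(), y_pred.max())) + 1
    cm = np.zeros((n_classes, n_classes), dtype=np.int64)
    np.add.at(cm, (y_true, y_pred), 1)
    return cm


def cohens_kappa(y_true, y_pred) -> float:
    """Chance-corrected agreement, kappa = (acc - p_e) / (1 - p_e).

    p_e is the expected chance agreement from the marginal class
    frequencies of the two label vectors. The degenerate case p_e == 1
    (both raters constant on one category) returns 0.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.size == 0 or y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must be equal-length and non-empty")
    acc = accuracy(y_true, y_pred)
    cats = np.union1d(y_true, y_pred)
    n = y_true.size
    p_e = sum((np.mean(y_true == c)) * (np.mean(y_pred == c)) for c in cats)
    if abs(1.0 - p_e) < 1e-12:
        return 0.0
    return float((acc - p_e) / (1.0 - p_e))


# ---------------------------------------------------------------------------
# Statistical tests
# ---------------------------------------------------------------------------

def paired_ttest(a, b) -> float:
    """Two-sided paired t-test p-value on per-fold metric vectors.

    Degenerate conventions: identical vectors -> 1.0; zero-variance
    differences with nonzero mean -> 0.0.
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape or a.size < 2:
        raise ValueError("need two equal-length vectors of length >= 2")
    d = a - b
    if np.ptp(d) == 0.0:
        return 1.0 if d[0] == 0.0 else 0.0
    return float(stats.ttest_rel(a, b).pvalue)


def bonferroni(p_values, m: int | None = None) -> np.ndarray:
    """Bonferroni correction: min(1, p * m), m defaulting to len(p_values)."""
    p = np.asarray(p_values, dtype=np.float64)
    if m is None:
        m = p.size
    return np.minimum(1.0, p * m)


# ---------------------------------------------------------------------------
# Cross-validation
# ---------------------------------------------------------------------------

@dataclass
class EvalResult:
    """Cross-validated metrics for one pipeline on one condition."""

    accuracy: float
    kappa: float
    fold_accuracies: np.ndarray
    fold_kappas: np.ndarray
    confusion: np.ndarray

    def to_frame(self, **annotations) -> pd.DataFrame:
        rows = [
            {**annotations, "fold": i, "accuracy": a, "kappa": k}
            for i, (a, k) in enumerate(zip(self.fold_accuracies, self.fold_kappas))
        ]
        return pd.DataFrame(rows)


def stratified_folds(labels: np.ndarray, n_folds: int = 5,
                     seed: int = 0) -> list[tuple[np.ndarray, np.ndarray]]:
    """Reusable stratified (train, test) index pairs, deterministic in seed."""
    labels = np.asarray(labels)
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    counts = np.bincount(labels)
    if counts.min() < n_folds:
        raise ValueError(
            f"smallest class has {counts.min()} trials; cannot stratify "
            f"into {n_folds} folds"
        )
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    return [(tr, te) for tr, te in skf.split(np.zeros(labels.size), labels)]


def cross_validate(spec: PipelineSpec, epochs: EpochSet,
                   labels: np.ndarray | None = None, n_folds: int = 5,
                   seed: int = 0,
                   folds: list[tuple[np.ndarray, np.ndarray]] | None = None,
                   ) -> EvalResult:
    """Stratified k-fold evaluation of a pipeline spec.

    All fitting (band filters, CSP, MI selection, classifier calibration)
    happens inside the training fold; every trial is tested exactly once.
    The headline accuracy is the pooled trace/total of the summed
    confusion matrix (equal to the fold mean for equal-size folds);
    per-fold values are kept for paired testing.
    """
    if labels is None:
        labels = epochs.labels
    labels = np.asarray(labels)
    if folds is None:
        folds = stratified_folds(labels, n_folds, seed)
    n_classes = int(labels.max()) + 1
    fold_acc, fold_kap = [], []
    confusion = np.zeros((n_classes, n_classes), dtype=np.int64)
    for train, test in folds:
        pipe = fit_pipeline(spec, epochs.select_trials(train), labels[train],
                            seed=seed)
        pred = pipe.predict(epochs.select_trials(test))
        fold_acc.append(accuracy(labels[test], pred))
        fold_kap.append(cohens_kappa(labels[test], pred))
        confusion += confusion_matrix(labels[test], pred, n_classes)
    return EvalResult(
        accuracy=float(np.trace(confusion) / confusion.sum()),
        kappa=float(np.mean(fold_kap)),
        fold_accuracies=np.array(fold_acc),
        fold_kappas=np.array(fold_kap),
        confusion=confusion,
    )


# ---------------------------------------------------------------------------
# Degradation sweep
# ---------------------------------------------------------------------------

@dataclass
class SweepResult:
    """Per-rate cross-validated metrics and paired statistics vs. the
    reference rate."""

    rates: list[float]
    reference_rate: float
    results: dict[float, EvalResult]
    failures: dict[float, str]
    p_raw: dict[float, float]
    p_corrected: dict[float, float]
    significant: dict[float, bool]
    spec: PipelineSpec = None

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for rate in self.rates:
            if rate in self.failures:
                continue
            r = self.results[rate]
            for fold, (a, k) in enumerate(zip(r.fold_accuracies, r.fold_kappas)):
                rows.append({
                    "method": self.spec.method if self.spec else "",
                    "sfreq": rate, "fold": fold, "accuracy": a, "kappa": k,
                })
        return pd.DataFrame(rows)

    def summary(self) -> pd.DataFrame:
        rows = []
        for rate in self.rates:
            if rate in self.failures:
                rows.append({"sfreq": rate, "accuracy": np.nan, "kappa": np.nan,
                             "p_raw": np.nan, "p_corrected": np.nan,
                             "significant": False, "failure": self.failures[rate]})
                continue
            r = self.results[rate]
            rows.append({
                "sfreq": rate, "accuracy": r.accuracy, "kappa": r.kappa,
                "p_raw": self.p_raw.get(rate, np.nan),
                "p_corrected": self.p_corrected.get(rate, np.nan),
                "significant": self.significant.get(rate, False),
                "failure": "",
            })
        return pd.DataFrame(rows)


def degradation_sweep(spec: PipelineSpec, epochs: EpochSet,
                      labels: np.ndarray | None = None,
                      rates: list[float] | None = None, n_folds: int = 5,
                      seed: int = 0, reference_rate: float | None = None,
                      prefilter: BandSpec | None = BandSpec(8.0, 32.0),
                      filter_order: int = 4) -> SweepResult:
    """Evaluate a pipeline across progressively degraded sampling rates.

    The epochs are band-pass filtered once at the original rate (default
    8-32 Hz), then resampled to each target rate and cross-validated with
    the identical fold assignment. Per-fold accuracies at each rate are
    compared with the reference rate (default: the highest rate) by
    paired t-tests, Bonferroni-corrected over the non-reference rates.
    Rates at which the pipeline cannot run (no admissible band) are
    recorded as failures, not skipped silently.
    """
    if labels is None:
        labels = epochs.labels
    labels = np.asarray(labels)
    if rates is None:
        rates = sweep_rates()
    if not rates:
        raise ValueError("rates must be non-empty")
    if reference_rate is None:
        reference_rate = max(rates)

    if prefilter is not None:
        band = clip_band(prefilter, epochs.sfreq)
        if band is not None:
            epochs = bandpass_filter(epochs, band, order=filter_order)
        else:
            logger.warning("prefilter %s inadmissible at %g Hz; skipped",
                           prefilter, epochs.sfreq)
    folds = stratified_folds(labels, n_folds, seed)

    results: dict[float, EvalResult] = {}
    failures: dict[float, str] = {}
    for rate in rates:
        try:
            degraded = resample_epochs(epochs, rate)
            results[rate] = cross_validate(spec, degraded, labels,
                                           seed=seed, folds=folds)
        except ValueError as exc:
            logger.warning("rate %g Hz failed: %s", rate, exc)
            failures[rate] = str(exc)

    p_raw: dict[float, float] = {}
    if reference_rate not in results:
        raise ValueError(f"reference rate {reference_rate} Hz failed or absent")
    ref = results[reference_rate].fold_accuracies
    compared = [r for r in rates if r != reference_rate and r in results]
    for rate in compared:
        p_raw[rate] = paired_ttest(results[rate].fold_accuracies, ref)
    corrected = bonferroni([p_raw[r] for r in compared], m=len(compared))
    p_corrected = dict(zip(compared, (float(p) for p in corrected)))
    significant = {r: p_corrected[r] < ALPHA for r in compared}
    return SweepResult(rates=list(rates), reference_rate=reference_rate,
                       results=results, failures=failures, p_raw=p_raw,
                       p_corrected=p_corrected, significant=significant,
                       spec=spec)


# ---------------------------------------------------------------------------
# Temporal-grid search
# ---------------------------------------------------------------------------

@dataclass
class GridResult:
    """Mean cross-validated accuracy over the (window, step) grid.

    The matrix is indexed [step, window] (rows: moving length, columns:
    window length), matching the conventional heatmap layout.
    """

    w_values: list[float]
    s_values: list[float]
    matrix: np.ndarray
    best_config: SegmentConfig
    best_accuracy: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.s_values,
                            columns=self.w_values)


def grid_search(epochs: EpochSet, labels: np.ndarray | None = None,
                w_values=DEFAULT_GRID_VALUES, s_values=DEFAULT_GRID_VALUES,
                n_folds: int = 5, seed: int = 0, k: int = 4,
                n_pairs: int = 2, base_spec: PipelineSpec | None = None,
                ) -> GridResult:
    """Cross-validate FBCSP-TS over every (window, step) combination.

    Configurations that enumerate identical segment lists (e.g. every step
    when the window spans the whole trial) are computed once and shared.
    The argmax breaks ties toward the larger window, then the smaller step.
    """
    if labels is None:
        labels = epochs.labels
    labels = np.asarray(labels)
    if base_spec is None:
        base_spec = PipelineSpec(method="fbcsp-ts", k=k, n_pairs=n_pairs)
    folds = stratified_folds(labels, n_folds, seed)
    T = epochs.trial_length
    matrix = np.full((len(s_values), len(w_values)), np.nan)
    cache: dict[tuple, float] = {}
    best = (-np.inf, -np.inf, np.inf, None)  # (acc, window, -step? ...)
    for i, s in enumerate(s_values):
        for j, w in enumerate(w_values):
            config = SegmentConfig(min(w, T), s, T)
            key = tuple(enumerate_segments(config))
            if key not in cache:
                spec = base_spec.with_segments(config.window_length, s)
                res = cross_validate(spec, epochs, labels, seed=seed,
                                     folds=folds)
                cache[key] = res.accuracy
            acc = cache[key]
            matrix[i, j] = acc
            cand = (acc, w, -s)
            if cand > (best[0], best[1], best[2]):
                best = (acc, w, -s, config)
    return GridResult(w_values=list(w_values), s_values=list(s_values),
                      matrix=matrix, best_config=best[3],
                      best_accuracy=float(best[0]))
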