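# Methods

This note documents the models, estimators and numerical conventions the
package implements, the design choices taken where the method family
leaves them open, and what the synthetic benchmark does and does not
establish.

## Data model

All pipelines operate on an `EpochSet`: a dense trial tensor
(n_trials × n_channels × n_samples, microvolts), integer labels, the
sampling frequency and the epoch window in seconds relative to cue onset.
Invariants enforced at construction: finite data, sfreq > 0, labels
forming a contiguous set {0..K−1} with K ≥ 2, and
n_samples = round(sfreq · window length). Time windows are half-open
[start, end); seconds map to sample indices via round(t · sfreq), which
keeps segment boundaries consistent after resampling. Because every
`EpochSet` must contain all K classes, per-class trial groups are passed
to the CSP fitting routines as plain arrays rather than as sub-EpochSets.

Epoch windows for the reference datasets default to (2.0, 6.0) s for the
4-class 250 Hz set (cue at 2 s, imagery until 6 s) and (0.0, 4.0) s after
the cue for the binary 100 Hz set; both are configurable, since only the
4 s duration is essential.

## Preprocessing

* **Band-pass:** Butterworth, default order 4, applied forward–backward
  (`sosfiltfilt`) for zero phase; effective roll-off is twice the
  one-pass slope. The broad artifact-rejection band is 8–32 Hz. The order
  is a convention of EEG practice — stable on 0.5 s segments while still
  giving > 20 dB attenuation one octave beyond each edge.
* **Resampling:** Fourier-domain (`scipy.signal.resample`), output length
  exactly round(N·f_target/f_original). Frequency-domain truncation is
  intrinsically anti-aliasing, so no additional low-pass is applied after
  resampling.
* **Nyquist policy at degraded rates:** a band whose high edge reaches
  0.95 × Nyquist is clipped to that limit with a logged warning; a band
  whose *low* edge reaches it is dropped. This keeps every pipeline
  defined down to 10 Hz: at 10 Hz only the 4–4.75 Hz remnant of the
  4–8 Hz band survives, and decoding falls to chance because no μ/β
  information remains — the scientifically expected outcome, produced
  gracefully instead of by exception. Rates at which *no* band survives
  are recorded as explicit failures by the sweep.
* Filtering precedes resampling in the degradation experiment.

## CSP

Per-trial covariances are trace-normalized (XXᵀ/tr XXᵀ) and averaged per
class; if the composite covariance is ill-conditioned (condition number
> 1e10) both class covariances are shrunk toward the scaled identity
(1−γ)C + γ(trC/n)I with γ escalating through 1e−10, 1e−6, 1e−2 until the
generalized eigenproblem Σ₁w = λ(Σ₁+Σ₂)w is solvable; a covariance that
stays singular raises. Eigenvector normalization vᵀ(Σ₁+Σ₂)v = 1 makes the
two diagonalized class variances sum to one per component, so λ and 1−λ
are the component's class variances.

Components: the `n_pairs` largest-λ and `n_pairs` smallest-λ eigenvectors
(default 2 pairs per contrast, the FBCSP-literature convention), stored in
order of discriminability |λ−0.5| (ties broken by eigenvalue rank), with
an explicit partner map linking each component to its opposite-extreme
mate. Patterns (channel topographies) are the forward-model columns
(Σ₁+Σ₂)·v taken from the full eigenbasis — *not* the pseudo-inverse of
the truncated filter matrix, which lives in the wrong subspace when only
2·n_pairs of n_channels components are retained and visibly corrupts
pattern recovery on low-noise data.

Multiclass uses one-vs-rest (K models for K > 2; the method family never
specifies the decomposition, and one-vs-rest is the standard FBCSP
extension). Features are log(varⱼ/Σₖvarₖ) per component, concatenated in
class-index order; they are invariant to per-trial global scaling and to
consistent channel reordering.

## FBCSP

Filter bank: seven contiguous 4 Hz bands covering 4–32 Hz. Mutual
information is estimated by discretizing each feature into
equal-frequency bins (default 4) and evaluating the plug-in discrete MI
in bits — deterministic and adequate for *ranking* features; it is not a
consistent estimator of continuous MI, and no Parzen-window variant is
provided. Selection keeps the top-k features (default k = 4; ties broken
by feature index) and adds each selected feature's CSP partner, so at
most 2k features survive. Selection is refit independently inside every
training fold and every time segment.

## FBCSP-TS

Segments are the half-open windows [i·s, i·s+w) for
i = 0..⌊(T−w)/s⌋; the member count depends only on (T, w, s) in seconds,
never on the sampling rate. Each member refits the full FBCSP stack and
its own classifier on the training trials of its segment. The classifier
is an RBF-kernel SVM (C = 1, gamma = "scale") wrapped in Platt sigmoid
calibration fitted on unshuffled 3-fold out-of-fold decision values of
the member's training data — deterministic, and fitted strictly inside
the training fold. Fusion is the unweighted mean of member probability
matrices; argmax ties resolve to the lowest class index.

With w = T the ensemble has one member and is *identically* plain FBCSP —
all three method presets share one code path, so the CSP/FBCSP/FBCSP-TS
comparison isolates exactly what the filter bank and the segmentation
each add. The temporal grid search evaluates the 8 × 8 default grid
(0.5–4.0 s in 0.5 s steps on both axes); cells that enumerate the same
segment list (every step when w = T) are computed once and shared, and
the argmax breaks ties toward the larger window, then the smaller step.

## Evaluation and statistics

Accuracy is trace/total of the summed confusion matrix (equal to the
fold-mean for the equal-size stratified folds used); per-fold accuracies
and kappas are retained. Cohen's kappa uses
p_e = Σ_c p_true(c)·p_pred(c), with the degenerate p_e = 1 case defined
as 0. Cross-validation is stratified k-fold (default 5) with a seeded
shuffle; every fit — filters, CSP, MI selection, calibration — happens
inside the training fold.

The degradation sweep reuses one fold assignment across all rates so the
per-rate fold accuracies form genuinely paired samples; each rate is
compared with the reference (default: highest) rate by a two-sided paired
t-test, Bonferroni-corrected over the non-reference rates at α = 0.05.
Degenerate difference vectors are defined as p = 1 when identically zero
and p = 0 when constant nonzero — needed so a rate compared with itself
reports "no difference" rather than an error.

## Synthetic benchmark

The generator emulates the covariance structure the method family
exploits: one band-limited Gaussian source per class (band-passed white
noise, *not* a sinusoid, so covariance estimation is exercised
realistically), default bands 9–11, 13–15, 21–23 and 29–31 Hz (one per
μ/β filter-bank subband), mixed through a random orthonormal-column
matrix into the channels, plus spatially white Gaussian noise at a stated
linear SNR. A class's own source variance is amplified by the modulation
factor (default 6) inside the activation interval (default: whole trial)
on that class's trials only. Event-related modulation is amplification
rather than suppression; CSP is contrast-based, so the direction is
irrelevant. Defaults — 25 trials/class, 22 channels, 4 classes, 250 Hz,
4 s — mirror a single-subject 4-class MI session scaled to desk size.

What the benchmark does **not** contain: 1/f background EEG, volume-
conduction forward modeling, artifacts, non-stationarity across trials,
or inter-subject variability. Passing it therefore demonstrates the
*algorithmic* correctness of each stage (the right sources are found, the
right bands are ranked, the statistics behave), not expected accuracy on
real recordings.

Problem sizes for the shipped experiments were chosen at desk scale: 20
trials/class for the decoding and sweep checks, SNR 50 for separability
and pattern-recovery checks (the near-noise-free regime), SNR 5 for the
degradation sweep (learnable but unsaturated, so degradation is visible),
and the full 25-rate sweep at 5 folds.

## Known limitations

* The MI estimator's bin count (4) is a ranking heuristic; features with
  identical binned profiles tie and resolve by index.
* The CSP baseline keeps all 2·n_pairs·K features without MI selection;
  other baselines in the literature sometimes select subsets.
* Prediction requires an `EpochSet` containing at least two classes of
  labels (the container invariant); single-trial streaming prediction is
  out of scope, as is any online/adaptive CSP update.
* `grid_search` reports the pooled cross-validated accuracy per cell; on
  multi-subject datasets a per-subject mean would need an outer loop.
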