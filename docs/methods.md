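# Methods

## Problem setting

Four-class inner-speech EEG decoding: each trial is an epoched multichannel
segment time-locked to one silently verbalised Spanish direction word
(0 "arriba", 1 "abajo", 2 "derecha", 3 "izquierda"; the Spanish words are
authoritative and no English gloss is stored). Two regimes matter and behave
very differently: *subject-dependent* decoding (train and test on the same
person) and *subject-independent* decoding (test subjects entirely unseen
during training), where cross-subject variability dominates and accuracies
collapse toward the 25% chance level.

## The classifier

The base learner is an extremely randomized decision tree grown on a feature
matrix. At each node, `k = ⌈√d⌉` distinct non-constant features are drawn
uniformly (implemented as the first `k` non-constant entries of a random
feature permutation, which is the same distribution without scanning all `d`
columns); one cut-point per candidate is drawn uniformly inside that
feature's open (min, max) interval among the node's rows; candidates are
scored by Gini impurity decrease,
`Δ = G(parent) − (n_L·G(L) + n_R·G(R))/n` with `G = 1 − Σ p_k²`,
and ties resolve to the earliest draw. A node becomes a leaf when pure,
smaller than `min_samples_split` (default 2), at the depth cap (default
none), or when all its features are constant. Prediction routes rows by
`value < threshold`; the label is the argmax of leaf class counts (ties to
the lowest class index) and probabilities are the normalised counts. The
whole fit is a pure function of `(X, y, params)` including the seed.

The seed search ("BruteExtraTree") trains `m` such trees with consecutive
seeds `s₀ … s₀+m−1` — the models are completely independent — scores each on
a held-out development split by plain accuracy, and keeps the argmax,
smallest seed on ties. Selection never touches the test split: although one
could describe the goal as finding "the best seed for test accuracy", the
only defensible protocol selects on a development split, and that is what is
implemented. One shared development split serves all seeds. The budget
follows training-set size, `m = clamp(round(450000/n_train), 1000, 2500)`;
the constant 450 000 is chosen so the within-subject extreme (~160 training
rows) maps to the upper bound 2500 and the pooled multi-subject extreme
(~1800 rows) to the lower bound 1000, keeping total fitting time roughly
constant across regimes. This is a single selected tree, deliberately not an
averaged ensemble.

## Feature pipelines

All fitting uses training rows only; dev/test rows are only ever transformed.

* **raw** — trials flattened to `channels × samples` columns.
* **ica** — FastICA over channels, fitted on the concatenated training
  trials: whitening by eigendecomposition, symmetric decorrelation, logcosh
  contrast, iteration cap 500 at tolerance 1e-6, initialised from a fixed
  internal seed so refits are bit-identical; non-convergence is flagged in
  the feature matrix's `meta` and the last iterate is used. Each unmixed
  component's per-trial time series is summarised by (mean, population sd,
  energy). ICA operates in channel space (source separation); PCA operates
  on flattened trials (feature decorrelation) — both defensible readings,
  fixed here as the defaults, with raw-coefficient DWT output available
  behind a flag for users who want unsummarised features.
* **pca** — full-rank SVD-based PCA of the flattened training matrix, all
  components kept (a pure rotation; total variance preserved), deterministic
  sign convention (largest-magnitude loading positive).
* **csp_pair / csp_ova** — per contrast (6 class pairs, or 4 class-vs-rest),
  class covariances are means of trace-normalised per-trial covariances
  `X·Xᵗ/tr(X·Xᵗ)`; the generalized eigenproblem `C_i·w = λ(C_i+C_j)·w` is
  solved directly (λ ∈ [0,1], sorted descending; swapping the contrast maps
  λ ↦ 1−λ). A singular composite matrix gets one ridge-regularised retry
  with `ε = 1e-9·tr/n`. Per contrast `n_keep = 4` filters are retained, two
  from each end of the spectrum (the standard CSP practice when no component
  count is prescribed); features are `log(var(wᵗX))` with a variance floor
  of 1e-12.
* **car_dwt** — common average reference (subtract the instantaneous channel
  mean), then a multilevel DWT per channel with periodised signal extension,
  under which orthonormal wavelets conserve energy exactly (Parseval), with
  (mean, sd, energy) per band. Defaults: db4, level
  `min(5, ⌊log₂ n_samples⌋ − 1)`; Haar is used in the worked-example tests.
* **all** — column-wise concatenation in the fixed order (raw, ica, pca,
  csp_pair, csp_ova, car_dwt). Normalisation is applied once, after
  concatenation, not per part.

Normalisation is a fixed final step for every pipeline: per-feature z-score
with moments from the training rows (population sd); features with sd below
1e-12 are flagged constant and map to exactly 0.

## Evaluation protocols

Subject-dependent splits are stratified within one subject: per class,
`round(test_frac·n_c)` trials go to test (default 0.2), then
`round(dev_frac·n_remaining)` of the remainder to dev (default 0.2 — a
development fraction has to be fixed somewhere, and 20% of training rows is
the simplest choice). Subject-independent splits put *every* trial of the
held-out subject set in test and draw a stratified dev fraction from the
remaining subjects' trials; the subject sets of train∪dev and test are
disjoint by construction. The alternative of a subject-held-out development
split is deliberately not the default. Benchmark grids execute
split → featurize (fit on train) → normalise (fit on train) → train →
evaluate for every (model, method) cell; subject-dependent cells are
unweighted means over subjects; failed cells are flagged and the grid is
still returned; the CSV schema is fixed
(`axis1,axis2,train_acc,test_acc,status,seed`) and reruns under the same
master seed are byte-identical.

## The synthetic generator

The generator emulates a multi-subject inner-speech recording regime:
10 subjects, 4 classes, per-(subject, class) trial counts uniform on
[45, 60], 1-s epochs at 256 Hz over 16 channels. Class structure is planted
as a source-variance contrast: a base mixing matrix `A0` (standard normal)
maps `n_sources = n_channels` sources to channels; subject `j` uses
`A_j = A0 + σ_subj·E_j` (default σ 0.3); class `c` owns a contiguous block
of `n_sources/4` sources whose variance is `class_power_contrast` (default
3) while all others are 1. Sources are white Gaussian noise band-limited to
1–40 Hz (4th-order Butterworth, forward-backward, gain-normalised to unit
power — a plausible EEG band with zero phase distortion); sensor noise is
white and scaled per trial so the signal-to-noise power ratio equals `snr`
(default 2) exactly. The master seed spawns four named substreams (mixing,
sources, noise, counts), so generation is a pure function of the config and
component draws do not interfere.

What the generator does *not* emulate: biophysical forward modelling,
electrode geometry, 1/f spectra, artifacts (blinks, EMG), non-stationarity,
or class-dependent *spectral* (rather than spatial-power) signatures.
Passing tests therefore demonstrate that the stack recovers planted
spatial-covariance structure under subject-specific mixing and realistic
trial counts — not that any particular accuracy transfers to recorded EEG.
One consequence of the Gaussian band-limited sources with a shared spectrum
is that they are not ICA-identifiable (any rotation of whitened Gaussians is
an equally valid solution), so ICA source-recovery is tested on a
non-Gaussian (Laplace) two-source mixture instead, the setting where the
model is identifiable.

## Experiment sizes and numerical choices

The canned experiments (`bruteeg.experiments`) run the full default
generator regime (~2100 trials per dataset) with CSP-pair features — the
most informative compact representation on planted covariance structure —
and scaled search budgets chosen once: `m = 32` per fit inside the
multi-seed contrast and chance experiments, `m = 200` with per-repetition
averaging over all 10 subjects in the seed-search-vs-single-tree comparison,
and 11 single-seed trees per subject for the median baseline. The full
budget rule remains the default (`m='auto'`) outside these experiments.
Tolerances: CSP eigenvalues agree with a dense generalized eigensolver to
1e-10; Parseval to 1e-8 relative; z-score moments to 1e-10; the seed search
agrees with its exhaustive oracle exactly.

## Known limitations

* The epoch container stores any channel count; conversion from original
  recording formats (BDF/FIF/BIDS) is an external step, not part of the
  tested surface.
* Trees store Python node objects; fitting is vectorised per node but very
  wide feature matrices with deep trees are slower than a compiled learner.
* The subject-independent development split is stratified over the training
  subjects' trials, not subject-held-out; with few subjects this can make
  dev accuracy an optimistic proxy for transfer.
* Four classes are assumed throughout the splitting/benchmark layer
  (`n_classes` is configurable on the tree itself).
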