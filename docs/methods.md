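# Methods

`eegfusion` implements an EEG-based three-class dementia screen (normal
control NC = 0, frontotemporal dementia FTD = 1, Alzheimer's disease AD = 2)
in two stages: a dual-branch neural feature extractor over resting-state EEG,
and a two-factor clinical decision layer that fuses the network's predictions
with the subject's Mini-Mental State Examination (MMSE) score.

## Signal model and preprocessing

Recordings are 19-channel (10–20 montage) resting-state EEG at 250 Hz,
at least 40 s long.  Each recording is turned into two parallel inputs:

- **Time domain** — ten contiguous, non-overlapping 4-s windows taken from
  the recording start (`segment_time_domain`).  10 × 4 s × 250 Hz gives ten
  19 × 1000 matrices per subject.
- **Frequency domain** — the five canonical rhythm bands, delta 0.5–4,
  theta 4–8, alpha 8–13, beta 13–25 and gamma 25–45 Hz, each obtained by
  zero-phase (forward–backward) 4th-order Butterworth band-pass filtering of
  every channel (`decompose_bands`).  Zero-phase filtering keeps the
  decomposition linear and free of group delay; the filter order is
  configurable.

Welch PSDs (`welch_psd`, Hann windows, default 2 s at 50 % overlap, both
configurable) are used for spectral analysis and as the oracle that validates
the synthetic generator.  Note the estimator's resolution: resolving the
0.5 Hz lower delta edge requires windows of several seconds (the validation
tests use 8-s windows, 0.125 Hz resolution).

Amplitude normalization is a per-channel z-score of the **whole recording**,
applied before segmentation and band decomposition (toggleable).  Normalizing
each band matrix separately would equalize band variances and thereby erase
the relative band-power structure that distinguishes the classes; normalizing
the broadband recording removes absolute scale (sensor gain) while keeping
the spectral composition intact.

## The dual-branch network

**Transformer branch.**  Each 4-s segment is cut per channel into
fixed-length patches (default 100 samples), linearly embedded (default 128
dimensions) and given a within-channel positional embedding that is *shared
across channels* — so the branch is equivariant to channel permutation and
the 19 electrode rows keep their identity.  A pre-norm transformer encoder
(default depth 2, 4 heads, scaled dot-product attention with
softmax(qkᵀ/√d_head)·v per head, concatenated and projected) processes all
19 × 10 tokens jointly; tokens are then mean-pooled per channel and projected,
yielding a (19, 128) feature map.

**CNN branch.**  The five band signals are stacked into a
(band × channel × time) array and passed through 3 × 3 convolution blocks
with ReLU and temporal average pooling (default widths 8/16/32, pool factor
4), then globally averaged over time and projected per electrode row to
(19, 128).  The branch uses **no normalization layer by default**: in
band-decomposed EEG the class signal largely lives in the per-band signal
*scale* (e.g. elevated delta/theta and depressed alpha power in AD), and
per-example normalization of the activation maps provably removes exactly
that cue — with normalization enabled the branch's pooled features become
nearly scale-invariant and held-out accuracy collapses to chance.  An
instance-norm variant remains available (`cnn_norm="instance"`) for inputs
where scale is a nuisance rather than the signal.

**Fusion and filtering.**  The two (19, 128) maps are concatenated along the
feature axis, transformer block first, into a (19, 256) fused map — a
lossless, order-fixed feature-level fusion.  A CBAM-style filter then
rescales it in two steps: channel attention
σ(MLP(avgpool) + MLP(maxpool)) with a shared two-layer MLP (reduction ratio
8) produces per-feature weights in (0, 1); spatial attention
σ(conv7×7([channel-avg, channel-max])) produces per-electrode weights.  Both
are multiplicative, so the filter is an element-wise contraction.  On the
19 × 1 electrode layout the 7 × 7 kernel degenerates gracefully to effective
7 × 1 support through zero padding.

**Classifier and loss.**  Flatten → fully-connected (ReLU) →
fully-connected → softmax over the three classes; training minimises mean
cross-entropy −(1/N) Σᵢ Σ_c y_ic log p_ic with Adam (reference settings:
learning rate 5 × 10⁻⁴, 100 epochs, batch size 4).  A 10⁻¹² clamp inside the
log guards exactly-zero probabilities.  The hidden nonlinearity is ReLU;
sigmoid is reserved for the attention weights so the softmax/cross-entropy
pair stays well-defined.

**Training-time augmentation.**  Each training segment receives a random
circular time shift (on by default, `TrainConfig.augment_time_shift`).
Resting-state EEG is phase-random, so the shift is label-preserving; it
destroys the per-segment phase fingerprint that a high-capacity branch would
otherwise memorise on small cohorts (we observed the transformer branch
driving the training loss to zero by memorisation, starving the CNN path and
collapsing held-out accuracy).  With augmentation disabled and a zero
learning rate, loss traces are exactly constant — a contract the test suite
asserts.

## Evaluation

Cross-validation is **subject-wise** ten-fold: all segments of a subject stay
on one side of every split, which prevents segment-level leakage (and is
stricter than segment-level splitting).  Folds are class-stratified at the
subject level by default, so every fold's training side contains all three
classes — on cohorts of tens of subjects an unstratified split can drop an
entire class from training.  Metrics follow the clinical
conventions, in percent: accuracy (TP+TN)/(TP+TN+FP+FN), sensitivity
TP/(TP+FN) and 1−specificity 1−TN/(TN+FP), computed one-vs-rest per class; a
zero denominator yields NaN (an explicit undefined signal), never a silent
zero.  ROC curves are built by thresholding a class's probability against the
rest; AUC is the trapezoidal area (equivalently the Mann–Whitney pairwise
rank statistic, which the tests verify); three-class summaries are unweighted
macro means, with absent classes flagged undefined rather than averaged in.
Metrics are reported at segment level and at subject level (majority vote
over a subject's segments).

## Two-factor decision mechanism

For each subject the network yields ten per-segment probability vectors and
hard labels.  Their internal **consistency** P is the mean pairwise Pearson
correlation between segment probability vectors, clamped to [0, 1] (identical
vectors give P = 1; a pair of orthogonal one-hots gives Pearson −0.5 → 0).
Constant-vector pairs, where Pearson is undefined, score 1 if identical and 0
otherwise.  The mixture weight is λ = P, and

    AD_score = λ · mean(segment hard labels) + (1 − λ) · MMSE_score,

a convex combination of the two factors; the final class is the nearest
integer (half rounded up) clipped to {0, 1, 2}.  λ = 1 reproduces the
EEG-only decision, λ = 0 the MMSE-only one.  Alternative consistency pairings
are exposed behind a strategy option (`labels_vs_majority`).

The MMSE banding maps the raw 0–30 score to {0, 1, 2}: raw ≥ 27 → 2,
10 ≤ raw < 27 → 1, raw < 10 → 0.  **Caution:** this assigns the highest MMSE
band to AD and the lowest to NC — the reverse of clinical convention, where
higher MMSE means better cognition.  It is kept as the method's defining
banding; `preset="clinical"` reverses the direction, and the thresholds are
configurable.

## Synthetic data generator

Because the pipeline must be testable without any clinical download, the
generator emulates the qualitative group-level electrophysiology: each class
has a band-gain profile (NC alpha-dominant; AD with elevated delta/theta and
suppressed alpha; FTD element-wise between the two on that triplet), and a
recording is Σ_b √(gain_b) · n_b(t) + σ·w(t), where n_b is unit-power
band-limited Gaussian noise (white noise through the same zero-phase
Butterworth band-passes) and w is white sensor noise (σ = 0.1 by default).
A `contrast` knob in [0, 1] interpolates every class profile toward the
class-neutral mean: 1 gives the full profiles, 0 makes the classes
statistically identical.  MMSE raw scores are drawn uniformly within each
class's banding range (AD 27–30, FTD 10–26, NC 0–9).  Channels are
independent by default; a cross-channel mixing matrix can be supplied.

What the generator does **not** emulate: eye-blink/EMG artifacts (the target
datasets are pre-cleaned), 1/f background structure, within-class
heterogeneity of spectral profiles beyond the noise realisation, volume
conduction, and non-stationarity.  Passing the synthetic study therefore
demonstrates that the pipeline's machinery — preprocessing, both branches,
fusion, filtering, training, CV, and the decision layer — recovers planted
class structure; it does not certify clinical performance on real EEG.

## The packaged validation study (`eegfusion.study`)

The study runs end to end on one CPU in minutes by scaling sizes down, while
keeping the architecture and protocol identical in structure:

- cohort: 12 subjects (4 per class), 40 s at 250 Hz, noise_sd 0.1;
- model: feature_dim 32, embed 32, 2 heads, encoder depth 1, patch 250,
  CNN widths (4, 8), classifier hidden 32;
- band signals average-binned by 10 (25 Hz effective rate) before the CNN —
  the bands are narrowband, so their envelope structure survives;
- training: Adam, learning rate 3 × 10⁻³, batch 16, 15 epochs;
- parameter recovery: ten-fold subject-wise CV at contrast 1 (expected
  segment accuracy ≥ 90 %); chance collapse: stratified three-fold CV on an
  18-subject cohort at contrast 0 (expected 33 % ± 10 — stratification
  matters here, because unstratified leave-out on a tiny cohort biases an
  uninformative classifier systematically *below* chance); ablations
  (CNN-only vs dual-branch; filter off vs on) on shared three-fold splits;
  and the two-factor comparison, which reuses the contrast-0 predictions
  where EEG is uninformative but MMSE is class-banded, so the joint decision
  should match or beat EEG-only.

The full-size defaults (feature 128, embed 128, 4 heads, depth 2, CNN widths
8/16/32, learning rate 5 × 10⁻⁴, 100 epochs, batch 4) remain the package
defaults everywhere outside the study helpers.

## Numerical and design notes

- The network and its training run on a small in-repo reverse-mode autodiff
  engine over float64 NumPy arrays; gradients of every primitive are checked
  against central finite differences in the test suite.  All randomness
  (initialisation, shuffling, augmentation, data generation) flows through
  seeded `numpy.random.Generator` instances, so runs are bit-reproducible on
  a single thread, and eval-mode forward passes are deterministic.
- Ties in `max` gradients are split evenly; softmax uses max-subtraction;
  attention weight rows sum to 1 to 1e-6 by construction.
- The trapezoid AUC is computed as a positive area with x ascending (the
  rank-statistic equivalence fixes the sign convention).
- Checkpoints are a `.npz` of named arrays plus a JSON sidecar holding the
  full architecture description, so a checkpoint is self-describing.
- Known limitations: no GPU path and no minibatch parallelism (the intended
  regime is small clinical cohorts); the consistency statistic treats
  segment probability vectors as exchangeable and ignores their temporal
  order; the EEGLAB `.set` reader requires the optional `mne` dependency and
  infers class/MMSE from a BIDS `participants.tsv` when present.
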