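# Methods

This note records the models, conventions and design choices behind
`msvdfuse`, in the order data flows through the pipeline.

## Multi-resolution SVD

One analysis level maps X ∈ R^(2n)×(2m) to four n×m subbands through three
orthogonal steps: 2×2 blockification (block-row-major column ordering,
entries stacked UL, UR, LL, LR), full SVD of the 4×nm data matrix, and
row-wise reshaping of the scatter matrix T = UᵀA.  Conventions that the
printed index notation of the source material leaves ambiguous are pinned
by one binding contract: `deblockify` is the exact inverse of `blockify`,
and decompose → reconstruct is the identity to 1e-10 (tested across shapes
and depths).

* **Sign convention.** Each left singular vector's first non-zero entry is
  made non-negative (T is computed from the fixed U), so decompositions are
  deterministic across LAPACK drivers.  Under exactly degenerate singular
  values the subband *split* is still backend-dependent; reconstruction is
  exact regardless, so only subband identity, not the round trip, is
  non-contractual there.
* **Padding.** Shapes not divisible by 2^L are edge-replicated up to the
  next multiple (e.g. 6×60 → 8×60 for L = 2); the padding is recorded in
  the pyramid and cropped after reconstruction.  The maximum depth is
  floor(log2(min(shape))).
* **Default depth L = 1** for both fusion schemes: the matrices the
  pipeline actually fuses (6 channels × 60 samples; 2×4 feature blocks)
  support little more, and depth is configurable everywhere.

## Fusion rules

Per level: details fuse by element-wise maximum absolute value with sign
preserved (exact ties, a measure-zero event, take the first argument — the
EEG stream by pipeline convention), singular-vector matrices and the
coarsest approximation fuse by averaging.  The average of two orthogonal
matrices has spectral norm ≤ 1, which gives the tested norm bound
‖fused‖_F ≤ ‖X_a‖_F + ‖X_b‖_F, and self-fusion is the identity at every
API level.

For feature-based fusion the per-trial 6-vectors are zero-padded by two
entries into 2×4 matrices (6 has no even factorization); the padding is
cropped after reconstruction.  Each modality's feature columns are rescaled
to [0, 1] across trials before fusion so the max-absolute rule compares
commensurate magnitudes; this rescaling uses feature values only, never
labels.

## Signal conditioning

* **Filtering** is Butterworth in second-order-section form (stable at the
  0.0019 normalized corner the hemodynamic band requires).  Presets:
  `buccino`/`synthetic` — EEG band-pass 1–50 Hz order 4 causal, HbO/HbR
  band-pass 0.01–0.2 Hz order 4 **zero-phase**; `tuberlin` — EEG
  down-sampled to 200 Hz, band-pass 1–40 Hz order 6 zero-phase, NIRS
  down-sampled to 10 Hz, low-pass 0.2 Hz order 6 zero-phase.  The
  hemodynamic filter is zero-phase by design: a causal filter of that band
  delays the ~0.08 Hz trial-cycle component by several seconds and would
  misalign every trial window with its own response.  EEG causal filtering
  is unproblematic (group delay ≪ trial length in the pass band).
  Zero-phase filtering uses forward–backward application with reflection
  padding (~3× the effective order), so its magnitude response is the
  square of the one-pass response and its phase is zero.
* **Modified Beer–Lambert law.**  ΔOD_λ = −log10(I_λ / baseline mean);
  ΔOD = ε · d · DPF · (ΔHbO, ΔHbR) solved per optode and sample.  Shipped
  defaults: wavelengths 760/850 nm, extinction (1.4866, 3.8437; 2.5264,
  1.7986) cm⁻¹·mM⁻¹ from the standard compiled hemoglobin absorption
  tables, DPF 6.0/6.0, separation 3 cm — all overridable via `MbllParams`.
* **Baseline standardization** is per-channel z-scoring with the
  *population* (divide-by-n) standard deviation; the choice is arbitrary
  but fixed, and the operation is idempotent.
* **Moving-average downsizing** computes the *valid* sliding mean of a 1 s
  window and samples it at the target-grid stride (block means available by
  flag).  The common grid is 10 Hz for both modalities — the fNIRS rate
  rounded down — so EEG and fNIRS trials have identical sample counts.
* **EEG envelope.**  All slow representations of EEG (channel selection,
  the common-grid stream entering system fusion) use the 1-s RMS band-power
  envelope: a plain 1 s average of a 10–20 Hz oscillation is ≈ 0, its power
  is not.  Unimodal EEG features are extracted from the envelope at the
  native 250 Hz rate, where 6 s trials (1500 samples) support the full
  4-level sym4 decomposition.

## Channel selection

Pearson correlation between every EEG-envelope × HbO channel pair on the
common grid, ranked by |ρ|: neurovascular coupling can invert sign, and in
a strictly periodic 6 s/6 s protocol the ~6 s hemodynamic lag is close to
half the 12 s trial period, making strong *negative* correlations the norm.
Greedy selection walks the ranking and takes pairs whose channels are both
unused until k per modality are chosen; ties break toward lower channel
indices, which makes the selection deterministic and nested in k.  By
default selection runs once per session on the full filtered recordings
(the once-per-subject convention); a strict variant that re-selects inside
every training fold is available (`per_fold_selection=True`).  A
calibration segment containing rest only cannot drive this selection —
cross-modal correlation needs task variance — which is why the session-wide
default was chosen.

## Features

* **DWT**: hand-implemented periodic-boundary cascade (correlation form,
  even phase), filter taps from PyWavelets with the high-pass rebuilt from
  the quadrature-mirror relation h[k] = (−1)^k g[F−1−k].  Periodic
  boundaries make the transform an orthonormal change of basis, so energy
  conservation is exact and testable; symmetric extension is available by
  flag.  Maximum depth floor(log2(N/(F−1))).  Odd intermediate lengths are
  extended by one wrapped sample.
* **Statistics**: M (mean), P (maximum), SK = m₃/m₂^1.5 and KR = m₄/m₂²
  with population central moments (raw, non-excess kurtosis), SD/VAR with
  the n−1 convention.  These conventions are fixed because cross-study
  comparisons of feature tables depend on them.  P is the signed maximum;
  a maximum-absolute variant sits behind a flag.  Constant vectors have
  undefined SK/KR: error by default, NaN in `partial` mode (the pipeline
  drops and logs such trials).
* **Normalization**: min–max to [0, 1]; constant vectors map to zeros by
  documented convention.  Classifier-side scaling is always fit on
  training folds only.

## Classification and metrics

KNN (Euclidean, majority vote, default k = 5 — the source protocol does
not state k) and Gini decision trees (unlimited depth, leaf size 1 by
default) from scikit-learn; predictions take the argmax of class scores, so
ties resolve toward the smaller class index.  Cross-validation is
stratified 10-fold with a seeded shuffle — stratification keeps per-fold
class balance at the trial counts involved.  Metrics, all in percent:
accuracy; specificity as the macro average of one-vs-rest TN/(TN+FP); AUC
as the macro average of one-vs-rest areas under the ROC of each class's
score column (classes absent from a fold's truth are skipped with a
warning).  Both are verified against brute-force counting / pairwise
rank-sum oracles.

## Synthetic sessions

The generator emulates a block-design motor protocol: alternating 6 s
rest / 6 s task, balanced shuffled class order, one trailing rest block,
EEG at 250 Hz, fNIRS at 10.42 Hz, 12 channels per modality of which 6 are
informative, defaults of 5 classes × 40 trials.  All randomness flows from
one seed through per-purpose child generators (protocol, pair gains, EEG,
fNIRS), so sessions are byte-reproducible and enlarging one modality never
perturbs another.

* **EEG**: informative channels add class-weighted 10 + 20 Hz oscillations
  (0.5 s cosine ramps) on 1/f-shaped unit-RMS background noise;
  `eeg_snr` is the amplitude ratio of a unit-weight response to that
  background (noise scales as 1/snr, so snr → ∞ is noiseless).
* **fNIRS**: the same class-weighted boxcar convolved with a canonical
  double-gamma hemodynamic response (positive lobe peaking at 6 s,
  undershoot at 16 s scaled by 1/6, normalized so a unit boxcar gives unit
  peak response), plus sinusoidal physiological oscillations at 0.1 Hz
  (Mayer), 0.3 Hz (respiration) and 1.2 Hz (cardiac) and white noise, all
  scaled by 1/`nirs_snr`.  HbR is −0.4 × the hemodynamic component with
  its own noise.
* **Class code**: spatial by default.  Informative channels split into two
  regions; EEG regions respond by the class's *effector* attribute
  (consecutive class pairs), fNIRS regions by its *side* attribute
  (alternating classes); off-region response is 25 % of full.  Class 0 is
  rest.  This mirrors somatotopy and hemispheric lateralization in a
  four-task motor protocol: either modality alone confuses one attribute,
  their combination identifies every class, and spatial averaging destroys
  most of the code while per-channel waveform features keep it.
  `spatial_code=False` switches to amplitude-per-class coding with
  user-supplied amplitude tables, which the analytic generator tests use.
* **Pair structure**: a per-trial gain jitter (SD 0.3) shared between EEG
  channel i and HbO channel i, independent across i, so matched pairs
  correlate above unmatched ones — the ground truth for selection.

What the generator does *not* model: volume conduction and channel
cross-talk, motion and ocular artifacts, biophysical forward models
(conductivity, photon transport), non-stationary noise, subject
variability.  Passing tests therefore demonstrate correctness of the
algorithms and the claimed qualitative orderings under controlled
conditions, not expected accuracy on real recordings.

## Problem sizes and defaults

The shipped study conditions — 5 classes × 40 trials, 12 + 12 channels,
6 informative, snr 1.0 — give a 2 406 s session per modality and leave the
full pipeline (generation through 10-fold CV) at a few seconds on one
core; the transform-exactness checks use hundreds of random matrices and
50-signal oracle comparisons.  At these conditions, system-based fusion
with DWT features reaches ~70 % accuracy against a 20 % chance level,
above both unimodal pipelines, and waveform features dominate summary
statistics of the fused signal — the orderings the method is meant to
produce, here guaranteed by the generative design rather than discovered.

## Known limitations

* External dataset loaders are interface stubs; delimited text is the only
  implemented input path.
* Ocular-artifact removal is a pluggable hook with no built-in method.
* The pre-fusion feature rescaling uses session-wide minima/maxima
  (unsupervised); the strict per-fold path covers channel selection but
  not that rescaling.
* Fusion supports exactly two sources and 2×2 blocks.
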