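# Methods

## Model

Each voxel's activity is modelled independently as a linear function of the
lagged story-feature magnitudes:

    y_v(t) = sum_f sum_{d=1..L} w_{v,f,d} x_f(t - d) + e_v(t),  L = 4.

`x_f(t)` is the within-TR sum of the per-word values of feature `f` (words
on a TR boundary count toward the later TR; at the RSVP rate of 0.5 s/word
and a 2 s TR, four words are summed per TR).  The lags cover 2–8 s after
onset — lag 0 is deliberately excluded, since BOLD does not respond
instantaneously — and the `L` weights of one (voxel, feature) pair form a
nonparametric response signature: no hemodynamic shape is assumed by the
estimator.  Columns of the lagged design are ordered feature-major,
lag-minor, so a weight row reshapes directly to a `(F, L)` signature array.

### Assumptions

- Linearity and time invariance of the feature-to-BOLD mapping; no
  saturation or interaction between features.
- Within-TR summation: feature magnitude, not mere presence, drives the
  response.
- Voxels are conditionally independent given the stimulus (fitting is
  per-voxel; spatial structure enters only through the searchlight).
- Subjects are already in MNI space; no registration is performed.

## Fitting

Ridge regression with a per-voxel penalty `lambda_v`.  Both the design
columns and the voxel time series are z-scored with training-row statistics
(recorded, so the identical transform applies to held-out rows; constant
columns map to zero with unit scale).  The solver eigendecomposes `X'X`
once and reuses the basis for every penalty and voxel, which makes the
exact penalized least-squares solution essentially free across a grid.

Penalty selection: the training rows are split into 5 contiguous inner
blocks (contiguous, to respect temporal autocorrelation), the grid default
is `10^0 .. 10^7` in decade steps, and the per-voxel criterion is mean
held-out squared error.  Any penalty within 0.5% relative error of the
per-voxel minimum counts as a tie and the largest such penalty wins.  This
near-tie rule matters: CV error curves of pure-noise voxels are flat at the
top of the grid to within ~0.2%, so an exact-argmin rule scatters their
penalties across the upper decades, whereas the intended behaviour —
noisy voxels shrunk essentially to zero, an automatic voxel selection — is
recovered (>= 90% of simulated noise voxels land in the top two decades).
For a signal voxel the rule can at most move the penalty one decade past
the optimum at a <= 0.5% CV-error cost, which is negligible.

## Evaluation: two-alternative passage classification

- 10 contiguous cross-validation folds (90% train / 10% test); `n_lags`
  rows on each side of a held-out block are dropped from training so that
  hemodynamic carry-over of test stimuli cannot leak into training targets.
- Held-out blocks are cut into non-overlapping 20-TR segments
  (left-aligned; leftovers unused).
- For each true segment, alternatives are drawn without replacement from
  all other held-out segments of the same cross-validation round; both
  candidate predictions come from the fold model that held out the true
  segment.  Per-segment scores average over pairings (default 10; with
  pairings >= available alternatives the result is deterministic).
- The decision statistic is Euclidean distance between observed and
  predicted *group* series — per-subject matrices concatenated along the
  voxel axis on the standardized training scale; data is never averaged
  across subjects.  Exact distance ties score 0.5, which keeps the task
  unbiased under the null.
- Alongside accuracy, the mean distance margin `d_alt - d_true` is
  recorded.  It is the graded counterpart of the binary decision and keeps
  discriminating once accuracy saturates at 1.

## Concatenated searchlight

For each centre on a coordinate grid (default: every voxel coordinate in
the union of subject masks, stride configurable), each subject contributes
its own voxels whose coordinates fall in the surrounding cube (default edge
5 voxels; the acceptance mapping scenario uses 3).  Subjects may contribute
different counts — including zero — and are pooled by concatenation.
Because the model is per-voxel, the per-(fold, subject) fits are computed
once on all voxels and every cube simply selects its columns for the
distance computation; this is exactly equivalent to rerunning the task
inside the cube.  A single all-covering cube reproduces the whole-brain
result bit-for-bit (pairing draws depend only on the seed and the segment
index, not on the voxel subset).  Centres pooling fewer than 10 voxels
(configurable) are reported as missing.  Top-decile rankings order centres
by accuracy with the distance margin breaking ties; without the margin the
ranking is ill-defined wherever accuracy saturates.

Optional Gaussian smoothing (`smooth_volumes`) operates on each subject
independently — never across subjects — and is a sensitivity knob, not part
of the default pipeline.

## Significance

The empirical null circularly shifts the TR-aligned feature series by a
uniform random offset in `[2*seg_len, T - 2*seg_len]` before training and
classification.  This destroys the stimulus–response alignment while
preserving the autocorrelation of both series, which segment-label
shuffling would not; it requires `T >= 4*seg_len`.  Per-location p-values
use the add-one permutation estimator `(1 + #{null >= acc}) / (1 + n)`,
never exactly zero.  Maps are corrected with Benjamini–Hochberg FDR
(q-values via `statsmodels.stats.multitest`), default level 0.05, with
per-location nulls by default and pooling across locations as an option.
A top-K ranking (`top_k_mask`, default K = 1000) is provided as the
threshold-free alternative map.

## Synthetic data

The generator emulates the study design from the model's own equation:

- **Story**: one word per 0.5 s; word length (letters of the generated
  token) as the continuous visual feature; sparse 0/1 indicators
  (activation probability 0.1) for syntax and discourse; positive
  gamma-distributed columns for semantics, emulating non-negative sparse
  embeddings.  Sets are named visual/syntax/semantics/discourse.
- **Truth**: driven regions are compact 3D blobs grown by Chebyshev
  distance from alternating corners of a near-cubic voxel grid (3 mm
  voxels).  Within a region, each voxel responds to every feature of its
  set with a random normal amplitude times the canonical double-gamma HRF
  sampled at the lags and peak-normalized.  The default layout drives 25%
  of voxels with semantics and 25% with visual features.
- **Noise**: stationary AR(1) (coefficient 0.3 — fMRI noise is
  autocorrelated), normalized to exact unit SD per voxel and scaled so that
  SD(signal)/SD(noise) equals the requested SNR in every driven voxel;
  undriven voxels get noise at the mean driven noise scale.  `snr = 0`
  produces pure noise with all-zero true weights; `snr = inf` is
  noise-free.
- **Anatomy**: each subject's whole grid is translated by a uniform random
  offset up to `jitter_mm` (default 3 mm) per axis — the simplest model of
  small anatomical variation that the concatenated pooling is meant to
  absorb.

What the generator does *not* emulate: physiological drifts and motion,
spatially correlated noise, nonlinear BOLD saturation, voxel-wise HRF
variability, and feature correlations of real text (columns are sampled
independently).  Passing tests therefore demonstrate correctness of the
machinery and calibration under the stated model, not performance on real
fMRI.

## Problem sizes and numerical choices

Desk-scale defaults were chosen so every check runs comfortably on one CPU:

- Chance calibration: 20 replicates of 2 subjects x 600 TRs x 200 voxels x
  10 features, 450 trials each (15 pairings x 30 segments); the mean
  accuracy over 9 000 pure-noise trials sits within 2 percentage points
  of 50%.
- Signal detection: the same geometry at SNR 0.5 classifies essentially
  perfectly; the bound asserted by the tests is >= 70%.
- Mapping: 2 subjects, 400 voxels (10 x 8 x 5 grid), 400 TRs, two plants of
  15% each (semantics and syntax — both multi-column sets; a plant larger
  than the 10% decile makes full containment achievable), SNR 0.5, cube
  edge 3, jitter 1.5 mm (half a voxel, so the base grid remains a
  meaningful reference for scoring spatial recovery), all 29 pairings per
  segment for fine-grained accuracy resolution.
- FDR calibration runs at the statistics level on simulated binomial
  accuracy maps (200 locations, 50 replicates, 999-draw empirical nulls),
  exercising the permutation-p and BH machinery end to end.

Degenerate inputs are contracts, not surprises: constant design columns
standardize to zero and receive zero weight; an all-zero feature column
gets exactly zero ridge weight; folds that cannot hold a full segment
contribute none; centres below the voxel minimum report NaN rather than an
accuracy.

## Known limitations

- Feature standardization before summation is a modelling choice (columns
  are z-scored per training fold after lagging); raw-scale fitting is
  available via `standardize=False`.
- The alternative-segment pool spans all held-out segments of the
  cross-validation round, so alternatives may fall in other folds; their
  predictions still come from the true segment's fold model.
- The circular-shift null treats the feature series as exchangeable under
  rotation; very non-stationary stimuli would violate this.
- Searchlight centres are scored independently; no spatial cluster
  statistics are provided.
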