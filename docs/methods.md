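# Methods

This note documents the models and numerical choices behind `capdyn`: what
is computed, under which conventions, and what the synthetic-data tests do
and do not establish.

## 1. Input model and preprocessing boundary

The package starts from *parcellated* time series: one frames × ROIs matrix
per run (TSV), with a parcel table mapping each ROI to a canonical network
(seven cortical networks plus a subcortical block; default 400 + 54
parcels) and a manifest carrying group, timepoint, covariates, motion and
mood scores. Everything upstream — image reconstruction, denoising,
registration, parcellation itself — is out of scope.

Two preprocessing steps are implemented:

- **Motion QC** on session-mean framewise displacement (FD). The retention
  rule is strict "mean FD below the threshold" (default 0.5 mm), so a
  session at exactly 0.5 mm is excluded, and exclusion propagates to the
  subject. No frame-level scrubbing is performed: QC is a subject-level
  decision only. The first frame of each run carries FD 0 by convention
  (FD is a frame-to-frame difference).
- **Z-scoring** of each ROI time series (sample SD, denominator n−1),
  *per run* by default. The per-run choice removes run-level offsets before
  frames from different acquisitions are pooled; a session-level option
  exists (`per_run=False`) because the convention is genuinely ambiguous in
  practice. Zero-variance ROIs are an error by default, with an opt-in
  policy that emits zeros and warns.

## 2. CAP extraction

Frames from all subjects and sessions are pooled (with an index map back to
(subject, timepoint, run, frame)) and clustered by Lloyd k-means under
correlation distance `d(x, c) = 1 − corr(x, c)`.

Numerical conventions:

- Frames are row-standardized internally (zero mean, unit population SD
  across ROIs), which makes `1 − corr` proportional to squared Euclidean
  distance between standardized rows; the centroid update is the arithmetic
  mean of the standardized member frames. This is spherical k-means in
  disguise, so the objective is non-increasing across iterations (asserted
  with a 1e-6 relative slack).
- Initialization is k-means++-style under correlation distance (squared-
  distance-weighted seeding). Plain uniform seeding fails on zero-noise
  data, where all frames of a state are identical point masses and two
  seeds can land on the same mass.
- Empty clusters during iteration are re-seeded from the farthest frame
  (logged); the monotonicity assertion is suspended for that one step.
- A zero-variance frame makes correlation undefined and is a hard error
  naming the frame.
- Replicates: default 100 restarts, 1000 iterations; the accepted solution
  is the replicate with the lowest objective. Per-(k, replicate) generator
  seeds derive deterministically from one base seed, so every fit is
  reproducible bit for bit.

**Choice of K.** The cluster validity index is the ratio of the mean
frame-to-own-centroid distance to the mean frame-to-other-centroid
distance (the cited "within over between" ratio admits several readings;
this one is computable from a single fitted model and behaves monotonically
in separation). The elbow is found by exhaustive two-segment piecewise-
linear least squares over interior breakpoints, minimizing total RSS, with
ties toward smaller k. If the best two-segment fit improves on a single
line by less than 1% RSS (or the curve is numerically exactly linear), the
elbow is declared ambiguous: the smallest k is returned and the fit is
flagged. The desk-scale scan default is k = 2..15 with 10 restarts per k
(the full-study protocol is 2..50 with 100 restarts; both are config
values). Per-cluster silhouette under correlation distance is available as
the alternative criterion but builds the full pairwise distance matrix, so
it is desk-scale only.

**State naming.** Each centroid is correlated with each network's binary
parcel-membership indicator; the argmax names the state. For reporting,
states are renumbered to a canonical network order (visual, somatomotor,
default-mode, ventral-DMN stand-in, salience, executive) so that state 5
is always the salience state and state 6 the executive state; raw cluster
ids are retained in the fitted object.

## 3. Dynamics metrics

Per session (states 1..K, runs never bridged):

- **FT**: state counts over total frames; sums to 1 exactly, unvisited
  states are 0.
- **MDT**: mean maximal-run length in TRs; unvisited states are *missing*
  (NaN), not 0 — treating them as 0 would bias group means downward, and
  the statistics drop missing values pairwise.
- **TP**: computed on the collapsed sequence (consecutive duplicates
  removed within each run). Default denominator counts occurrences of the
  source state that have a within-run successor, so every defined row sums
  to 1 and the estimate is a proper embedded-jump-chain estimate — the
  Markov reading of the transition metric. The literal "all occurrences"
  denominator is available (`literal=True`); its rows sum to ≤ 1 when a
  state ends a run. The diagonal is structurally 0 after collapsing and is
  reported as 0, not missing. Transitions are never counted across the
  run boundary: runs are separate acquisitions, and bridging them would
  manufacture a transition that never happened in time.
- **Per-state FD**: mean FD over the frames assigned to each state, the
  diagnostic that states are not motion artifacts.
- **Static FC**: full pairwise Pearson correlation of ROI time series
  (the conventional comparison point for the dynamic metrics).

The analytic oracle for TP is the embedded jump chain: for a chain with
transition matrix P, the collapsed-sequence transition probabilities are
`P̃_ij = P_ij / (1 − P_ii)`; the tests verify the estimator against this
closed form at T = 20 000 within ±0.03.

## 4. Statistics

All tests are two-sided; all reported p-values are unadjusted; Bonferroni
family thresholds (α/m) set significance flags only.

- Longitudinal change: classical paired t (df = n−1) per state for FT and
  MDT, each a family of m = K (0.05/6 = 0.0083 at the default K).
- Transition selection rule: TP is tested only for transitions *into*
  states with significant FT or MDT effects, from all other states; with
  two selected states among six this is the 10-test family (0.05/10).
- Brain–behavior: Pearson r between per-subject metric change and percent
  change of each mood score that significantly improved, where percent
  change is `(post − baseline) / post` (note the *post* denominator; a
  zero post score propagates as missing with a warning).
- Cross-sectional: "controlling for age and sex" is implemented as OLS of
  the metric on intercept + group + age + sex with the group-coefficient t
  (df = n−4) — the ANCOVA reading of a covariate-controlled two-sample
  comparison; a residualize-then-t option is exposed for comparison.
- Demographics: Welch t from summary statistics (Welch–Satterthwaite df)
  for continuous variables; Pearson chi-square *without* continuity
  correction for 2×2 tables. These conventions reproduce the printed
  worked examples (|t| = 3.70 for age from the group summaries; chi-square
  12.851 / 1.427 / 2.055 from counts reconstructed from printed
  percentages with group sizes 55 and 58).
- Diagnostics: one-way ANOVA of per-state FD and of frame-to-centroid
  similarity across (control, patient-baseline, patient-post).

The statistical layer is pure: same inputs, same outputs, no hidden state.

## 5. Synthetic cohort: what it states and what it omits

The generator's defaults are the stated world of the emulated study design:
58 patients scanned at baseline and post-treatment, 56 controls at baseline
with 18 rescanned, two runs per session, TR 0.8 s, 454 ROIs, and a planted
correlation of −0.402 between the change in salience-state occupancy and
percent-change reflective rumination. Desk-scale defaults chosen here, once:

- **frames_per_run = 250** (a full acquisition is ~2000 frames); enough for
  FT sampling error ≈ 0.02 per session while keeping the default pipeline
  in minutes on one CPU. `n_rois` and `frames_per_run` are reducible in
  config and in tests.
- **noise_sigma = 1.0** on ROI channels, i.i.d. Gaussian by default. With
  unit-variance patterns this puts frame-to-own-pattern correlation near
  0.7 — cleaner than real BOLD frames, noisier than a toy. An AR(1)
  temporal-noise option exists (`ar1_phi`), default off: independent noise
  keeps every property test analyzable.
- **Group dynamics** are expressed through the transition structure with a
  shared state inventory (patterns never differ by group): the patient
  baseline chain routes extra mass into the salience state and away from
  the executive state, and skews salience-state exits toward the visual
  state; the post-treatment chain is a 25/75 mixture of baseline and
  control chains, i.e. mostly normalized. Stationary occupancies: control
  1/6 everywhere; patient baseline ≈ 0.244 (salience) and 0.090
  (executive); post ≈ 0.185 / 0.148. Effect *sizes* are calibration
  choices — the emulated study reports t statistics, not effect sizes.
- **Subject heterogeneity**: one multiplicative log-normal jitter field
  (SD 0.15) per subject applied to the group transition rows and shared
  across that subject's timepoints, making treatment a within-subject
  shift. Control rescans reuse the subject's chain unchanged, so the
  control-stability analysis is exactly null.
- **Mood coupling** regresses the planted reflection percent change on each
  subject's *realized* salience-occupancy change (standardized), plus a
  Gaussian residual sized so the correlation is −0.402 in expectation —
  recovery is a true estimation problem, not a table lookup. Other mood
  scores are drawn from the printed group means/SDs without coupling.
- **FD traces** are folded-normal draws (mean 0.15, SD 0.17 mm),
  independent of states — the generator plants *no* state–motion coupling,
  so the per-state FD ANOVA is a null check.

Not emulated: hemodynamic convolution, spatial autocorrelation, scanner
drift and physiological noise, integer-valued clinical scales, missing
visits. A green test on this cohort therefore establishes that the
*pipeline* recovers planted structure under well-behaved noise, not that
the method is robust to real acquisition artifacts.

## 6. Degenerate inputs and conventions

- Reducible chains (e.g. identity) have no unique stationary distribution:
  error naming the condition. Identity chains are still *simulable* (each
  run is one dwell).
- Singleton clusters take silhouette 0 for their member.
- Near-duplicate centroids (r > 0.999) inflate the CVI denominator's
  near-zero distances; the CVI computation warns.
- Ties in nearest-centroid assignment go to the lowest state id.
- Manifest keys (subject, timepoint, run) must be unique; session files
  are validated for numeric content and parcel count, with the offending
  cell named.

## 7. Known limitations

- The elbow criterion assumes a single well-defined bend; on curves where
  the planted structure is weak relative to noise the two-segment fit can
  land one k off. The sensitivity analysis at k±1 mirrors this.
- In-sample state labels come from the clustering itself; out-of-sample
  sessions use nearest-centroid assignment, which slightly regularizes
  their metrics relative to in-sample sessions.
- Silhouette computation is quadratic in pooled frames.
- The per-run z-scoring convention and the stochastic-row TP denominator
  are choices among defensible readings; both alternatives are exposed as
  options and switching them changes numerical results.
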