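# Methods

This note documents the models, statistics and numerical choices behind
`gazefield`, and what its synthetic cohorts do and do not establish about
real eye-tracking data.

## Problem setting

Glaucomatous visual field defects (VFD) are normally mapped with standard
automated perimetry (SAP), which demands prolonged fixation and sustained
attention.  `gazefield` implements the alternative analysis route: infer the
presence (and, where possible, the location) of a VFD from the eye movements
an observer makes while freely watching short video clips.  The pipeline
compares a tested observer against a normal-sighted control cohort through
five families of statistics, each implemented as an independent module:

1. **Basic event features** — per-participant median fixation duration,
   number of fixations, median saccade amplitude and median peak velocity,
   pooled over all clips.  Groups are compared with the two-sample
   Mann–Whitney U rank-sum test; with four feature/VP comparisons the
   Bonferroni-corrected alpha is 0.05/4, reported as 0.013.  Both median and
   mean summaries are available; the median is the default reporting path.
   All velocities are handled in deg/s internally.
2. **Directional saccade-amplitude profiles** — median and maximum amplitude
   in 18 half-open bins of 20° covering [0°, 360°).  A patient's per-bin
   value is ranked among the control cohort's values; ranks are normalized
   by the number of controls and the outer 2.5% tails flagged.
3. **Viewing priority (VP)** — a per-fixation gaze-consistency score in
   [0, 1] (below).
4. **Visual-field maps** — Gaussian fixation heat maps, mean-VP maps,
   z-normalized relative-frequency rank maps, saccade-endpoint proportion
   maps on the 12 × 10°-half-angle central-exclusion grid, and discrete maps
   aligned with the HFA 24-2/30-2 test locations, correlated against the
   measured dB sensitivities.
5. **Kernel PCA + naive Bayes** — participants are embedded through kernels
   over Euclidean distances between their per-clip maps and classified with
   Gaussian naive Bayes under stratified 10-fold cross-validation.

Perimetry handling (best-location binocular integration, the 0/1/2-penalty
IVF score over 52 locations, MD summaries) closes the loop between gaze
statistics and clinically measured field damage.

## Coordinate conventions

Screen positions arrive as top-left-origin pixels and are converted to a
screen-centered, right-handed degree frame (x right, y up) using per-axis
tangent geometry: a pixel offset of `d` cm at viewing distance `D` subtends
`atan(d/D)`.  The monocular-study display (1,920 × 1,080 px, 50 × 35 cm,
60 cm) then subtends 45.2° × 32.5°, matching its published subtense; the
conversion is exact off-axis and invertible to < 1e-9°.  Whether the
original analyses used linear or trigonometric conversion is not stated
anywhere; the trigonometric form is this package's choice.  Gaze-relative
("visual field") vectors are successive fixation differences — leftward and
downward negative — so every map lives in retina-centered coordinates.

## Event detection

Raw 1,000-Hz samples are classified with the standard tracker criterion:
a sample belongs to a saccade when speed > 30 deg/s or |acceleration| >
8,000 deg/s², sustained over at least two samples; saccade runs are then
grown outward to the surrounding velocity minimum (10% of the velocity
threshold) so that sub-threshold tails belong to the saccade.  Velocity is a
three-sample central difference with no additional smoothing — the simplest
reproducible stand-in for a tracker's proprietary parser.  Fixations shorter
than 40 ms squeezed between two saccades are treated as detection jitter and
merged (the 40-ms floor is this package's choice; no published value
exists).  Fixations, saccades and flagged NaN gaps partition the trial span
exactly.  On the simulator's own emitted samples the detector recovers 100%
of ground-truth events with boundaries within one sample.

## Viewing priority

VP scores how well one fixation matches where a reference cohort looked at
the same moment of the same clip, discounted by where that cohort looks
regardless of content.  For a fixation at onset t, the *reference set* holds
control-cohort fixations on the same clip whose [onset, offset] intersects
t ± 500 ms, and the *random set* holds cohort fixations in the same window
on other clips; the scored observer's own fixations are excluded from both
(controls are therefore scored leave-one-out).  Reference/random pools
always come from the control cohort only.

The score itself is a cluster-priority construction built on fuzzy c-means
(implemented in-package; fuzzifier m = 2, C = 5 clusters per pool, all
config-exposed).  Each pool is clustered separately; over the combined
cluster list, cluster k gets priority `R_k / (R_k + S_k)` where `R_k`
(`S_k`) is the mean reference (random) mass *near* k — fuzzy membership
weighted by the Gaussian typicality `exp(-d²/(2 s_k²))` with `s_k` the
cluster's own fuzzy dispersion (floored at 0.5°, a tracker-accuracy
footprint).  The fixation's VP is its membership-weighted mean of cluster
priorities.  Three properties pin the construction down: an all-reference
neighborhood scores 1, an all-random neighborhood scores 0, and exchangeable
pools score 0.5 on average.  Two numerical details matter:

* **Held-out mass estimation.** Each pool is split in half; clusters are
  fitted on one half and masses measured on the other.  Fitting and
  evaluating on the same points biases VP away from 0.5 under
  exchangeability, because centers adapt to their own sampling noise.
* **Determinism and equivariance.** Cluster initialization draws data-point
  indices from the seeded generator, so the whole score is deterministic
  given the seed and exactly equivariant under rigid transforms of all
  inputs (verified to < 1e-9 with the default convergence tolerance of
  1e-8 on center movement, 300 iterations maximum).

An empty reference set leaves VP undefined (excluded from means, logged).
An empty random set substitutes a seeded uniform baseline over the expanded
reference bounding box.  Whether VP should additionally be rescaled per clip
is left open; raw values are emitted and summaries operate on them.

## Maps and kernels

Heat maps place one unit-mass isotropic Gaussian (SD 1°, reflecting tracker
accuracy and foveal extent) per fixation vector, evaluated pointwise at bin
centers; mean-VP maps divide the VP-weighted map by the unweighted map and
mask bins with less than 1e-3 fixation mass (the published procedure leaves
the validity region undefined; the mask makes it explicit).  Rank maps
z-normalize each participant's trial-averaged map over unmasked bins before
per-bin mid-rank comparison — mid-rank tie handling keeps ranks uniform
under exchangeability, which the 2.5% flags assume.  The rank construction
assumes the grid roughly covers the cohort's gaze spread (which the
saccade-extent grid fitting ensures): on a grid much larger than the gaze
distribution, the near-empty peripheral bins of a z-normalized map all
inherit that participant's −mean/SD value, so their ranks become systematic
rather than exchangeable and leave-one-out rank means drift from 0.5.
Discrete
perimetry-aligned maps use the true HFA lattice (6° spacing offset 3° from
the meridians, 24-2 = 54 locations with the two nasal 27° points,
30-2 = 76, blind spot at (15°, ±3°) in right-eye orientation) rather than an
arbitrary square tiling.

Participant kernels follow the two published forms: over all clips,
`k_ij = exp(-0.5 (meanDist+maxDist)²/σ²)` with σ = 2 for fixation/VP maps
and σ = 0.2 for saccade maps (saccade-map values are proportions over 116
bins and vary on a much smaller scale); per clip, `k_ij = exp(-Dist)`.
These kernels are not guaranteed positive semidefinite; after
double-centering, negative eigenvalues are dropped with their mass logged,
which keeps projections real while preserving the printed formulas.
Component signs are fixed by making each component's largest-magnitude
loading positive.  Explained-variance fractions are taken over the retained
positive eigenvalues.  Cross-validation folds are stratified by group with
a fixed seed; a fold whose training split degenerates to one class triggers
a reseeded refold.

## Synthetic cohorts

The generator emulates the study design, not the videos: each clip is
summarized by a *salience track* — the single most conspicuous screen
location over time, jumping at Poisson times (default 0.5 jumps/s) to
uniform positions in a ±16° × ±10° box.  Observers alternate fixations and
saccades:

* Fixation durations are log-normal (median 280 ms, log-SD 0.4).
* At each fixation end the salient target's gaze-relative position is tested
  against the observer's dB sensitivity field; detection probability is a
  logistic in dB calibrated so 30 dB → ≈0.98 and 10 dB → ≈0.3.
* A detected target is followed with probability 0.8, landing with 1°
  isotropic noise.  Otherwise the gaze relocates by a small exploratory step
  with center bias: gaze′ = 0.9·gaze + noise, stationary SD 6° — the high
  pull weight keeps undirected relocation saccades short, as exploratory
  saccades are.  An optional compensation gain redirects relocations toward
  damaged field regions instead.
* Relocations below 0.5° merge into the ongoing fixation (real parsers do
  not segment sub-detectable micro-relocations).  Peak velocity follows the
  main sequence `500·(1 − e^(−amp/5°))` deg/s and duration the classic
  linear relation 2.2·amp + 21 ms.

These defaults reproduce the order of magnitude of published control
statistics: ≈3 fixations/s, fixation-duration medians near 280 ms, saccade
amplitude medians of a few degrees, peak velocities near 200 deg/s, and
leave-one-out control VP medians around 0.9.

Sensitivity fields start from a 30 dB baseline with 1 dB measurement noise
and attenuate an archetype region multiplicatively by severity ∈ [0, 1]:
`peripheral` (a seed-oriented 180° sector beyond 10°), `nasal_arc` (nasal
locations beyond 9°), `tunnel` (everything beyond a 10° island), `central`
(within 10°), `blind` (everywhere), `normal` (nothing).  Patients carry the
full-severity field in the tested eye and a 0.25-severity field in the
covered eye (asymmetric loss); the monocular regime drives the observer
with the tested-eye field, the binocular regime with the best-location
merged field — which for asymmetric defects largely restores detection, the
study's central contrast.

**What the simulator does not emulate:** real video content and semantics,
smooth pursuit, blinks, drift/tremor, tracker noise spectra, filling-in, or
learned long-term compensation strategies.  Passing tests therefore show
that the *analysis pipeline* recovers the mechanisms the generative model
encodes (missed salient targets → fewer long saccades toward damage → lower
VP → separable map distributions), not that real patients behave this way.

## Problem sizes and tolerances

Analyses are exercised at desk scale: mechanism checks run cohorts of
8–20 observers per group with 3–10 clips of 20–60 s (the classification
check uses the full 20/20 × 10 × 60 s condition; VP-based checks use
8/8 × 3 × 20 s across 20 seeds), chosen as the smallest sizes at which the
simulated effects are stable.  Calibration checks use 200 resamples; the directional 2.5% tail flags are
calibrated with 40-control cohorts because with n controls the extreme
normalized ranks fire with probability 1/(n+1) per tail, so the nominal 5%
two-sided rate is only attainable for n ≥ 39.
Key numeric tolerances: pixel↔degree round trip < 1e-9°, map file round
trip < 1e-12, kPCA vs. dense eigendecomposition < 1e-9, VP rigid-transform
equivariance < 1e-9, rank-sum p exactly equal to exhaustive enumeration for
group sizes ≤ 6.

## Known limitations

* The VP formula is a faithful instantiation of the published verbal
  contract, not a re-derivation of the original algorithm's exact code;
  absolute VP values are comparable within, not across, implementations.
* The per-clip kernel `exp(-Dist)` is scale-sensitive; map normalization
  must match between participants (the pipeline guarantees this).
* Degenerate inputs are handled conservatively: empty bins, empty reference
  sets, zero-variance correlations and rank-0 embeddings all surface as
  undefined markers or logged warnings, never as silent zeros.
* EyeLink ASC support covers EFIX/ESACC/MSG event lines only; proprietary
  EDF binaries and raw ASC sample lines are out of scope (raw samples enter
  via CSV).
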