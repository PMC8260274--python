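# Methods

This note documents the models, algorithms and numerical choices behind
`spinedyn`, and what the synthetic-data generators do and do not emulate.

## Coordinate model

A dendritic segment is a 1-D domain of arc length along the dendrite path,
origin at the proximal end; analyzed stretches are half-open intervals
`[start, end)` in μm and occluded stretches are simply absent from the
analyzed set.  This is the minimal faithful representation of spine-map
annotations: all distances that matter (track matching, the 9 μm
clustered/isolated rule) are arc-length distances on the same dendrite,
never 3-D Euclidean distances, and cross-segment neighbors never qualify.

## Spine pipeline

**Filtering.**  An observation is retained iff it protrudes ≥ 0.4 μm from
the shaft (≈ 2 SD of typical shaft noise blur), protrudes laterally in the
imaging plane (axial protrusions are unmeasurable with two-photon z
resolution), is not occluded, and is not a filopodium.  Filopodia are
recognized morphologically; since "lacks a distinct head" is qualitative,
it is operationalized as protrusion length > 4 μm AND head/neck intensity
ratio < 1.1 (both configurable).  Every removed observation lands in an
exclusion log with a reason code — the pipeline never filters silently.

**Track matching.**  Observations at consecutive timepoints are linked per
segment by minimum-total-distance bipartite assignment (Hungarian
algorithm) over pairs within a distance tolerance, default 1.0 μm.  The
human re-identification step this replaces has no published tolerance; 1 μm
is several times the registration jitter of a good chronic preparation and
well below typical inter-spine spacing.  An iterated mutual-nearest-neighbor
matcher is available as `method="mutual_nn"`; the two agree except on
crossing near-ties, where the global assignment mis-assembles fewer tracks
(measured on synthetic ground truth: ~99.6% vs ~98.7% event-label accuracy
for the control preset at 0.2 μm jitter).  A spine absent at T1 but present
at T0 and T2 is taken at face value as two tracks, because matching links
only consecutive timepoints.

**Known tracking limit.**  With positional jitter σ and baseline density
ρ, two protrusions generated within ~σ of each other are positionally
indistinguishable, and an eliminated new spine can capture the follow-up
observation of an adjacent baseline spine.  The capture decision compares
|δ + ε| with |ε′| (ε, ε′ ~ N(0, σ√2)), which is already the
maximum-likelihood rule — squared-cost assignment and track-mean anchoring
were measured and do not improve it.  At σ = 0.2 μm and ρ = 0.4 μm⁻¹ this
caps event-label accuracy near 99% for low-turnover groups and ~98% for
high-turnover groups; at σ = 0 recovery is exact.  Accuracy is scored as
per-segment multisets of event labels, since identity swaps between
indistinguishable spines change no reported label, count or rate.

**Events and rates.**  Formation = first presence if not at baseline;
elimination = first timepoint after last presence; stabilized = formed at
T1 and present at T2.  Rates divide pooled per-animal counts by the
animal's total analyzed length (× 100 μm); they are invariant to how the
analyzed length is split into segments.

## Clustered/isolated classification

A stabilized new spine is clustered iff its nearest qualifying neighbor is
strictly closer than the threshold (default 9 μm; distance exactly equal is
isolated).  Two neighbor definitions are first-class because the field uses
both: `stabilized_only` (default; neighbors are other stabilized new
spines) and `any_new_spine` (any training-associated new spine, surviving
or not).  The choice is stamped into the output labels.  T1 (formation
time) positions are used for the distances.

The Monte-Carlo null answers "how much clustering would uniform placement
produce?": spine counts per segment are held fixed, positions are redrawn
uniformly within each segment's analyzed intervals, and the clustered
fraction is recomputed; `p = (1 + #{null ≥ observed}) / (n_perm + 1)`.  For
two spines on a 100 μm segment the clustered probability has the closed
form (2·9·100 − 9²)/100² = 0.1719, which the permutation null reproduces —
the test suite checks this to Monte-Carlo precision.  The p-value is valid
(conservative under ties) by the add-one construction.

## Statistics

All procedures are implemented from their defining computations; scipy
supplies only distribution functions (normal, t, F, studentized range).

* **Mann–Whitney U** — midrank ties; mode `exact` enumerates all
  C(n, n_x) assignments of the pooled midranks (a permutation test, hence
  valid under ties) and doubles the smaller tail, capped at 1; mode
  `normal_approx` uses the tie-corrected variance with a 0.5 continuity
  correction.  `auto` switches at n ≤ 12, where enumeration is ≤ 924
  assignments.
* **Unpaired t** — pooled variance, df = n₁+n₂−2.  Zero pooled variance
  with equal means returns p = 1 by convention; with unequal means it is a
  degenerate-variance error rather than a silent infinity.
* **Two-way ANOVA** — type-II sums of squares via residual-sum-of-squares
  differences of nested OLS fits (each main effect adjusted for the other,
  interaction adjusted for both), chosen because the group sizes such data
  produce are rarely balanced; for balanced designs this equals the
  textbook cell-mean decomposition, which is the test oracle.  Optional
  Tukey–Kramer comparisons of cell means use the studentized range on the
  full-model MSE.  Degenerate designs are guarded: zero error with zero
  effect gives F = 0, zero error with a real effect gives F = ∞, p = 0.
* **Split-plot repeated-measures ANOVA** — between-subject factors
  (genotype, treatment, their interaction, plus litter as an additive
  blocking term) are tested against the subjects-within-groups mean square
  computed from subject means; the within factor (trial) against the
  subject × trial residual.  Trial × group interactions are pooled into the
  within error, matching the convention of reporting a single trial F.  The
  blocking term absorbs across-litter performance variance that would
  otherwise inflate the subject error.  No sphericity correction is applied
  by default; Greenhouse–Geisser is available (`gg_correction=True`).  This
  univariate split-plot construction is one defensible reading of "mixed
  effects repeated-measures ANOVA with a litter term"; a likelihood-based
  mixed model is out of scope.
* **Cohen's d** (pooled SD) and **Pearson r** (p from the t transform).

## Behavioral and densitometric preparation

Rotarod latencies are analyzed raw, per trial (within factor = overall
trial index); the displayed quantity is the per-animal daily peak (or
median — both modes provided), normalized to the wild-type-vehicle mean
day-1 peak to absorb cohort effects.  This raw-for-statistics /
normalized-for-display split is deliberate and preserved in the API.  ERK
activation is (pERK₄₂ + pERK₄₄)/(totalERK₄₂ + totalERK₄₄); actin is carried
as metadata only.  Ratios are invariant to global rescaling of band
densities, so lane-loading factors cancel.

## Synthetic-data generators

The spine-study generator emulates the *data structure* of a three-timepoint
chronic imaging experiment, not its biophysics: segments are uniform-length
1-D intervals (40–120 μm, mean 80 μm, matching published per-group totals
over ~30–55 segments); baseline spines are a uniform Poisson population
(0.4 μm⁻¹); training-induced new spines appear at T1 as a Poisson process
of intensity λ_form per 100 μm, a fraction p_cluster seeded uniformly
within 9 μm of an earlier new spine (rejection-sampled inside the segment);
a new spine's true clustered status is its realized proximity (< 9 μm to
another new spine), so chance clustering of uniform placements is labelled
consistently with the classifier; survival to T2 is Bernoulli
(s_clustered / s_isolated); observed positions get independent Gaussian
jitter per timepoint (σ = 0.1 μm by default, comparable to registration
error at 0.1 μm/pixel); filopodia are transient single-timepoint
structures with unambiguous morphology (length 4.5–8 μm, ratio ≈ 1).
Everything is a pure function of (preset, seed).

Not emulated: pixel-level appearance, z-axis structure, baseline-density
gradients, spine-size dynamics, serial correlation of jitter, and any ERK
biochemistry.  Passing tests therefore certify the *analysis*, not image
processing.

**Preset calibration.**  Formation intensities come directly from published
spines-formed/segment counts (2.4, 1.25, 4.26, 3.575 per 100 μm for
WT-vehicle, WT-SL327, mutant-vehicle, mutant-SL327).  One survival knob per
group was then calibrated by full-pipeline Monte-Carlo (linear response fit
over three knob values × 250 seeded replicate studies, one refinement step,
1000+-replicate verification on fresh seeds) so the pipeline-measured group
mean reproduces exactly one published rate per group: WT-vehicle
clustered-stabilized 1.1/100 μm (s_clustered = 0.800), mutant-vehicle 2.2
(0.697), mutant-SL327 total stabilized 1.0 (s = 0.215).  Calibrating
through the full pipeline (rather than the generator's truth) absorbs the
small measurement bias of position-only tracking.  Each preset targets a
single published quantity because the published clustered rates exceed the
published total stabilization rates for the same groups — the two cannot be
matched simultaneously and no attempt is made to.

The rotarod generator produces latency = baseline + rate × trial + litter
effect + noise, truncated to [0, 180] s (the rod accelerates 5→80 rpm over
3 min); default rates make the mutant-vehicle group learn faster
(9 s/trial vs 5) with SL327 removing the elevation.  The densitometry
generator applies a 1.5-fold p-ERK increase to trained mutants under
multiplicative lognormal band noise plus a per-animal loading factor (which
cancels in the ratio).

## Problem sizes and tolerances

Replicate-level checks use 20–80 replicate studies at the published group
sizes (4–8 animals, 30–56 segments), which puts the SEM of a grand-mean
rate at 0.02–0.06 per 100 μm; type-I error calibrations use 500 replicates
at α = 0.05 (binomial SE ≈ 0.01); exact-oracle comparisons are bit-exact;
worked-example ANOVA oracles agree to 1e-10.  The permutation test's
clustered-fraction statistic is discrete, so its size sits slightly below
nominal (measured 0.032–0.034 with 40–60 spines), as expected for add-one
permutation p-values under ties.
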