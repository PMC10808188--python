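# Methods

This note documents the statistical procedures, the synthetic-data model,
the numerical choices and the known limitations of `tinnpheno`.

## Data model

A cohort is a pair of patients × variables tables at baseline (t0) and
post-treatment (t1). The default battery has 64 variables from 14
questionnaire instruments in 10 categories: tinnitus characteristics
(3 visual-analogue scales + 8 binary localization/noise items), physical
quality of life (4), experiences of pain (6), somatic expressions (5),
affective symptoms (15 continuous + 1 binary panic item), tinnitus-related
distress (8), internal resources (3), perceived stress (5), general quality
of life (1) and mental quality of life (5). Published raw ranges for the
instruments are not available to this package; the shipped variable table
uses plausible instrument ranges with `raw_min = 0`, which makes the
reverse-coding map `x* = raw_max − x` an involution of `[0, raw_max]` onto
itself. Users can substitute their own variable table (CSV sidecar:
`name,questionnaire,category,kind,polarity,raw_min,raw_max`).

## Preprocessing

* **Reverse coding.** Variables declared higher-is-better are replaced by
  `raw_max − x` and renamed with a `*` suffix, so higher always means
  higher disease burden.
* **Completer filtering.** Analysis is restricted to patients with no
  missing value at either timepoint; the staged counts
  (enrolled → complete-t0 → complete-both) are reported and preserved in
  the run manifest.
* **Standardization.** Each variable is z-scored, `z = (x − μ)/σ`, with μ
  and σ (sample SD, denominator n−1) estimated **on the baseline completer
  table only** and applied unchanged to t1. The alternative — per-timepoint
  scaling — would force every variable's mean change to zero and erase the
  population-level treatment effect, so a single t0-anchored scale is the
  only choice under which Δ(t0,t1) is interpretable and a score decrease
  reads as improvement. Binary items are z-scored like continuous ones.
  Constant columns are a hard error (they cannot be z-scored).

## Baseline phenotyping

Clustering is a plug-in (`fit(X, random_state) → labels`). The default is
partitioning around medoids in the alternating (Voronoi-iteration) form
with k-medoids++ seeding, 10 restarts, and the lowest total
point-to-medoid distance kept; distances are Euclidean on the full
standardized 64-variable space, binary items included. The number of
clusters is selected by maximal mean silhouette width over a configurable
range (default 2…10; ties go to the smaller k). Clusters are renumbered by
decreasing size, so phenotype 1 is always the largest subgroup, and each
cluster's medoid — the member minimizing the summed Euclidean distance to
all members — is recomputed in the full standardized space with ties broken
toward the lowest patient id.

Mean silhouette is a deliberately conservative selector: it only resolves
cluster numbers beyond 2 when subgroups are well separated relative to
their internal spread. On weakly separated data it will return a coarse
2-way partition and the per-k silhouette table in the run manifest should
be inspected before interpreting k.

## Projection and factor map

The 2-D embedding is fitted on the standardized baseline table, by UMAP
(2 components, fixed `random_state`, single-threaded, library defaults
otherwise) or by PCA as a fully deterministic linear fallback whose
transform of a training point reproduces its training coordinate exactly.
Post-treatment patients are placed by the **out-of-sample transform** of
the t0-fitted model — not a joint refit — so both timepoints live in one
coordinate system and positions are comparable.

The factor map assigns each variable the vector (r₁, r₂) of Pearson
correlations with the two projected dimensions; the arrow's angle follows
the correlation signs (negative r₂ points downward) and its length
‖(r₁, r₂)‖₂ is the correlation strength. Ring classes use closed
boundaries: outer for magnitude ≥ 0.75, inner for ≤ 0.5, middle otherwise.
Magnitudes are invariant to affine rescaling of either projected dimension.

## Change with treatment

* **Core hull.** For each phenotype, members whose 2-D distance to the
  medoid is ≤ the median of all members' medoid distances (medoid included
  at distance 0; even counts use the midpoint of the two middle values)
  form the core; the core hull is their convex polygon and its shoelace
  area is reported. Growing core-hull area between timepoints indicates
  heterogeneous treatment response within a phenotype. Core-membership
  distances and polygons are computed in the projected plane (where the
  hulls are drawn), while medoids are found in the full standardized space
  (where they are defined) and then projected.
* **Re-assignment.** Each t1 patient is labeled with the phenotype of the
  Euclidean-nearest **baseline** medoid in the standardized 64-variable
  space; ties go to the lowest cluster index. The t1 core hull is built
  over the re-assigned members around a medoid recomputed at t1, matching
  the distinct post-treatment medoid positions in the visualization.
* **Transitions.** The k×k count matrix (rows t0, columns t1) conserves
  baseline sizes by construction. The link list for the Sankey view hides
  flows with share ≤ 3% of N (counts are never modified, only the display
  list is filtered).
* **Radial summary.** Per phenotype and variable: standardized means at
  both timepoints, the phenotype's mean change minus the population mean
  change, and a flag — *improved* when the t0 mean exceeds the t1 mean by
  more than 0.25 standardized units, *worsened* for the reverse.

## Pathways of change

Change vectors Δ(t0,t1) = z₁ − z₀ (negative = improvement) are clustered
with the same plug-in. Clusters are ordered by decreasing mean overall Δ
(cluster mean of each patient's mean change across all variables) —
deterioration first — and, when five clusters are found, given the
canonical names *high deterioration, low deterioration, low improvement,
moderate improvement, high improvement*; otherwise the neutral "pathway
r/m". The ordering statistic is a design choice: pathways are named by
overall severity of change, and the all-variable mean is the simplest
statistic consistent with that reading.

Association with baseline is quantified two ways:

* **Spearman panel.** "Correlation of a variable with a pathway" is
  operationalized as the Spearman correlation between the baseline variable
  and the *one-vs-rest binary membership indicator* of that pathway — the
  only encoding that yields one correlation per (variable, pathway) pair.
  95% confidence intervals use the percentile bootstrap over 2000 patient
  resamples (resamples shared across variables within a pathway; a fixed
  seed makes the panel reproducible). Pathways with fewer than 3 members
  get missing CIs. No multiple-testing adjustment is applied; the panel is
  presented CI-only.
* **χ² test.** Pearson chi-square of independence on the k×m contingency
  table without continuity correction, df = (k−1)(m−1). Reported mosaic
  percentages are within-phenotype shares rounded to one decimal, half away
  from zero (697/1228 → 56.8, 45/989 → 4.6).

## Synthetic cohort generator

The generator emulates the study conditions so that every downstream stage
can be verified against ground truth:

* **Enrolment and attrition.** Default `n_total = 4103` with staged
  attrition probabilities calibrated so that the expected completer counts
  match 4103 → 1228 → 989. Attrition is independent of phenotype by
  default; an optional per-phenotype bias can emulate selective dropout.
  Incomplete patients get one randomly chosen answer blanked at the
  affected timepoint.
* **Phenotypes.** Patients draw one of four latent phenotypes
  (weights 0.568 / 0.141 / 0.152 / 0.139). Continuous scores are generated
  on the standardized scale as `category offset + N(0, noise_sd)` and
  affine-mapped onto the declared raw range (z ∈ [−3, 3] spans the scale;
  values clip at the bounds; higher-is-better variables are stored
  inverted so reverse-coding recovers the latent burden). The default
  offsets realize the qualitative profiles: an avoidant group below
  average on everything (−0.55), a psychosomatic group highest on both
  affective and somatic burden, a somatic group high on somatic/pain
  scores with near-average affect, and a distress group high on affective
  and stress scores with near-average somatic expression.
* **Pathways.** Each patient draws one of five pathways
  (weights 0.046 / 0.219 / 0.345 / 0.292 / 0.098) whose shift
  (default +1.2, +0.45, −0.25, −0.95, −1.65 standardized units, strictly
  decreasing) is added uniformly to all continuous variables at t1 only.
  Binary tinnitus-characteristic items are stable traits — identical at
  both timepoints — so pathways do not separate on them and their
  standardized deltas are exactly zero.
* **Noise.** Default residual SD 0.15 per variable (per-variable overrides
  available). Together with the profile offsets this makes the latent
  subgroups strongly separated — deliberately so. Mean silhouette has an
  irreducible within-cluster distance floor from the nine
  phenotype-independent binary items and a general bias toward coarse
  partitions, so automatic selection of the true cluster number requires
  separation well beyond what marginal overlap statistics would suggest.
  The defaults are chosen as the weakest separation at which k = 4 and
  m = 5 are selected reproducibly across independent seeds.

**What the generator does not emulate** — and hence what passing tests do
not show: item-level questionnaire structure (composite scores are drawn
directly), correlated residuals within instruments, floor/ceiling effects
beyond simple clipping, demographic covariates, phenotype-dependent binary
rates, and, most importantly, realistic cluster overlap. Real
patient-reported-outcome data are far noisier; recovery with ARI ≈ 1 on
the defaults demonstrates the correctness of the pipeline's mechanics, not
that phenotypes of this clarity exist clinically. On real data the
silhouette table, not the recovered k alone, should drive interpretation.

## Numerical choices

* Sample SD (n−1) throughout; z-scaling errors on zero variance.
* Medoid ties → lowest patient id; nearest-medoid ties → lowest cluster
  index; silhouette ties → smaller k; size-rank ties → lower original
  cluster label; pathway-order ties → original cluster index (stable sort).
* Median of member–medoid distances uses the midpoint rule for even
  counts; membership uses ≤ with a 1e-12 tolerance.
* Convex hulls of < 3 distinct or collinear points degrade to the extreme
  points with area 0.
* PAM: 10 seeded k-medoids++ restarts, max 200 alternating iterations,
  best total-distance solution kept; fully deterministic given the seed.
* Percentages: one decimal, half away from zero.
* Bootstrap quantiles: `numpy` linear-interpolation quantiles of the
  resampled correlation, α/2 and 1−α/2.

## Problem sizes

The test suite and the acceptance script run the full pipeline at the
default enrolment (4103, ≈ 950–1030 completers), the recovery experiments
at n = 800, the oracle equivalences on ≤ 50-point instances, and the
bootstrap-calibration simulation with 500 replicates of n = 200 at 2000
resamples each. These sizes were chosen so every property is measured at
meaningful precision while a complete run stays in the minutes range on a
single core.

## Limitations

* The clustering default (PAM + silhouette) is a stand-in for the
  non-parametric algorithm used in the original line of work, which is not
  described in enough detail to reimplement; conclusions about the *number*
  of subgroups are selector-dependent.
* UMAP coordinates are seed-dependent; only the PCA engine is exactly
  reproducible across library versions.
* The χ² test requires adequately filled cells; with very small pathways
  the statistic is approximate.
* Completer-only analysis can bias results when dropout is informative;
  the generator's attrition-bias knob exists to study exactly that, but the
  pipeline itself performs no missing-data correction.
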