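# Methods

This note documents the models implemented in `claudinlow`, the parameter
choices that matter, what the synthetic data generators do and do not
emulate, and the numerical decisions taken where the design was open.

## Expression-based subtyping

Samples are assigned to one of seven intrinsic breast cancer subtypes
(luminal A, luminal B, HER2-enriched, basal-like, normal-like, molecular
apocrine, claudin-low) by nearest-centroid classification.  For each
subtype *s* and classifier gene *g* the **standardized centroid** is

    c_{g,s} = mean_{i in s}(x_{g,i}) / sd_{i in s}(x_{g,i})

with the sample (n−1) standard deviation.  A new sample's expression
vector over the classifier genes is compared with each centroid by
Spearman rank correlation; the subtype with the highest ρ is assigned if
ρ ≥ 0.3, otherwise the sample is unclassified.  Rank correlation makes the
assignment invariant to any strictly monotone transform of the sample's
values, which is the property that lets centroids trained on one
normalization be applied to another.

Design points:

* Published centroid tables are not reprinted anywhere; the module
  therefore *re-derives* centroids from any labeled reference set, so the
  method is exercisable on synthetic or user-supplied references.  The
  classifier gene set (710 genes in the reference analysis) is an input,
  not a fixture.
* A gene whose within-subtype SD is zero in any subtype is dropped from
  the classifier set globally, because all centroids must share one gene
  list for rank correlation to be comparable across subtypes.
* An exact tie for the maximal ρ yields "unclassified" with a tie flag;
  inventing a priority order would be arbitrary.

## Compendium quality control

When profiles from several studies are merged, broken samples betray
themselves on housekeeping genes.  Pairwise Spearman correlations are
computed between samples restricted to a housekeeping set (68 genes in the
reference setting); a sample is kept iff its correlation exceeds 0.95 with
at least ⌈0.5·(N−1)⌉ *other* samples.  "Half of the dataset" is read as
half of the other samples: self-correlation is always 1 and would
otherwise hand every sample a free vote.  The filter is a single pass —
removals do not trigger re-filtering.  Pairs in which either sample has a
constant housekeeping vector (ρ undefined) never count toward the
threshold.

`center_batches` is deliberately minimal: per gene, subtract the per-batch
mean and restore the global gene mean.  It removes additive location
shifts only; it is not a substitute for a full batch-effect model and is
skipped for batches of size one (the shift is unidentifiable).

## Signature derivation

The claudin-low signature is the set of genes consistently and strongly
differentially expressed between claudin-low samples and each of the six
other subtypes.  Per contrast, an empirical-Bayes moderated t-statistic is
used: the pooled two-group residual variance s² (d degrees of freedom) is
shrunk toward a prior s₀² with d₀ prior degrees of freedom,

    s̃² = (d0·s0² + d·s²) / (d0 + d),
    t  = (mean_A − mean_B) / (s̃ · sqrt(1/n_A + 1/n_B)),

referred to a t-distribution on d₀+d degrees of freedom (moderated F = t²
for the single contrast).  (d₀, s₀²) are fitted by matching the mean and
variance of log s² to those of the log of a scaled chi-square, using
digamma/trigamma identities; the trigamma inverse is solved by bracketed
root finding.  When the observed spread of log s² does not exceed what the
residual chi-square alone explains, the moment equation has no positive
solution and the fit falls back to d₀ = ∞ (every gene shares s₀²) with a
warning.  This is the correct limit for exactly homoscedastic data, which
is also why the fallback fires routinely on idealized simulations with a
common noise SD.  Both analytic limits are verified in tests: d₀ → 0
reproduces the ordinary pooled t-test, d₀ → ∞ makes t proportional to the
fold change.

Multiple testing uses the **Benjamini–Yekutieli** step-up procedure (valid
under arbitrary dependence): Benjamini–Hochberg inflated by
c(m) = Σ_{k=1..m} 1/k, with monotonicity enforced from the largest p-value
down and capping at 1.

A gene enters the signature iff, in **every** one of the six comparisons:
BY-adjusted p < α (default 0.05 — conventional, as no level is inherent to
the procedure), |log2 FC| ≥ 1 (the standard reading of "2-fold change" on
log2 data), and the sign of the change is identical across comparisons
(the published signature reports one direction per gene, which presumes
sign consistency).  The six pairwise contrasts — rather than one global
7-group F — are used because the membership criterion is defined relative
to each subtype separately.

## Surrogate IHC classifier

**Allred arithmetic.**  raw = intensity (absent 0 / weak 1 / moderate 2 /
strong 3) + proportion category (0%: 0, <1%: 1, 1–10%: 2, 11–33%: 3,
34–66%: 4, 67–100%: 5).  Nonzero intensity forces a nonzero proportion
and vice versa, so the raw score is 0 or 2–8 — a score of 1 is
unrepresentable by construction.

**Marker cutoffs** (all overridable in `MarkerCutoffRules`): ER/PR
positive at raw 3–8; HER2 positive at raw ≥ 6, equivocal at 4–5 and then
resolved by FISH (HER2/CEP17 ratio ≥ 2 = amplified), negative at ≤ 3
(only ≥ 6 and 4–5 are stated explicitly; everything below equivocal is
taken as negative); CK5, EGFR, CD24, CD44, ALDH1 positive at ≥ 4;
claudin 3/4/7 and E-cadherin "low" at ≤ 4; Ki67 high at ≥ 14%.  The
overlap at exactly 4 — "low" for adhesion markers but "positive" for the
others — is intentional and inherited from the cutoff definitions.

**Aggregation.**  Tumors are stained in triplicate 0.6 mm TMA cores; the
highest core score per marker represents the tumor.  Ki67 percentages are
likewise aggregated by maximum, by analogy with the stated highest-score
rule (the original choice for Ki67 is unstated).  Missing cores are absent
records, never zeros — zero is a legitimate Allred score.

**Decision rules**, evaluated in order on the aggregated profile:

1. ER or PR positive → luminal B if HER2-positive or Ki67-high, luminal A
   if HER2-negative and Ki67-low.
2. Otherwise HER2-positive → HER2-enriched.
3. Otherwise (triple negative): **claudin-low** if ≥ 2 of the four
   adhesion markers are low; else basal-like if CK5 or EGFR positive; else
   an explicit `triple-negative-other` category (the rules as stated give
   such tumors no home; silently coercing them would distort both the
   basal and CL groups).

Claudin-low takes precedence over basal-like: the reference claudin-low
cell lines BT549 and MDA-MB-231 are EGFR-positive (scores 7 and 8) yet are
claudin-low, which fixes the precedence empirically.  A tumor whose first
applicable rule needs a missing marker (including HER2 equivocal without
FISH) is unclassified, with the blocking marker named in the call's
`reason`; in the triple-negative branch a tumor is also unclassified when
enough adhesion markers are missing that the claudin-low criterion could
still be met.

**Stem-cell phenotypes.**  ALDH1-positive at raw ≥ 4; the
CD44⁺/CD24⁻/low phenotype requires CD44 ≥ 4 and CD24 < 4, and is missing
if either marker is missing.

## Cohort statistics

* Pearson chi-square without continuity correction ("chi-square test"
  names the uncorrected statistic; software defaults differ, so p-values
  on small 2×2 tables reproduce published clinical tables within rounding
  rather than exactly).
* Cochran–Armitage trend with equally spaced scores, two-sided normal p.
* Kruskal–Wallis with tie correction; all-identical input returns H = 0,
  p = 1 by convention.
* Kaplan–Meier via the product-limit estimator (lifelines), Greenwood
  variance accumulated over the event table, and 95% bands on the
  complementary log-log scale — the common clinical-paper default.  Events
  at a time are processed before censorings at the same time.
* k-group log-rank with k−1 degrees of freedom.
* All tests two-sided at α = 0.05.
* Percentages are formatted by half-up rounding to one decimal, the
  convention of clinical tables (so 49/72 prints as 68.1).

The characteristics table reports, per subtype and for
claudin-low-versus-rest: counts and percentages, age (mean/SD, ≥ 50
split), grade, size ≥ 2 cm, adjuvant therapy, lymphocytic infiltrate,
margins, LVI, the stemness phenotypes when available, and KM estimates at
3/5/10 years (OS) and 5/10 years (DFS, local recurrence), with
Kruskal–Wallis for age, chi-square for categorical rows and log-rank for
event rows.

## Synthetic data: what it emulates and what it does not

**Expression compendium.**  Log2-scale values with Gaussian residual noise
(default SD 0.5, a typical residual spread for normalized arrays).
Classifier genes receive an independent ±`effect_size` shift per subtype
(default 2 log2 units), which separates the subtype centroids; 68
housekeeping genes share one mean across subtypes *and* batches, drawn
over a wide intensity range (log2 3–14, as housekeeping probe sets span on
real arrays) so that intact samples rank-correlate strongly over them;
remaining genes carry only batch shifts and noise.  Batch effects are
additive Gaussian gene-level offsets (default SD 0.5).  One integer seed
feeds all substreams via `SeedSequence` spawning, so adding a downstream
draw never perturbs earlier streams.

Not emulated: probe-level intensities, normalization artifacts,
correlated gene modules, intensity-dependent variance, or non-additive
batch distortions.  Passing tests therefore demonstrate correctness of
the *procedures* under their stated assumptions, not performance on raw
array data.

**TMA cohort.**  Subtype labels are drawn from the observed cohort mix
(41.3% luminal A, 24.8% luminal B, 2.2% HER2-enriched, 5.6% basal-like,
8.4% claudin-low, 17.7% unclassified).  Marker scores come from
subtype-conditional Allred distributions constructed to be consistent with
each subtype's defining rule, and a validator warns when a user-supplied
distribution contradicts its own subtype (e.g. an ER-positive
"claudin-low").  Each marker is stained on three cores whose maximum
equals the tumor-level draw, with independent core dropouts (default 3%).
"Unclassified" tumors are real-subtype tumors whose HER2 and Ki67 stains
are entirely lost — the same mechanism (missing IHC data) that produces
unclassifiable tumors in practice.  Clinical covariates (age, grade, size,
therapy, infiltrate, margins, LVI) follow per-subtype distributions
matching the cohort-scale figures.  Event times are exponential with
per-subtype hazards chosen so the implied 10-year survival matches the
cohort-scale rates (e.g. claudin-low local recurrence λ = 0.0013/year);
censoring is one independent exponential follow-up time per tumor
(default hazard 0.02/year).  Exponential event times have a closed-form
truth, which is what the Kaplan–Meier validation tests rely on.

Not emulated: spatial TMA structure, inter-observer scoring variability,
informative censoring, competing risks, or correlation between markers
beyond what subtype membership induces.

## Problem sizes and numerical choices

Simulation-based tests use 7 × 15 samples and 1,000 genes for signature
recovery, 10 seeds per property, 100–150 samples for the QC filter, and
n = 500–1,000 arms for survival checks — sizes at which the checked
properties (exact recovery, ≥ 95% label recovery, band coverage) are
stable while the whole suite runs in about a minute.  Oracle agreement
(BY, chi-square, Kruskal–Wallis, KM, log-rank, Spearman) is asserted to
1e-10 or tighter against brute-force implementations written independently
in the tests.  The trigamma inverse is solved to 1e-12; fold-change
thresholds are compared on the log2 scale; the duplicate-gene collapse in
the expression reader takes the per-sample maximum, mirroring the
highest-core convention.

## Known limitations

* The published 60-gene signature ships as a fixture; recomputing it would
  require the original multi-study compendium, which is not distributed.
  The derivation code is validated on planted-signal simulations instead.
* The centroid classifier re-derives centroids from labeled references; it
  does not reproduce any published centroid table.
* The IHC rule engine implements the stated cutoffs exactly; borderline
  behaviors the rules leave open (Ki67 core aggregation, sub-equivocal
  HER2, triple negatives matching neither branch) are resolved as
  documented above and surfaced in the call's `reason` string.
* `center_batches` corrects additive location shifts only.
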