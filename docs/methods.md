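# Methods

`ppx` re-implements, as a tested library, the computational procedures of a
systems-biology workup of preeclampsia: tissue-specific gene calling against
an expression atlas, moderated differential expression with co-expression
module discovery and hub selection, clinical-trait association, virtual
liquid biopsy trend aggregation, a discretized match-score permutation test,
and targeted bisulfite methylation classification. This note records the
models, the parameters that matter, the numerical choices, and what the
synthetic-data generators do and do not emulate.

## Statistical primitives

**Fisher's exact test.** Enrichment questions are 2×2 contingency tables
(`a` = in-set & positive, `b` = in-set & negative, `c`/`d` the complement).
The reported odds ratio is the sample OR `ad/bc` (+inf when `bc = 0`). The
p-value conditions on the margins and enumerates the hypergeometric support;
the two-sided value follows the minimum-likelihood convention — the sum of
probabilities of all tables no more likely than the observed one. Ties at the
observed likelihood are resolved by comparing *exact integer* pmf numerators
(`comb(col1, i) · comb(n−col1, row1−i)`), so no floating-point epsilon enters
and the result is reproducible to the last bit. One-sided alternatives are
available by flag; enrichment defaults to two-sided because the study does
not state sidedness.

**Benjamini–Hochberg.** q-values are the standard step-up adjustment
(delegated to `statsmodels.stats.multitest`). Note that BH is *not*
idempotent on arbitrary monotone vectors (`bh([0.02, 0.5]) = [0.04, 0.5]`);
the properties that do hold — elementwise domination of the input,
monotonicity after sorting by p, cap at 1 — are what the tests assert.

**Kendall tau.** The tie-corrected tau-b variant (scipy), chosen because
methylation ratios tie frequently at the sequencing depths involved.
Constant vectors raise an error rather than returning NaN.

**Permutation engine.** For a two-group labeling with `C(n, n1)` distinct
arrangements, the engine enumerates all of them when the count is at most
`max_exhaustive` (default 20,000) and the p-value is the plain proportion of
null statistics at least as extreme as the observed one — the observed
arrangement is part of the enumeration, so p > 0 by construction. Otherwise
5,000 random arrangements are drawn and the +1-smoothed estimator
`(1 + #extreme)/(1 + n_random)` is used, the standard bias-avoiding choice
where the source procedure is silent.

**Power-simulation rule.** Small pilot designs are evaluated by resimulating
the study `n_repeats` times (paired t or Mann–Whitney) and counting the
fraction of repeats with p < 0.05; the design is *accepted* when that
fraction strictly exceeds 25%.

## Expression preprocessing and differential expression

Raw matrices are log2-transformed (with a +1 offset for linear input),
quantile-normalized column-wise (sorted values replaced by cross-sample means
of order statistics; ties receive interpolated quantiles, so within-sample
ranks are preserved exactly), and filtered to genes exceeding log2(50) in at
least two samples.

Differential expression fits one least-squares model per gene
(`y ~ group + batch`; factors dummy-coded, rank checked with the collinear
columns named on failure). Residual variances are shrunk toward a pooled
prior by empirical Bayes: a scaled inverse chi-square prior is fitted by
matching the mean and variance of `log s²` (the digamma/trigamma moment
equations; the trigamma inverse is solved by Newton iteration), giving prior
df `d0` and prior variance `s0²`; moderated t uses the posterior variance on
`d0 + d` degrees of freedom. With homogeneous simulated noise the estimated
`d0` is effectively infinite and the moderated t approaches the pooled-
variance z — expected behaviour, not an error. Genes are called DE at
q ≤ 0.2 and linear fold-change ≥ 1.5 (i.e. |log2FC| ≥ log2 1.5). Setting
`eb_shrink=False` reproduces the classical per-gene t exactly, which is how
the moderation code is validated.

qPCR tables are processed as −ΔCt = Ct(RPLP0) − Ct(gene) (log2 relative
expression); calibrator samples measured in every batch define a per-batch,
per-gene additive offset so calibrators agree across batches. Group models
fit `−ΔCt ~ group * maturity` per gene and report the group effect within
each maturity stratum plus the interaction. Display clustering uses
1 − Pearson distance with average linkage.

## Tissue specificity and the enrichment score

A gene is predominantly expressed in the target tissue when, on the linear
scale, (1) target ≥ 1,000 fluorescence units, (2) target ≥ 6 × median of the
other 78 tissues, and (3) target ≥ 2 × the highest other tissue. Ties at a
threshold pass (≥ semantics). The "median of the others" excludes the target;
"second highest" is read as the highest non-target tissue. Probeset-level
calls collapse to genes by *any-probeset-passes*. The liquid-biopsy
enrichment score is target expression divided by the mean of all non-target
tissues.

## Co-expression modules

Similarity is |Pearson| across samples; adjacency is `s^β` with β = 10 by
default (the soft power, chosen on the scale-free topology criterion);
topological overlap is

    TOM_ij = (Σ_{u≠i,j} a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 − a_ij)

with unit diagonal by convention. The scale-free criterion is the signed fit
index −sign(slope)·R² of the binned log–log degree regression; with only 17
samples one simulated study gives a noisy index, so the invariant check
compares means over five generator replicates at β = 10 vs β = 1.

Modules are branches of the average-linkage dendrogram on 1 − TOM, cut with
a re-implemented *hybrid dynamic tree cut* exposing three knobs rather than
the many internal constants of the original: a static cut at a
`deep_split`-dependent fraction of the dendrogram height range (0.99 / 0.97 /
0.95 / 0.92 for deep_split 0–3), a minimum module size (30), and a PAM-like
reassignment pass. Candidate branches must also *validate* on the
β-independent |r| scale: mean within-branch similarity must exceed both the
branch-to-rest mean and the network-wide background by `min_separation`
(0.1), which is what sends pure-noise dendrograms to "unassigned" instead of
one giant module; the exact degenerate case of all-equal distances returns a
single module with a warning. The PAM stage attaches an unassigned gene to
the module with the highest mean TOM provided it reaches that module's TOM
radius (the lower decile of members' own mean intra-module overlap). Module
labels are "M1", "M2", … by decreasing size with deterministic tie-breaks;
acceptance is by planted-module recovery (adjusted Rand index), not
label-for-label agreement with any particular implementation.

Hub candidates are transcription-regulator genes with mean log2 intensity
> 9, ranked within module by the number of partner genes at |Pearson| > 0.7,
with ties broken by summed |r| and then gene id.

## Clinical association

Gene–trait models fit `y ~ MAP + BW + batch` per gene with the same
moderated-t machinery, BH-adjusted per trait, significant at q ≤ 0.2. Traits
are continuous; the birthweight trait may enter as grams or percentile (both
schemas supported; the synthetic cohort uses percentiles). Module–trait
enrichment is a Fisher test of module membership against trait-significance.
The maternal vascular malperfusion score is the integer count of lesions in
that histologic category; gene–histology association is a simple per-gene
regression of −ΔCt on the score.

## Virtual liquid biopsy

Literature-style measurements carry (study, marker, week,
percent-of-control). Trends are Pearson correlations of percent against
gestational week, per marker (a pooled option exists because the source
figures could be read either way). The trimester summary bins rows into the
half-open windows [start, 12) and [12, end] — every measurement lands in
exactly one bin — and labels each side below / at / above the 100% control
line. Aggregation across studies is unweighted by default with optional
sample-size weights.

## Match-score permutation test

Genes are discretized per contrast into UP / DN / NS (q ≤ 0.05 and linear
fold-change ≥ 1.5 by default inside the test; configurable). A pair of
conditions scores +1 per UP/UP or DN/DN gene, 0 for NS/NS, −1 for UP/DN or
DN/UP, −0.5 otherwise; the matching score is the sum. Significance permutes
the in vitro class labels and *recomputes the whole DE → discretize chain*
for every arrangement, because the class labels feed the DE computation;
exhaustive when feasible, otherwise 5,000 samples; one-sided for high
concordance by default.

Calibration has three regimes worth knowing about. Under a complete null
(pure noise; no gene called under any labeling) every arrangement ties at
score 0 and the p-value is 1 — maximally conservative, as expected for a
discrete statistic. Under an exchangeable null with latent,
label-independent sample structure (some factor drives real expression
splits unrelated to the labels) the states vary across arrangements and the
p-value is nearly uniform: rejection at α = 0.05 sits inside the binomial
99% band over 200 repeats. When in vitro DE *exists* but is independent of
the in vivo pattern, the labels are not exchangeable and the test is
anticonservative (~15% at α = 0.05 in our simulations) — an inherent
property of label-permutation tests, inherited from the source design and
worth remembering when interpreting borderline concordance p-values.

## Methylation

Ratios are methylated / total reads per CpG per sample; multiple sequencing
runs are summed per sample before the coverage filter (total ≥ 4) applies.
Group comparisons fit a Poisson GLM of methylated counts on group with a
log(total) offset, so the coefficient is a log rate ratio of methylation —
the offset makes counts comparable across coverages; with only intercept and
group the fitted rate ratio equals the ratio of pooled rates (verified
against numeric likelihood maximization at 1e-8). When every sample of one
group has zero methylated counts the Poisson MLE diverges and a two-sample
t-test on ratios substitutes. Clinical-group comparisons require n ≥ 4 per
group and use the Wilcoxon rank-sum test. Differential methylation is mild /
moderate / strong at p < 0.05 with |Δratio| ≥ 0.125 / 0.25 / 0.5 (nested
tiers; the unsigned difference is used). Clinical correlation is Kendall
tau-b, significant at p < 0.05.

A calibration caveat: real methylated counts are binomial given totals, and
binomial counts are *underdispersed* relative to Poisson, so the Poisson
Wald test is conservative on such data (~1–2% rejection at α = 0.05 for
ratios 0.2–0.4 in our simulations). The calibration check therefore runs in
the correctly-specified regime (Poisson-sampled counts given totals), where
the rejection rate is ~5%, and additionally verifies the test is never
anticonservative under binomial sampling. Coordinates are 1-based
everywhere; the BED export converts to 0-based half-open.

## Synthetic data: what it emulates, what it does not

The generators are pure functions of (spec, seed) and attach their ground
truth to the outputs.

* **Expression studies** default to the discovery design: 12 cases vs 5
  controls, two planted 50-gene modules linked to MAP and birthweight. Each
  module has a single latent eigen-signal per sample; member genes load on it
  with uniform(0.5, 1) loadings and per-gene noise calibrated so the expected
  within-module correlation equals the requested value (the simplest
  structure the module detector should recover). An optional group shift on the eigen-signal
  makes module genes differentially expressed, as the discovery modules were.
  Batch effects are additive, gene-independent per-batch offsets — exactly
  the structure the linear-model batch adjustment removes. Background noise
  is 0.2 log2 units. Traits are affine in the linked eigen-signal with
  correlation 0.8 (MAP scaled to ~100 ± 15 mmHg; birthweight mapped through
  a normal CDF to percentiles).
* **Atlases** have 79 tissues with lognormal background around 100 units and
  a chosen number of target-specific genes constructed to satisfy all three
  calling rules (and verified by the caller at construction).
* **Biomarker tables** are linear in gestational week plus Gaussian noise,
  floored at 1%.
* **CpG tables** draw totals negative-binomial (floor 1, so the coverage
  filter is exercised) and methylated counts binomial, with the case-group
  probability shifted by the planted delta at planted CpGs.

None of this emulates probe-level microarray artefacts, correlated gene
noise beyond the planted modules, study-level heterogeneity in the biomarker
database, or read-level bisulfite errors. Passing tests therefore show that
the *procedures* recover the structure they assume, at the stated sample
sizes and noise levels — not that the procedures are robust to real-data
pathologies outside those assumptions.

## Problem sizes and numerical choices

Recovery and calibration checks use the study's own scale where that is
cheap (17 samples; 100–500 genes; 200 null repeats for calibration; 25 CpGs
at depth ~60 for methylation recovery), chosen so the whole suite and the
acceptance script each run in a few minutes on one CPU. Degenerate inputs
fail loudly (constant traits, rank-deficient designs, empty strata,
single-group permutations) or are skipped with a logged reason (under-covered
CpGs, groups below the minimum n). All randomness flows through
`numpy.random.default_rng` seeds recorded in reports; pipeline runs with the
same config are byte-identical (checksummed in `report.json`).

## Known limitations

* The dynamic tree cut is a three-knob re-implementation; it recovers
  clean planted blocks exactly but will not reproduce the original R
  implementation's labels on borderline branches.
* The moderated-t hyperparameterization matches moments of log-variances;
  other estimators of (d0, s0²) exist and differ in small samples.
* The match-score test's calibration depends on label exchangeability, as
  documented above.
* Fisher enrichment assumes a fixed background; choosing the background
  (module genes vs all DE genes vs the whole array) changes the question
  being asked, and the API makes the choice explicit rather than defaulting
  silently.
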