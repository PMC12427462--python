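# Methods

This note records the models the package implements, the defaults and why
they were chosen, what the synthetic cohort does and does not emulate,
and the numerical choices that matter when reproducing results.

## Compositional preprocessing

Count tables are treated as compositions. The rare-taxon filter removes
taxa whose **mean** relative abundance across all samples falls below a
threshold (default 1 × 10⁻⁵). The mean basis is the most common
convention and is order-independent; `max` (laxest) and `per-sample`
(strictest) bases are available for sensitivity analysis. The filter is
applied to raw counts; rarefaction is used only for alpha diversity.

Rarefaction subsamples each sample without replacement (multivariate
hypergeometric draw) to a common depth, defaulting to the minimum
per-sample total, with a single seeded draw. Shannon diversity
H = −Σ pᵢ ln pᵢ is computed in natural-log units on the rarefied counts;
the subsampling bias of H is approximately constant across timepoints
when depth is drawn identically, so fitted time trends are unbiased even
though H itself is biased slightly low.

The CLR transform adds a pseudocount of 0.5 to every count (a common
compositional default; configurable) before taking log ratios against
the sample's geometric mean. Aitchison distance is the Euclidean
distance between CLR rows, and ordination is plain centered PCA of the
CLR matrix — full-dimensional PC coordinates preserve Aitchison
distances to machine precision, which the tests assert.

## PERMANOVA

The distance matrix is Gower-centered (G = −½ J D² J) and partitioned by
sequential (Type I) sums of squares in the user's term order, matching
the behaviour of vegan's `adonis2` defaults; term SS are differences of
tr(H G) between successive cumulative hat matrices built from an
SVD-derived orthonormal basis (rank-safe with redundant dummy coding).
The permutation p-value is (1 + #{F* ≥ F}) / (1 + n_perm) with free
row/column permutation of G. Free permutation ignores the repeated
measures per cat — mirroring standard practice for this design — but a
`strata` argument confines permutations within blocks (e.g. within cat)
when exchangeability across cats is in doubt.

## Butyrate screen

The pathway catalog is data, not code: three routes to butyryl-CoA with
their enzyme lists, plus the terminal butyrate-forming genes buk
(K00929), ptb (K00634) and atoD (K01034). Decision rules:

* acetyl-CoA route — both terminal reductases (EC 1.3.1.86 and
  EC 1.3.1.44) present. Biochemically the two are alternatives, so an
  `acetyl_rule="either"` option relaxes the conjunction; the strict
  reading is the default.
* glutarate and 4-aminobutyrate routes — every listed enzyme present.
  These routes are not additionally required to carry a terminal
  butyrate-forming gene.

A species is a likely producer iff **any** of its genomes satisfies any
route; species with no annotated genome are classified `none` rather
than missing so that downstream subsetting has total coverage. The
terminal KOs play no role in species classification; they define the KO
feature subset usually taken into differential abundance.

## Functional potential

Per sample, each species with relative abundance strictly above the
inclusion threshold (default 1 × 10⁻⁴, applied **per sample**, so a
species can be included in one sample and excluded in another)
contributes its relative abundance to every feature in the union of its
genomes' annotations. Feature presence is binary (no copy number), and
weights are not re-closed after the threshold cut — so values are
directly interpretable as the covered fraction of the community, bounded
by 1. Re-closure after the cut is a documented divergence risk if
comparing against pipelines that renormalize.

## Longitudinal differential abundance

Features (CLR-scale taxon abundances, functional-potential values, or
any continuous outcome) are fitted one at a time with a random-intercept
linear mixed model, REML by default, delegated to statsmodels MixedLM
(with an optimizer fallback chain for near-zero variance components).
Fixed effects: treatment, timepoint and their interaction, optionally
sex. Treatment is coded either as ordered dose (orthonormal linear and
quadratic polynomial contrasts over 0/150/300 mg/kg, built by QR on the
centered Vandermonde matrix so unequal spacing is handled and the coding
is invariant to affine relabeling) or as binary control-vs-supplemented.
Timepoints get the same polynomial coding.

Arm-specific time trends are linear combinations of coefficients
(emmeans-style), rescaled from the orthonormal contrast to
change-per-timepoint-step so estimates compare directly with planted or
reported slopes. P-values use a t reference with residual degrees of
freedom (n − fixed-effect rank); Satterthwaite approximation is not
available in the delegated fitter, and with 189 observations the
difference is negligible.

The compositional bias correction is LinDA-style: the per-feature
coefficient vector for a contrast is centered by its median (a
kernel-mode estimator is available), the offset is reported, and
p-values are recomputed from the corrected estimates. This reproduces
the published method's logic — CLR regression plus location-shift
debiasing — without replicating its exact mode-kernel and Satterthwaite
details. With fewer than five features no correction is applied (the
location estimate would be dominated by the signal features) and a
warning is raised. BH adjustment is the standard step-up procedure.

Count outcomes (e.g. blood cell counts) use the day-ratio contrast: a
cell-means log-link mixed model (Gaussian on log counts, or Poisson GEE
with exchangeable within-cat correlation), from which each group's
day-last:day-first ratio is exp of a cell-mean difference, and pairwise
and polynomial dose comparisons are linear contrasts of log-ratios.
Continuous fecal outcomes follow the rule: log-transform when
|skewness| > 1 (a quantified stand-in for "considerable deviation from
normality").

## Palatability analytics

The first-choice chi-square uses an expected count of
n_cats × n_days / 2 per diet. This convention matters: choices can sum
to fewer than the cat-days when a cat abstains, and the abstention does
not reduce the null expectation. With 19 recorded choices split 14/5
over 20 cat-days the statistic is (14−10)²/10 + (5−10)²/10 = 4.1,
p = 0.043 — which matches the published panel only under this
convention (verified against all six printed daily/overall p-values
before freezing).

Consumption ratios are reported larger-consumed diet first; 2:1 is the
accepted clear-preference criterion (boundary inclusive). Intake ratios
pool a cat's grams over days before normalizing. The paired daily
t-test handles the degenerate zero-variance case explicitly (identical
columns → t = 0, p = 1; constant non-zero difference → p = 0). The
acceptance model fits empirical logits of intake/offered with a cat
random intercept; a true binomial GLMM is not available in the
delegated fitter, and the logit-LMM recovers planted log-odds shifts
within the tested tolerance. ATTD is the exact formula
(intake − output)/intake × 100, flagged when negative.

## Synthetic cohort

The generator's defaults are the trial's stated conditions: 21 cats per
arm across CD/T150/T300, 38 F / 25 M, body weights near 4.4 kg, days
0/21/42, 560 species collapsible to 198 genera, per-sample depth uniform
on 89 217–1 527 695 reads, 30 butyrate-producer species, and a 20-cat,
2-day, 100 g-per-bowl palatability panel.

Mechanisms:

* Species base abundances are log-normal (σ = 2), with independent
  per-cat log-normal noise (σ = 0.6) and multinomial read sampling.
* The control-arm Shannon decline is a progressive power-tilt
  pᵢ ∝ pᵢ^(1+ε) with ε solved per cat and timepoint (Brent root-finding)
  so the composition-level H declines by exactly the target slope
  (−0.07/step by default) — the decline is only ever reported as a
  fitted linear trend, so the tilt is a mechanism choice, not a claim.
* Planted differential-abundance trends multiply selected producer
  species by exp(slope × step) in one arm. Defaults: five producers in
  the high-dose arm, three declining and two rising at ±0.4 log units
  per step, boosted to high baseline abundance. The trial reports no
  effect sizes for these shifts, so the defaults are power-based
  calibration choices: at 21 cats/arm and this abundance the per-step
  slope is estimated with SE ≈ 0.006–0.08 CLR units, giving essentially
  full power at q < 0.05.
* Butyrate routes are planted in a configurable share (default 0.6) of
  each producer's genomes, with at least one carrier forced and the
  first producer deliberately given two genomes of which only one
  carries the route. Decoy annotations may contain partial routes but
  never a complete one.
* Palatability bowls are offered_g × Beta fractions with a logit shift
  of the preference effect on the supplemented bowl's mean; the two
  bowls' means sum to twice the base fraction so total intake is
  effect-invariant and the expected consumption ratio is exp(effect).
  Default effects are ln of the observed panel ratios (ln 1.72,
  ln 2.35, ln 1.42 toward T150 in the last pair). First choices are
  Bernoulli with the same log-odds; abstentions occur with probability
  0.03 to exercise the expected-count convention.
* Digestibility records draw intake per nutrient and compute fecal
  output from a target ATTD (±1.5 percentage points of noise).

What the generator does **not** emulate: phylogenetic correlation among
taxa, over-dispersion beyond multinomial (no Dirichlet layer),
covariance between diversity and palatability outcomes, classification
noise in the upstream taxonomic profiling, and sequencing error. Passing
recovery tests therefore demonstrate correctness of the estimators under
the stated generative model, not robustness to real-data artifacts such
as over-dispersion or taxonomic misassignment.

## Problem sizes used in validation

Heavy checks run at documented scales chosen to keep full validation
fast while preserving power: PERMANOVA size uses 500 null replicates of
30 samples with 199 permutations each; differential-abundance recovery
uses 50 cohorts at the full design size (63 cats, 560 species) with DA
restricted to the 30-species producer subset; Shannon-trend recovery
uses 200 cohorts of 10 cats/arm and 200 species at 20 000–60 000 reads
per sample (depth enters only through a nearly constant bias in H, so
the reduced depth does not move the recovered slope).

## Known limitations

* The LinDA approximation uses median centering and residual-df t
  tests; exact agreement with the published package's mode-kernel and
  Satterthwaite machinery is not expected, particularly for small
  feature sets with many true effects.
* PERMANOVA p-values under free permutation are anti-conservative for
  repeated-measures designs when within-cat correlation is strong; use
  `strata="cat_id"` for a conservative alternative.
* The acceptance model's empirical-logit LMM approximates a binomial
  GLMM; it is inaccurate when proportions pile up at 0 or 1.
* Bracken reports are consumed, never produced: `new_est_reads` is the
  count primitive and printed fractions are ignored and recomputed.
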