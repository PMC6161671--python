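# Methods

## Scales and sign conventions

All qPCR arithmetic is on the cycle (log2) scale. ΔCt = Ct(target) −
Ct(reference), so one unit is a two-fold expression change and *higher ΔCt
means lower expression*. Scores and cutoffs are kept in ΔCt units because
the clinically quoted thresholds (e.g. "≤ 5.01 ΔCt") live there; regression
covariates use the reflected value −ΔCt so that positive coefficients mean
"more interferon activity raises the odds". Fold differences are
2^−ΔΔCt with ΔΔCt the difference of group mean ΔCt; their confidence
intervals are computed on the ΔΔCt scale (Welch t by default; the Tukey
studentised range when the contrast sits inside a ≥3-group ANOVA — both are
provided because the variance assumption behind the published intervals is
not stated) and exponentiated, re-ordering the endpoints after the
sign-flipping transform. Missing Ct values are NaN throughout and are
excluded pairwise from group means.

## The two-score system

The gene panel is reduced by principal-axis factoring on the gene–gene
correlation matrix of reflected ΔCt (complete samples only), with
communalities initialised at squared multiple correlations and iterated to
convergence, followed by varimax rotation. Per-factor variance shares are
quoted for the *unrotated* extraction: rotation redistributes sums of
squared loadings (and will happily split a single general factor in two),
while the total explained variance is rotation-invariant. Genes are assigned
to the factor with the larger absolute loading when that loading reaches a
threshold (default |loading| ≥ 0.4, ties to Score-A), else left unassigned.
These are the common defaults for this procedure; the original gene sets
were fixed in prior work, so the primary operating mode supplies a
pre-specified partition as JSON and skips fitting entirely.

A sample's score for a set is the **median ΔCt** of the set's observed
genes (even cardinality: mean of the central pair). A score is NaN when
fewer than half the set (rounded up; configurable) is observed — the floor
is not stated in the source analysis and exists to guard degenerate medians.
Classification against a cutoff is inclusive: score ≤ cutoff ⇒ IFN-positive.

## Biomarker evaluation

ROC curves sweep the unique score values; AUC is the Mann–Whitney
probability of correct ranking with ties counted ½, its CI uses the DeLong
structural-components variance, and the two scores are compared on the same
samples with DeLong's paired test (statistic reported as χ² = z², 1 df).
A singleton outcome class contributes no variance term. The Youden cutoff
maximises sensitivity + specificity − 1 with ties broken toward sensitivity;
the rule-in cutoff is the most sensitive threshold meeting a specificity
floor. All proportions carry two-sided 95% **Wilson score intervals without
continuity correction** — this choice reproduces every published interval
bound exactly after integer rounding (e.g. lower bound 75% for 18/19, upper
bound 55% for 7/21), which is how the method was identified. Human-readable
output rounds percentages to integers; machine output keeps full precision.

## Paired categorical transitions

Stuart–Maxwell's χ² of marginal homogeneity uses the quadratic form d′S⁻¹d
with d the row−column marginal differences and S the usual covariance
matrix, after dropping the category with the smallest marginal sum
(structural zeros otherwise make S singular, as in a table where every
subject starts in the same category); a generalised inverse with
rank-based df is the fallback. For 2×2 tables this is exactly McNemar's
(b−c)²/(b+c) without continuity correction.

## Prognostic model

Missing covariates (in practice the two scores, missing for whole samples
whose expression was never measured) are imputed by chained equations with
predictive-mean matching for every variable — PMM donors preserve the {0,1}
support of binary variables, so no separate logistic sub-model is used —
with m independent, seed-derived streams (default m = 20, 10 cycles);
observed cells are never altered and the whole procedure is deterministic
given the master seed.

The penalised model minimises (1/n)·NLL + λ‖β‖₁ with an unpenalised
intercept, by cyclic coordinate descent on the IRLS quadratic
approximation; predictors are standardised to unit variance internally and
coefficients mapped back to the original scale. The path is 100 log-spaced
penalties from λ_max = maxⱼ|Xⱼ′(y−ȳ)|/n down to 10⁻³·λ_max (glmnet-style).
Convergence requires a maximum coefficient change below 1e-7; IRLS weights
are floored at 1e-5 and held-out probabilities clipped at 1e-8 when scoring
deviance. λ is chosen per dataset by leave-one-out cross-validation:
λ_min minimises the mean held-out binomial deviance and λ_1se is the
largest penalty within one standard error of that minimum (a degenerate
fold with a single class predicts the prevalence). Per-imputation λ_1se
coefficients are averaged; the averaged coefficient and its exponential are
reported as the "penalised coefficient → OR" pair, with the across-
imputation min/max retained as a dispersion diagnostic.

Unpenalised univariable and multivariable fits use Newton–Raphson with a
light ridge fallback under separation (flagged by a warning); estimates are
pooled by Rubin's rules (T = W + (1+1/m)·B) with Barnard–Rubin adjusted
degrees of freedom, and predictors whose pooled univariable p exceeds 10%
are excluded from the multivariable set, mirroring the published screen.

## Synthetic cohorts

The generator draws, per sample, two latent factors from a bivariate normal
(correlation 0.6 — both scores index interferon activity, and this value
reproduces the reported marginal association of Score-A with progression
when only Score-B is causal). Group means on the reflected log2 scale come
from the reported fold differences (at-risk vs HC: 2.21-fold for Score-A,
none for Score-B; SLE vs HC: 7.81 / 3.85). Latent SDs are 1.9 (Score-A) and
1.3 (Score-B, ≈ the prevalence-pooled reported group SDs). Each gene's ΔCt
is a fixed baseline minus its factor (loading 1.0, so score shifts equal
factor shifts in log2 units) plus Gaussian cycle noise (SD 0.5); Ct adds a
constant reference Ct of 20, and the reference gene itself is constant.

Progression is Bernoulli from a logistic model in family history
(OR 8.2) and the centred reflected Score-B (OR 3.79 per unit), with the
intercept calibrated by root-finding so the realised marginal rate is 16%.
Remaining covariates are drawn independently at the reported baseline
distributions. Missingness is completely at random and whole-sample: ~11%
of at-risk samples lose their entire expression profile (truth labels are
retained). Under these conditions the emergent progressor-vs-non-progressor
Score-B fold difference is ≈ 2.8 and the two scores' AUCs are ≈ 0.82 / 0.70,
matching the reported operating points; the emergent fold difference is
smaller than β·σ² because of the 16% prevalence and the family-history term.

What the generator does **not** emulate: correlation among clinical
covariates (independence is assumed; the real structure is unreported),
non-normal score distributions, informative missingness, assay-level
artefacts (plate effects, efficiency ≠ 2), and any tissue sub-study.
Passing tests therefore show the pipeline recovers known truth under the
stated statistical structure, not that it is robust to violations of it.

## Problem sizes and determinism

Tests run the full pipeline at the default cohort size (n = 118 at-risk)
with reduced MI settings (m = 3–5) and shorter penalty paths where only the
plumbing is under test; effect-size recovery uses n = 1000 with three seeded
replicates and compares geometric-mean odds ratios within a factor of two.
The acceptance script uses the full study settings (m = 20, 100-λ path,
LOOCV). Every source of randomness flows from a single seed via
`numpy.random.default_rng`; the chained-equation imputer consumes a
seed-derived state per stream, so reruns are bit-identical.

## Known limitations

* PMM imputation for binary variables departs from a logistic sub-model
  (support is preserved; calibration under heavy missingness is not).
* The Stuart–Maxwell category-drop rule (smallest marginal sum) is one of
  several reasonable resolutions for structurally singular tables; on the
  all-from-one-category transition table it yields 19.0, and variant
  statistics in the vicinity of 20 exist.
* No PCR efficiency correction or multi-reference-gene normalisation.
* DeLong intervals are asymptotic; at 19 events they are approximate, and
  the published interval method (DeLong vs bootstrap) is not stated.
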