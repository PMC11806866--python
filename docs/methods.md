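# Methods

This note documents the statistical procedures implemented in `plscortex`,
the choices made where the methodology is genuinely open, and what the
synthetic benchmark does and does not establish.

## Atrophy signatures (w-scores and contrasts)

Per region, cortical thickness in healthy controls is modeled by ordinary
least squares as `thickness = β₀ + β₁·age + β₂·sex + ε` (age in years, sex
as a 0/1 indicator, thickness in mm). The residual SD uses an n−3
denominator (three fitted parameters), the standard unbiased choice for
w-scoring. A patient's w-score per region is
`(observed − predicted)/residual SD`; it is dimensionless and invariant to
a consistent affine rescaling of the thickness unit. Controls with missing
covariates are dropped with a warning rather than imputed; a constant age
or sex column raises a degenerate-design error naming the covariate.

The contrast map fits, per region, `w ~ intercept + group + duration` over
the two compared groups and reports the t-statistic of the group indicator
(target coded 1, so **negative t = thinner cortex in the target group**;
the convention is recorded in the output metadata). If duration is constant
across the included subjects it is collinear with the intercept and is
dropped, which reduces the model to the pooled two-sample t-test. Scanner
model and intracranial volume are not modeled; region counts are arbitrary
(the motivating use case has 100 left-hemisphere parcels).

## PLS1 and gene-level inference

Both blocks are centered internally; by default gene columns are only
centered beforehand (`column_standardize(..., "center")`), since
atlas-derived expression matrices arrive already normalized across
regions; z-scoring is available and changes weight scales but not sign
patterns on well-conditioned data. For a single response the first PLS
weight vector is exactly `normalize(Xcᵀ yc)`; further components are
computed by deflation but only PLS1 is consumed downstream. Weight
columns have unit norm and the PLS1 sign is fixed so that its scores
correlate non-negatively with Y. `variance_explained` is 100 × R² of Y
regressed on the PLS1 scores.

**Null for variance explained.** The default re-draws Y by permuting its
regional values with X fixed (`method="permute"`); resampling Y with
replacement (`method="bootstrap"`) is also offered. Permutation is the
default because bootstrap re-drawing changes Y's marginal distribution as
well as breaking the region pairing, which conflates two sources of
variation in the null. Empirical p-values use add-one smoothing,
`(1 + #{null ≥ observed})/(1 + n_iter)`, so they are never zero. Neither
null preserves spatial autocorrelation; spin-style nulls are out of scope
and p-values should be read accordingly.

**Bootstrap gene z-scores.** Regions are resampled with replacement
jointly in X and Y (replicates with fewer than three distinct regions are
redrawn and counted); each replicate's weight vector is sign-aligned to
the original fit by dot product, since without alignment arbitrary sign
flips inflate the SEs. Replicate weights are expressed as the raw
cross-covariance divided by the **observed** norm rather than re-normalized
per replicate: z = weight/SE is invariant to any common rescaling, but
per-replicate renormalization injects the resampled norm's variability
into the SE. Empirically that deflates SEs by roughly √2 in every n/p
regime (the resampled cross-covariance norm is systematically larger than
the observed one) and makes the gene-level test reject ~19% of null genes
at α = 0.05; with the fixed-norm scaling the null rejection rate is within
Monte-Carlo error of the nominal 5% (verified in the acceptance suite).
p-values are two-sided standard-normal tails of z, assuming approximate
normality of the bootstrap weights; percentile intervals can be computed
from the retained replicates (`keep_replicates=True`). A gene whose
aligned weight is identical in every replicate (SE = 0) with a nonzero
weight is flagged degenerate and assigned p = 0.

**VIP and selection.** For k components,
`VIP_j = sqrt(p · Σ_k SSY_k (w_jk/‖w_k‖)² / Σ_k SSY_k)`; with one
component this is `sqrt(p)·|w_j|/‖w‖` and mean(VIP²) = 1 exactly. Gene
selection uses strict thresholds VIP > 1 and uncorrected p < 0.05 (the
field's convention); BH-FDR adjustment is available via `fdr=True`.

## Receptor mapping

Spatial correlations are Pearson by default (Spearman available) with
parametric t-based p-values and BH-FDR across receptors; a permutation
null on the contrast map's regions is offered (two-sided on |r|,
add-one smoothed). Dominance analysis z-scores the receptor columns for
conditioning (R² is affine-invariant, so results are unchanged), computes
subset R² values from the Gram system of the standardized design for all
2^m predictor subsets, averages each predictor's incremental R² first
within subset size and then across sizes (total dominance), and reports
relative importance as a percentage of the full-model R². Total dominances
sum to the full-model R² exactly — the suite checks this to 1e−8 and
agreement with a brute-force all-subsets oracle to 1e−10. The predictor
count is capped at 20 (2^20 subset fits); beyond that, pre-select.

## Gene-set overlap

The permutation test draws |query| genes uniformly without replacement
from the background and counts the overlap with the target list restricted
to the background (both raw and restricted target sizes reported),
one-sided for enrichment with add-one smoothing. Its analytic limit is the
hypergeometric tail P(X ≥ observed), which is also the ORA statistic used
per GMT term, with BH-FDR across terms (statsmodels' step-up
implementation) and significance at q < 0.05. Gene symbols are
canonicalized by uppercasing and whitespace-stripping only; alias
resolution would need an external database and is out of scope.

## Synthetic data: what it emulates and what it does not

`make_expression` builds X = S·Gᵀ + noise with smooth spatial factors
(low-order sinusoids plus smoothed noise over a 1-D region ordering,
standing in for anterior–posterior expression gradients without surface
geometry) and a planted block of genes loading predominantly on factor 1
(loading magnitude ~N(2, 0.25), random sign, vs N(0, 0.3) for background
genes; defaults 3 latent factors, noise SD 0.5, planted block = a tenth of
the gene universe). `make_cohort` mirrors the motivating cohort's
demographics (defaults 172 controls, 117 sporadic, 32 genetic; age uniform
45–75 y; disease duration Gamma with mean 3.8 / SD 2.7 y) and a control
thickness model of baseline + (−0.010 mm/y)·age + 0.05 mm·sex + N(0, 0.1 mm)
noise; the genetic group is shifted by `effect` (w-score units) × the
standardized atrophy map × the residual SD, and the sporadic group by
`effect/3` × an independent smooth map, so `effect=0` makes the groups
exchangeable while a positive effect yields a contrast dominated by the
planted pattern. `make_receptor_atlas` mixes the standardized atrophy map
with independent noise at weights (r, √(1−r²)) so the expected correlation
equals the target. All generators take one seed each and are
bit-reproducible.

Not emulated: MRI images or surfaces, hemispheric asymmetry, realistic
cortical spatial autocorrelation (the smoothness parameterization is a
stand-in, not an estimate), donor-level microarray noise, scanner effects,
and gene–gene co-expression structure beyond the low-rank factors.
Passing tests therefore establish the *statistical machinery* — oracle
agreement, calibration, recovery of planted signal — not that real
atrophy–expression associations of a given magnitude will be detected.

## Problem sizes and numerical choices

The acceptance benchmark runs at 100 regions × 2,000 genes with 200
planted genes, 1,000 bootstrap draws, 1,000 null iterations and 1,000
overlap permutations — large enough for stable recovery statistics while
keeping a full run in seconds. Field-standard defaults (5,000 bootstraps,
5,000 null iterations, 1,000 permutations) remain the pipeline's
configuration defaults. Note the false-discovery proportion against the
planted truth is substantial by design: non-planted genes share the
low-rank spatial factors and so carry real (if weaker) association with
the contrast map; the benchmark reports the proportion rather than
pretending the planted set is the only truth.

Other numerics: bootstrap SEs use a streaming mean/variance (ddof = 1) so
memory stays O(p) at 15,000+ genes; empirical p-values are never 0 by
construction; degenerate inputs (constant Y, constant covariates,
rank-deficient receptor designs, duplicate gene columns) raise typed
errors early rather than propagating NaNs; and the pipeline derives one
seed per stage from the master seed by hashing the stage name, so adding a
stage never perturbs another stage's stream.
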