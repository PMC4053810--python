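# Methods

## The mixture model

Bulk-tissue methylation at probe j in sample i is modeled as a convex
combination of cell-type profiles,

    y_ij = Σ_k w_ik · μ_jk + ε_ij,

with w_ik ≥ 0 the fraction of cell type k in sample i (Σ_k w_ik = 1 for a
complete panel) and μ_jk the mean beta value of type k at probe j. Beta
values are proportions in [0,1]; the model is linear on that scale because a
mixed sample's methylated-read fraction is the count-weighted average of its
constituents'. The package estimates μ from flow-sorted reference samples
and w from bulk samples by constrained least squares over a small set of
signature probes.

Working assumptions, and where they matter:

- *Cell-type profiles are age-stable at the signature probes.* This is
  enforced rather than assumed: probes whose methylation associates with
  donor age in the sorted reference (pooled regression with an additive
  cell-type covariate, age term p ≤ 0.05) are excluded before selection. A
  per-cell-type variant of the filter is available.
- *The reference panel spans the bulk tissue.* Missing cell types load onto
  the nearest available profiles; the per-sample residual norm reported with
  every projection is the diagnostic.
- *Noise is additive and uncorrelated with composition* at the signature
  probes.

## Signature selection

For each cell type a Welch one-vs-rest t-test is computed at every probe
(pooled-variance option available; the unequal-variance default is robust to
cell types with different within-type spread). Among probes with
p < 10⁻⁸ and not excluded by the age pre-filter, each type contributes its
top 50 hypermethylated and top 50 hypomethylated probes. Ranking is by
absolute beta-scale difference in group means; "most differentially
methylated by effect size" could also be read as ranking by t, so both are
offered (`rank_by`), with the mean difference as default because it is the
natural effect measure on the beta scale. Ties break by larger |t|, then
lexicographically by probe id, making selection deterministic and invariant
to probe/sample order. A probe selected for two cell types is kept once
(credited to the first type in declared order) with a warning; in a
two-cell-type design every discriminating probe is necessarily shared (hyper
in one type is hypo in the other), so the warning is routine there and the
signature holds each probe once.

Probes with zero variance in both groups are reported t = 0, p = 1
(undefined contrast) unless their group means still differ — the noiseless
limit, where separation is perfect and they are reported t = ±∞, p = 0.
Variance thresholds (1e-24 on the squared scale) absorb float accumulation
noise.

Outlier handling in the sorted reference is explicit: callers may pass a
leave-out list, and an advisory rule flags samples whose correlation with
their own cell-type centroid falls more than 3 MADs below the within-type
median. The rule never removes anything by itself and is off by default,
since any automated criterion here is a judgment call.

## Constrained projection

Per bulk sample, minimize ‖y − Xw‖² subject to w ≥ 0 ("nonneg" mode,
default) or additionally Σw = 1 ("simplex" mode). The nonnegative problem is
solved with Lawson–Hanson NNLS; the simplex problem with an active-set
method that solves the equality-constrained KKT system on the passive set,
clamps variables driven negative, and releases active variables with
negative multipliers until the KKT conditions hold — exact (to machine
precision) for well-conditioned designs, which 100+ probes per cell type
guarantee in practice. In nonneg mode a post-hoc normalized copy w/Σw is
reported alongside the raw weights, and the constraint mode is recorded in
the output, because proportion plots conventionally sum to one while the
projection itself need not be equality-constrained. At least 80% of the
signature probes must be present in the target matrix; missing probes below
that threshold are dropped with a warning.

Reference quality is assessed by leave-one-out cross-validation: fold f
holds out the f-th replicate of every cell type, rebuilds the signature on
the remaining samples only, and projects the held-out samples; for sorted
samples the truth is the unit vector on their own type, so mean own-type
proportion is the concordance summary.

## Confounding diagnostics and adjustment

The per-probe composition ANOVA (one-way, across cell types in the sorted
reference) yields the F statistic, p value, per-type means and the beta
range used by the composition filter, which removes probes meeting BOTH
p < 10⁻⁴ AND range > 10% — a conjunctive rule, so a statistically clear but
tiny between-type difference is not filtered.

Three EWAS strategies are implemented over the same vectorized OLS core
(single QR per design, broadcast across probes; rank-deficient designs raise
an error naming the collinear columns):

- *univariate*: β ~ age (+ known covariates such as processing plate);
- *naive*: proportions added as covariates, one cell-type column dropped to
  break the simplex collinearity (the dropped column is recorded; constant
  proportion columns are also dropped, so a constant-composition cohort
  reduces exactly to the univariate model);
- *ruv2*: two-step remove-unwanted-variation. Step 1 centers each control
  probe across samples and takes the top k right-singular vectors of that
  submatrix as sample-level surrogate covariates; step 2 regresses every
  probe on age + covariates + surrogates. Controls must be unassociated with
  the outcome; the signature probes qualify by construction of the age
  pre-filter. k = 0 reproduces the univariate analysis exactly; k is a user
  decision, supported by a scree of the control-matrix singular values.

Multiple testing uses Benjamini–Hochberg at 5% and each result reports the
|t| cutoff attained at that FDR.

The CETS transform T(Y_i) = Y_i + (1−π_i)(μ̄_N − μ̄_G) and its bias
decomposition T(Y_i) = μ_iN + (1−π_i)[(μ̄_N−μ_iN) − (μ̄_G−μ_iG)] + ε_i are
implemented as exact elementwise identities (verified to 1e-12 by property
test); transformed values outside [0,1] are flagged, never clamped. The
neuron fraction π is taken as given, matching the decomposition's setting.

## Enrichment

CpGs — not genes — are the counting unit. For each gene set with at least 25
genes annotated in the background: observed = query CpGs mapping to a set
gene (a CpG with several genes counts once per set), expected =
|query mapped| × (set CpGs / background mapped CpGs), ratio = obs/exp, and a
one-sided hypergeometric p; sets are ranked by p. The background denominator
is mapped-only CpGs (probes without a gene id drop out of both numerator and
denominator). No ontology database is bundled; sets load from two-column TSV
or GMT, so GO, KEGG or synthetic collections are interchangeable and no
graph propagation is performed.

## The synthetic-data generator

Defaults emulate a six-cell-type sorted-blood design with six replicates per
type and a 200-sample, 5,000-probe bulk cohort:

- Baseline probe means are bimodal (mixture of Beta(2,18) and Beta(18,2)),
  mimicking methylation's concentration near 0.1/0.9. All betas are
  truncated to [0.01, 0.99].
- Each cell type carries 50 hyper- and 50 hypomethylated marker probes with
  beta-scale effect δ = 0.5, the magnitude of clear cell-type differences on
  arrays.
- Noise is Gaussian on the logit scale (sd 0.01 for sorted replicates and
  bulk samples), inverse-transformed — heteroskedastic on the beta scale,
  largest near 0.5, like real beta-value error.
- Composition follows a logistic age trend with inflection at 40 years and
  a granulocyte swing of 0.3 across the lifespan (T-cell fractions fall,
  granulocytes rise), plus lognormal inter-individual jitter (sd 0.15) on
  the raw shares: real cohorts scatter widely around the trend, and a
  deterministic composition-of-age curve would make proportions a rank-two
  function of age, which no real cohort exhibits.
- Confounded scenarios can plant genuine within-cell-type age slopes on
  chosen probes (mixed-tissue marginal slope = slope × mean proportion of
  the affected type), age-associated decoy probes in the sorted reference
  (marker-sized cell-type effect plus 0.005 beta/yr drift), and a
  single-category plate shift.
- The brain design generates NeuN+/NeuN− profiles, a 10–90% titration
  series, and individual-level deviations from the average profiles that can
  be forced equal across cell types (the CETS transform's unbiased special
  case) or drawn independently.

What the generator does *not* emulate: probe-type chemistry differences and
dye bias, spatially correlated probes, SNP-driven trimodality, realistic
linkage between annotation and position, batch structure beyond one
categorical shift, and cell-type profiles that drift with age outside the
planted probes. Passing tests therefore demonstrate the correctness of the
algorithms under the mixture model, not robustness to every artifact of real
arrays.

## Numerical choices

- Intensity floor 1.0 unit before the log keeps the logit route defined at
  zero intensity with minimal perturbation.
- Quantile normalization maps each value to the across-column mean of order
  statistics at its rank; tied ranks receive the average of the adjacent
  targets (linear interpolation on the rank grid), deterministic by
  construction.
- The loess smoother for age trends is a tricube-weighted local polynomial
  (span 0.75, degree 2), evaluated at the data points.
- Spearman p values use the asymptotic approximation by default; a
  permutation p value (9,999 resamples) can be enabled for small cohorts.
- PCA centers probes but does not scale them — beta values share a scale,
  and unscaled variance fractions are comparable across studies.
- Solver tolerances: NNLS is exact; the simplex active-set solver uses
  1e-12 feasibility/optimality thresholds and is capped at 4K+10 iterations.

## Problem sizes and runtime

The test suite and the acceptance script run simulations at 1,200–5,000
probes, 36 sorted samples and up to 200 bulk samples — large enough that
marker t statistics, FDR behavior and calibration rates are in their
asymptotic regime, small enough that the whole suite completes in well under
a minute on one CPU. Null-calibration checks use 10,000 probes so the ±1
percentage-point acceptance band sits ~4.5 Monte-Carlo standard errors from
the nominal rate.

## Known limitations

- The projection assumes the reference spans the mixture; no reference-free
  or semi-supervised mode is provided.
- No probe-level measurement-error weighting in the projection.
- The RUV implementation is the two-step surrogate-covariate form; RUV-4
  style shrinkage estimators are out of scope.
- 27k↔450k lift-over, IDAT parsing and array manifests are out of scope;
  all interfaces are generic annotation tables.
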