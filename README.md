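# methdecon

Reference-based cell-composition estimation and composition-confounding
diagnostics for DNA methylation arrays.

Whole blood (and any other heterogeneous tissue) is a mixture of cell types
with very different DNA methylation profiles, so an epigenome-wide
association study (EWAS) run on bulk tissue can mistake a shift in cell
counts for a change in methylation. Age is the canonical example: blood
composition changes monotonically across the lifespan, so naive per-CpG
regressions of methylation on age produce large numbers of hits that reflect
composition, not site-specific biology. `methdecon` implements the full
workflow for detecting and handling this problem:

- **Preprocessing** — across-array quantile normalization of the methylated
  (M) and unmethylated (U) intensity channels separately, beta values via
  the logit route (β = 2^x/(1+2^x) with x = log₂(M/U), equal to M/(M+U)
  after intensity flooring; no +100 offset), and probe filtering by
  annotation (sex chromosomes, SNPs at the CpG site / single-base-extension
  site / probe body).
- **Reference building** — selection of cell-type-discriminating signature
  CpGs from flow-sorted reference samples: per cell type a one-vs-rest
  Welch t-test at every probe, an age pre-filter (drop probes with age
  association at p ≤ 0.05), then the 50 most hypermethylated and 50 most
  hypomethylated probes by beta-scale effect size among those with
  p < 10⁻⁸ — a 600-probe signature for a six-cell-type blood panel.
- **Deconvolution** — for each bulk sample y over the signature probes,
  solve min‖y − Xw‖² subject to w ≥ 0 (optionally Σw = 1), where X holds the
  per-cell-type mean beta profiles and w the cell proportions; plus
  leave-one-sample-per-type-out cross-validation of the reference.
- **Diagnostics** — a per-probe composition ANOVA table (F, p, per-type
  means, beta range), age/cell-type variance partitioning in sorted data,
  correlation of methylation principal components with composition,
  Spearman age trends of the estimated proportions with loess smoothing,
  and the conjunctive composition filter (F-test p < 10⁻⁴ AND beta
  range > 10%).
- **Adjustment** — univariate, naive (proportions as covariates) and
  two-step RUV age EWAS (surrogate covariates from the singular vectors of
  the signature-probe submatrix), each with Benjamini–Hochberg FDR; and the
  two-cell-type CETS transform T(Y) = Y + (1−π)(μ̄_N − μ̄_G) together with its
  closed-form bias T(Y) − μ_N = (1−π)[(μ̄_N−μ_N) − (μ̄_G−μ_G)] + ε, which
  shows the transform is unbiased only when individual deviations from the
  average profiles agree across cell types.
- **Enrichment** — gene-set over-representation of CpG lists by
  observed/expected count ratios with hypergeometric p values, before and
  after composition filtering.
- **Synthetic data** — seed-deterministic generators for sorted references
  with planted markers, age-trend mixture cohorts (logistic trend,
  inflection near 40 years), confounded EWAS scenarios with known ground
  truth, and a NeuN+/NeuN− brain titration design.

All I/O is plain TSV/CSV (probes × samples matrices, annotation and sample
sheets); IDAT parsing and array manifests are out of scope.

## Worked example

Build a signature from a simulated sorted-blood panel, deconvolve an
age-trend mixture cohort, and summarize the composition–age relationship:

```python
import methdecon as md

cfg = md.SimulationConfig(seed=42, n_probes=3000, n_mixture_samples=50)
ref, truth = md.simulate_reference(cfg)
sig = md.select_signature(md.one_vs_rest_tstats(ref), ref)
print(f"signature probes: {len(sig.probe_ids)}")

mix, mix_truth = md.simulate_mixtures(truth.reference_means, cfg, mode="age_trend")
props = md.project_proportions(mix, sig)
print(props.normalized.round(3).head(3))

stats, _ = md.age_trend(props, mix_truth.ages)
print(stats.round(3))
```

prints

```
signature probes: 600
           CD8T   CD4T     NK  Bcell   Mono   Gran
mix_0001  0.071  0.073  0.081  0.054  0.055  0.667
mix_0002  0.087  0.127  0.063  0.081  0.049  0.593
mix_0003  0.044  0.059  0.072  0.047  0.068  0.710
           spearman_rho     p
cell_type
CD8T             -0.808  0.00
CD4T             -0.887  0.00
NK                0.278  0.05
Bcell            -0.809  0.00
Mono              0.505  0.00
Gran              0.865  0.00
```

Each row of the proportions table is one bulk sample's estimated cell-count
fractions (granulocytes dominate adult blood, as expected); the Spearman
table shows the recovered age trends — granulocyte fraction rising with age,
T-cell fractions falling. Against the generator's ground-truth weights the
mean absolute proportion error here is 0.0003.

The same pipeline is available from the shell:

```sh
methdecon simulate --seed 7 --scenario mixtures --outdir sim/
methdecon build-reference --beta sim/reference_beta.tsv \
    --samples sim/reference_samples.tsv --out sig.tsv
methdecon deconvolve --beta sim/mixture_beta.tsv --signature sig.tsv \
    --mode nonneg --out props.tsv
```

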