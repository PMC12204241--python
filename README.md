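# popcellmeta

Statistical and combinatorial machinery for finding cell-type signatures that
are **conserved across population groups** in stratified single-nucleus
RNA + ATAC studies of Alzheimer's disease, exercisable end-to-end on
synthetic data with known ground truth.

Cohort studies that profile donors from several self-identified population
groups (here `AA-NL`, `L`, `W-NL`) across several brain regions (`DLPFC`,
`STG`, `AC`) need analysis machinery that (a) respects the compositional
nature of cell-type proportions, (b) treats each population group as its own
stratum, and (c) only calls an association *conserved* when the evidence
agrees across all strata. This package implements that pipeline:

- **Composition models** (`popcellmeta.composition` / `popcellmeta.glm`):
  for each subcluster *s* within a broad cell class, the proportion
  p<sub>s</sub> is modeled per (group, region) with a quasibinomial logistic
  GLM,

  logit E[p<sub>s</sub>] = β₀ + β₁·trait + β₂·age + β₃·sex + β₄·pmi
  (+ β₅·education for cognitive traits),

  fit by IRLS with the broad-class nucleus totals as binomial denominators, a
  free Pearson dispersion φ, and heteroskedasticity-consistent (sandwich)
  standard errors; inference uses t tests on n − p degrees of freedom.
  Subclusters enter only with at least one more complete observation than
  model terms; calibration is checked by permutation.
- **Conservation meta-analysis** (`popcellmeta.meta`): the three per-group
  slopes are pooled by a random-effects model, τ² estimated by REML (Fisher
  scoring; restart cascade to ML and finally a fixed-effect t-test on
  non-convergence), with Hartung–Knapp–Sidik–Jonkman tests on k − 1 df.
  An association is conserved iff BH-adjusted p < 0.05, the per-group slopes
  share one sign, and I² < 50%.
- **Expression-program rules** (`popcellmeta.programs`): a pluggable count
  factorizer (seeded multiplicative-update KL-NMF by default; any external
  gene-weight/cell-score matrices accepted), the largest-K-without-duplicate-
  factors selection rule (pairwise correlation ≤ 0.75), the top-5-genes-at-
  CPM>10 reporting rule, and per-sample median-score linear models that feed
  the same meta-analysis.
- **Taxonomy rules** (`popcellmeta.taxonomy`): nucleus QC (UMIs > 500,
  mito% < 5), the pairwise subcluster merge rule (≥4 genes with
  |log2FC| > 2 in each direction), Calinski–Harabasz / Davies–Bouldin model
  selection scores, marker-gene filters, and 4-of-5 consensus label transfer.
- **Locus accessibility** (`popcellmeta.atac`): the four-step risk-locus
  normalization of pseudobulked ATAC peak counts (CPM → peak-length
  normalization → group means → per-locus max scaling).
- **Pooled demultiplexing** (`popcellmeta.demux`): validation of the
  no-repeated-donor-pair pooling design and genotype-free assignment of
  anonymous per-library genotype clusters to donors via cross-library VAF
  concordance and library-set fingerprints.
- **Donor subgroups** (`popcellmeta.subgroups`): Ward clustering of donors on
  concatenated proportion + median-factor features under 1 − Pearson r
  distance, cut chosen by median silhouette, with hypergeometric enrichment
  summaries.
- **Synthetic data** (`popcellmeta.synthetic`): generators for every input —
  three-group cohorts with latent-severity-correlated AD phenotypes,
  Dirichlet-multinomial compositions with planted log-odds effects, Poisson
  factor-structured count matrices, pooled genotype mixtures — all
  deterministic given a seed, all returning their ground truth.

## Worked example

```python
from popcellmeta import meta, synthetic
from popcellmeta.composition import fit_group_table
from popcellmeta.datatypes import PlantedEffect

cohort = synthetic.generate_cohort(n_per_group=40, seed=1)
comp = synthetic.generate_composition(
    cohort, [f"SC{i}" for i in range(8)],
    effects=[PlantedEffect("SC2", "amyloid_sqrt",
                           {"AA-NL": 0.6, "L": 0.6, "W-NL": 0.6})],
    seed=2,
)
fits = fit_group_table(comp, cohort.frame(), ["amyloid_sqrt", "cog_decline"])
pooled = meta.meta_analyze_table(fits)
hit = pooled[pooled.conserved]
print(hit[["region", "subcluster", "trait", "pooled_beta", "I2", "p_adj"]])
```

prints

```
   region subcluster         trait  pooled_beta         I2     p_adj
0      AC        SC0  amyloid_sqrt    -0.275362   0.000000  0.023621
4      AC        SC2  amyloid_sqrt     0.606389   0.000000  0.024530
5      AC        SC2   cog_decline     0.890387   0.000000  0.044515
20  DLPFC        SC2  amyloid_sqrt     0.593297   0.000000  0.012795
32    STG        SC0  amyloid_sqrt    -0.260474   0.000000  0.025523
36    STG        SC2  amyloid_sqrt     0.608904  10.890408  0.034023
44    STG        SC6  amyloid_sqrt    -0.225659   0.000000  0.044515
```

— the planted association (true log-odds slope 0.6 of SC2 on sqrt-amyloid)
is recovered in all three regions with low heterogeneity and small
BH-adjusted HKSJ p. The remaining rows are *real* consequences of the
generated data, not false positives: proportions within a class sum to 1,
so enriching SC2 in high-amyloid donors necessarily depletes the abundant
subclusters (SC0, SC6 — negative slopes), and amyloid load correlates with
cognitive decline through the cohort's latent severity, carrying the SC2
signal onto `cog_decline` as well.

The same stages are exposed as a CLI:

```bash
popcellmeta simulate --seed 1 --out sim/
popcellmeta assoc --composition sim/composition --cohort sim/cohort.tsv --out fits.tsv
popcellmeta meta --in fits.tsv --alpha 0.05 --i2-max 50 --out meta.tsv
popcellmeta run --seed 1 --out run/          # full pipeline with manifest
```

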