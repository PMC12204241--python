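# Methods

This note documents the statistical models implemented in popcellmeta, the
choices made where the design was genuinely open, and what the synthetic
benchmarks do and do not demonstrate.

## Compositional association model

Within one broad cell class, the per-sample proportion of subcluster *s* is
`y = count_s / total`, with `total` the class's nucleus count for that
(donor, region) sample. Proportions live in [0, 1], are zero-enriched and
left-skewed, and are overdispersed relative to a binomial because nuclei
within a sample are not independent draws. The model is a binomial-family
GLM with logit link fit by IRLS:

- **Prior weights.** Samples carry their class totals as binomial
  denominators by default (`weighted=True`): a sample contributing 8,000
  nuclei estimates its proportion better than one contributing 600.
  `weighted=False` gives a pure proportion regression. Under
  Dirichlet-multinomial noise the variance is *not* proportional to
  1/total — sample-level overdispersion dominates at realistic totals — so
  either weighting is variance-misspecified; inference therefore never
  relies on the model-based covariance.
- **Dispersion.** φ = Pearson X²/(n − p), reported per fit. On simulated
  binomial data the median φ̂ is within [0.9, 1.1] of 1.
- **Robust covariance.** Sandwich estimator with score residuals
  u_i = w_i(y_i − μ_i) (the variance function cancels under the logit link),
  bread (XᵀWX)⁻¹. The *flavor* matters at stratified sample sizes: with a
  few dozen samples per (group, region) and 5–6 model terms, the
  uncorrected HC0 meat understates sampling variance enough to roughly
  double the nominal type-I error (measured ≈11% at α = 0.05 over 7,680
  null fits at n = 30 per group). The default is therefore the
  leverage-corrected HC3 form, u_i/(1 − h_ii), which measured 4.0% in the
  same experiment; HC0 and HC1 remain available via `hc=`. Tests are t on
  n − p df; 95% CIs use the robust SE.
- **Numerics.** IRLS max 100 iterations, relative deviance tolerance 1e-8,
  step-halving when the deviance increases. Exact 0/1 proportions are
  retained (the quasi-likelihood is defined there); no continuity
  correction. Rank-deficient designs raise; non-convergence is flagged in
  the result, not raised.
- **Eligibility.** A subcluster is fit only when the number of samples with
  complete trait + covariates is at least the number of model terms
  (intercept, trait, age, sex, pmi, and education for cognitive traits)
  plus one.
- **Trait coding.** Continuous traits enter as-is. Categorical AD
  phenotypes use binary contrasts, configurable in
  `popcellmeta.config.DEFAULT_CONTRASTS`: CERAD 1–2 (definite/probable
  pathology, per the 1=Definite…4=No-AD coding) vs 3–4; Braak ≥3 vs 0–2;
  diagnosis MCI-or-AD vs NCI. Sex is a single M=1 indicator.

Calibration can always be re-measured on real data with
`permutation_calibration`, which shuffles (proportion, denominator) pairs
across samples within a group and reports rejection rates at α ∈
{0.01, 0.05, 0.10}.

## Conservation meta-analysis

Per-group slopes β̂ᵢ with robust SEs are pooled under the random-effects
model β̂ᵢ ~ N(β, seᵢ² + τ²):

- τ² by REML Fisher scoring on the profiled restricted likelihood
  (score −½[tr(P) − yᵀPPy], information ½tr(PP)), floored at 0, max 50
  iterations. The restart cascade doubles the iteration cap and halves the
  scoring step twice, then falls back to ML, then to a fixed-effect model
  with a plain t-test; the first success is recorded in `method_used`.
- HKSJ inference: se² = q/Σwᵢ with q = Σwᵢ(β̂ᵢ − β̂)²/(k − 1), t on k − 1
  df. q is **untruncated** by default (the adjustment's standard form; CIs
  can be narrower than the normal-approximation ones when the estimates are
  very homogeneous); `truncate_hksj=True` applies max(q, 1).
- Heterogeneity: Cochran's Q against the fixed-effect mean;
  I² = max(0, (Q − (k−1))/Q)·100, defined 0 at Q = 0.
- Conservation: BH-adjusted p < α (family = every pooled result in the
  analysis, jointly across classes, regions and traits), identical slope
  signs in all groups (a zero slope breaks conservation), and I² strictly
  below 50%.
- Leave-one-out pooled estimates are reported for outlier inspection.

k = 3 groups is a very small meta-analysis: τ̂² is noisy, which is exactly
why the HKSJ t-test is used rather than a normal test, and why I² at the
50% cut-off has substantial sampling noise — under perfect homogeneity
P(I² ≥ 50) = P(χ²₂ > 4) ≈ 13.5%, an irreducible false-negative source for
the conservation flag that the benchmarks below reflect.

## Expression programs

The factor engine is pluggable: any nonnegative gene-weight (genes × K) and
cell-score (cells × K) pair wraps into a `FactorModel` via `from_matrices`,
which renormalizes gene-weight columns to sum to 1 (scale moved into the
cell scores) so the correlation and top-gene rules are reproducible across
engines and runs. The built-in engine is seeded Lee–Seung multiplicative-
update KL-NMF (generalized KL divergence = Poisson likelihood up to
constants; objective provably non-increasing; 500 iterations, relative
tolerance 1e-6).

- **Factor-number rule**: for each K in an ascending grid, the max pairwise
  Pearson correlation among gene-weight columns *and* among cell-score
  columns (within that K's model; 0 when K = 1); chosen K = the **largest**
  K whose max ≤ 0.75 — read literally as an argmax over the grid, not the
  last K before the first crossing (`first_crossing=True` gives that
  alternative). If no K qualifies the smallest grid K is returned with a
  warning flag. Correlations are compared within one model only — comparing
  factors across models of different K is not self-consistent.
- **Top genes**: per factor, the 5 largest-weight genes among genes with
  mean pseudobulk CPM strictly greater than 10; weight ties break
  lexicographically. Note the strict `>` here versus the inclusive `>=` of
  the marker filter — the two rules are deliberately not unified.
- **Associations**: per-(donor, region) sample medians of cell scores,
  then OLS on trait + the same covariates as the composition models,
  stratified by group; the output table feeds `meta_analyze_table`
  unchanged.

Fitting KL-NMF on counts whose generative factors include a duplicated gene
program does not reliably reproduce the duplication — the extra factor's
likelihood-optimal use is often to absorb Poisson noise — so guarantees
about the capping behavior of the selection rule are stated (and tested)
for models supplied through the engine interface, where the construction
forces the near-duplicate columns.

## Taxonomy rules

- QC keeps nuclei with UMIs strictly above 500 and mitochondrial percentage
  strictly below 5.
- Merge rule: pairwise log2 fold changes on CPM + pseudocount 1; a pair is
  separable iff ≥4 genes exceed |log2FC| = 2 in *each* direction (the only
  symmetric reading of "each direction" for an unordered pair). While any
  pair fails, the least-separable failing pair (fewest qualifying genes,
  lexicographic tie-break — this makes the procedure order-invariant and
  idempotent) is merged by summing raw counts and everything is recomputed.
- Clustering model-selection scores are the standard Calinski–Harabasz and
  Davies–Bouldin definitions (delegated to scikit-learn; verified against
  brute-force formula evaluation in the tests).
- Consensus transfer: the reference is randomly split into 5 folds, one
  classifier per fold (default: nearest centroid on log1p-CPM with Pearson
  similarity — deliberately simple; the protocol, not the classifier, is
  the point), and a query keeps its modal label only with ≥4 of 5 votes,
  else `"ambiguous"`. A fold that loses all examples of a label simply
  cannot vote for it.

## Locus accessibility

Peak counts pseudobulked per (donor, region, cell class) sample are (1) CPM
normalized within sample, (2) summed over peaks overlapping the risk locus
by ≥1 bp (half-open BED semantics; prose 1-based inclusive coordinates
convert as start−1) and divided by the summed **full** lengths of those
peaks — the intersection-length alternative is available via `clip=True` —
(3) averaged over samples within (region, class, group) with equal
per-sample weight, and (4) divided by the per-locus max, so each locus's
most accessible combination scores exactly 1. Loci with no overlapping
peaks score 0 everywhere and are flagged, as are ties at the maximum.

## Pooled demultiplexing

Libraries pool 3 samples from 3 distinct donors; the design constraint —
no donor *pair* in more than one library — makes each donor's library set
(fingerprint) unique and enables genotype-free identity assignment:
cluster pairs from different libraries with VAF concordance ≥0.9 over ≥100
shared SNPs (defaults far above the random-match expectation ≈0.4–0.6 at
realistic MAFs) are linked by union-find; each connected component's
library set must equal exactly one planned fingerprint. Partial detection
(component libraries a strict subset of a donor's set) leaves the component
unassigned rather than guessed; a lone cluster whose fingerprint several
donors share is unassigned; a multi-cluster component matching several
donors (e.g. genetically identical donors) is a hard ambiguity error.

## Donor subgroups

Feature vectors concatenate within-class renormalized subcluster
proportions (raw) and per-donor median factor scores (z-scaled per feature
by default, so high-variance factors do not dominate the correlation).
Distance is 1 − Pearson r; linkage is Ward applied to these dissimilarities
directly through the Lance–Williams recurrence — common practice, but an
approximation, since Ward's variance interpretation assumes Euclidean
distances. Each cut k in range scores the median silhouette on the same
distance matrix; the chosen k maximizes it, ties to the smallest k.
Subgroup composition is summarized by contingency fractions and one-sided
hypergeometric enrichment (P(X ≥ x)) with BH adjustment across all
(subgroup, level) pairs.

## Synthetic data: what it does and does not emulate

The generators reproduce the *statistical* structure the stages assume, not
transcriptome biology — no marker genes, ambient RNA, batch effects, or
doublets.

- **Cohort**: three groups of donors; a latent severity variable drives
  Braak (discretized), CERAD (inverted scale), diagnosis (thresholded),
  quantitative pathologies and cognitive slope, so phenotypes are mutually
  correlated. Ages are normal around 81 (SD 6); the AA-NL group's mean age
  is offset −4 years by default, mimicking the demographic imbalance such
  cohorts show (configurable to 0). Each region is profiled independently
  with probability `region_coverage`, conditioned on at least one region.
- **Composition**: Dirichlet-multinomial (concentration default 50; the
  qualitative description of zero-enrichment and left-skew does not pin a
  noise family, and Dirichlet-multinomial is the standard choice). Planted
  effects shift one subcluster's log-weight by β·phenotype, which makes the
  logit of its expected proportion *exactly* linear in the phenotype with
  slope β — the estimand of the composition model, so recovery tests are
  calibrated against a true value. Per-sample totals are log-normal with
  median 5,000 (the per-sample nucleus count distribution is not published;
  this is a stand-in of realistic magnitude).
- **Factor counts**: gamma cell scores and gene weights, Poisson counts at
  rate θβᵀ — the generative skeleton of hierarchical Poisson factorization.
- **Pooled genotypes**: Hardy–Weinberg diploid VAFs at MAF ~ U(0.05, 0.5);
  noise is a per-SNP deterministic 3-cycle "flip" applied with probability
  e, chosen as the simplest model with a closed-form same-donor concordance
  (1−e)² + e² for validating the matcher.
- **Donor features**: each planted subgroup has a structurally distinct
  Dirichlet baseline (its own subcluster block boosted 3×) and factor-mean
  block (+2 shift), so "distinct subgroups" holds by construction for
  every seed.

Passing benchmarks on these generators shows the *procedures* behave as
specified under their own assumptions (calibration, recovery, boundary
exactness, determinism); it does not validate them against the failure
modes of real tissue data.

## Benchmark problem sizes

The test suite and `scripts/acceptance.py` use: 1,000+ null fits at 30
donors/group for calibration; 100–200 replicates at 40 donors/group for
recovery, coverage and the conservation filter; 50 seeds for
demultiplexing (9 donors, 6 libraries, 500 SNPs, 1% flip noise) and donor
subgrouping (3 × 20 donors); 20 seeds for the factor-capping rule. These
sizes give Monte-Carlo error comfortably inside each acceptance band while
keeping a full run to a few minutes on one CPU.

## Known limitations

- k = 3 strata is the smallest possible meta-analysis; τ̂² and I² are noisy
  and the conservation flag inherits that noise (see above).
- Ward on correlation distances is an approximation (metric mismatch).
- The KL-NMF engine is a stand-in with the right likelihood geometry, not a
  reimplementation of hierarchical Poisson factorization; published factor
  matrices can be supplied directly.
- The demultiplexing matcher consumes cluster-level VAF signatures; raw
  read pileups, doublet handling and the probabilistic genotype model live
  upstream.
- BH family definition (joint across classes/regions/traits) is the
  default; per-class families are a configuration choice.
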