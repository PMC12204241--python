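"""Synthetic cohorts, compositions, factor counts and pooled genotypes.

Every generator is deterministic given its seed and emits known ground truth
(planted effects, true factor matrices, true donor identities) so downstream
stages can be tested by parameter recovery rather than against fixtures.

The generators emulate the *statistical* structure the pipeline assumes — a
three-group cohort with correlated AD phenotypes, Dirichlet-multinomial
compositional counts with log-odds effect plants, Poisson factor-structured
count matrices, and pooled-library genotype mixtures — not realistic
transcriptome biology.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._rng import check_seed
from .datatypes import (
    GROUPS,
    REGIONS,
    CompositionTable,
    DonorRecord,
    GenotypeSignature,
    PhenotypeSet,
    PlantedEffect,
    PoolPlan,
    cohort_frame,
)

#: Default mean-age offsets per group, mimicking a demographic imbalance in
#: which the AA-NL group died on average ~4 years younger. Set to zeros for a
#: perfectly balanced cohort.
DEFAULT_AGE_OFFSETS = {"AA-NL": -4.0, "L": 0.0, "W-NL": 0.0}

#: Default Dirichlet-multinomial concentration (overdispersion) for
#: composition draws; moderate donor-to-donor variability in proportions.
DEFAULT_CONCENTRATION = 50.0

#: Median nuclei per (donor, region) sample; drawn log-normal around this.
DEFAULT_TOTAL_NUCLEI = 5000.0


@dataclass
class Cohort:
    """A generated cohort: donor records plus the regions profiled per donor."""

    donors: list[DonorRecord]
    regions: dict[str, tuple[str, ...]]

    def __len__(self) -> int:
        return len(self.donors)

    def __iter__(self):
        return iter(self.donors)

    def frame(self) -> pd.DataFrame:
        return cohort_frame(self.donors)

    def samples(self) -> list[tuple[str, str]]:
        """All (donor_id, region) samples, in donor then region order."""
        return [(d.donor_id, r) for d in self.donors for r in self.regions[d.donor_id]]


def transform_phenotypes(
    *,
    amyloid_raw: float,
    tangles_raw: float,
    neuritic_counts: np.ndarray,
    diffuse_counts: np.ndarray,
    neuritic_sds: np.ndarray,
    diffuse_sds: np.ndarray,
    slope: float,
    cerad: int,
    braak: int,
    clinical_dx: str,
) -> PhenotypeSet:
    """Apply the study's phenotype transforms to raw pathology measures.

    Amyloid load and tangle density enter analyses as square roots; regional
    plaque counts are each scaled by the corresponding per-region standard
    deviation, then averaged; the person-specific slope of cognitive decline
    is negated so that higher values mean steeper decline.
    """
    if amyloid_raw < 0 or tangles_raw < 0:
        raise ValueError("raw amyloid and tangle measures must be nonnegative")
    neuritic_counts = np.asarray(neuritic_counts, dtype=float)
    diffuse_counts = np.asarray(diffuse_counts, dtype=float)
    neuritic_sds = np.asarray(neuritic_sds, dtype=float)
    diffuse_sds = np.asarray(diffuse_sds, dtype=float)
    if (neuritic_sds <= 0).any() or (diffuse_sds <= 0).any():
        raise ValueError("per-region standard deviations must be positive")
    return PhenotypeSet(
        cerad=int(cerad),
        braak=int(braak),
        neuritic_plaques=float(np.mean(neuritic_counts / neuritic_sds)),
        diffuse_plaques=float(np.mean(diffuse_counts / diffuse_sds)),
        amyloid_sqrt=math.sqrt(amyloid_raw),
        tangles_sqrt=math.sqrt(tangles_raw),
        clinical_dx=clinical_dx,
        cog_decline=-float(slope),
    )


def _draw_dx(z: float) -> str:
    if z < 0.0:
        return "NCI"
    if z < 0.8:
        return "MCI"
    return "AD"


def generate_cohort(
    n_per_group: int,
    region_coverage: float = 1.0,
    seed: int = 0,
    age_offsets: dict[str, float] | None = None,
) -> Cohort:
    """Generate a three-group cohort with internally correlated AD phenotypes.

    A latent severity variable per donor drives Braak stage, CERAD score,
    clinical diagnosis, and the quantitative pathology measures, so phenotypes
    are mutually correlated as in real aging cohorts. Each of the three brain
    regions is profiled independently with probability ``region_coverage``;
    donors are guaranteed at least one region.
    """
    if n_per_group < 2:
        raise ValueError("n_per_group must be at least 2")
    if not 0 < region_coverage <= 1:
        raise ValueError("region_coverage must lie in (0, 1]")
    seed = check_seed(seed)
    if age_offsets is None:
        age_offsets = DEFAULT_AGE_OFFSETS
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(1,)))

    n_total = 3 * n_per_group
    n_path_regions = 5  # plaque counts are scored in 5 anatomical regions

    # Latent severity drives every phenotype.
    severity = rng.normal(0.0, 1.0, n_total)
    # Raw regional plaque counts, Poisson around a severity-dependent rate.
    lam_neu = np.exp(0.6 + 0.7 * severity)[:, None] * np.ones(n_path_regions)
    lam_dif = np.exp(0.9 + 0.6 * severity)[:, None] * np.ones(n_path_regions)
    neuritic = rng.poisson(lam_neu).astype(float)
    diffuse = rng.poisson(lam_dif).astype(float)
    neu_sds = np.maximum(neuritic.std(axis=0, ddof=1), 1e-8)
    dif_sds = np.maximum(diffuse.std(axis=0, ddof=1), 1e-8)

    amyloid_raw = np.maximum(0.0, 1.5 + 0.9 * severity + rng.normal(0, 0.45, n_total)) ** 2
    tangles_raw = np.maximum(0.0, 1.4 + 0.8 * severity + rng.normal(0, 0.5, n_total)) ** 2
    slope = -(0.4 * severity + rng.normal(0, 0.6, n_total)) * 0.1  # raw slopes: negative = decline
    braak = np.clip(np.round(3.0 + 1.4 * severity + rng.normal(0, 0.8, n_total)), 0, 6)
    cerad = np.clip(np.round(2.5 - 1.1 * severity + rng.normal(0, 0.6, n_total)), 1, 4)
    dx_latent = severity + rng.normal(0, 0.5, n_total)

    donors: list[DonorRecord] = []
    regions: dict[str, tuple[str, ...]] = {}
    i = 0
    for group in GROUPS:
        offset = age_offsets.get(group, 0.0)
        for _ in range(n_per_group):
            donor_id = f"D{i:04d}"
            pheno = transform_phenotypes(
                amyloid_raw=float(amyloid_raw[i]),
                tangles_raw=float(tangles_raw[i]),
                neuritic_counts=neuritic[i],
                diffuse_counts=diffuse[i],
                neuritic_sds=neu_sds,
                diffuse_sds=dif_sds,
                slope=float(slope[i]),
                cerad=int(cerad[i]),
                braak=int(braak[i]),
                clinical_dx=_draw_dx(float(dx_latent[i])),
            )
            donors.append(
                DonorRecord(
                    donor_id=donor_id,
                    group=group,
                    age_at_death=float(np.clip(rng.normal(81.0 + offset, 6.0), 60, 110)),
                    sex="F" if rng.random() < 0.6 else "M",
                    pmi=float(np.clip(rng.gamma(3.0, 2.3), 0, 72)),
                    education=float(max(0.0, rng.normal(16.0, 3.0))),
                    phenotypes=pheno,
                )
            )
            while True:
                mask = rng.random(3) < region_coverage
                if mask.any():
                    break
            regions[donor_id] = tuple(r for r, m in zip(REGIONS, mask) if m)
            i += 1
    return Cohort(donors=donors, regions=regions)


def _baseline_logweights(subclusters: list[str]) -> np.ndarray:
    # Decreasing baseline abundances: a few common subclusters, a long tail.
    return np.linspace(1.5, -1.5, len(subclusters))


def generate_composition(
    cohort: Cohort,
    subclusters: list[str],
    effects: list[PlantedEffect] | None = None,
    total_nuclei: float = DEFAULT_TOTAL_NUCLEI,
    concentration: float = DEFAULT_CONCENTRATION,
    seed: int = 0,
    broad_class: str = "synthetic",
) -> CompositionTable:
    """Draw Dirichlet-multinomial subcluster counts per (donor, region) sample.

    Planted effects shift the log-weight of their subcluster by
    ``beta[group] * phenotype_value``; because the other subclusters'
    weights do not depend on the phenotype, the log-odds of the target
    subcluster's proportion is exactly linear in the phenotype with slope
    ``beta``, which is the estimand of the downstream quasibinomial fit.

    ``concentration=numpy.inf`` draws plain multinomial counts (no
    donor-level overdispersion).
    """
    effects = effects or []
    if concentration <= 0:
        raise ValueError("concentration must be positive")
    seed = check_seed(seed)
    unknown = {e.subcluster for e in effects} - set(subclusters)
    if unknown:
        raise ValueError(f"effects reference unknown subclusters: {sorted(unknown)}")
    frame = cohort.frame()
    for e in effects:
        if e.phenotype not in frame.columns:
            raise ValueError(f"unknown phenotype {e.phenotype!r}")
        if not np.issubdtype(frame[e.phenotype].dtype, np.number):
            raise ValueError(f"planted effects require a numeric phenotype, got {e.phenotype!r}")

    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(2,)))
    base = _baseline_logweights(subclusters)
    idx_of = {s: j for j, s in enumerate(subclusters)}

    rows = []
    index = []
    sigma = 0.4  # log-normal spread of per-sample totals
    for donor in cohort:
        for region in cohort.regions[donor.donor_id]:
            logw = base.copy()
            for e in effects:
                x = float(frame.loc[donor.donor_id, e.phenotype])
                logw[idx_of[e.subcluster]] += e.beta_per_group[donor.group] * x
            p = np.exp(logw - logw.max())
            p /= p.sum()
            n = max(50, int(round(total_nuclei * math.exp(rng.normal(0.0, sigma)))))
            if np.isinf(concentration):
                q = p
            else:
                q = rng.dirichlet(concentration * p)
            counts = rng.multinomial(n, q)
            rows.append(counts)
            index.append((donor.donor_id, region))
    counts = pd.DataFrame(
        np.asarray(rows),
        index=pd.MultiIndex.from_tuples(index, names=["donor_id", "region"]),
        columns=subclusters,
    )
    return CompositionTable(counts=counts, broad_class=broad_class)


def generate_factor_counts(
    n_cells: int,
    n_genes: int,
    k_true: int,
    seed: int = 0,
    mean_count: float = 1.0,
    duplicate_last: bool = False,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Poisson counts with a planted low-rank rate: counts ~ Poisson(theta @ beta.T).

    Cell scores ``theta`` (cells x K) and gene weights ``beta`` (genes x K) are
    gamma-distributed, as in hierarchical Poisson factorization's generative
    model. ``duplicate_last=True`` copies the gene program of factor K-1 into
    factor K (two factors with identical gene weights but independent cell
    scores), a construction that forces near-duplicate fitted factors.

    Returns ``(counts, theta, beta)``.
    """
    if k_true < 1:
        raise ValueError("k_true must be at least 1")
    if duplicate_last and k_true < 2:
        raise ValueError("duplicate_last requires k_true >= 2")
    seed = check_seed(seed)
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(3,)))
    theta = rng.gamma(2.0, 1.0, size=(n_cells, k_true))
    beta = rng.gamma(0.5, 1.0, size=(n_genes, k_true))
    if duplicate_last:
        beta[:, -1] = beta[:, -2]
    rate = theta @ beta.T
    scale = mean_count / rate.mean()
    theta *= scale  # fold the depth scaling into the cell scores
    rate *= scale
    counts = rng.poisson(rate).astype(np.int64)
    # factorizers require no all-zero cells; give empty cells one count at
    # their highest-rate gene
    empty = counts.sum(axis=1) == 0
    if empty.any():
        counts[np.nonzero(empty)[0], rate[empty].argmax(axis=1)] = 1
    return counts, theta, beta


def _flip_vaf(vaf: np.ndarray) -> np.ndarray:
    # deterministic 3-cycle on {0, 0.5, 1}; two independently flipped copies of
    # the same genotype therefore still agree
    return (vaf + 0.5) % 1.5


@dataclass
class PooledGenotypes:
    """Output of :func:`generate_pooled_genotypes`."""

    signatures: list[GenotypeSignature]
    truth: dict[tuple[str, int], str]
    genotypes: pd.DataFrame  # donors x SNPs latent diploid VAFs
    design_valid: bool
    design_violations: list[tuple[str, str]] = field(default_factory=list)


def generate_pooled_genotypes(
    n_donors: int,
    n_snps: int,
    plan: PoolPlan,
    error_rate: float = 0.0,
    seed: int = 0,
) -> PooledGenotypes:
    """Simulate anonymous per-library genotype clusters for a pooling design.

    Each donor gets one latent diploid genotype per SNP (Hardy-Weinberg at
    MAFs ~ Uniform(0.05, 0.5), VAF in {0, 0.5, 1}). Each library yields three
    anonymous signatures in shuffled order; each SNP call is independently
    replaced by a deterministic 3-cycle "flip" of the true VAF with
    probability ``error_rate``, so two noisy copies of the same genotype agree
    per SNP with probability (1-e)^2 + e^2.

    A plan violating the no-repeated-pair design is still generated (so the
    validator can be exercised) but flagged in the returned metadata.
    """
    if not 0 <= error_rate < 0.5:
        raise ValueError("error_rate must lie in [0, 0.5)")
    seed = check_seed(seed)
    from .demux import validate_design  # local import to avoid a cycle

    donor_ids = sorted({d for samples in plan.members.values() for d, _ in samples})
    if len(donor_ids) > n_donors:
        raise ValueError(
            f"plan references {len(donor_ids)} donors but n_donors={n_donors}"
        )
    report = validate_design(plan)

    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(4,)))
    maf = rng.uniform(0.05, 0.5, n_snps)
    geno = rng.binomial(2, maf, size=(len(donor_ids), n_snps)) / 2.0
    genotypes = pd.DataFrame(geno, index=donor_ids)

    signatures: list[GenotypeSignature] = []
    truth: dict[tuple[str, int], str] = {}
    for lib in plan.libraries:
        donors = [d for d, _ in plan.members[lib]]
        order = rng.permutation(len(donors))
        for cluster_index, j in enumerate(order):
            vaf = genotypes.loc[donors[j]].to_numpy().copy()
            flip = rng.random(n_snps) < error_rate
            vaf[flip] = _flip_vaf(vaf[flip])
            signatures.append(
                GenotypeSignature(library=lib, cluster_index=cluster_index, vaf=vaf)
            )
            truth[(lib, cluster_index)] = donors[j]
    return PooledGenotypes(
        signatures=signatures,
        truth=truth,
        genotypes=genotypes,
        design_valid=report.valid,
        design_violations=report.violations,
    )


def grid_pool_plan(regions: tuple[str, ...] = ("DLPFC", "STG")) -> PoolPlan:
    """A 9-donor, 6-library no-repeated-pair design (rows and columns of a 3x3 grid).

    Each donor appears in exactly two libraries (one row, one column), no
    donor pair shares two libraries, and every donor's library fingerprint is
    unique.
    """
    donors = [f"D{i:04d}" for i in range(9)]
    members: dict[str, list[tuple[str, str]]] = {}
    for r in range(3):
        members[f"LIB_R{r}"] = [(donors[3 * r + c], regions[0]) for c in range(3)]
    for c in range(3):
        members[f"LIB_C{c}"] = [(donors[3 * r + c], regions[min(1, len(regions) - 1)]) for r in range(3)]
    return PoolPlan(members=members)


def generate_donor_features(
    n_per_subgroup: int,
    n_subgroups: int = 3,
    n_subclusters: int = 12,
    n_factors: int = 6,
    concentration: float = 60.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Donor feature vectors with planted molecular subgroups.

    Each planted subgroup has its own Dirichlet baseline of subcluster
    proportions and its own mean vector of factor scores; donors draw
    proportions Dirichlet(concentration * baseline) and factor scores
    N(mean, 0.5). Baselines are guaranteed distinct: every subgroup has its
    own block of subclusters with boosted baseline weight, and its factor
    means are shifted along its own factor block, so no two planted
    subgroups coincide regardless of seed. Returns (features, true_labels).
    """
    seed = check_seed(seed)
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(5,)))
    baselines = rng.dirichlet(np.full(n_subclusters, 2.0), size=n_subgroups)
    block = max(1, n_subclusters // n_subgroups)
    for g in range(n_subgroups):
        baselines[g, g * block:(g + 1) * block] *= 3.0
    baselines /= baselines.sum(axis=1, keepdims=True)
    factor_means = rng.normal(0.0, 1.0, size=(n_subgroups, n_factors))
    fblock = max(1, n_factors // n_subgroups)
    for g in range(n_subgroups):
        factor_means[g, g * fblock:(g + 1) * fblock] += 2.0
    rows, labels = [], []
    for g in range(n_subgroups):
        for _ in range(n_per_subgroup):
            props = rng.dirichlet(concentration * baselines[g])
            scores = rng.normal(factor_means[g], 0.5)
            rows.append(np.concatenate([props, scores]))
            labels.append(g)
    cols = [f"prop_{j}" for j in range(n_subclusters)] + [
        f"factor_{j}" for j in range(n_factors)
    ]
    ids = [f"D{i:04d}" for i in range(len(rows))]
    return pd.DataFrame(rows, index=ids, columns=cols), np.asarray(labels)
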