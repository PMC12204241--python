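"""Continuous expression programs: factorization and the program rules.

The study's continuous programs come from a hierarchical Poisson
factorization of nuclei counts; this module implements the *rules* applied on
top of any such factorization — the correlation-based factor-number
selection, the top-gene reporting filter, per-sample median factor scores and
their linear-model phenotype associations — over a pluggable engine. The
default engine is a seeded multiplicative-update KL-NMF, whose generalized
Kullback-Leibler objective matches the Poisson likelihood up to constants;
pre-trained factorizations can be slotted in as plain matrices.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import numpy as np
import pandas as pd
from scipy import stats

from ._rng import check_seed
from .composition import COGNITIVE_COVARIATES, PATHOLOGICAL_COVARIATES
from .config import encode_trait
from .datatypes import COGNITIVE_TRAITS

NMF_MAX_ITER = 500
NMF_TOL = 1e-6


@dataclass
class FactorModel:
    """Nonnegative factorization: counts ~ cell_scores @ gene_weights.T.

    Gene-weight columns are normalized to sum to 1 (scale moved into the cell
    scores), which makes the correlation and top-gene rules reproducible
    across runs and engines.
    """

    gene_weights: np.ndarray
    cell_scores: np.ndarray
    K: int
    engine: str = "klnmf"
    objective: list[float] = field(default_factory=list, repr=False)

    def __post_init__(self) -> None:
        if self.gene_weights.shape[1] != self.K or self.cell_scores.shape[1] != self.K:
            raise ValueError("both matrices must have exactly K columns")
        if (self.gene_weights < 0).any() or (self.cell_scores < 0).any():
            raise ValueError("factor matrices must be nonnegative")


def _kl_divergence(V: np.ndarray, WH: np.ndarray) -> float:
    # generalized KL: sum(V log(V/WH) - V + WH), 0 log 0 = 0
    mask = V > 0
    val = float(WH.sum() - V.sum())
    val += float(np.sum(V[mask] * np.log(V[mask] / WH[mask])))
    return val


def factorize(
    counts: np.ndarray,
    K: int,
    seed: int = 0,
    engine: str = "klnmf",
    max_iter: int = NMF_MAX_ITER,
    tol: float = NMF_TOL,
) -> FactorModel:
    """Fit a K-factor nonnegative model to a cells x genes count matrix.

    The KL-NMF engine uses Lee-Seung multiplicative updates, under which the
    generalized KL objective is non-increasing; iteration stops when the
    relative objective change drops below ``tol``.
    """
    if engine != "klnmf":
        raise ValueError(f"unknown engine {engine!r}; pass matrices to from_matrices instead")
    V = np.asarray(counts, dtype=float)
    if (V < 0).any():
        raise ValueError("counts must be nonnegative")
    n_cells, n_genes = V.shape
    if not 1 <= K <= min(n_cells, n_genes):
        raise ValueError(f"K must lie in [1, {min(n_cells, n_genes)}], got {K}")
    if (V.sum(axis=1) == 0).any():
        raise ValueError("counts must contain no all-zero cells")
    seed = check_seed(seed)
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(6,)))

    scale = np.sqrt(V.mean() / K)
    W = rng.uniform(0.5, 1.5, size=(n_cells, K)) * scale  # cell scores
    H = rng.uniform(0.5, 1.5, size=(K, n_genes)) * scale  # gene weights (K x genes)
    eps = 1e-12
    objective = []
    prev = np.inf
    for _ in range(max_iter):
        WH = W @ H + eps
        W *= ((V / WH) @ H.T) / (H.sum(axis=1) + eps)
        WH = W @ H + eps
        H *= (W.T @ (V / WH)) / (W.sum(axis=0)[:, None] + eps)
        obj = _kl_divergence(V, W @ H + eps)
        objective.append(obj)
        if prev - obj < tol * (abs(obj) + 1.0):
            break
        prev = obj
    return from_matrices(H.T, W, engine="klnmf", objective=objective)


def from_matrices(
    gene_weights: np.ndarray,
    cell_scores: np.ndarray,
    engine: str = "external",
    objective: list[float] | None = None,
) -> FactorModel:
    """Wrap an external factorization, normalizing gene-weight columns to sum 1."""
    gw = np.asarray(gene_weights, dtype=float).copy()
    cs = np.asarray(cell_scores, dtype=float).copy()
    colsum = gw.sum(axis=0)
    if (colsum <= 0).any():
        raise ValueError("every gene-weight column must have positive mass")
    gw /= colsum
    cs *= colsum
    return FactorModel(
        gene_weights=gw, cell_scores=cs, K=gw.shape[1], engine=engine,
        objective=objective or [],
    )


def _max_pairwise_corr(model: FactorModel) -> float:
    """Max Pearson correlation over factor pairs, among gene-weight columns
    and among cell-score columns; 0 when K = 1 (no pairs)."""
    if model.K == 1:
        return 0.0
    best = -np.inf
    for M in (model.gene_weights, model.cell_scores):
        with np.errstate(invalid="ignore"):
            C = np.corrcoef(M.T)
        np.fill_diagonal(C, -np.inf)
        C = np.nan_to_num(C, nan=-np.inf)
        best = max(best, float(C.max()))
    return max(best, 0.0) if np.isfinite(best) else 0.0


@dataclass
class FactorSelection:
    chosen_K: int
    max_corr_per_k: dict[int, float]
    models: dict[int, FactorModel]
    satisfied: bool  # False when no K in the grid met the rule


def select_num_factors(
    counts: np.ndarray | None,
    k_grid: list[int],
    corr_max: float = 0.75,
    seed: int = 0,
    first_crossing: bool = False,
    models: dict[int, FactorModel] | None = None,
    _corr_table: dict[int, float] | None = None,
) -> FactorSelection:
    """Choose the largest factor set without near-duplicate factors.

    For each K in the (ascending) grid the max pairwise Pearson correlation
    among gene-weight columns and among cell-score columns of that K's model
    is computed; the chosen K is the *largest* K whose max does not exceed
    ``corr_max`` (``first_crossing=True`` instead stops at the last K before
    the first violation). If no K qualifies, the smallest grid K is returned
    with ``satisfied=False``.

    Models come from the default KL-NMF engine fit on ``counts``, or — via
    ``models`` — from any external factorization (e.g. pre-trained
    hierarchical Poisson factorization runs wrapped with
    :func:`from_matrices`). ``_corr_table`` is a test hook injecting
    precomputed correlations directly.
    """
    if not k_grid:
        raise ValueError("k_grid must be nonempty")
    if list(k_grid) != sorted(k_grid):
        raise ValueError("k_grid must be sorted ascending")
    models = dict(models) if models is not None else {}
    corrs: dict[int, float] = {}
    for K in k_grid:
        if _corr_table is not None:
            corrs[K] = _corr_table[K]
            continue
        if K not in models:
            if counts is None:
                raise ValueError(f"no model supplied for K={K} and no counts to fit")
            models[K] = factorize(counts, K, seed=seed)
        corrs[K] = _max_pairwise_corr(models[K])
    passing = [K for K in k_grid if corrs[K] <= corr_max]
    if first_crossing:
        passing_fc: list[int] = []
        for K in k_grid:
            if corrs[K] > corr_max:
                break
            passing_fc.append(K)
        passing = passing_fc
    if passing:
        return FactorSelection(max(passing), corrs, models, satisfied=True)
    return FactorSelection(min(k_grid), corrs, models, satisfied=False)


@dataclass
class TopGenes:
    per_factor: list[list[str]]
    truncated: bool  # True when fewer eligible genes than requested


def top_genes(
    model: FactorModel,
    gene_names: list[str],
    pseudobulk_cpm: np.ndarray,
    n_top: int = 5,
    cpm_min: float = 10.0,
) -> TopGenes:
    """Per factor, the n_top largest-weight genes with mean CPM strictly above cpm_min.

    Weight ties are broken lexicographically by gene name.
    """
    cpm = np.asarray(pseudobulk_cpm, dtype=float)
    if cpm.shape[0] != model.gene_weights.shape[0] or len(gene_names) != cpm.shape[0]:
        raise ValueError("gene_names and pseudobulk_cpm must align with the gene axis")
    eligible = np.nonzero(cpm > cpm_min)[0]
    truncated = eligible.size < n_top
    out = []
    for k in range(model.K):
        ranked = sorted(eligible, key=lambda j: (-model.gene_weights[j, k], gene_names[j]))
        out.append([gene_names[j] for j in ranked[:n_top]])
    return TopGenes(per_factor=out, truncated=truncated)


def median_scores_per_sample(
    model: FactorModel, sample_of_cell: np.ndarray | list
) -> pd.DataFrame:
    """Median cell score per (sample, factor); samples with no cells are absent."""
    samples = np.asarray(sample_of_cell)
    if samples.shape[0] != model.cell_scores.shape[0]:
        raise ValueError("every cell must map to a sample")
    df = pd.DataFrame(
        model.cell_scores, columns=[f"factor_{k}" for k in range(model.K)]
    )
    df["sample"] = samples
    return df.groupby("sample", sort=True).median()


def associate_factors(
    medians: pd.DataFrame,
    covariate_table: pd.DataFrame,
    traits: list[str],
    contrasts: dict | None = None,
) -> pd.DataFrame:
    """OLS of per-sample median factor scores on each trait plus covariates.

    ``medians`` is indexed by (donor_id, region) samples. Output columns match
    the composition fit table so results can feed the meta-analysis
    unchanged; models are fit per population group. Standard errors are the
    classical OLS ones (simple linear models), with t-tests on n - p df.
    """
    donors = medians.index.get_level_values("donor_id")
    rows = []
    for group, gmask in (
        (g, (covariate_table.loc[donors, "group"] == g).to_numpy())
        for g in covariate_table["group"].unique()
    ):
        sub = medians.loc[gmask]
        sub_donors = sub.index.get_level_values("donor_id")
        regions = sub.index.get_level_values("region")
        for region in sorted(set(regions)):
            rsub = sub.loc[(regions == region)]
            rdon = rsub.index.get_level_values("donor_id")
            for trait in traits:
                covs = (
                    COGNITIVE_COVARIATES if trait in COGNITIVE_TRAITS
                    else PATHOLOGICAL_COVARIATES
                )
                x = encode_trait(trait, covariate_table.loc[rdon, trait], contrasts)
                Xcols = [np.ones(len(rsub)), x]
                for c in covs:
                    v = covariate_table.loc[rdon, c]
                    Xcols.append(
                        (v == "M").astype(float).to_numpy() if c == "sex"
                        else v.to_numpy(dtype=float)
                    )
                X = np.column_stack(Xcols)
                keep = ~np.isnan(X).any(axis=1)
                X = X[keep]
                if X.shape[0] < X.shape[1] + 1 or np.linalg.matrix_rank(X) < X.shape[1]:
                    continue
                XtX_inv = np.linalg.inv(X.T @ X)
                for col in rsub.columns:
                    y = rsub[col].to_numpy()[keep]
                    beta = XtX_inv @ (X.T @ y)
                    resid = y - X @ beta
                    dfree = X.shape[0] - X.shape[1]
                    sigma2 = float(resid @ resid) / dfree
                    se = float(np.sqrt(sigma2 * XtX_inv[1, 1]))
                    if se == 0:
                        t, p = 0.0, 1.0
                    else:
                        t = float(beta[1] / se)
                        p = float(2 * stats.t.sf(abs(t), dfree))
                    rows.append(
                        {
                            "broad_class": "factors",
                            "group": group,
                            "region": region,
                            "subcluster": col,
                            "trait": trait,
                            "beta_hat": float(beta[1]),
                            "robust_se": se if se > 0 else np.nan,
                            "t_stat": t,
                            "p_value": p,
                            "n_samples": int(X.shape[0]),
                            "converged": True,
                        }
                    )
    return pd.DataFrame(rows)
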