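"""Donor molecular subgrouping.

Donors are clustered on the concatenation of their within-class normalized
subcluster proportions and per-donor median factor scores, using
1 - Pearson correlation as the distance and Ward linkage (applied to the
correlation dissimilarities directly via the Lance-Williams recurrence — a
common, if metrically approximate, practice). The tree is cut at every k in
range and the cut maximizing the median silhouette (computed on the same
distances) is chosen, with ties going to the smallest k. Subgroup
composition is summarized by contingency fractions and one-sided
hypergeometric enrichment with BH adjustment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.metrics import silhouette_samples

from .meta import benjamini_hochberg


def assemble_features(
    proportion_blocks: list[pd.DataFrame],
    factor_scores: pd.DataFrame | None = None,
    scale_factors: bool = True,
) -> pd.DataFrame:
    """Concatenate per-class proportion blocks and median factor scores per donor.

    Each proportion block is row-renormalized to sum to 1. Factor-score
    columns are z-scaled (``scale_factors=True``) so high-variance factors do
    not dominate the correlation distance; proportions stay raw. Donors
    missing any block are dropped.
    """
    blocks = []
    for block in proportion_blocks:
        totals = block.sum(axis=1)
        blocks.append(block.div(totals, axis=0))
    if factor_scores is not None:
        fs = factor_scores.copy()
        if scale_factors:
            sd = fs.std(ddof=0).replace(0.0, 1.0)
            fs = (fs - fs.mean()) / sd
        blocks.append(fs)
    out = pd.concat(blocks, axis=1, join="inner")
    return out.dropna()


def correlation_distance(features: pd.DataFrame) -> np.ndarray:
    """Pairwise 1 - Pearson r between donor feature vectors (square matrix)."""
    X = features.to_numpy(dtype=float)
    if (X.std(axis=1) == 0).any():
        bad = features.index[X.std(axis=1) == 0].tolist()
        raise ValueError(f"constant feature vectors (correlation undefined): {bad}")
    D = 1.0 - np.corrcoef(X)
    np.fill_diagonal(D, 0.0)
    return np.clip(0.5 * (D + D.T), 0.0, 2.0)


@dataclass
class DonorClustering:
    linkage_matrix: np.ndarray
    labels_per_k: dict[int, np.ndarray]
    median_silhouette: dict[int, float]
    chosen_k: int
    donors: list[str]

    @property
    def labels(self) -> pd.Series:
        return pd.Series(self.labels_per_k[self.chosen_k], index=self.donors, name="subgroup")


def cluster_donors(
    features: pd.DataFrame, k_range: range | list[int] = range(2, 9)
) -> DonorClustering:
    """Ward tree on correlation distances; cut chosen by max median silhouette."""
    if len(features) < 3:
        raise ValueError("need at least 3 donors to cluster")
    D = correlation_distance(features)
    Z = linkage(squareform(D, checks=False), method="ward")
    labels_per_k: dict[int, np.ndarray] = {}
    med_sil: dict[int, float] = {}
    for k in k_range:
        if not 2 <= k <= len(features) - 1:
            continue
        lab = fcluster(Z, t=k, criterion="maxclust")
        if np.unique(lab).size < 2:
            continue
        sil = silhouette_samples(D, lab, metric="precomputed")
        labels_per_k[k] = lab
        med_sil[k] = float(np.median(sil))
    if not med_sil:
        raise ValueError("no k in range produced a valid partition")
    best = max(med_sil.values())
    chosen = min(k for k, v in med_sil.items() if v == best)
    return DonorClustering(
        linkage_matrix=Z,
        labels_per_k=labels_per_k,
        median_silhouette=med_sil,
        chosen_k=chosen,
        donors=list(features.index),
    )


def summarize_groups(labels: pd.Series, annotations: pd.DataFrame) -> pd.DataFrame:
    """Per-subgroup composition fractions for each annotation column.

    Returns a long frame (subgroup, annotation, level, count, fraction);
    fractions sum to 1 within each (subgroup, annotation).
    """
    rows = []
    ann = annotations.loc[labels.index]
    for g, members in labels.groupby(labels):
        idx = members.index
        for col in annotations.columns:
            counts = ann.loc[idx, col].value_counts()
            total = int(counts.sum())
            for level, n in counts.items():
                rows.append(
                    {
                        "subgroup": g,
                        "annotation": col,
                        "level": level,
                        "count": int(n),
                        "fraction": float(n / total),
                    }
                )
    return pd.DataFrame(rows)


def enrichment_test(labels: pd.Series, annotations: pd.DataFrame) -> pd.DataFrame:
    """One-sided hypergeometric enrichment of each level in each subgroup.

    For a subgroup of size n drawn from a universe of N donors of which K
    carry the level, the p-value is P(X >= x) for X ~ Hypergeom(N, K, n);
    BH adjustment runs across all (subgroup, annotation level) pairs.
    """
    if labels.empty:
        raise ValueError("labels must be nonempty")
    ann = annotations.loc[labels.index]
    N = len(labels)
    rows = []
    for col in annotations.columns:
        universe_counts = ann[col].value_counts()
        for g, members in labels.groupby(labels):
            n = len(members)
            sub_counts = ann.loc[members.index, col].value_counts()
            for level, K in universe_counts.items():
                x = int(sub_counts.get(level, 0))
                p = float(stats.hypergeom.sf(x - 1, N, int(K), n))
                rows.append(
                    {
                        "subgroup": g,
                        "annotation": col,
                        "level": level,
                        "observed": x,
                        "group_size": n,
                        "universe_level": int(K),
                        "universe": N,
                        "p_value": p,
                    }
                )
    out = pd.DataFrame(rows)
    out["p_adj"] = benjamini_hochberg(out["p_value"].to_numpy())
    return out
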