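"""Discrete-taxonomy decision rules.

Nucleus-level QC thresholds, the pairwise subcluster merge rule on
pseudobulk profiles, clustering model-selection scores, the marker-gene
filter for enrichment input, and the 5-split consensus label-transfer
protocol with a pluggable per-fold classifier.
"""

from __future__ import annotations

from typing import Protocol

import numpy as np
import pandas as pd
from sklearn.metrics import calinski_harabasz_score, davies_bouldin_score

from ._rng import check_seed

QC_MIN_UMIS = 500
QC_MAX_MITO_PCT = 5.0


def qc_filter(
    nuclei: pd.DataFrame,
    min_umis: int = QC_MIN_UMIS,
    max_mito_pct: float = QC_MAX_MITO_PCT,
) -> pd.DataFrame:
    """Retain nuclei with strictly more than ``min_umis`` UMIs and
    mitochondrial percentage strictly below ``max_mito_pct``.

    Expects columns ``total_umis`` and ``mito_pct``.
    """
    keep = (nuclei["total_umis"] > min_umis) & (nuclei["mito_pct"] < max_mito_pct)
    return nuclei.loc[keep]


def cpm(counts: pd.DataFrame | np.ndarray) -> pd.DataFrame | np.ndarray:
    """Counts-per-million row normalization."""
    arr = counts.to_numpy(dtype=float) if isinstance(counts, pd.DataFrame) else np.asarray(counts, float)
    totals = arr.sum(axis=1, keepdims=True)
    if (totals <= 0).any():
        raise ValueError("every row must have a positive total")
    out = arr / totals * 1e6
    if isinstance(counts, pd.DataFrame):
        return pd.DataFrame(out, index=counts.index, columns=counts.columns)
    return out


def merge_subclusters(
    pseudobulk: pd.DataFrame,
    min_genes: int = 4,
    lfc_min: float = 2.0,
) -> dict[str, str]:
    """Iteratively merge subcluster pairs that are not transcriptomically separable.

    Pairwise log2 fold changes are computed on CPM with a pseudocount of 1. A
    pair is separable iff at least ``min_genes`` genes exceed ``lfc_min`` in
    each direction. While any pair fails, the least-separable failing pair
    (fewest qualifying genes; ties broken lexicographically by label pair) is
    merged by summing raw pseudobulk counts, and separability is recomputed.

    Returns a map from every input label to its final (merged) label; the
    merged label is the lexicographically smallest member label.
    """
    if len(pseudobulk) < 2:
        return {lab: lab for lab in pseudobulk.index}
    groups: dict[str, list[str]] = {lab: [lab] for lab in pseudobulk.index}
    profiles = {lab: pseudobulk.loc[lab].to_numpy(dtype=float) for lab in pseudobulk.index}

    def log_cpm_of(lab: str) -> np.ndarray:
        v = profiles[lab]
        return np.log2(v / v.sum() * 1e6 + 1.0)

    while len(groups) > 1:
        labels = sorted(groups)
        lcpm = {lab: log_cpm_of(lab) for lab in labels}
        failing = []
        for a_i in range(len(labels)):
            for b_i in range(a_i + 1, len(labels)):
                a, b = labels[a_i], labels[b_i]
                lfc = lcpm[a] - lcpm[b]
                n_up = int((lfc > lfc_min).sum())
                n_down = int((lfc < -lfc_min).sum())
                if n_up < min_genes or n_down < min_genes:
                    failing.append((n_up + n_down, a, b))
        if not failing:
            break
        _, a, b = min(failing)
        keep = min(a, b)
        drop = max(a, b)
        profiles[keep] = profiles[a] + profiles[b]
        groups[keep] = groups[a] + groups[b]
        del profiles[drop], groups[drop]
    out = {}
    for final, members in groups.items():
        for m in members:
            out[m] = final
    return out


def clustering_scores(points: np.ndarray, labels: np.ndarray) -> tuple[float, float]:
    """(Calinski-Harabasz, Davies-Bouldin) for a labeled embedding.

    CH is the between/within dispersion ratio scaled by (n-k)/(k-1); DB is
    the mean over clusters of the worst (sigma_i + sigma_j) / d_ij ratio.
    Both require at least two nonempty clusters.
    """
    labels = np.asarray(labels)
    uniq, counts = np.unique(labels, return_counts=True)
    if uniq.size < 2:
        raise ValueError("clustering scores require at least 2 clusters")
    if (counts == 0).any():
        raise ValueError("every cluster must be nonempty")
    return (
        float(calinski_harabasz_score(points, labels)),
        float(davies_bouldin_score(points, labels)),
    )


def marker_filter(
    de_table: pd.DataFrame,
    fdr_max: float = 0.05,
    cpm_min: float = 10.0,
    lfc_min: float = 1.0,
) -> list[str]:
    """Marker genes for enrichment input: FDR < 0.05, mean CPM >= 10, log2FC > 1.

    Note the CPM bound is inclusive here, unlike the strictly-greater CPM
    filter of the factor top-gene rule. Expects columns ``gene``, ``fdr``,
    ``mean_cpm``, ``log2fc``.
    """
    keep = (
        (de_table["fdr"] < fdr_max)
        & (de_table["mean_cpm"] >= cpm_min)
        & (de_table["log2fc"] > lfc_min)
    )
    return de_table.loc[keep, "gene"].tolist()


class FoldClassifier(Protocol):
    def __call__(self, ref_counts: np.ndarray, ref_labels: np.ndarray,
                 query_counts: np.ndarray) -> np.ndarray: ...


def centroid_classifier(
    ref_counts: np.ndarray, ref_labels: np.ndarray, query_counts: np.ndarray
) -> np.ndarray:
    """Nearest-centroid on log1p-CPM profiles with Pearson similarity."""
    ref = np.log1p(cpm(np.asarray(ref_counts, float)))
    qry = np.log1p(cpm(np.asarray(query_counts, float)))
    labels = np.asarray(ref_labels)
    uniq = np.unique(labels)
    centroids = np.vstack([ref[labels == u].mean(axis=0) for u in uniq])
    c = centroids - centroids.mean(axis=1, keepdims=True)
    q = qry - qry.mean(axis=1, keepdims=True)
    c /= np.maximum(np.linalg.norm(c, axis=1, keepdims=True), 1e-12)
    q /= np.maximum(np.linalg.norm(q, axis=1, keepdims=True), 1e-12)
    sim = q @ c.T
    return uniq[sim.argmax(axis=1)]


AMBIGUOUS = "ambiguous"


def consensus_transfer(
    ref_counts: np.ndarray,
    ref_labels: np.ndarray,
    query_counts: np.ndarray,
    n_splits: int = 5,
    min_agree: int = 4,
    seed: int = 0,
    classifier: FoldClassifier = centroid_classifier,
) -> np.ndarray:
    """Label query cells by >= min_agree-of-n_splits consensus voting.

    Reference cells are randomly partitioned into ``n_splits`` folds; one
    classifier is trained per fold and each query cell collects one vote per
    fold. A query keeps its modal label only if that label's vote count
    reaches ``min_agree``; otherwise it is called ``"ambiguous"``. A fold
    that loses all examples of some label simply cannot vote for it.
    """
    if min_agree > n_splits:
        raise ValueError("min_agree cannot exceed n_splits")
    seed = check_seed(seed)
    ref_counts = np.asarray(ref_counts)
    ref_labels = np.asarray(ref_labels)
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(7,)))
    order = rng.permutation(ref_counts.shape[0])
    folds = np.array_split(order, n_splits)
    votes = np.empty((n_splits, np.asarray(query_counts).shape[0]), dtype=object)
    for f, idx in enumerate(folds):
        votes[f] = classifier(ref_counts[idx], ref_labels[idx], query_counts)
    out = np.empty(votes.shape[1], dtype=object)
    for j in range(votes.shape[1]):
        labs, counts = np.unique(votes[:, j].astype(str), return_counts=True)
        best = counts.argmax()
        out[j] = labs[best] if counts[best] >= min_agree else AMBIGUOUS
    return out
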