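"""Taxonomy rules: QC, merging, clustering scores, markers, consensus transfer."""

import numpy as np
import pandas as pd
import pytest

from popcellmeta.taxonomy import (
    AMBIGUOUS,
    centroid_classifier,
    clustering_scores,
    consensus_transfer,
    marker_filter,
    merge_subclusters,
    qc_filter,
)


class TestQC:
    @pytest.mark.parametrize(
        "umis,mito,kept",
        [
            (500, 1.0, False),   # boundary: strictly more than 500 required
            (501, 5.0, False),   # boundary: strictly below 5% required
            (501, 4.99, True),
            (10000, 0.0, True),
        ],
    )
    def test_strict_thresholds(self, umis, mito, kept):
        df = pd.DataFrame({"total_umis": [umis], "mito_pct": [mito]})
        assert (len(qc_filter(df)) == 1) is kept


def _pseudobulk(profiles, genes=None):
    genes = genes or [f"g{i}" for i in range(len(next(iter(profiles.values()))))]
    return pd.DataFrame.from_dict(profiles, orient="index", columns=genes)


class TestMerge:
    def _separated_pair(self, n_up, n_down, n_genes=30, fold=6.0):
        """Two profiles differing by > 2^2-fold CPM in n_up/n_down genes."""
        base = np.full(n_genes, 100.0)
        a, b = base.copy(), base.copy()
        a[:n_up] *= 2.0**fold
        b[n_up:n_up + n_down] *= 2.0**fold
        return _pseudobulk({"A": a, "B": b})

    def test_boundary_four_up_four_down_not_merged(self):
        pb = self._separated_pair(4, 4)
        label_map = merge_subclusters(pb)
        assert label_map == {"A": "A", "B": "B"}

    def test_three_down_merges(self):
        pb = self._separated_pair(4, 3)
        label_map = merge_subclusters(pb)
        assert label_map == {"A": "A", "B": "A"}

    def test_identical_profiles_all_merge(self):
        v = np.full(20, 50.0)
        pb = _pseudobulk({"A": v, "B": v, "C": v})
        label_map = merge_subclusters(pb)
        assert set(label_map.values()) == {"A"}

    def test_idempotent(self):
        rng = np.random.default_rng(1)
        pb = _pseudobulk({
            f"S{i}": rng.gamma(1.0, 100, 40) for i in range(5)
        })
        first = merge_subclusters(pb)
        merged = pb.groupby(pd.Series(first)).sum()
        second = merge_subclusters(merged)
        assert all(k == v for k, v in second.items())

    def test_order_invariant(self):
        rng = np.random.default_rng(2)
        profiles = {f"S{i}": rng.gamma(1.0, 100, 40) for i in range(6)}
        pb = _pseudobulk(profiles)
        shuffled = pb.loc[["S3", "S0", "S5", "S1", "S4", "S2"]]
        m1 = merge_subclusters(pb)
        m2 = merge_subclusters(shuffled)
        assert m1 == m2


class TestClusteringScores:
    def test_hand_instance_matches_brute_force(self):
        pts = np.array([[0.0, 0], [0, 1], [1, 0], [10, 10], [10, 11], [11, 10]])
        lab = np.array([0, 0, 0, 1, 1, 1])
        ch, db = clustering_scores(pts, lab)
        # brute-force CH
        n, k = 6, 2
        overall = pts.mean(axis=0)
        B = sum(
            3 * np.sum((pts[lab == c].mean(axis=0) - overall) ** 2) for c in (0, 1)
        )
        W = sum(
            np.sum((pts[lab == c] - pts[lab == c].mean(axis=0)) ** 2) for c in (0, 1)
        )
        assert ch == pytest.approx((B / (k - 1)) / (W / (n - k)))
        # brute-force DB
        cents = [pts[lab == c].mean(axis=0) for c in (0, 1)]
        sig = [
            np.mean(np.linalg.norm(pts[lab == c] - cents[c], axis=1)) for c in (0, 1)
        ]
        d01 = np.linalg.norm(cents[0] - cents[1])
        assert db == pytest.approx((sig[0] + sig[1]) / d01)

    def test_ch_increases_with_separation(self):
        rng = np.random.default_rng(3)
        a = rng.normal(0, 1, (40, 2))
        lab = np.repeat([0, 1], 40)
        prev = 0.0
        for sep in (3.0, 6.0, 12.0):
            pts = np.vstack([a, a + sep])
            ch, db = clustering_scores(pts, lab)
            assert ch > prev
            prev = ch
        assert db < 0.5

    def test_true_labels_beat_random_labels(self):
        rng = np.random.default_rng(4)
        wins = 0
        for seed in range(20):
            r = np.random.default_rng(seed)
            pts = np.vstack([r.normal(0, 1, (30, 2)), r.normal(6, 1, (30, 2))])
            true = np.repeat([0, 1], 30)
            rand = r.permutation(true)
            wins += clustering_scores(pts, true)[0] > clustering_scores(pts, rand)[0]
        assert wins == 20

    def test_single_cluster_rejected(self):
        with pytest.raises(ValueError):
            clustering_scores(np.zeros((4, 2)), np.zeros(4))


class TestMarkerFilter:
    def test_boundary_rules(self):
        de = pd.DataFrame(
            {
                "gene": ["a", "b", "c", "d"],
                "fdr": [0.05, 0.01, 0.01, 0.01],
                "mean_cpm": [20.0, 10.0, 50.0, 15.0],
                "log2fc": [2.0, 1.5, 1.0, 1.5],
            }
        )
        kept = marker_filter(de)
        assert "a" not in kept   # FDR 0.05 excluded (strict <)
        assert "b" in kept       # CPM exactly 10 included (>=)
        assert "c" not in kept   # log2FC exactly 1 excluded (strict >)
        assert "d" in kept


class TestConsensusTransfer:
    def _three_class_data(self, rng, n_per=60, n_genes=30, sep=200.0):
        centers = np.full((3, n_genes), 50.0)
        for c in range(3):
            centers[c, c * 5:(c + 1) * 5] += sep
        counts = np.vstack(
            [rng.poisson(centers[c], (n_per, n_genes)) for c in range(3)]
        )
        labels = np.repeat(["A", "B", "C"], n_per)
        return counts, labels

    def test_vote_rule(self):
        calls = iter(
            [np.array(["A"]), np.array(["A"]), np.array(["A"]),
             np.array(["A"]), np.array(["B"])]
        )

        def scripted(ref, labels, query):
            return next(calls)

        out = consensus_transfer(
            np.ones((10, 3)), np.repeat(["A", "B"], 5), np.ones((1, 3)),
            classifier=scripted, seed=0,
        )
        assert out[0] == "A"

    def test_three_two_split_is_ambiguous(self):
        calls = iter(
            [np.array(["A"]), np.array(["A"]), np.array(["A"]),
             np.array(["B"]), np.array(["B"])]
        )
        out = consensus_transfer(
            np.ones((10, 3)), np.repeat(["A", "B"], 5), np.ones((1, 3)),
            classifier=lambda *a: next(calls), seed=0,
        )
        assert out[0] == AMBIGUOUS

    def test_well_separated_data_high_accuracy_low_ambiguity(self):
        rng = np.random.default_rng(5)
        ref, labels = self._three_class_data(rng)
        query, qlabels = self._three_class_data(rng)
        out = consensus_transfer(ref, labels, query, seed=1)
        assert np.mean(out == AMBIGUOUS) < 0.05
        called = out != AMBIGUOUS
        assert np.mean(out[called] == qlabels[called]) > 0.95

    def test_degenerates_to_plain_classifier(self):
        rng = np.random.default_rng(6)
        ref, labels = self._three_class_data(rng)
        query, _ = self._three_class_data(rng)
        single = consensus_transfer(ref, labels, query, n_splits=1, min_agree=1, seed=2)
        direct = centroid_classifier(ref, labels, query)
        assert np.array_equal(single.astype(str), direct.astype(str))
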