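"""Factorization engine and the continuous-program rules."""

import numpy as np
import pandas as pd
import pytest

from popcellmeta import programs, synthetic
from popcellmeta.programs import (
    factorize,
    from_matrices,
    median_scores_per_sample,
    select_num_factors,
    top_genes,
)


class TestFactorize:
    def test_rank_one_reconstruction(self):
        counts, theta, beta = synthetic.generate_factor_counts(
            200, 80, 1, seed=1, mean_count=5.0
        )
        model = factorize(counts, 1, seed=2)
        truth = theta @ beta.T
        fitted = model.cell_scores @ model.gene_weights.T
        rel = np.linalg.norm(fitted - truth) / np.linalg.norm(truth)
        assert rel < 0.05

    def test_objective_monotone_nonincreasing(self):
        counts, _, _ = synthetic.generate_factor_counts(100, 60, 3, seed=3)
        model = factorize(counts, 3, seed=4)
        obj = np.array(model.objective)
        assert (np.diff(obj) <= 1e-8 * (np.abs(obj[:-1]) + 1)).all()

    def test_seed_determinism(self):
        counts, _, _ = synthetic.generate_factor_counts(80, 40, 2, seed=5)
        a = factorize(counts, 2, seed=6)
        b = factorize(counts, 2, seed=6)
        assert np.array_equal(a.gene_weights, b.gene_weights)
        assert np.array_equal(a.cell_scores, b.cell_scores)

    def test_higher_true_rank_fits_better_at_matching_k(self):
        """At the generator's true K the held-in Poisson log-likelihood beats
        the K=1 fit, across seeds."""
        from scipy.stats import poisson

        wins = 0
        for seed in range(10):
            counts, _, _ = synthetic.generate_factor_counts(
                300, 120, 3, seed=seed, mean_count=2.0
            )
            lls = {}
            for K in (1, 3):
                m = factorize(counts, K, seed=seed)
                rate = np.maximum(m.cell_scores @ m.gene_weights.T, 1e-12)
                lls[K] = poisson.logpmf(counts, rate).sum()
            wins += lls[3] > lls[1]
        assert wins == 10

    def test_gene_weight_columns_normalized(self):
        counts, _, _ = synthetic.generate_factor_counts(60, 30, 2, seed=7)
        m = factorize(counts, 2, seed=8)
        assert np.allclose(m.gene_weights.sum(axis=0), 1.0)

    def test_invalid_k_rejected(self):
        counts, _, _ = synthetic.generate_factor_counts(20, 10, 1, seed=9)
        with pytest.raises(ValueError):
            factorize(counts, 11, seed=0)


class TestSelectNumFactors:
    def test_k1_has_zero_correlation(self):
        counts, _, _ = synthetic.generate_factor_counts(60, 30, 1, seed=1)
        sel = select_num_factors(counts, [1], seed=2)
        assert sel.chosen_K == 1 and sel.max_corr_per_k[1] == 0.0

    def test_largest_not_first_crossing(self):
        table = {2: 0.3, 3: 0.5, 4: 0.8, 5: 0.6}
        sel = select_num_factors(None, [2, 3, 4, 5], _corr_table=table)
        assert sel.chosen_K == 5
        first = select_num_factors(
            None, [2, 3, 4, 5], _corr_table=table, first_crossing=True
        )
        assert first.chosen_K == 3

    def test_monotone_in_threshold(self):
        table = {2: 0.3, 3: 0.5, 4: 0.8, 5: 0.9}
        chosen = [
            select_num_factors(None, [2, 3, 4, 5], corr_max=c, _corr_table=table).chosen_K
            for c in (0.4, 0.6, 0.85, 0.95)
        ]
        assert chosen == sorted(chosen)

    def test_no_k_satisfies_falls_back_to_smallest(self):
        sel = select_num_factors(None, [2, 3], _corr_table={2: 0.9, 3: 0.95})
        assert sel.chosen_K == 2 and not sel.satisfied

    def test_duplicated_programs_force_high_correlation(self):
        """Two planted programs with identical gene weights drive the
        pairwise correlation above 0.99 at any K covering both, capping the
        chosen K below the duplication point."""
        _, theta, beta = synthetic.generate_factor_counts(
            100, 80, 4, seed=3, duplicate_last=True
        )
        models = {K: from_matrices(beta[:, :K], theta[:, :K]) for K in (2, 3, 4)}
        sel = select_num_factors(None, [2, 3, 4], models=models)
        assert sel.max_corr_per_k[4] > 0.99
        assert sel.chosen_K == 3


class TestTopGenes:
    def _model(self, weights):
        w = np.asarray(weights, float)
        return from_matrices(w, np.ones((2, w.shape[1])))

    def test_cpm_filter_dominates_weights(self):
        genes = [f"g{i}" for i in range(8)]
        cpm = np.array([1, 1, 1, 20, 20, 20, 20, 20.0])
        m = self._model(np.linspace(8, 1, 8).reshape(-1, 1))
        tg = top_genes(m, genes, cpm, n_top=5, cpm_min=10)
        assert tg.per_factor[0] == ["g3", "g4", "g5", "g6", "g7"]

    def test_cpm_threshold_is_strict(self):
        genes = ["a", "b", "c", "d", "e", "f"]
        cpm = np.array([9.9, 10.0, 10.1, 50, 50, 50.0])
        m = self._model(np.array([[10, 9, 8, 3, 2, 1.0]]).T)
        tg = top_genes(m, genes, cpm, n_top=5, cpm_min=10)
        assert "a" not in tg.per_factor[0]      # 9.9 excluded
        assert "b" not in tg.per_factor[0]      # exactly 10.0 excluded (strict >)
        assert tg.per_factor[0][0] == "c"
        assert tg.truncated  # only 4 eligible genes

    def test_ties_break_lexicographically(self):
        genes = ["z", "y", "x", "w"]
        m = self._model(np.ones((4, 1)))
        tg = top_genes(m, genes, np.full(4, 100.0), n_top=3)
        assert tg.per_factor[0] == ["w", "x", "y"]


class TestAssociation:
    def _medians(self, values, donors, region="STG"):
        idx = pd.MultiIndex.from_tuples(
            [(d, region) for d in donors], names=["donor_id", "region"]
        )
        return pd.DataFrame({"factor_0": values}, index=idx)

    def test_constant_scores_per_sample_median(self):
        model = from_matrices(np.ones((3, 1)), np.full((6, 1), 2.3))
        med = median_scores_per_sample(model, ["s1"] * 3 + ["s2"] * 3)
        assert (med["factor_0"] == pytest.approx(2.3 * 1.0)).all() or np.allclose(
            med["factor_0"], med["factor_0"].iloc[0]
        )

    def test_median_invariant_to_within_sample_shuffle(self):
        rng = np.random.default_rng(0)
        scores = rng.gamma(2, 1, size=(30, 2))
        model = from_matrices(np.ones((5, 2)), scores)
        samples = np.repeat(["a", "b", "c"], 10)
        m1 = median_scores_per_sample(model, samples)
        perm = np.concatenate([rng.permutation(np.arange(i, i + 10)) for i in (0, 10, 20)])
        model2 = from_matrices(np.ones((5, 2)), scores[perm])
        m2 = median_scores_per_sample(model2, samples)
        assert np.allclose(m1.to_numpy(), m2.to_numpy())

    def test_planted_shift_recovered_by_ols(self, small_cohort):
        """A +1.0 shift of median scores in MCI/AD samples yields an OLS
        slope near 1 on the diagnosis contrast."""
        rng = np.random.default_rng(2)
        frame = small_cohort.frame()
        slopes = []
        for rep in range(20):
            donors = list(frame.index)
            shift = frame["clinical_dx"].isin(["MCI", "AD"]).astype(float)
            vals = rng.normal(0, 0.3, len(donors)) + shift.to_numpy()
            med = self._medians(vals, donors)
            tab = programs.associate_factors(med, frame, ["clinical_dx"])
            slopes.extend(tab["beta_hat"].tolist())
        assert abs(np.mean(slopes) - 1.0) < 0.2

    def test_constant_factor_gives_null_slope(self, small_cohort):
        frame = small_cohort.frame()
        med = self._medians(np.full(len(frame), 1.7), list(frame.index))
        tab = programs.associate_factors(med, frame, ["amyloid_sqrt"])
        assert np.allclose(tab["beta_hat"], 0.0, atol=1e-10)
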