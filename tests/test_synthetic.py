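"""Generators: determinism, planted structure, closed-form noise properties."""

import math

import numpy as np
import pytest

from popcellmeta import synthetic
from popcellmeta.datatypes import GROUPS, PlantedEffect
from popcellmeta.synthetic import (
    generate_cohort,
    generate_composition,
    generate_factor_counts,
    generate_pooled_genotypes,
    grid_pool_plan,
    transform_phenotypes,
)


class TestCohort:
    def test_full_coverage_gives_all_regions(self):
        cohort = generate_cohort(10, 1.0, seed=7)
        assert len(cohort) == 30
        assert all(len(r) == 3 for r in cohort.regions.values())

    def test_seed_determinism(self):
        a = generate_cohort(10, 1.0, seed=7)
        b = generate_cohort(10, 1.0, seed=7)
        assert a.donors == b.donors and a.regions == b.regions

    def test_partial_coverage_mean_regions(self):
        """Region count per donor is Binomial(3, c) conditioned on >= 1;
        the sample mean must sit within MC error of that conditional mean."""
        c = 0.66
        cohorts = [generate_cohort(10, c, seed=s) for s in range(40)]
        counts = np.array(
            [len(r) for co in cohorts for r in co.regions.values()]
        )
        assert set(np.unique(counts)) <= {1, 2, 3}
        expected = 3 * c / (1 - (1 - c) ** 3)
        var = (  # conditional variance by direct enumeration
            sum(
                k**2 * math.comb(3, k) * c**k * (1 - c) ** (3 - k)
                for k in (1, 2, 3)
            ) / (1 - (1 - c) ** 3) - expected**2
        )
        se = np.sqrt(var / counts.size)
        assert abs(counts.mean() - expected) < 4 * se

    def test_phenotypes_are_correlated(self):
        frame = generate_cohort(60, 1.0, seed=3).frame()
        assert frame["braak"].corr(frame["amyloid_sqrt"]) > 0.3
        assert frame["braak"].corr(frame["cerad"]) < -0.3

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            generate_cohort(1, 1.0, seed=0)
        with pytest.raises(ValueError):
            generate_cohort(5, 0.0, seed=0)


class TestTransforms:
    def test_sqrt_and_negated_slope(self):
        p = transform_phenotypes(
            amyloid_raw=4.0, tangles_raw=9.0,
            neuritic_counts=np.ones(5), diffuse_counts=np.ones(5),
            neuritic_sds=np.ones(5), diffuse_sds=np.ones(5),
            slope=-0.05, cerad=2, braak=4, clinical_dx="AD",
        )
        assert p.amyloid_sqrt == 2.0
        assert p.tangles_sqrt == 3.0
        assert p.cog_decline == pytest.approx(0.05)

    def test_counts_equal_to_sds_scale_to_one(self):
        sds = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        p = transform_phenotypes(
            amyloid_raw=0.0, tangles_raw=0.0,
            neuritic_counts=sds, diffuse_counts=2 * sds,
            neuritic_sds=sds, diffuse_sds=sds,
            slope=0.0, cerad=4, braak=0, clinical_dx="NCI",
        )
        assert p.neuritic_plaques == pytest.approx(1.0)
        assert p.diffuse_plaques == pytest.approx(2.0)

    def test_negative_pathology_rejected(self):
        with pytest.raises(ValueError):
            transform_phenotypes(
                amyloid_raw=-1.0, tangles_raw=0.0,
                neuritic_counts=np.ones(5), diffuse_counts=np.ones(5),
                neuritic_sds=np.ones(5), diffuse_sds=np.ones(5),
                slope=0.0, cerad=4, braak=0, clinical_dx="NCI",
            )


class TestComposition:
    def test_rows_sum_to_totals_and_proportions_valid(self, small_composition):
        counts = small_composition.counts
        assert (counts.values >= 0).all()
        props = counts.div(counts.sum(axis=1), axis=0)
        assert np.allclose(props.sum(axis=1), 1.0)

    def test_no_signal_converges_to_baseline(self, small_cohort):
        """With no effects and no overdispersion, empirical proportions match
        the baseline simplex."""
        subs = [f"SC{i}" for i in range(5)]
        table = generate_composition(
            small_cohort, subs, [], total_nuclei=20000,
            concentration=np.inf, seed=5,
        )
        logw = np.linspace(1.5, -1.5, 5)
        base = np.exp(logw) / np.exp(logw).sum()
        emp = (table.counts.div(table.counts.sum(axis=1), axis=0)).mean(axis=0)
        assert np.allclose(emp.to_numpy(), base, atol=0.01)

    def test_unknown_subcluster_in_effect_rejected(self, small_cohort):
        eff = [PlantedEffect("nope", "amyloid_sqrt", {g: 0.1 for g in GROUPS})]
        with pytest.raises(ValueError, match="unknown subclusters"):
            generate_composition(small_cohort, ["SC0", "SC1"], eff, seed=1)

    def test_seed_determinism(self, small_cohort):
        a = generate_composition(small_cohort, ["SC0", "SC1"], [], seed=9)
        b = generate_composition(small_cohort, ["SC0", "SC1"], [], seed=9)
        assert a.counts.equals(b.counts)


class TestFactorCounts:
    def test_rank_one_rates_proportional(self):
        _, theta, beta = generate_factor_counts(50, 30, 1, seed=2)
        rate = theta @ beta.T
        ratios = rate / rate[0]
        assert np.allclose(ratios, ratios[:, :1], rtol=1e-10)

    def test_seed_determinism_and_no_empty_cells(self):
        a, _, _ = generate_factor_counts(100, 50, 3, seed=4)
        b, _, _ = generate_factor_counts(100, 50, 3, seed=4)
        assert (a == b).all()
        assert (a.sum(axis=1) > 0).all()

    def test_duplicate_last_copies_gene_program(self):
        _, _, beta = generate_factor_counts(50, 40, 4, seed=6, duplicate_last=True)
        assert np.array_equal(beta[:, -1], beta[:, -2])


class TestPooledGenotypes:
    def test_noise_free_signatures_match_latent_genotypes(self):
        plan = grid_pool_plan()
        pg = generate_pooled_genotypes(9, 200, plan, error_rate=0.0, seed=1)
        for (lib, idx), donor in pg.truth.items():
            sig = next(
                s for s in pg.signatures
                if s.library == lib and s.cluster_index == idx
            )
            assert np.array_equal(sig.vaf, pg.genotypes.loc[donor].to_numpy())

    def test_same_donor_cross_library_concordance_formula(self):
        """Flip noise model: two noisy copies agree per SNP with probability
        (1-e)^2 + e^2; check the empirical rate against that closed form."""
        from popcellmeta.demux import concordance

        plan = grid_pool_plan()
        e = 0.02
        pg = generate_pooled_genotypes(9, 500, plan, error_rate=e, seed=3)
        by_donor: dict[str, list] = {}
        for (lib, idx), donor in pg.truth.items():
            sig = next(
                s for s in pg.signatures
                if s.library == lib and s.cluster_index == idx
            )
            by_donor.setdefault(donor, []).append(sig)
        rates = [concordance(a, b) for a, b in by_donor.values()]
        expected = (1 - e) ** 2 + e**2
        se = np.sqrt(expected * (1 - expected) / (500 * len(rates)))
        assert abs(np.mean(rates) - expected) < 4 * se

    def test_violating_plan_generable_but_flagged(self):
        from popcellmeta.datatypes import PoolPlan

        plan = PoolPlan(members={
            "L1": [("D0", "STG"), ("D1", "STG"), ("D2", "STG")],
            "L2": [("D0", "DLPFC"), ("D1", "DLPFC"), ("D3", "STG")],
        })
        pg = generate_pooled_genotypes(4, 50, plan, seed=0)
        assert not pg.design_valid
        assert ("D0", "D1") in pg.design_violations

    def test_bad_error_rate_rejected(self):
        with pytest.raises(ValueError):
            generate_pooled_genotypes(9, 10, grid_pool_plan(), error_rate=0.5, seed=0)
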