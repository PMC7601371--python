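"""Aggregation tests vs closed forms and exhaustive enumeration oracles."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import comb as scomb

from pedagg import (
    Cohort,
    FamilyCounts,
    Individual,
    bh_adjust,
    binomial_family_test,
    familial_clustering_test,
    family_counts,
    family_genealogical_index,
    genealogical_index,
    kinship_matrix,
    kinship_sum_test,
    prevalence_scenarios,
)

from . import _oracles
from .conftest import nuclear_family


def exact_binom_tail(n, k, p):
    """Independent direct summation of the upper binomial tail."""
    return sum(
        scomb(n, j, exact=True) * p**j * (1 - p) ** (n - j)
        for j in range(k, n + 1)
    )


class TestBinomialFamilyTest:
    def test_family_of_seven_with_five_cases(self):
        res = binomial_family_test(
            FamilyCounts("A", 7, 5), prevalence=46 / 468
        )
        assert res.statistic == 5
        assert res.p == pytest.approx(
            exact_binom_tail(7, 5, 46 / 468), rel=1e-12
        )
        assert float(f"{res.p:.3g}") == 1.62e-4

    def test_myxedematous_prevalence_value(self):
        # direct summation, deliberately not matched to any printed table
        res = binomial_family_test(FamilyCounts("A", 7, 5), 44 / 468)
        assert res.p == pytest.approx(exact_binom_tail(7, 5, 44 / 468),
                                      rel=1e-12)
        assert res.p == pytest.approx(1.31e-4, rel=5e-3)

    def test_zero_cases_gives_one(self):
        assert binomial_family_test(FamilyCounts("F", 9, 0), 0.3).p == 1.0

    def test_k_exceeding_n_rejected(self):
        with pytest.raises(ValueError):
            FamilyCounts("F", 3, 4)

    @settings(max_examples=50, deadline=None)
    @given(
        n=st.integers(2, 30),
        k=st.integers(1, 29),
        pi=st.floats(0.01, 0.5),
    )
    def test_monotone_in_k_and_prevalence(self, n, k, pi):
        k = min(k, n - 1)
        p_k = binomial_family_test(FamilyCounts("F", n, k), pi).p
        p_k1 = binomial_family_test(FamilyCounts("F", n, k + 1), pi).p
        p_hi = binomial_family_test(FamilyCounts("F", n, k), pi * 1.5).p
        assert p_k1 < p_k
        assert p_hi >= p_k


class TestKinshipSum:
    def test_four_affected_full_sibs_sum_to_one(self):
        inds = nuclear_family("F1", 5, affected=(1, 2, 3, 4, 5))
        cohort = Cohort(inds)
        res = kinship_sum_test(
            kinship_matrix(cohort), cohort.phenotype_mask("combined"),
            B=10, seed=0,
        )
        assert all(r.statistic == 1.0 for r in res)

    def test_unrelated_affected_all_p_one(self):
        inds = [
            Individual(id=f"u{i}", family_id=f"U{i}",
                       phenotype="myxedematous_severe" if i < 3
                       else "unaffected")
            for i in range(8)
        ]
        cohort = Cohort(inds)
        res = kinship_sum_test(
            kinship_matrix(cohort), cohort.phenotype_mask("combined"),
            B=200, seed=0,
        )
        assert all(r.statistic == 0.0 for r in res)
        assert all(r.p == 1.0 for r in res)

    def test_pooled_null_matches_enumeration(self, toy_six_member_cohort):
        """Sampled p at large B falls in the 99% CI of the exact pooled tail."""
        cohort = toy_six_member_cohort
        kin = kinship_matrix(cohort)
        mask = cohort.phenotype_mask("combined")
        results = kinship_sum_test(kin, mask, B=100_000, seed=3)
        pheno = [m for m in kin.member_ids if mask[m] != "unphenotyped"]
        phi = kin.submatrix(pheno)
        for r in results:
            exact = _oracles.enum_kinship_sum_pooled(phi, 2, r.statistic)
            n_pool = r.null_size
            assert abs(r.p - exact) <= _oracles.mc_ci99(exact, n_pool)

    def test_requires_two_affected(self, toy_six_member_cohort):
        cohort = toy_six_member_cohort
        kin = kinship_matrix(cohort)
        mask = cohort.phenotype_mask("neurological")  # no affected
        with pytest.raises(ValueError):
            kinship_sum_test(kin, mask, B=10, seed=0)

    def test_max_null_convention_differs_and_reproduces(
        self, toy_six_member_cohort
    ):
        cohort = toy_six_member_cohort
        kin = kinship_matrix(cohort)
        mask = cohort.phenotype_mask("combined")
        a = kinship_sum_test(kin, mask, B=5000, seed=9, null="max")
        b = kinship_sum_test(kin, mask, B=5000, seed=9, null="max")
        assert a == b
        pooled = kinship_sum_test(kin, mask, B=5000, seed=9, null="pooled")
        assert pooled[0].null_size != a[0].null_size


class TestGenealogicalIndex:
    def test_five_affected_sibs_gif(self):
        inds = nuclear_family("F1", 5, affected=(1, 2, 3, 4, 5))
        inds += nuclear_family("F2", 5, prefix="x")
        cohort = Cohort(inds)
        res = genealogical_index(
            kinship_matrix(cohort), cohort.phenotype_mask("combined"),
            B=100, seed=0,
        )
        assert res.statistic == 25_000.0

    def test_unrelated_affected_p_one(self):
        inds = [
            Individual(id=f"u{i}", family_id=f"U{i}",
                       phenotype="neurological" if i < 2 else "unaffected")
            for i in range(6)
        ]
        cohort = Cohort(inds)
        res = genealogical_index(
            kinship_matrix(cohort), cohort.phenotype_mask("combined"),
            B=500, seed=1,
        )
        assert res.statistic == 0.0
        assert res.p == 1.0

    def test_matches_enumeration_on_eight_members(self):
        """2 affected among 8: exhaustive null over C(8,2)=28 pairs."""
        inds = nuclear_family("F1", 4, affected=(1, 2))
        inds += [
            Individual(id=f"u{i}", family_id="U", phenotype="unaffected")
            for i in range(2)
        ]
        cohort = Cohort(inds)
        kin = kinship_matrix(cohort)
        mask = cohort.phenotype_mask("combined")
        res = genealogical_index(kin, mask, B=100_000, seed=5)
        pheno = [m for m in kin.member_ids if mask[m] != "unphenotyped"]
        phi = kin.submatrix(pheno)
        exact = _oracles.enum_gif_tail(phi, 2, res.statistic)
        assert abs(res.p - exact) <= _oracles.mc_ci99(exact, res.n_sims)


class TestFamilyGenealogicalIndex:
    def test_fully_affected_family_degenerate(self):
        # every phenotyped family member affected, parents included
        inds = nuclear_family("F1", 3)
        inds = [
            Individual(
                id=x.id, family_id=x.family_id, father_id=x.father_id,
                mother_id=x.mother_id, sex=x.sex,
                phenotype="myxedematous_severe",
            )
            for x in inds
        ]
        cohort = Cohort(inds)
        res = family_genealogical_index(
            kinship_matrix(cohort), cohort.phenotype_mask("combined"),
            "F1", cohort, B=500, seed=0,
        )
        assert res.degenerate
        assert res.p is None

    def test_matches_enumeration_within_family(self):
        """4 sibs + 2 parents, 2 affected sibs: null over C(6,2)=15 subsets."""
        inds = nuclear_family("F1", 4, affected=(1, 2))
        cohort = Cohort(inds)
        kin = kinship_matrix(cohort)
        mask = cohort.phenotype_mask("combined")
        res = family_genealogical_index(
            kin, mask, "F1", cohort, B=100_000, seed=2
        )
        members = [m.id for m in cohort.family_members("F1")]
        phi = kin.submatrix(members)
        exact = _oracles.enum_gif_tail(phi, 2, res.statistic)
        assert res.statistic == 25_000.0
        assert abs(res.p - exact) <= _oracles.mc_ci99(exact, res.n_sims)

    def test_two_affected_parents_statistic_zero(self):
        inds = nuclear_family("F1", 3)
        inds[0] = Individual(id="f", family_id="F1", sex="male",
                             phenotype="myxedematous_severe")
        inds[1] = Individual(id="m", family_id="F1", sex="female",
                             phenotype="neurological")
        cohort = Cohort(inds)
        res = family_genealogical_index(
            kinship_matrix(cohort), cohort.phenotype_mask("combined"),
            "F1", cohort, B=2000, seed=0,
        )
        assert res.statistic == 0.0
        assert not res.degenerate
        assert res.p == 1.0


class TestFamilialClustering:
    def test_matches_enumeration_two_families(self):
        counts = [FamilyCounts("X", 2, 2), FamilyCounts("Y", 2, 0)]
        res = familial_clustering_test(counts, B=50_000, seed=4)
        exact = _oracles.enum_clustering_tail([2, 2], [2, 0])
        assert abs(res.p - exact) <= _oracles.mc_ci99(exact, res.n_sims)

    def test_concentration_is_more_extreme(self):
        spread = [FamilyCounts(f"F{i}", 5, 1) for i in range(3)]
        packed = [
            FamilyCounts("F0", 5, 3),
            FamilyCounts("F1", 5, 0),
            FamilyCounts("F2", 5, 0),
        ]
        p_spread = familial_clustering_test(spread, B=20_000, seed=6).p
        p_packed = familial_clustering_test(packed, B=20_000, seed=6).p
        assert p_packed <= p_spread

    def test_single_family_p_one(self):
        res = familial_clustering_test([FamilyCounts("F", 10, 3)],
                                       B=100, seed=0)
        assert res.p == 1.0

    def test_cohort_without_cases_rejected(self):
        with pytest.raises(ValueError):
            familial_clustering_test(
                [FamilyCounts("F", 2, 0), FamilyCounts("G", 3, 0)],
                B=10, seed=0,
            )


class TestBHAdjust:
    def test_two_tied_smallest_of_62(self):
        p0 = exact_binom_tail(7, 5, 46 / 468)
        pvals = [p0, p0] + [0.5] * 60
        adj = bh_adjust(pvals)
        assert float(f"{adj[0]:.3g}") == 5.04e-3
        assert adj[0] == pytest.approx(p0 * 62 / 2, rel=1e-12)

    def test_single_p_unchanged(self):
        assert bh_adjust([0.123]) == pytest.approx([0.123])

    def test_identical_values_unchanged(self):
        assert bh_adjust([0.2] * 7) == pytest.approx([0.2] * 7)

    def test_rejects_out_of_range(self):
        for bad in ([0.0, 0.5], [0.5, 1.2], [-0.1]):
            with pytest.raises(ValueError):
                bh_adjust(bad)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        st.lists(
            st.floats(1e-12, 1.0, exclude_min=False), min_size=1, max_size=40
        )
    )
    def test_matches_literal_stepup_and_never_decreases(self, pvals):
        adj = bh_adjust(pvals)
        ref = _oracles.stepup_bh(pvals)
        assert adj == pytest.approx(ref, rel=1e-12)
        assert np.all(adj >= np.asarray(pvals) - 1e-15)

    def test_matches_statsmodels_reference(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(0)
        for _ in range(100):
            p = rng.uniform(1e-6, 1.0, size=rng.integers(1, 80))
            ours = bh_adjust(p)
            theirs = multipletests(p, method="fdr_bh")[1]
            assert ours == pytest.approx(theirs, rel=1e-10)


class TestScenariosAndReproducibility:
    def test_scenario_counts_monotone_in_prevalence(self, fixture_cohort):
        table = prevalence_scenarios(
            fixture_cohort, "combined", [0.02, 0.05, 0.07, 46 / 468]
        )
        counts = table.sort_values("prevalence")["n_significant"].tolist()
        assert counts == sorted(counts, reverse=True)

    def test_empty_prevalence_list_rejected(self, fixture_cohort):
        with pytest.raises(ValueError):
            prevalence_scenarios(fixture_cohort, "combined", [])

    def test_identical_seed_identical_results(self, toy_six_member_cohort):
        cohort = toy_six_member_cohort
        kin = kinship_matrix(cohort)
        mask = cohort.phenotype_mask("combined")
        counts = family_counts(cohort, mask)
        for call in (
            lambda: kinship_sum_test(kin, mask, B=3000, seed=11),
            lambda: genealogical_index(kin, mask, B=3000, seed=11),
            lambda: familial_clustering_test(counts, B=3000, seed=11),
        ):
            assert call() == call()
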