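"""Edge-shuffle null, permutation p-values, enrichment, and profiles."""

from collections import Counter

import numpy as np
import pytest

from conftest import make_mgdn, random_mgdn
from metnet.errors import ConfigError, DomainError
from metnet.significance import (
    MetaboliteProfile,
    SignificanceResult,
    build_profiles,
    enrichment_fold,
    format_enrichment_percent,
    jaccard,
    permutation_test,
    profile_expectation_matrix,
    profile_jaccard_matrix,
    random_overlap_expectation,
    shuffle_mgdn,
)


def degree_sequence(mgdn):
    deg = Counter()
    for a, b, _ in mgdn.all_edges():
        deg[a] += 1
        deg[b] += 1
    return deg


class TestShuffle:
    def test_preserves_degrees_count_and_weights(self):
        rng = np.random.default_rng(5)
        for k in range(25):
            mgdn = random_mgdn(rng)
            try:
                shuffled = shuffle_mgdn(mgdn, seed=k)
            except DomainError:  # tiny rigid graph, no legal swap
                continue
            assert degree_sequence(shuffled) == degree_sequence(mgdn)
            orig = sorted(w for *_, w in mgdn.all_edges())
            new = sorted(w for *_, w in shuffled.all_edges())
            assert np.allclose(orig, new)

    def test_seed_determinism_and_divergence(self):
        rng = np.random.default_rng(99)
        mgdn = random_mgdn(rng, max_nodes=15)
        while len(mgdn.all_edges()) < 30:
            mgdn = random_mgdn(rng, max_nodes=15)
        e_a = sorted(shuffle_mgdn(mgdn, seed=1).all_edges())
        e_b = sorted(shuffle_mgdn(mgdn, seed=1).all_edges())
        e_c = sorted(shuffle_mgdn(mgdn, seed=2).all_edges())
        assert e_a == e_b
        assert e_a != e_c

    def test_rigid_graph_suggests_naive_fallback(self):
        mgdn = make_mgdn({("A", "B"): 0.5}, {"B": 0.4})  # path, unswappable
        with pytest.raises(DomainError, match="naive"):
            shuffle_mgdn(mgdn, seed=0)
        # the naive endpoint shuffle still works on it
        shuffled = shuffle_mgdn(mgdn, seed=0, naive=True)
        assert len(shuffled.all_edges()) == 2

    def test_single_edge_rejected(self):
        with pytest.raises(DomainError):
            shuffle_mgdn(make_mgdn({}, {"A": 0.5}), seed=0)


class TestPermutationTest:
    def test_result_invariants(self):
        rng = np.random.default_rng(3)
        mgdn = random_mgdn(rng)
        disease = mgdn.disease_labels[0]
        res = permutation_test(mgdn, disease, n_perm=50, seed=11)
        assert res.null_mean == pytest.approx(res.null_percentiles.mean())
        assert res.enrichment_fold == pytest.approx(
            res.null_mean / res.observed_percentile
        )
        assert res.p_empirical == pytest.approx(
            (1 + np.sum(res.null_percentiles <= res.observed_percentile)) / 51
        )
        assert res.p_empirical > 0.0
        assert 0.0 <= res.p_ttest <= 1.0
        assert len(res.null_percentiles) == 50

    def test_same_seed_reproduces_result(self):
        rng = np.random.default_rng(8)
        mgdn = random_mgdn(rng)
        d = mgdn.disease_labels[1]
        r1 = permutation_test(mgdn, d, n_perm=30, seed=7)
        r2 = permutation_test(mgdn, d, n_perm=30, seed=7)
        assert np.array_equal(r1.null_percentiles, r2.null_percentiles)
        assert r1.p_empirical == r2.p_empirical

    def test_unknown_disease_rejected(self):
        rng = np.random.default_rng(4)
        mgdn = random_mgdn(rng)
        with pytest.raises(KeyError):
            permutation_test(mgdn, "no such trait", n_perm=5, seed=0)


class TestEnrichment:
    def test_centered_case_fold_one(self):
        assert enrichment_fold(40.0, [30.0, 50.0]) == pytest.approx(1.0)

    def test_headline_fold(self):
        # observed top 1.25 % vs null mean 44 % -> 35.2-fold
        assert enrichment_fold(1.25, [44.0]) == pytest.approx(35.2)

    def test_percent_rendering(self):
        assert format_enrichment_percent(3.534) == "353.4 %"
        assert format_enrichment_percent(1.0) == "100.0 %"

    def test_zero_observed_rejected(self):
        with pytest.raises(DomainError):
            enrichment_fold(0.0, [10.0])


def result(met, trait, p):
    return SignificanceResult(
        metabolite_id=met,
        disease=trait,
        observed_percentile=10.0,
        null_percentiles=np.array([50.0]),
        null_mean=50.0,
        enrichment_fold=5.0,
        p_empirical=p,
        p_ttest=p,
        n_perm=100,
        seed=0,
    )


class TestProfiles:
    def test_all_insignificant_gives_empty_profiles(self):
        results = [result(f"M{i}", "T1", 1.0) for i in range(5)]
        profiles = build_profiles(results, alpha=0.05, correction="bh")
        assert profiles[0].significant_metabolites == frozenset()

    def test_bonferroni_threshold(self):
        ps = [0.004, 0.004999, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9]
        results = [result(f"M{i}", "T1", p) for i, p in enumerate(ps)]
        profiles = build_profiles(results, alpha=0.05, correction="bonferroni")
        assert profiles[0].significant_metabolites == {"M0", "M1"}

    def test_no_correction_alpha_one_keeps_everything(self):
        results = [result(f"M{i}", "T1", 0.99) for i in range(4)]
        profiles = build_profiles(results, alpha=1.0, correction="none")
        assert len(profiles[0]) == 4

    def test_alpha_domain(self):
        with pytest.raises(ConfigError):
            build_profiles([result("M1", "T1", 0.5)], alpha=0.0)

    def test_profile_self_similarity_is_one(self):
        profiles = [
            MetaboliteProfile("T1", frozenset({"M1", "M2"})),
            MetaboliteProfile("T2", frozenset({"M2", "M3", "M4"})),
        ]
        mat = profile_jaccard_matrix(profiles)
        assert mat.loc["T1", "T1"] == 1.0
        assert mat.loc["T1", "T2"] == pytest.approx(1 / 4)
        exp = profile_expectation_matrix(profiles, total=10)
        assert exp.loc["T1", "T2"] == pytest.approx(0.2 * 0.3)


class TestSetStatistics:
    @pytest.mark.parametrize(
        "a,b,expected",
        [
            ({"x", "y"}, {"x", "y"}, 1.0),
            ({"x"}, {"y"}, 0.0),
            ({"a", "b", "c", "d", "e"}, {"d", "e", "f", "g", "h"}, 2 / 8),
        ],
    )
    def test_jaccard(self, a, b, expected):
        assert jaccard(a, b) == pytest.approx(expected)

    def test_jaccard_of_empty_sets_undefined(self):
        with pytest.raises(DomainError):
            jaccard(set(), set())

    @pytest.mark.parametrize(
        "n1,n2,total,expected",
        [
            (56, 62, 171, (56 / 171) * (62 / 171)),
            (10, 10, 10, 1.0),
            (0, 7, 10, 0.0),
        ],
    )
    def test_random_overlap_expectation(self, n1, n2, total, expected):
        assert random_overlap_expectation(n1, n2, total) == pytest.approx(expected)

    def test_random_overlap_domain(self):
        with pytest.raises(DomainError):
            random_overlap_expectation(1, 1, 0)
        with pytest.raises(DomainError):
            random_overlap_expectation(11, 1, 10)
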