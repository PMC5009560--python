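"""GDN construction, metabolite insertion, and cosine edge weights."""

import math
from itertools import combinations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from metnet.errors import ConfigError, DomainError
from metnet.io_formats import (
    AssociationRecord,
    AssociationTable,
    InteractionNetwork,
    PathwayCollection,
)
from metnet.network import build_gdn, cosine_similarity, insert_metabolite


def assoc_from_sets(sets: dict[str, set[str]]) -> AssociationTable:
    # apply the reader's normalization so sets mix with PPI/pathway inputs
    return AssociationTable(
        [
            AssociationRecord(d, g.upper())
            for d, genes in sets.items()
            for g in genes
        ]
    )


class TestCosine:
    def test_identical_sets(self):
        assert cosine_similarity({"a", "b", "c"}, {"a", "b", "c"}) == 1.0

    def test_disjoint_sets(self):
        assert cosine_similarity({"a"}, {"b"}) == 0.0

    def test_hand_computed_value(self):
        a = {f"x{i}" for i in range(4)}
        b = {"x0", "x1", "x2"} | {f"y{i}" for i in range(6)}
        assert cosine_similarity(a, b) == pytest.approx(3 / math.sqrt(36))

    def test_empty_set_rejected(self):
        with pytest.raises(DomainError):
            cosine_similarity(set(), {"a"})

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        a=st.sets(st.integers(0, 30), min_size=1, max_size=15),
        b=st.sets(st.integers(0, 30), min_size=1, max_size=15),
    )
    def test_symmetric_and_bounded(self, a, b):
        s = cosine_similarity(a, b)
        assert s == cosine_similarity(b, a)
        assert 0.0 <= s <= 1.0


class TestBuildGDN:
    def test_no_shared_genes_no_edge(self):
        gdn = build_gdn(assoc_from_sets({"D1": {"g1", "g2"}, "D2": {"g3"}}))
        assert gdn.graph.number_of_edges() == 0

    def test_shared_gene_cosine_weight(self):
        gdn = build_gdn(
            assoc_from_sets({"D1": {"g1", "g2"}, "D2": {"g2", "g3", "g4"}})
        )
        assert gdn.graph.number_of_edges() == 1
        assert gdn.graph["D1"]["D2"]["weight"] == pytest.approx(1 / math.sqrt(6))

    def test_fewer_than_two_diseases_rejected(self):
        with pytest.raises(DomainError):
            build_gdn(assoc_from_sets({"D1": {"g1"}}))

    def test_indirect_requires_a_link_source(self):
        table = assoc_from_sets({"D1": {"g1"}, "D2": {"g2"}})
        with pytest.raises(ConfigError):
            build_gdn(table, mode="indirect")

    def test_ppi_bridges_disjoint_diseases(self):
        table = assoc_from_sets({"D1": {"g1", "g2"}, "D2": {"g3"}})
        ppi = InteractionNetwork({("G1", "G3"): 0.9})
        direct = build_gdn(table, mode="direct")
        indirect = build_gdn(table, mode="indirect", ppi=ppi)
        assert not direct.graph.has_edge("D1", "D2")
        assert indirect.graph.has_edge("D1", "D2")
        assert indirect.graph["D1"]["D2"]["weight"] > 0.0

    def test_pathway_comembership_bridges_diseases(self):
        table = assoc_from_sets({"D1": {"g1"}, "D2": {"g2"}})
        coll = PathwayCollection({"P1": frozenset({"G1", "G2"})})
        gdn = build_gdn(table, mode="indirect", pathways=coll)
        assert gdn.graph.has_edge("D1", "D2")

    def test_direct_matches_bruteforce_pairwise_intersection(self):
        rng = np.random.default_rng(7)
        genes = [f"g{i}" for i in range(60)]
        sets = {
            f"D{i}": set(rng.choice(genes, size=rng.integers(2, 8), replace=False))
            for i in range(30)
        }
        gdn = build_gdn(assoc_from_sets(sets))
        expected = {
            frozenset((a, b))
            for a, b in combinations(sets, 2)
            if sets[a] & sets[b]
        }
        observed = {frozenset(e) for e in gdn.graph.edges}
        assert observed == expected

    def test_indirect_edge_set_superset_of_direct(self):
        rng = np.random.default_rng(11)
        genes = [f"g{i}" for i in range(40)]
        sets = {
            f"D{i}": set(rng.choice(genes, size=4, replace=False))
            for i in range(15)
        }
        ppi_edges = {}
        for _ in range(30):
            a, b = rng.choice(genes, size=2, replace=False)
            key = (a.upper(), b.upper()) if a < b else (b.upper(), a.upper())
            ppi_edges[key] = 0.8
        table = assoc_from_sets(sets)
        direct = build_gdn(table, mode="direct")
        indirect = build_gdn(table, mode="indirect", ppi=InteractionNetwork(ppi_edges))
        direct_edges = {frozenset(e) for e in direct.graph.edges}
        indirect_edges = {frozenset(e) for e in indirect.graph.edges}
        assert direct_edges <= indirect_edges


class TestInsertMetabolite:
    def test_disjoint_metabolite_has_no_edges(self, toy_assoc):
        gdn = build_gdn(toy_assoc)
        mgdn = insert_metabolite(gdn, "M1", {"zz1", "zz2"})
        assert mgdn.metabolite_edges == {}

    def test_overlap_weight_is_cosine(self, toy_assoc):
        gdn = build_gdn(toy_assoc)
        mgdn = insert_metabolite(gdn, "M1", {"g2"})
        # D2 has 3 genes, shares g2 with the metabolite's single gene
        assert mgdn.metabolite_edges["D2"] == pytest.approx(1 / math.sqrt(3))
        assert mgdn.metabolite_edges["D1"] == pytest.approx(1 / math.sqrt(2))

    def test_insertion_leaves_base_gdn_unchanged(self, toy_assoc):
        gdn = build_gdn(toy_assoc)
        before = {frozenset(e): d["weight"] for *e, d in gdn.graph.edges(data=True)}
        insert_metabolite(gdn, "M1", {"g2", "g5"})
        after = {frozenset(e): d["weight"] for *e, d in gdn.graph.edges(data=True)}
        assert before == after

    def test_empty_metabolite_set_rejected(self, toy_assoc):
        with pytest.raises(DomainError):
            insert_metabolite(build_gdn(toy_assoc), "M1", set())
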