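"""Shared fixtures and small graph builders."""

from __future__ import annotations

import networkx as nx
import numpy as np
import pytest

from metnet.io_formats import AssociationRecord, AssociationTable
from metnet.network import MGDN, GeneticDiseaseNetwork


def make_mgdn(
    disease_edges: dict[tuple[str, str], float],
    metabolite_edges: dict[str, float],
    diseases: list[str] | None = None,
    metabolite_id: str = "MET",
) -> MGDN:
    """Assemble an mGDN directly from weighted edges (topology-level tests)."""
    graph = nx.Graph()
    nodes: list[str] = list(diseases) if diseases else []
    for (a, b) in disease_edges:
        for n in (a, b):
            if n not in nodes:
                nodes.append(n)
    for d in metabolite_edges:
        if d not in nodes:
            nodes.append(d)
    gene_sets = {d: frozenset({f"g_{d}"}) for d in nodes}
    for d in nodes:
        graph.add_node(d, genes=gene_sets[d])
    for (a, b), w in disease_edges.items():
        graph.add_edge(a, b, weight=w)
    gdn = GeneticDiseaseNetwork(
        graph=graph,
        mode="direct",
        gene_sets=gene_sets,
        effective_sets=dict(gene_sets),
    )
    return MGDN(
        base=gdn,
        metabolite_id=metabolite_id,
        metabolite_genes=frozenset({"g_met"}),
        metabolite_edges=dict(metabolite_edges),
    )


def random_mgdn(rng: np.random.Generator, max_nodes: int = 20) -> MGDN:
    """Random weighted mGDN with at most ``max_nodes`` nodes in total."""
    n_d = int(rng.integers(2, max_nodes))  # + metabolite stays <= max_nodes
    labels = [f"D{i:02d}" for i in range(n_d)]
    dd: dict[tuple[str, str], float] = {}
    for i in range(n_d):
        for j in range(i + 1, n_d):
            if rng.random() < 0.3:
                dd[(labels[i], labels[j])] = float(rng.uniform(0.05, 1.0))
    met: dict[str, float] = {
        d: float(rng.uniform(0.05, 1.0))
        for d in labels
        if rng.random() < 0.4
    }
    if not met:
        met[labels[int(rng.integers(0, n_d))]] = float(rng.uniform(0.05, 1.0))
    while len(dd) + len(met) < 2:
        met[labels[int(rng.integers(0, n_d))]] = float(rng.uniform(0.05, 1.0))
    return make_mgdn(dd, met, diseases=labels)


def rwr_linear_solve(mgdn: MGDN, restart: float) -> np.ndarray:
    """Closed-form restart-walk stationary vector, p = r (I - (1-r) T)^-1 e.

    Builds the column-normalized transition matrix with plain Python
    loops and solves the linear system directly, independently of the
    iterative implementation it cross-checks.
    """
    labels, u, v, w = mgdn.to_arrays()
    n = len(labels)
    seed_idx = n - 1
    A = [[0.0] * n for _ in range(n)]
    for a, b, wt in zip(u.tolist(), v.tolist(), w.tolist()):
        A[b][a] += wt
        A[a][b] += wt
    for j in range(n):
        col = sum(A[i][j] for i in range(n))
        if col > 0:
            for i in range(n):
                A[i][j] /= col
        else:
            A[seed_idx][j] = 1.0
    T = np.array(A)
    e = np.zeros(n)
    e[seed_idx] = 1.0
    return np.linalg.solve(np.eye(n) - (1.0 - restart) * T, restart * e)


@pytest.fixture()
def toy_assoc() -> AssociationTable:
    """Three diseases with partially overlapping gene sets."""
    return AssociationTable(
        [
            AssociationRecord("D1", "G1"),
            AssociationRecord("D1", "G2"),
            AssociationRecord("D2", "G2"),
            AssociationRecord("D2", "G3"),
            AssociationRecord("D2", "G4"),
            AssociationRecord("D3", "G5"),
        ]
    )
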