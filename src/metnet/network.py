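"""Genetic disease networks (GDNs) and metabolite insertion (mGDNs).

A GDN is a weighted undirected graph over disease/trait nodes.  In
``direct`` mode two diseases are connected iff their associated gene
sets intersect, with edge weight equal to the cosine similarity of the
two sets.  In ``indirect`` mode diseases whose genes do not overlap can
also be connected when their genes interact in a protein-protein
interaction (PPI) network or co-occur in an annotated pathway; weights
are then cosine similarities of functionally augmented gene sets (the
original set plus PPI neighbors and/or pathway co-members, restricted to
genes present in the association table), which reduces to the direct
weight when augmentation adds nothing.

An mGDN is a GDN with a single metabolite node inserted; the metabolite
connects to every disease whose gene set overlaps its own (or satisfies
the indirect criterion), weighted by the same cosine similarity.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import networkx as nx
import numpy as np

from .errors import ConfigError, DomainError
from .io_formats import (
    AssociationTable,
    InteractionNetwork,
    PathwayCollection,
    normalize_gene,
)

__all__ = [
    "cosine_similarity",
    "GeneticDiseaseNetwork",
    "MGDN",
    "build_gdn",
    "insert_metabolite",
]

logger = logging.getLogger(__name__)


def cosine_similarity(a: Iterable[str], b: Iterable[str]) -> float:
    """Cosine similarity of two gene sets: |a & b| / sqrt(|a| * |b|).

    This is the cosine of the angle between the binary indicator vectors
    of the two sets; it is 1.0 for identical sets and 0.0 for disjoint
    ones.  Both sets must be non-empty.
    """
    sa, sb = set(a), set(b)
    if not sa or not sb:
        raise DomainError("cosine similarity requires non-empty gene sets")
    return len(sa & sb) / math.sqrt(len(sa) * len(sb))


@dataclass
class GeneticDiseaseNetwork:
    """Weighted undirected disease-disease network.

    ``gene_sets`` maps each disease label to its (normalized) gene set;
    ``effective_sets`` equals ``gene_sets`` in direct mode and the
    augmented sets in indirect mode.  The underlying ``networkx`` graph
    stores edge weights under the ``weight`` attribute; zero-weight
    edges are never stored.
    """

    graph: nx.Graph
    mode: str
    gene_sets: dict[str, frozenset[str]]
    effective_sets: dict[str, frozenset[str]]
    ppi: InteractionNetwork | None = field(default=None, repr=False)
    pathways: PathwayCollection | None = field(default=None, repr=False)
    combine: str = "or"

    @property
    def diseases(self) -> list[str]:
        return list(self.graph.nodes)

    def edge_weights(self) -> dict[tuple[str, str], float]:
        return {
            (a, b): d["weight"] for a, b, d in self.graph.edges(data=True)
        }

    def __len__(self) -> int:
        return self.graph.number_of_nodes()


@dataclass
class MGDN:
    """A GDN augmented with one metabolite node.

    ``metabolite_edges`` maps disease labels to the metabolite-disease
    cosine weights; the base GDN is shared, never mutated.
    """

    base: GeneticDiseaseNetwork
    metabolite_id: str
    metabolite_genes: frozenset[str]
    metabolite_edges: dict[str, float]

    @property
    def disease_labels(self) -> list[str]:
        return list(self.base.graph.nodes)

    @property
    def n_diseases(self) -> int:
        return self.base.graph.number_of_nodes()

    def to_arrays(self) -> tuple[list[str], np.ndarray, np.ndarray, np.ndarray]:
        """Flatten to (labels, u, v, w) with the metabolite as last node.

        Labels list the diseases in node order followed by the
        metabolite id; u/v are integer endpoint arrays over the combined
        edge set (disease-disease then metabolite-disease), w the
        matching weights.
        """
        labels = self.disease_labels
        index = {d: i for i, d in enumerate(labels)}
        m_idx = len(labels)
        us: list[int] = []
        vs: list[int] = []
        ws: list[float] = []
        for a, b, data in self.base.graph.edges(data=True):
            us.append(index[a])
            vs.append(index[b])
            ws.append(data["weight"])
        for d, w in self.metabolite_edges.items():
            us.append(index[d])
            vs.append(m_idx)
            ws.append(w)
        return (
            labels + [self.metabolite_id],
            np.asarray(us, dtype=np.int64),
            np.asarray(vs, dtype=np.int64),
            np.asarray(ws, dtype=np.float64),
        )

    def all_edges(self) -> list[tuple[str, str, float]]:
        edges = [
            (a, b, d["weight"]) for a, b, d in self.base.graph.edges(data=True)
        ]
        edges.extend(
            (self.metabolite_id, d, w)
            for d, w in self.metabolite_edges.items()
        )
        return edges


def _augment(
    gene_sets: Mapping[str, frozenset[str]],
    universe: frozenset[str],
    ppi: InteractionNetwork | None,
    pathways: PathwayCollection | None,
) -> dict[str, frozenset[str]]:
    """Expand each gene set by PPI neighbors and/or pathway co-members.

    Added genes are restricted to ``universe`` (genes appearing anywhere
    in the association table) so augmentation never invents nodes the
    network cannot see.
    """
    co_members: dict[str, set[str]] = {}
    if pathways is not None:
        for _, genes in pathways.items():
            keep = genes & universe
            for g in genes:
                co_members.setdefault(g, set()).update(keep)
    out: dict[str, frozenset[str]] = {}
    for label, genes in gene_sets.items():
        expanded = set(genes)
        if ppi is not None:
            for g in genes:
                expanded.update(ppi.neighbors(g) & universe)
        if pathways is not None:
            for g in genes:
                expanded.update(co_members.get(g, ()))
        out[label] = frozenset(expanded)
    return out


def _indirect_link(
    genes_a: frozenset[str],
    genes_b: frozenset[str],
    ppi: InteractionNetwork | None,
    pathways: PathwayCollection | None,
    combine: str,
) -> bool:
    """Whether two non-overlapping gene sets are functionally linked."""
    ppi_link = None
    if ppi is not None:
        ppi_link = any(ppi.neighbors(g) & genes_b for g in genes_a)
    pw_link = None
    if pathways is not None:
        pw_link = any(
            (genes & genes_a) and (genes & genes_b)
            for _, genes in pathways.items()
        )
    criteria = [c for c in (ppi_link, pw_link) if c is not None]
    if combine == "or":
        return any(criteria)
    return all(criteria)


def build_gdn(
    assoc: AssociationTable,
    mode: str = "direct",
    ppi: InteractionNetwork | None = None,
    pathways: PathwayCollection | None = None,
    combine: str = "or",
) -> GeneticDiseaseNetwork:
    """Construct a genetic disease network from an association table.

    Parameters
    ----------
    assoc
        Disease/trait-gene association table; each distinct trait label
        becomes its own node.
    mode
        ``direct`` connects diseases iff they share genes; ``indirect``
        additionally connects diseases whose genes interact (PPI) or
        share a pathway.
    ppi, pathways
        Functional-link sources, required (at least one) for indirect
        mode.
    combine
        How PPI and pathway criteria combine for indirect links when
        both sources are given: ``or`` (default) or ``and``.
    """
    if mode not in ("direct", "indirect"):
        raise ConfigError(f"unknown GDN mode {mode!r}")
    if combine not in ("or", "and"):
        raise ConfigError(f"combine must be 'or' or 'and', got {combine!r}")
    if mode == "indirect" and ppi is None and pathways is None:
        raise ConfigError(
            "indirect mode requires a PPI network and/or a pathway collection"
        )
    gene_sets = assoc.gene_sets()
    if len(gene_sets) < 2:
        raise DomainError(
            f"need at least 2 diseases to build a network, got {len(gene_sets)}"
        )
    universe = frozenset(g for genes in gene_sets.values() for g in genes)
    if mode == "indirect":
        effective = _augment(gene_sets, universe, ppi, pathways)
    else:
        effective = dict(gene_sets)

    graph = nx.Graph()
    for label in gene_sets:
        graph.add_node(label, genes=gene_sets[label])
    labels = list(gene_sets)
    for i, a in enumerate(labels):
        for b in labels[i + 1:]:
            direct = bool(gene_sets[a] & gene_sets[b])
            if direct:
                connected = True
            elif mode == "indirect":
                connected = _indirect_link(
                    gene_sets[a], gene_sets[b], ppi, pathways, combine
                )
            else:
                connected = False
            if not connected:
                continue
            weight = cosine_similarity(effective[a], effective[b])
            if weight > 0.0:
                graph.add_edge(a, b, weight=weight)
    return GeneticDiseaseNetwork(
        graph=graph,
        mode=mode,
        gene_sets=gene_sets,
        effective_sets=effective,
        ppi=ppi,
        pathways=pathways,
        combine=combine,
    )


def insert_metabolite(
    gdn: GeneticDiseaseNetwork,
    metabolite_id: str,
    metabolite_genes: Iterable[str],
) -> MGDN:
    """Insert a metabolite node into a GDN, yielding an mGDN.

    The metabolite connects to every disease whose gene set overlaps the
    metabolite's (direct mode) or satisfies the GDN's indirect linkage
    criterion; edge weights are cosine similarities.  The base GDN is
    not mutated.  A metabolite with no connection to any disease yields
    a valid mGDN with zero metabolite edges (and a logged warning).
    """
    genes = frozenset(normalize_gene(g) for g in metabolite_genes)
    if not genes:
        raise DomainError("metabolite gene set must be non-empty")
    universe = frozenset(
        g for gs in gdn.gene_sets.values() for g in gs
    )
    if gdn.mode == "indirect":
        eff_met = _augment(
            {metabolite_id: genes}, universe, gdn.ppi, gdn.pathways
        )[metabolite_id]
    else:
        eff_met = genes
    edges: dict[str, float] = {}
    for disease, dgenes in gdn.gene_sets.items():
        direct = bool(genes & dgenes)
        if direct:
            connected = True
        elif gdn.mode == "indirect":
            connected = _indirect_link(
                genes, dgenes, gdn.ppi, gdn.pathways, gdn.combine
            )
        else:
            connected = False
        if not connected:
            continue
        weight = cosine_similarity(eff_met, gdn.effective_sets[disease])
        if weight > 0.0:
            edges[disease] = weight
    if not edges:
        logger.warning(
            "metabolite %s shares no genes with any disease; mGDN has no "
            "metabolite edges",
            metabolite_id,
        )
    return MGDN(
        base=gdn,
        metabolite_id=metabolite_id,
        metabolite_genes=genes,
        metabolite_edges=edges,
    )
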