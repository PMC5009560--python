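"""Shared-pathway identification and co-regulation scoring.

Given a metabolite's associated genes and a disease's associated genes,
the shared pathways are those containing at least one gene from each
side.  Each shared pathway is scored by the product of its per-side gene
sums: with indicator weights this is simply

    score = (# metabolite genes in the pathway) x (# disease genes in it),

so pathways rich in both metabolite- and disease-associated genes rank
highest.  An optional ``evidence`` weighting replaces the unit counts by
sums of per-gene association scores (e.g. chemical-gene evidence).  A
gene associated with both sides counts on both sides; the two sums are
independent.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd

from .errors import ConfigError, DomainError
from .io_formats import PathwayCollection

__all__ = [
    "PathwayScore",
    "pathways_for_genes",
    "shared_pathways",
    "score_and_rank",
]


@dataclass(frozen=True)
class PathwayScore:
    pathway: str
    metabolite_gene_count: float
    disease_gene_count: float
    score: float


def pathways_for_genes(
    collection: PathwayCollection, genes: Iterable[str]
) -> set[str]:
    """Names of every pathway containing at least one query gene."""
    query = set(genes)
    return {
        name
        for name, members in collection.items()
        if members & query
    }


def shared_pathways(met_pathways: set[str], disease_pathways: set[str]) -> set[str]:
    """Pathways associated with both the metabolite and the disease."""
    return set(met_pathways) & set(disease_pathways)


def score_and_rank(
    collection: PathwayCollection,
    met_genes: Iterable[str],
    dis_genes: Iterable[str],
    weights: str = "indicator",
    met_scores: Mapping[str, float] | None = None,
    dis_scores: Mapping[str, float] | None = None,
) -> list[PathwayScore]:
    """Score and rank the pathways shared by two gene sets.

    Returns only shared pathways, sorted by score descending with ties
    broken by pathway name.  ``weights='evidence'`` sums the per-gene
    scores from ``met_scores`` / ``dis_scores`` (genes without an entry
    weigh 1.0) instead of unit counts.
    """
    if weights not in ("indicator", "evidence"):
        raise ConfigError(f"weights must be 'indicator' or 'evidence', got {weights!r}")
    met = set(met_genes)
    dis = set(dis_genes)
    if not met or not dis:
        raise DomainError("both gene sets must be non-empty")

    def side_weight(genes: set[str], scores: Mapping[str, float] | None) -> float:
        if weights == "indicator" or scores is None:
            return float(len(genes))
        return float(sum(scores.get(g, 1.0) for g in genes))

    results: list[PathwayScore] = []
    for name, members in collection.items():
        in_met = members & met
        in_dis = members & dis
        if not in_met or not in_dis:
            continue
        mw = side_weight(in_met, met_scores)
        dw = side_weight(in_dis, dis_scores)
        results.append(PathwayScore(name, mw, dw, mw * dw))
    results.sort(key=lambda s: (-s.score, s.pathway))
    return results


def scores_to_frame(scores: list[PathwayScore]) -> pd.DataFrame:
    """Tabulate ranked pathway scores (1-based rank column included)."""
    return pd.DataFrame(
        [
            (s.pathway, s.metabolite_gene_count, s.disease_gene_count, s.score, i + 1)
            for i, s in enumerate(scores)
        ],
        columns=["pathway", "met_gene_count", "dis_gene_count", "score", "rank"],
    )
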