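"""Permutation null, significance statistics, and metabolite profiles.

The null model randomizes the real mGDN by degree-preserving double-edge
swaps over the combined edge set (disease-disease plus metabolite-
disease); the multiset of edge weights is preserved and reassigned to
the shuffled edges uniformly at random.  Re-ranking the disease of
interest on each randomized network yields its null percentile
distribution; the observed percentile is compared with it via

* an add-one empirical p-value, (1 + #{null <= observed}) / (1 + n_perm),
  which can never be exactly 0 and is the recommended headline statistic;
* a one-sample two-sided t-test of the null percentiles against the
  observed value;
* the enrichment fold, mean(null) / observed (also renderable as a
  percent, e.g. fold 3.534 <-> "353.4 %"): folds above 1 mean the
  metabolite ranks the disease better than chance.

Metabolite profiles (the set of metabolites significant for a trait)
are compared across traits by Jaccard similarity, with the random
expectation (n1/total) * (n2/total) as baseline.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigError, DomainError
from .network import MGDN, GeneticDiseaseNetwork
from .ranking import (
    DEFAULT_MAX_ITER,
    DEFAULT_RESTART,
    DEFAULT_TOL,
    _disease_percentiles,
)

__all__ = [
    "SignificanceResult",
    "MetaboliteProfile",
    "shuffle_mgdn",
    "permutation_test",
    "permutation_test_edges",
    "enrichment_fold",
    "format_enrichment_percent",
    "build_profiles",
    "jaccard",
    "random_overlap_expectation",
    "profile_jaccard_matrix",
    "profile_expectation_matrix",
]

logger = logging.getLogger(__name__)

DEFAULT_SWAP_FACTOR = 10


# ---------------------------------------------------------------------------
# edge randomization
# ---------------------------------------------------------------------------


def _double_edge_swap(
    u: np.ndarray,
    v: np.ndarray,
    n_nodes: int,
    rng: np.random.Generator,
    n_attempts: int,
) -> tuple[list[int], list[int], int]:
    """Degree-preserving rewiring by repeated double-edge swaps.

    Picks two random edges (x,y), (p,q) and replaces them with (x,p),
    (y,q) (or the flipped variant) unless that would create a self-loop
    or a duplicate edge.  Returns the rewired endpoint lists and the
    number of successful swaps.
    """
    m = int(u.size)
    eu = u.tolist()
    ev = v.tolist()
    present: set[int] = set()
    for a, b in zip(eu, ev):
        present.add(a * n_nodes + b if a < b else b * n_nodes + a)
    idx1 = rng.integers(0, m, size=n_attempts).tolist()
    idx2 = rng.integers(0, m, size=n_attempts).tolist()
    flip = rng.integers(0, 2, size=n_attempts).tolist()
    swaps = 0
    for a_i, b_i, f in zip(idx1, idx2, flip):
        if a_i == b_i:
            continue
        x, y = eu[a_i], ev[a_i]
        p, q = eu[b_i], ev[b_i]
        if f:
            p, q = q, p
        if x == p or y == q:
            continue
        k1 = x * n_nodes + p if x < p else p * n_nodes + x
        k2 = y * n_nodes + q if y < q else q * n_nodes + y
        if k1 == k2 or k1 in present or k2 in present:
            continue
        k_old1 = x * n_nodes + y if x < y else y * n_nodes + x
        k_old2 = p * n_nodes + q if p < q else q * n_nodes + p
        present.discard(k_old1)
        present.discard(k_old2)
        present.add(k1)
        present.add(k2)
        eu[a_i], ev[a_i] = x, p
        eu[b_i], ev[b_i] = y, q
        swaps += 1
    return eu, ev, swaps


def _naive_rewire(
    m: int, n_nodes: int, rng: np.random.Generator
) -> tuple[list[int], list[int]]:
    """Endpoint shuffle: m distinct random non-loop edges (degrees free)."""
    max_edges = n_nodes * (n_nodes - 1) // 2
    if m > max_edges:
        raise DomainError(
            f"cannot place {m} simple edges on {n_nodes} nodes"
        )
    present: set[int] = set()
    eu: list[int] = []
    ev: list[int] = []
    while len(eu) < m:
        a = int(rng.integers(0, n_nodes))
        b = int(rng.integers(0, n_nodes))
        if a == b:
            continue
        if a > b:
            a, b = b, a
        key = a * n_nodes + b
        if key in present:
            continue
        present.add(key)
        eu.append(a)
        ev.append(b)
    return eu, ev


def _shuffle_arrays(
    u: np.ndarray,
    v: np.ndarray,
    w: np.ndarray,
    n_nodes: int,
    rng: np.random.Generator,
    swap_factor: int,
    naive: bool,
    strict: bool,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    m = int(u.size)
    if m < 2:
        raise DomainError(
            "need at least 2 edges (including metabolite edges) to shuffle"
        )
    if naive:
        eu, ev = _naive_rewire(m, n_nodes, rng)
    else:
        eu, ev, swaps = _double_edge_swap(
            u, v, n_nodes, rng, swap_factor * m
        )
        if strict and swaps == 0:
            raise DomainError(
                "graph is too small or rigid for any degree-preserving "
                "swap; consider the naive endpoint shuffle (naive=True)"
            )
    w_new = rng.permutation(w)
    return (
        np.asarray(eu, dtype=np.int64),
        np.asarray(ev, dtype=np.int64),
        w_new,
    )


def shuffle_mgdn(
    mgdn: MGDN,
    seed: int,
    swap_factor: int = DEFAULT_SWAP_FACTOR,
    naive: bool = False,
) -> MGDN:
    """Randomize an mGDN's combined edge set; same seed, same output.

    Degree-preserving double-edge swaps (``swap_factor`` x |E| attempts)
    rewire the edges; the weight multiset is preserved and reassigned
    uniformly at random.  With ``naive=True`` edges are instead replaced
    by uniformly random simple edges (degrees not preserved).

    The returned mGDN shares the original node set and gene sets; its
    edges are the randomized ones, so gene-overlap invariants of real
    networks deliberately do not hold for it.
    """
    labels, u, v, w = mgdn.to_arrays()
    n = len(labels)
    rng = np.random.default_rng(seed)
    u2, v2, w2 = _shuffle_arrays(
        u, v, w, n, rng, swap_factor, naive, strict=True
    )
    m_idx = n - 1
    base = mgdn.base
    graph = nx.Graph()
    for node in base.graph.nodes:
        graph.add_node(node, genes=base.gene_sets[node])
    met_edges: dict[str, float] = {}
    for a, b, wt in zip(u2.tolist(), v2.tolist(), w2.tolist()):
        if a == m_idx or b == m_idx:
            d = labels[b if a == m_idx else a]
            met_edges[d] = wt
        else:
            graph.add_edge(labels[a], labels[b], weight=wt)
    shuffled_base = GeneticDiseaseNetwork(
        graph=graph,
        mode=base.mode,
        gene_sets=base.gene_sets,
        effective_sets=base.effective_sets,
        ppi=base.ppi,
        pathways=base.pathways,
        combine=base.combine,
    )
    return MGDN(
        base=shuffled_base,
        metabolite_id=mgdn.metabolite_id,
        metabolite_genes=mgdn.metabolite_genes,
        metabolite_edges=met_edges,
    )


# ---------------------------------------------------------------------------
# significance statistics
# ---------------------------------------------------------------------------


@dataclass
class SignificanceResult:
    """Observed-vs-null comparison for one (metabolite, disease) pair."""

    metabolite_id: str
    disease: str
    observed_percentile: float
    null_percentiles: np.ndarray = field(repr=False)
    null_mean: float = 0.0
    enrichment_fold: float = 0.0
    p_empirical: float = 1.0
    p_ttest: float = 1.0
    n_perm: int = 0
    seed: int = 0

    @property
    def enrichment_percent(self) -> float:
        return self.enrichment_fold * 100.0


def enrichment_fold(
    observed_percentile: float, null_percentiles: Sequence[float]
) -> float:
    """mean(null percentiles) / observed percentile; > 1 beats chance."""
    if observed_percentile <= 0.0:
        raise DomainError(
            f"observed percentile must be > 0, got {observed_percentile}"
        )
    null = np.asarray(null_percentiles, dtype=np.float64)
    if null.size == 0:
        raise DomainError("null percentile list must be non-empty")
    return float(null.mean() / observed_percentile)


def format_enrichment_percent(fold: float) -> str:
    """Render an enrichment fold as a percent string: 3.534 -> '353.4 %'."""
    return f"{fold * 100.0:.1f} %"


def _ttest_pvalue(null: np.ndarray, observed: float) -> float:
    if np.all(null == null[0]):
        return 1.0 if null[0] == observed else 0.0
    return float(stats.ttest_1samp(null, popmean=observed).pvalue)


def _permutation_core(
    labels: Sequence[str],
    u: np.ndarray,
    v: np.ndarray,
    w: np.ndarray,
    metabolite_id: str,
    disease: str,
    n_perm: int,
    restart_prob: float,
    seed: int,
    tol: float,
    max_iter: int,
    swap_factor: int,
    naive: bool,
) -> SignificanceResult:
    n = len(labels)
    m_idx = n - 1
    try:
        d_idx = labels.index(disease)
    except ValueError:
        raise KeyError(f"disease {disease!r} not in the mGDN") from None
    if d_idx == m_idx:
        raise KeyError(f"{disease!r} is the metabolite node, not a disease")
    if n_perm < 1:
        raise ConfigError(f"n_perm must be >= 1, got {n_perm}")

    _, obs_pct = _disease_percentiles(n, u, v, w, restart_prob, tol, max_iter)
    observed = float(obs_pct[d_idx])

    n_d = m_idx
    median_pct = ((n_d + 1) / 2.0) / n_d * 100.0
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm, dtype=np.float64)
    n_disconnected = 0
    for k in range(n_perm):
        u2, v2, w2 = _shuffle_arrays(
            u, v, w, n, rng, swap_factor, naive, strict=False
        )
        if not np.any((u2 == m_idx) | (v2 == m_idx)):
            # only possible under the naive shuffle; assign the median rank
            null[k] = median_pct
            n_disconnected += 1
            continue
        _, pct = _disease_percentiles(
            n, u2, v2, w2, restart_prob, tol, max_iter
        )
        null[k] = pct[d_idx]
    if n_disconnected:
        logger.info(
            "%d/%d shuffled replicates left metabolite %s disconnected; "
            "median rank assigned",
            n_disconnected,
            n_perm,
            metabolite_id,
        )
    null_mean = float(null.mean())
    return SignificanceResult(
        metabolite_id=metabolite_id,
        disease=disease,
        observed_percentile=observed,
        null_percentiles=null,
        null_mean=null_mean,
        enrichment_fold=enrichment_fold(observed, null),
        p_empirical=float((1 + np.sum(null <= observed)) / (1 + n_perm)),
        p_ttest=_ttest_pvalue(null, observed),
        n_perm=n_perm,
        seed=seed,
    )


def permutation_test(
    mgdn: MGDN,
    disease: str,
    n_perm: int = 1000,
    restart_prob: float = DEFAULT_RESTART,
    seed: int = 0,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
    swap_factor: int = DEFAULT_SWAP_FACTOR,
    naive_shuffle: bool = False,
) -> SignificanceResult:
    """Test whether ``disease`` ranks better for the metabolite than chance.

    The observed percentile comes from the real mGDN; ``n_perm``
    randomized mGDNs (edge-shuffled, weights reassigned) are re-ranked
    identically to form the null.
    """
    if not mgdn.metabolite_edges:
        raise DomainError(
            f"metabolite {mgdn.metabolite_id} has no edges; nothing to test"
        )
    labels, u, v, w = mgdn.to_arrays()
    return _permutation_core(
        labels,
        u,
        v,
        w,
        mgdn.metabolite_id,
        disease,
        n_perm,
        restart_prob,
        seed,
        tol,
        max_iter,
        swap_factor,
        naive_shuffle,
    )


def permutation_test_edges(
    edges: Sequence[tuple[str, str, float]],
    metabolite_id: str,
    disease: str,
    n_perm: int = 1000,
    restart_prob: float = DEFAULT_RESTART,
    seed: int = 0,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
    swap_factor: int = DEFAULT_SWAP_FACTOR,
    naive_shuffle: bool = False,
) -> SignificanceResult:
    """``permutation_test`` on a serialized edge list (CLI entry point)."""
    labels: list[str] = []
    index: dict[str, int] = {}
    for a, b, _ in edges:
        for node in (a, b):
            if node != metabolite_id and node not in index:
                index[node] = len(labels)
                labels.append(node)
    m_idx = len(labels)
    index[metabolite_id] = m_idx
    u = np.asarray([index[a] for a, _, _ in edges], dtype=np.int64)
    v = np.asarray([index[b] for _, b, _ in edges], dtype=np.int64)
    w = np.asarray([wt for _, _, wt in edges], dtype=np.float64)
    if not np.any((u == m_idx) | (v == m_idx)):
        raise DomainError(
            f"metabolite {metabolite_id!r} has no edges; nothing to test"
        )
    return _permutation_core(
        labels + [metabolite_id],
        u,
        v,
        w,
        metabolite_id,
        disease,
        n_perm,
        restart_prob,
        seed,
        tol,
        max_iter,
        swap_factor,
        naive_shuffle,
    )


# ---------------------------------------------------------------------------
# profiles across traits
# ---------------------------------------------------------------------------


@dataclass
class MetaboliteProfile:
    """Set of metabolites significantly associated with one trait."""

    trait: str
    significant_metabolites: frozenset[str]

    def __len__(self) -> int:
        return len(self.significant_metabolites)


def build_profiles(
    results: Sequence[SignificanceResult],
    alpha: float = 0.05,
    correction: str = "bh",
    statistic: str = "p_empirical",
) -> list[MetaboliteProfile]:
    """Per trait, the metabolites passing the corrected threshold.

    ``correction`` is one of ``bh`` (Benjamini-Hochberg FDR, default),
    ``bonferroni``, or ``none``; the threshold is applied per trait to
    ``statistic`` (``p_empirical`` or ``p_ttest``).
    """
    if not 0.0 < alpha <= 1.0:
        raise ConfigError(f"alpha must be in (0, 1], got {alpha}")
    if correction not in ("bh", "bonferroni", "none"):
        raise ConfigError(f"unknown correction {correction!r}")
    if statistic not in ("p_empirical", "p_ttest"):
        raise ConfigError(f"unknown statistic {statistic!r}")
    by_trait: dict[str, list[SignificanceResult]] = {}
    for r in results:
        by_trait.setdefault(r.disease, []).append(r)
    profiles: list[MetaboliteProfile] = []
    for trait, rs in by_trait.items():
        pvals = np.asarray([getattr(r, statistic) for r in rs])
        if correction == "bh":
            passed = stats.false_discovery_control(pvals, method="bh") <= alpha
        elif correction == "bonferroni":
            passed = np.minimum(pvals * len(pvals), 1.0) <= alpha
        else:
            passed = pvals <= alpha
        profiles.append(
            MetaboliteProfile(
                trait=trait,
                significant_metabolites=frozenset(
                    r.metabolite_id for r, ok in zip(rs, passed) if ok
                ),
            )
        )
    return profiles


def jaccard(a: set, b: set) -> float:
    """|a & b| / |a | b|; the union must be non-empty."""
    sa, sb = set(a), set(b)
    union = sa | sb
    if not union:
        raise DomainError("Jaccard similarity of two empty sets is undefined")
    return len(sa & sb) / len(union)


def random_overlap_expectation(n1: int, n2: int, total: int) -> float:
    """Expected overlap fraction of two random subsets: (n1/total)(n2/total).

    E.g. profiles of 56 and 62 metabolites out of 171 have random
    expectation (56/171) * (62/171) = 0.1187 (11.9 %).
    """
    if total <= 0:
        raise DomainError(f"total must be positive, got {total}")
    if not (0 <= n1 <= total and 0 <= n2 <= total):
        raise DomainError(
            f"subset sizes must lie in [0, {total}], got {n1} and {n2}"
        )
    return (n1 / total) * (n2 / total)


def profile_jaccard_matrix(
    profiles: Sequence[MetaboliteProfile],
) -> pd.DataFrame:
    """Pairwise Jaccard similarities between trait profiles."""
    traits = [p.trait for p in profiles]
    n = len(profiles)
    mat = np.ones((n, n))
    for i in range(n):
        for j in range(n):
            a = profiles[i].significant_metabolites
            b = profiles[j].significant_metabolites
            mat[i, j] = jaccard(a, b) if (a | b) else 1.0
    return pd.DataFrame(mat, index=traits, columns=traits)


def profile_expectation_matrix(
    profiles: Sequence[MetaboliteProfile], total: int
) -> pd.DataFrame:
    """Random-overlap expectations for each trait pair, given the
    total number of metabolites tested."""
    traits = [p.trait for p in profiles]
    sizes = [len(p) for p in profiles]
    n = len(profiles)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            mat[i, j] = random_overlap_expectation(sizes[i], sizes[j], total)
    return pd.DataFrame(mat, index=traits, columns=traits)
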