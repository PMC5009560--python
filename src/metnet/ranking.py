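"""Disease prioritization by random walk with restart (RWR) on an mGDN.

The walker starts at the metabolite node; at each step it restarts at
the seed with probability ``restart_prob`` and otherwise moves along an
edge with probability proportional to edge weight (column/weighted-
degree normalization, so the score vector remains a probability
distribution at every iteration).  Steady-state visiting probabilities
restricted to the disease nodes define the ranking; ties receive the
average of their ranks and percentiles are rank / n_diseases x 100, so
"top 1.25 %" means rank/total = 0.0125.

Zero-degree nodes contribute no outgoing transitions; their columns
redirect to the seed so probability mass is conserved.  Such isolated
diseases score 0 and rank last.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .errors import ConfigError, ConvergenceError, DomainError
from .network import MGDN

__all__ = [
    "RankedDisease",
    "RankedDiseaseList",
    "rank_diseases",
    "rank_diseases_from_edges",
    "rank_percentile",
]

DEFAULT_RESTART = 0.75
DEFAULT_TOL = 1e-10
DEFAULT_MAX_ITER = 10_000


@dataclass(frozen=True)
class RankedDisease:
    disease: str
    score: float
    rank: float
    percentile: float


@dataclass
class RankedDiseaseList:
    """Diseases ordered by propagation score (descending).

    ``rank`` is fractional: tied scores share the average of the ranks
    they span, so tied diseases get identical percentiles.  The display
    order breaks ties by disease label.  ``metabolite_score`` is the
    steady-state probability retained by the seed node itself; scores
    over all nodes (diseases + metabolite) sum to 1.
    """

    metabolite_id: str
    entries: list[RankedDisease]
    metabolite_score: float

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self) -> Iterator[RankedDisease]:
        return iter(self.entries)

    def entry_of(self, disease: str) -> RankedDisease:
        for e in self.entries:
            if e.disease == disease:
                return e
        raise KeyError(f"disease {disease!r} not in ranked list")

    def percentile_of(self, disease: str) -> float:
        return self.entry_of(disease).percentile

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(e.disease, e.score, e.rank, e.percentile) for e in self.entries],
            columns=["disease", "score", "rank", "percentile"],
        )


# ---------------------------------------------------------------------------
# numerical core (operates on flat edge arrays; shared with significance)
# ---------------------------------------------------------------------------


def _transition_matrix(
    n: int, u: np.ndarray, v: np.ndarray, w: np.ndarray, seed_idx: int
) -> np.ndarray:
    """Column-stochastic transition matrix; dangling columns -> seed."""
    T = np.zeros((n, n), dtype=np.float64)
    np.add.at(T, (v, u), w)
    np.add.at(T, (u, v), w)
    col = T.sum(axis=0)
    live = col > 0.0
    T[:, live] /= col[live]
    T[seed_idx, ~live] = 1.0
    return T


def _rwr_scores(
    T: np.ndarray,
    seed_idx: int,
    restart: float,
    tol: float,
    max_iter: int,
) -> np.ndarray:
    """Power-iterate p <- (1-r) T p + r e until max|dp| < tol."""
    n = T.shape[0]
    p = np.zeros(n, dtype=np.float64)
    p[seed_idx] = 1.0
    damp = 1.0 - restart
    for _ in range(max_iter):
        p_new = damp * (T @ p)
        p_new[seed_idx] += restart
        if np.max(np.abs(p_new - p)) < tol:
            return p_new
        p = p_new
    residual = float(np.max(np.abs(p_new - p)))
    raise ConvergenceError(
        f"restart walk did not converge in {max_iter} iterations "
        f"(residual {residual:.3e} > tol {tol:.1e})"
    )


def _disease_percentiles(
    n_nodes: int,
    u: np.ndarray,
    v: np.ndarray,
    w: np.ndarray,
    restart: float,
    tol: float,
    max_iter: int,
) -> tuple[np.ndarray, np.ndarray]:
    """(scores, percentiles) over disease indices; seed is the last node."""
    seed_idx = n_nodes - 1
    T = _transition_matrix(n_nodes, u, v, w, seed_idx)
    p = _rwr_scores(T, seed_idx, restart, tol, max_iter)
    scores = p[:seed_idx]
    n_d = seed_idx
    ranks = rankdata(-scores, method="average")
    return scores, ranks / n_d * 100.0


def _validate_params(restart_prob: float, tol: float, max_iter: int) -> None:
    if not 0.0 < restart_prob < 1.0:
        raise ConfigError(
            f"restart_prob must be in (0, 1), got {restart_prob}"
        )
    if tol <= 0.0:
        raise ConfigError(f"tolerance must be positive, got {tol}")
    if max_iter < 1:
        raise ConfigError(f"max_iter must be >= 1, got {max_iter}")


def _ranked_list(
    metabolite_id: str,
    labels: Sequence[str],
    scores: np.ndarray,
    percentiles: np.ndarray,
    metabolite_score: float,
) -> RankedDiseaseList:
    n_d = len(labels)
    ranks = rankdata(-scores, method="average")
    order = sorted(range(n_d), key=lambda i: (-scores[i], labels[i]))
    entries = [
        RankedDisease(
            disease=labels[i],
            score=float(scores[i]),
            rank=float(ranks[i]),
            percentile=float(percentiles[i]),
        )
        for i in order
    ]
    return RankedDiseaseList(
        metabolite_id=metabolite_id,
        entries=entries,
        metabolite_score=float(metabolite_score),
    )


# ---------------------------------------------------------------------------
# public API
# ---------------------------------------------------------------------------


def rank_diseases(
    mgdn: MGDN,
    restart_prob: float = DEFAULT_RESTART,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
) -> RankedDiseaseList:
    """Rank all diseases of an mGDN by RWR proximity to the metabolite.

    Raises
    ------
    DomainError
        If the metabolite node has no edges (inspect the gene overlaps
        directly instead of propagating).
    ConvergenceError
        If the iteration does not reach ``tol`` within ``max_iter``.
    """
    _validate_params(restart_prob, tol, max_iter)
    if not mgdn.metabolite_edges:
        raise DomainError(
            f"metabolite {mgdn.metabolite_id} is disconnected from every "
            "disease; propagation is meaningless - inspect gene overlaps "
            "directly"
        )
    labels, u, v, w = mgdn.to_arrays()
    n = len(labels)
    scores, percentiles = _disease_percentiles(
        n, u, v, w, restart_prob, tol, max_iter
    )
    # scores over diseases + metabolite sum to 1
    metabolite_score = 1.0 - float(scores.sum())
    return _ranked_list(
        mgdn.metabolite_id, labels[:-1], scores, percentiles, metabolite_score
    )


def rank_diseases_from_edges(
    edges: Sequence[tuple[str, str, float]],
    metabolite_id: str,
    restart_prob: float = DEFAULT_RESTART,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
) -> RankedDiseaseList:
    """Rank diseases from a serialized weighted edge list.

    Every node other than ``metabolite_id`` is treated as a disease.
    """
    _validate_params(restart_prob, tol, max_iter)
    labels: list[str] = []
    index: dict[str, int] = {}
    for a, b, _ in edges:
        for node in (a, b):
            if node != metabolite_id and node not in index:
                index[node] = len(labels)
                labels.append(node)
    if not labels:
        raise DomainError("edge list contains no disease nodes")
    m_idx = len(labels)
    index[metabolite_id] = m_idx
    if not any(metabolite_id in (a, b) for a, b, _ in edges):
        raise DomainError(
            f"metabolite {metabolite_id!r} has no edges in the graph"
        )
    u = np.asarray([index[a] for a, _, _ in edges], dtype=np.int64)
    v = np.asarray([index[b] for _, b, _ in edges], dtype=np.int64)
    w = np.asarray([wt for _, _, wt in edges], dtype=np.float64)
    scores, percentiles = _disease_percentiles(
        m_idx + 1, u, v, w, restart_prob, tol, max_iter
    )
    return _ranked_list(
        metabolite_id, labels, scores, percentiles, 1.0 - float(scores.sum())
    )


def rank_percentile(ranked: RankedDiseaseList, disease: str) -> float:
    """Rank percentile of ``disease`` in a ranked list (rank/N x 100)."""
    return ranked.percentile_of(disease)
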