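"""Positional-tolerance comparison of two epistatic networks.

Because of linkage disequilibrium, SNPs at nearby positions carry nearly
the same signal, so two networks built from different interaction models
are compared with a base-pair tolerance δ: nodes n1 = (c1, p1) and
n2 = (c2, p2) match when c1 = c2 and |p1 − p2| ≤ δ, and edges match when
their endpoints match pairwise in either orientation.  Matching is
existential — an element counts as matched if *any* element of the other
network matches — and therefore directional: percentages are taken
against the querying network's own totals.

Community similarity is the directional count

    Λ(C_a → C_b)(δ) = Σ_{n ∈ C_a} max_{n' ∈ C_b} f_δ(n, n')

summarized over a δ grid by a trapezoid-style area under the curve,

    AUC = Σ_{k=0..M} [Λ(δ_min + ks) + Λ(δ_min + (k+1)s)] / (2 (M+1)),

with M = (δ_max − δ_min)/s − 1, and normalized by |C_a| so that
AUC_norm ∈ [0, 1].  The default grid is δ = 0..10 Mb in 1 Mb steps.
"""

from __future__ import annotations

from bisect import bisect_left, bisect_right
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .loci import SnpLocus
from .network import CommunityPartition, Edge, EpistaticNetwork

__all__ = [
    "ToleranceMatchResult",
    "MatchReport",
    "SimilarityResult",
    "nodes_match",
    "edges_match",
    "match_report",
    "community_lambda",
    "community_auc",
    "similarity_matrices",
    "DEFAULT_DELTA_GRID",
]

MB = 1_000_000
#: Tables in the field report node/edge overlap at 0..10 Mb in 1 Mb steps.
DEFAULT_DELTA_GRID: tuple[int, ...] = tuple(k * MB for k in range(11))


def nodes_match(n1: SnpLocus, n2: SnpLocus, delta: int) -> bool:
    """True iff same chromosome and positions within δ base pairs (inclusive)."""
    if delta < 0:
        raise ValueError(f"delta must be >= 0, got {delta}")
    return n1.chrom == n2.chrom and abs(n1.pos - n2.pos) <= delta


def edges_match(e_a: Edge, e_b: Edge, delta: int) -> bool:
    """True iff endpoints match pairwise in either orientation."""
    (a1, a2), (b1, b2) = e_a, e_b
    return (nodes_match(a1, b1, delta) and nodes_match(a2, b2, delta)) or (
        nodes_match(a1, b2, delta) and nodes_match(a2, b1, delta)
    )


class _PositionIndex:
    """Per-chromosome sorted positions for O(log n) tolerance queries."""

    def __init__(self, loci: Iterable[SnpLocus]):
        self._by_chrom: dict[str, list[int]] = {}
        for s in loci:
            self._by_chrom.setdefault(s.chrom, []).append(s.pos)
        for positions in self._by_chrom.values():
            positions.sort()

    def has_match(self, locus: SnpLocus, delta: int) -> bool:
        positions = self._by_chrom.get(locus.chrom)
        if not positions:
            return False
        lo = bisect_left(positions, locus.pos - delta)
        return lo < len(positions) and positions[lo] <= locus.pos + delta


@dataclass(frozen=True)
class ToleranceMatchResult:
    """Directional match count for one δ: how many a-elements have a b-match."""

    direction: str  # e.g. "a_to_b"
    delta: int
    matched_count: int
    total_count: int

    @property
    def percentage(self) -> float:
        return 100.0 * self.matched_count / self.total_count if self.total_count else 0.0


@dataclass
class MatchReport:
    """Node and edge tolerance-match tables for both directions."""

    nodes_a_to_b: list[ToleranceMatchResult]
    nodes_b_to_a: list[ToleranceMatchResult]
    edges_a_to_b: list[ToleranceMatchResult]
    edges_b_to_a: list[ToleranceMatchResult]


def _count_node_matches(query: set[SnpLocus], target: _PositionIndex, delta: int) -> int:
    return sum(1 for s in query if target.has_match(s, delta))


def _count_edge_matches(query: Sequence[Edge], target: Sequence[Edge], delta: int) -> int:
    # bucket target edges by sorted chromosome pair to prune comparisons
    buckets: dict[tuple[str, str], list[Edge]] = {}
    for e in target:
        c = tuple(sorted((e[0].chrom, e[1].chrom)))
        buckets.setdefault(c, []).append(e)
    matched = 0
    for e in query:
        c = tuple(sorted((e[0].chrom, e[1].chrom)))
        if any(edges_match(e, f, delta) for f in buckets.get(c, ())):
            matched += 1
    return matched


def match_report(
    net_a: EpistaticNetwork,
    net_b: EpistaticNetwork,
    delta_grid: Sequence[int] = DEFAULT_DELTA_GRID,
) -> MatchReport:
    """Node/edge tolerance matching between two networks over a δ grid."""
    if net_a.n_edges == 0 or net_b.n_edges == 0:
        raise ValueError("both networks must be non-empty")
    nodes_a, nodes_b = net_a.nodes, net_b.nodes
    idx_a, idx_b = _PositionIndex(nodes_a), _PositionIndex(nodes_b)
    edges_a = [k for k, _ in net_a.sorted_edges()]
    edges_b = [k for k, _ in net_b.sorted_edges()]
    rep = MatchReport([], [], [], [])
    for d in delta_grid:
        rep.nodes_a_to_b.append(
            ToleranceMatchResult("a_to_b", d, _count_node_matches(nodes_a, idx_b, d), len(nodes_a))
        )
        rep.nodes_b_to_a.append(
            ToleranceMatchResult("b_to_a", d, _count_node_matches(nodes_b, idx_a, d), len(nodes_b))
        )
        rep.edges_a_to_b.append(
            ToleranceMatchResult("a_to_b", d, _count_edge_matches(edges_a, edges_b, d), len(edges_a))
        )
        rep.edges_b_to_a.append(
            ToleranceMatchResult("b_to_a", d, _count_edge_matches(edges_b, edges_a, d), len(edges_b))
        )
    return rep


def community_lambda(
    C_a: Iterable[SnpLocus], C_b: Iterable[SnpLocus], delta: int
) -> int:
    """Λ(C_a → C_b)(δ): count of C_a nodes with ≥ 1 tolerant match in C_b."""
    ca = set(C_a)
    if not ca:
        raise ValueError("C_a must be non-empty")
    idx = _PositionIndex(C_b)
    return _count_node_matches(ca, idx, delta)


@dataclass
class SimilarityResult:
    """Directional community similarity: Λ over a δ grid, with its AUC."""

    community_a: int | None
    community_b: int | None
    delta_grid: list[int]
    lambda_curve: list[int]
    auc: float
    auc_norm: float


def community_auc(
    C_a: Iterable[SnpLocus],
    C_b: Iterable[SnpLocus],
    delta_min: int = 0,
    delta_max: int = 10 * MB,
    s: int = MB,
) -> SimilarityResult:
    """Area under the Λ(δ) curve on the grid δ_min..δ_max with step s.

    With M = (δ_max − δ_min)/s − 1, the grid has M + 2 values and the sum
    has M + 1 trapezoid terms divided by 2(M + 1); AUC_norm divides by
    |C_a| and lies in [0, 1].
    """
    if s <= 0:
        raise ValueError(f"step s must be > 0, got {s}")
    if delta_max <= delta_min:
        raise ValueError("delta_max must exceed delta_min")
    n_steps = (delta_max - delta_min) / s
    if abs(n_steps - round(n_steps)) > 1e-9:
        raise ValueError("(delta_max - delta_min) must be an integer multiple of s")
    ca = set(C_a)
    if not ca:
        raise ValueError("C_a must be non-empty")
    cb = set(C_b)
    M = int(round(n_steps)) - 1
    grid = [delta_min + k * s for k in range(M + 2)]
    idx = _PositionIndex(cb)
    lam = [_count_node_matches(ca, idx, d) for d in grid]
    auc = sum(lam[k] + lam[k + 1] for k in range(M + 1)) / (2.0 * (M + 1))
    return SimilarityResult(
        community_a=None,
        community_b=None,
        delta_grid=grid,
        lambda_curve=lam,
        auc=auc,
        auc_norm=auc / len(ca),
    )


def similarity_matrices(
    partition_a: CommunityPartition,
    partition_b: CommunityPartition,
    delta_min: int = 0,
    delta_max: int = 10 * MB,
    s: int = MB,
) -> tuple[np.ndarray, np.ndarray]:
    """Directional AUC_norm matrices between two community partitions.

    Entry (i, j) of the first matrix is AUC_norm(C_i of a → C_j of b);
    the second matrix is the reverse direction.  Rows/columns follow the
    partitions' community ids (descending size).  The two matrices are
    not transposes of each other in general.
    """
    comms_a = partition_a.communities()
    comms_b = partition_b.communities()
    if not comms_a or not comms_b:
        raise ValueError("both partitions must be non-empty")
    ab = np.zeros((len(comms_a), len(comms_b)))
    ba = np.zeros((len(comms_b), len(comms_a)))
    for i, ca in enumerate(comms_a):
        for j, cb in enumerate(comms_b):
            ab[i, j] = community_auc(ca, cb, delta_min, delta_max, s).auc_norm
            ba[j, i] = community_auc(cb, ca, delta_min, delta_max, s).auc_norm
    return ab, ba
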