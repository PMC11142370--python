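"""Epistatic network construction, modularity, communities, τ-sweep.

The network ``N = {V, E, τ}`` contains an edge for every tested SNP pair
whose FDR-adjusted p-value ω(e) is ≤ τ; nodes are exactly the endpoints
of surviving edges (SNPs left isolated by the cut do not appear).

Modularity with resolution γ is

    Q = (1 / 2m) Σ_ij [A_ij − γ k_i k_j / 2m] δ(c_i, c_j)

summed over all ordered node pairs including i = j (A_ii = 0).  Community
detection is greedy agglomeration (Clauset–Newman–Moore style): start
from singletons, repeatedly apply the merge with the largest modularity
gain, stop when no merge increases Q.  Ties are broken on the smallest
(community id, community id) pair so results are deterministic.

The edge-weight threshold is chosen by sweeping τ from 0 upward in fixed
increments, recording network metrics and the greedy Q at every grid
point, and keeping the smallest τ that attains the maximum Q.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np

from .loci import SnpLocus
from .scan import EpistasisPair

__all__ = [
    "EpistaticNetwork",
    "NetworkMetrics",
    "CommunityPartition",
    "SweepPoint",
    "ThresholdSweepResult",
    "build_network",
    "network_metrics",
    "modularity",
    "detect_communities",
    "sweep_threshold",
]

Edge = tuple[SnpLocus, SnpLocus]

# tolerance for float drift in ΔQ ties during greedy merging
_W_EPS = 1e-12


def _leq(w: float, tau: float) -> bool:
    """ω(e) ≤ τ with a relative guard for float drift (0 admits only 0)."""
    return w <= tau or math.isclose(w, tau, rel_tol=1e-9)


def _edge_key(a: SnpLocus, b: SnpLocus) -> Edge:
    if a == b:
        raise ValueError(f"self-loop at {a}")
    return (a, b) if a.sort_key <= b.sort_key else (b, a)


@dataclass
class EpistaticNetwork:
    """``N = {V, E, τ}``: weighted undirected SNP-interaction network."""

    edges: dict[Edge, float]
    tau: float

    def __post_init__(self) -> None:
        for (a, b), w in self.edges.items():
            if a == b:
                raise ValueError(f"self-loop at {a}")
            if not _leq(w, self.tau):
                raise ValueError(f"edge weight {w} exceeds tau={self.tau}")

    @property
    def nodes(self) -> set[SnpLocus]:
        out: set[SnpLocus] = set()
        for a, b in self.edges:
            out.add(a)
            out.add(b)
        return out

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def sorted_edges(self) -> list[tuple[Edge, float]]:
        return sorted(
            self.edges.items(), key=lambda kv: (kv[0][0].sort_key, kv[0][1].sort_key)
        )

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        for (a, b), w in self.edges.items():
            g.add_edge(a, b, weight=w)
        return g


@dataclass(frozen=True)
class NetworkMetrics:
    n_nodes: int
    n_edges: int
    n_components: int
    largest_component_size: int
    largest_component_ratio: float
    n_triangles: int


@dataclass
class CommunityPartition:
    """Node → community assignment with its modularity Q.

    Community ids are contiguous from 0, ordered by descending size
    (ties by smallest member locus).
    """

    assignment: dict[SnpLocus, int]
    q: float
    gamma: float = 1.0

    @property
    def n_communities(self) -> int:
        return len(set(self.assignment.values())) if self.assignment else 0

    def communities(self) -> list[set[SnpLocus]]:
        """Member sets indexed by community id."""
        out: list[set[SnpLocus]] = [set() for _ in range(self.n_communities)]
        for node, cid in self.assignment.items():
            out[cid].add(node)
        return out


@dataclass(frozen=True)
class SweepPoint:
    tau: float
    metrics: NetworkMetrics
    q: float


@dataclass
class ThresholdSweepResult:
    grid: list[SweepPoint]
    tau_star: float
    tau_triangle_onset: float | None


def collapse_pairs(pairs: Iterable[EpistasisPair]) -> dict[Edge, float]:
    """Unordered pair → weight map, duplicates collapsed to the smallest weight."""
    weights: dict[Edge, float] = {}
    for p in pairs:
        k = p.key
        w = p.p_adj
        if k not in weights or w < weights[k]:
            weights[k] = w
    return weights


def build_network(pairs: Sequence[EpistasisPair], tau: float) -> EpistaticNetwork:
    """Threshold a pair table: keep edges with ω(e) ≤ τ (inclusive)."""
    if tau < 0:
        raise ValueError(f"tau must be >= 0, got {tau}")
    if not pairs:
        raise ValueError("empty pair list")
    weights = collapse_pairs(pairs)
    kept = {k: w for k, w in weights.items() if _leq(w, tau)}
    return EpistaticNetwork(edges=kept, tau=tau)


def network_metrics(net: EpistaticNetwork) -> NetworkMetrics:
    """Component and triangle census of the network."""
    g = net.to_networkx()
    n = g.number_of_nodes()
    if n == 0:
        return NetworkMetrics(0, 0, 0, 0, 0.0, 0)
    comps = list(nx.connected_components(g))
    largest = max(len(c) for c in comps)
    n_tri = sum(nx.triangles(g).values()) // 3
    return NetworkMetrics(
        n_nodes=n,
        n_edges=g.number_of_edges(),
        n_components=len(comps),
        largest_component_size=largest,
        largest_component_ratio=largest / n,
        n_triangles=n_tri,
    )


def modularity(
    net: EpistaticNetwork,
    partition: CommunityPartition | Mapping[SnpLocus, int],
    gamma: float = 1.0,
) -> float:
    """Modularity Q of a partition, evaluated from the definition.

    The sum runs over all ordered node pairs, including i = j with
    A_ii = 0 (the diagonal contributes the −γ k_i²/2m null term).
    """
    assignment = (
        partition.assignment if isinstance(partition, CommunityPartition) else dict(partition)
    )
    nodes = sorted(net.nodes, key=lambda s: s.sort_key)
    missing = [v for v in nodes if v not in assignment]
    if missing:
        raise ValueError(f"{len(missing)} network node(s) missing from partition")
    m = net.n_edges
    if m == 0:
        return 0.0
    index = {v: i for i, v in enumerate(nodes)}
    n = len(nodes)
    A = np.zeros((n, n))
    for a, b in net.edges:
        i, j = index[a], index[b]
        A[i, j] = A[j, i] = 1.0
    k = A.sum(axis=1)
    comm = np.array([assignment[v] for v in nodes])
    same = comm[:, None] == comm[None, :]
    B = A - gamma * np.outer(k, k) / (2.0 * m)
    return float(B[same].sum() / (2.0 * m))


def _modularity_fast(
    edges: Iterable[Edge], assignment: Mapping[SnpLocus, int], gamma: float
) -> float:
    """Per-community form Σ_c [l_c/m − γ (d_c/2m)²]; equals the definition."""
    m = 0
    intra: dict[int, int] = {}
    deg: dict[int, int] = {}
    for a, b in edges:
        m += 1
        ca, cb = assignment[a], assignment[b]
        deg[ca] = deg.get(ca, 0) + 1
        deg[cb] = deg.get(cb, 0) + 1
        if ca == cb:
            intra[ca] = intra.get(ca, 0) + 1
    if m == 0:
        return 0.0
    q = 0.0
    for c, d in deg.items():
        q += intra.get(c, 0) / m - gamma * (d / (2.0 * m)) ** 2
    return q


def detect_communities(net: EpistaticNetwork, gamma: float = 1.0) -> CommunityPartition:
    """Greedy (CNM) modularity maximization.

    Starts from singleton communities and repeatedly merges the pair of
    connected communities with the maximal ΔQ, stopping when no merge
    increases Q.  Equal-gain merges take the lexicographically smallest
    community-id pair, so the outcome is deterministic.
    """
    if net.n_edges == 0:
        raise ValueError("cannot detect communities in an empty network")
    nodes = sorted(net.nodes, key=lambda s: s.sort_key)
    node_id = {v: i for i, v in enumerate(nodes)}
    m = net.n_edges
    gamma = float(gamma)

    members: dict[int, set[int]] = {i: {i} for i in range(len(nodes))}
    deg: dict[int, int] = {i: 0 for i in range(len(nodes))}
    # links[u][v] = number of edges between communities u and v (u != v)
    links: dict[int, dict[int, int]] = {i: {} for i in range(len(nodes))}
    for a, b in net.edges:
        u, v = node_id[a], node_id[b]
        deg[u] += 1
        deg[v] += 1
        links[u][v] = links[u].get(v, 0) + 1
        links[v][u] = links[v].get(u, 0) + 1

    while True:
        best: tuple[float, int, int] | None = None
        for u in sorted(links):
            for v in sorted(links[u]):
                if v <= u:
                    continue
                dq = links[u][v] / m - gamma * deg[u] * deg[v] / (2.0 * m * m)
                if best is None or dq > best[0] + _W_EPS:
                    best = (dq, u, v)
                # equal gains keep the earlier (smaller) id pair: the sorted
                # iteration order already visits (u, v) in lexicographic order
        if best is None or best[0] <= _W_EPS:
            break
        _, u, v = best
        members[u] |= members.pop(v)
        deg[u] += deg.pop(v)
        v_links = links.pop(v)
        for w, cnt in v_links.items():
            if w == v:
                continue
            links[w].pop(v, None)
            if w == u:
                continue
            links[u][w] = links[u].get(w, 0) + cnt
            links[w][u] = links[w].get(u, 0) + cnt
        links[u].pop(v, None)
        links[u].pop(u, None)

    # relabel: descending size, ties by smallest member locus
    groups = sorted(
        members.values(),
        key=lambda s: (-len(s), min(nodes[i].sort_key for i in s)),
    )
    assignment: dict[SnpLocus, int] = {}
    for cid, group in enumerate(groups):
        for i in group:
            assignment[nodes[i]] = cid
    q = _modularity_fast(net.edges.keys(), assignment, gamma)
    return CommunityPartition(assignment=assignment, q=q, gamma=gamma)


def sweep_threshold(
    pairs: Sequence[EpistasisPair],
    step: float = 0.0001,
    gamma: float = 1.0,
) -> ThresholdSweepResult:
    """Sweep τ over a fixed grid and pick the modularity-maximizing cut.

    The grid starts at 0 and rises in ``step`` increments up to the first
    grid point at or above the largest observed weight, so the final
    network contains every input pair.  The empty network is recorded with
    Q = 0.  ``tau_star`` is the smallest grid τ attaining the maximum Q;
    ``tau_triangle_onset`` is the smallest grid τ with at least one
    triangle (None if triangles never appear).
    """
    if not pairs:
        raise ValueError("empty pair list")
    if step <= 0:
        raise ValueError(f"step must be > 0, got {step}")
    weights = collapse_pairs(pairs)
    sorted_w = np.sort(np.fromiter(weights.values(), dtype=float))
    edges_sorted = sorted(weights.items(), key=lambda kv: kv[1])
    max_w = float(sorted_w[-1])
    n_steps = max(0, math.ceil(max_w / step - _W_EPS))
    grid = [round(k * step, 10) for k in range(n_steps + 1)]

    cache: dict[int, tuple[NetworkMetrics, float]] = {}
    points: list[SweepPoint] = []
    for tau in grid:
        n_edges = int(np.searchsorted(sorted_w, tau * (1.0 + 1e-9), side="right"))
        if n_edges not in cache:
            kept = dict(edges_sorted[:n_edges])
            net = EpistaticNetwork(edges=kept, tau=tau if kept else 0.0)
            met = network_metrics(net)
            q = detect_communities(net, gamma).q if n_edges else 0.0
            cache[n_edges] = (met, q)
        met, q = cache[n_edges]
        points.append(SweepPoint(tau=tau, metrics=met, q=q))

    q_max = max(p.q for p in points)
    tau_star = next(p.tau for p in points if p.q == q_max)
    tau_tri = next((p.tau for p in points if p.metrics.n_triangles > 0), None)
    return ThresholdSweepResult(grid=points, tau_star=tau_star, tau_triangle_onset=tau_tri)
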