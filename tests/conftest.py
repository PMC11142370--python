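import numpy as np
import pytest

from epinet.loci import SnpLocus
from epinet.network import EpistaticNetwork


def make_network(edges, tau=0.05, weight=0.01):
    """Build a network from (locus, locus) tuples or (locus, locus, w) triples."""
    ed = {}
    for e in edges:
        a, b = e[0], e[1]
        w = e[2] if len(e) > 2 else weight
        key = (a, b) if a.sort_key <= b.sort_key else (b, a)
        ed[key] = w
    return EpistaticNetwork(edges=ed, tau=tau)


def loci_on(chrom, positions):
    return [SnpLocus(str(chrom), int(p)) for p in positions]


def cycle_edges(nodes):
    n = len(nodes)
    return [(nodes[i], nodes[(i + 1) % n]) for i in range(n)]


def clique_edges(nodes):
    return [(a, b) for i, a in enumerate(nodes) for b in nodes[i + 1 :]]


@pytest.fixture
def two_cycles_net():
    """Two disjoint 3-cycles on separate chromosomes; optimal Q = 0.5."""
    c1 = loci_on(1, (100, 200, 300))
    c2 = loci_on(2, (100, 200, 300))
    return make_network(cycle_edges(c1) + cycle_edges(c2)), c1, c2


@pytest.fixture
def bridged_cliques_net():
    """Two 4-cliques joined by a single bridge edge; communities = cliques."""
    c1 = loci_on(1, (100, 200, 300, 400))
    c2 = loci_on(2, (100, 200, 300, 400))
    edges = clique_edges(c1) + clique_edges(c2) + [(c1[0], c2[0])]
    return make_network(edges), c1, c2


def exhaustive_best_partition(net, gamma=1.0):
    """Exhaustive search over all set partitions; independent modularity oracle.

    Only feasible for <= ~10 nodes (Bell numbers).  Modularity is computed
    from first principles here, not via the package.
    """
    nodes = sorted(net.nodes, key=lambda s: s.sort_key)
    edges = list(net.edges)
    m = len(edges)
    deg = {v: 0 for v in nodes}
    for a, b in edges:
        deg[a] += 1
        deg[b] += 1

    def q_of(groups):
        q = 0.0
        for g in groups:
            gs = set(g)
            l_c = sum(1 for a, b in edges if a in gs and b in gs)
            d_c = sum(deg[v] for v in gs)
            q += l_c / m - gamma * (d_c / (2.0 * m)) ** 2
        return q

    def partitions(items):
        if not items:
            yield []
            return
        first, rest = items[0], items[1:]
        for part in partitions(rest):
            for i in range(len(part)):
                yield part[:i] + [[first] + part[i]] + part[i + 1 :]
            yield [[first]] + part

    best_q, best_part = -2.0, None
    for part in partitions(nodes):
        q = q_of(part)
        if q > best_q:
            best_q, best_part = q, part
    return best_q, best_part
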