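"""Triangle motifs and higher-order epistasis prioritization.

A triangle — three SNPs whose three pairwise interactions all survive the
edge-weight cut — is a structural candidate for genuine three-way
epistasis.  Triangles are enumerated, classified by how their loci spread
over chromosomes (three co-located SNPs on one chromosome are more likely
a linkage-disequilibrium artifact than true trans interaction), and then
re-tested with an explicit three-way interaction model; BH-FDR is applied
across the triangle set only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import networkx as nx

from .loci import SnpLocus
from .network import EpistaticNetwork
from .scan import bh_adjust, threeway_test
from .synth import GenotypeMatrix, PhenotypeVector

__all__ = [
    "TriangleRecord",
    "enumerate_triangles",
    "classify_triangle",
    "test_triangles",
    "significant_triangle_multigraph",
    "DEFAULT_PROXIMITY_BP",
]

logger = logging.getLogger(__name__)

#: Span (bp) under which a single-chromosome triangle is flagged cis/LD-like.
DEFAULT_PROXIMITY_BP = 2_000_000


@dataclass(frozen=True)
class TriangleRecord:
    """One triangle: loci (sorted), edge weights, chromosomal dispersion."""

    snps: tuple[SnpLocus, SnpLocus, SnpLocus]
    edge_weights: tuple[float, float, float]
    chrom_pattern: str  # all_same_chromosome | two_shared | all_different
    span: int | None  # max pairwise bp distance when on one chromosome
    p3_raw: float | None = None
    p3_adj: float | None = None
    significant: bool = False


def _chrom_pattern(snps: tuple[SnpLocus, SnpLocus, SnpLocus]) -> tuple[str, int | None]:
    chroms = {s.chrom for s in snps}
    if len(chroms) == 1:
        span = max(s.pos for s in snps) - min(s.pos for s in snps)
        return "all_same_chromosome", span
    if len(chroms) == 2:
        return "two_shared", None
    return "all_different", None


def enumerate_triangles(net: EpistaticNetwork) -> list[TriangleRecord]:
    """All unordered node triples with three edges present, each listed once.

    Output is deterministically ordered by the sorted locus keys of each
    triangle.
    """
    g = net.to_networkx()
    order = {v: v.sort_key for v in g.nodes}
    records: list[TriangleRecord] = []
    for u in g.nodes:
        for v in g.neighbors(u):
            if order[v] <= order[u]:
                continue
            for w in g.neighbors(v):
                if order[w] <= order[v] or not g.has_edge(u, w):
                    continue
                snps = (u, v, w)
                weights = (
                    g[u][v]["weight"],
                    g[u][w]["weight"],
                    g[v][w]["weight"],
                )
                pattern, span = _chrom_pattern(snps)
                records.append(
                    TriangleRecord(
                        snps=snps, edge_weights=weights, chrom_pattern=pattern, span=span
                    )
                )
    records.sort(key=lambda r: tuple(s.sort_key for s in r.snps))
    return records


def classify_triangle(
    tri: TriangleRecord, proximity_bp: int = DEFAULT_PROXIMITY_BP
) -> tuple[str, bool]:
    """Chromosome-dispersion pattern plus a cis flag.

    ``cis_flag`` is true iff all three loci share a chromosome and their
    span is at most ``proximity_bp`` — the signature of an LD-driven
    (likely false-positive) triangle rather than trans epistasis.
    """
    if proximity_bp < 0:
        raise ValueError(f"proximity_bp must be >= 0, got {proximity_bp}")
    cis = tri.chrom_pattern == "all_same_chromosome" and tri.span is not None and tri.span <= proximity_bp
    return tri.chrom_pattern, cis


def test_triangles(
    tris: list[TriangleRecord],
    G: GenotypeMatrix,
    y: PhenotypeVector,
    encoding: str = "xor",
    alpha: float = 0.05,
) -> list[TriangleRecord]:
    """Three-way test of every triangle, BH-adjusted across the triangle set.

    Triangles whose loci cannot be resolved to genotype columns are
    skipped with a warning and excluded from the BH family.  Returns new
    records with ``p3_raw``/``p3_adj`` filled and ``significant`` set
    where ``p3_adj < alpha``.
    """
    tested: list[TriangleRecord] = []
    raws: list[float] = []
    for tri in tris:
        try:
            cols = [G.column(s) for s in tri.snps]
        except KeyError as err:
            logger.warning("skipping triangle %s: %s", tri.snps, err)
            continue
        res = threeway_test(y, *cols, encoding=encoding)
        tested.append(tri)
        raws.append(res.p)
    if not tested:
        return []
    adj = bh_adjust(raws)
    return [
        replace(tri, p3_raw=float(p), p3_adj=float(a), significant=bool(a < alpha))
        for tri, p, a in zip(tested, raws, adj)
    ]


def significant_triangle_multigraph(tris: list[TriangleRecord]) -> nx.MultiGraph:
    """Multigraph of significant triangles: one parallel edge per containing
    triangle, so node pairs shared by several triangles show multiplicity."""
    g = nx.MultiGraph()
    for t, tri in enumerate(tris):
        if not tri.significant:
            continue
        a, b, c = tri.snps
        for u, v in ((a, b), (a, c), (b, c)):
            g.add_edge(u, v, triangle=t)
    return g
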