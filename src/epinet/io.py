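"""Readers and writers for pair tables, genotype/phenotype matrices,
networks, sweep results, similarity matrices and enrichment query ranges.

All formats are plain text (TSV, GraphML, JSON) with deterministic,
locus-sorted ordering so identical inputs always produce byte-identical
files.  Coordinates are 1-based inclusive base pairs throughout.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .compare import MatchReport
from .loci import SnpLocus, format_snp_id, parse_snp_id
from .network import (
    EpistaticNetwork,
    ThresholdSweepResult,
    _edge_key,
)
from .scan import EpistasisPair
from .synth import MISSING, GenotypeMatrix, PhenotypeVector

__all__ = [
    "PairTableDialect",
    "RangeQuery",
    "read_pairs",
    "write_pairs",
    "read_genotypes",
    "write_genotypes",
    "read_phenotype",
    "write_phenotype",
    "export_network",
    "read_network",
    "export_sweep",
    "export_similarity",
    "export_gprofiler_ranges",
    "write_ranges",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PairTableDialect:
    """Column names, SNP id syntax and delimiter of a pair-table file."""

    col_a: str = "snp_a"
    col_b: str = "snp_b"
    col_p_adj: str = "p_adj"
    col_p_raw: str | None = "p_raw"
    id_style: str = "dot"  # "dot" -> chr1.281788173, "colon" -> 1:281788173
    delimiter: str = "\t"


DEFAULT_DIALECT = PairTableDialect()


@dataclass(frozen=True)
class RangeQuery:
    """A ``{chromosome}:{start}:{end}`` genomic range (1-based, inclusive)."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 1:
            raise ValueError(f"start must be >= 1, got {self.start}")
        if self.end <= self.start:
            raise ValueError(f"end must exceed start: {self.start}..{self.end}")

    def __str__(self) -> str:
        return f"{self.chrom}:{self.start}:{self.end}"


def read_pairs(
    path: str | Path,
    dialect: PairTableDialect = DEFAULT_DIALECT,
    encoding_label: str = "unknown",
) -> list[EpistasisPair]:
    """Read a pair table; duplicates collapse to the minimum weight."""
    path = Path(path)
    df = pd.read_csv(path, sep=dialect.delimiter)
    for col in (dialect.col_a, dialect.col_b, dialect.col_p_adj):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    have_raw = dialect.col_p_raw is not None and dialect.col_p_raw in df.columns
    best: dict[tuple[SnpLocus, SnpLocus], tuple[float, float]] = {}
    for row_no, row in enumerate(df.itertuples(index=False), start=2):
        rec = row._asdict() if hasattr(row, "_asdict") else dict(zip(df.columns, row))
        try:
            a = parse_snp_id(str(rec[dialect.col_a]))
            b = parse_snp_id(str(rec[dialect.col_b]))
        except ValueError as err:
            raise ValueError(f"{path}, line {row_no}: {err}") from None
        p_adj = float(rec[dialect.col_p_adj])
        p_raw = float(rec[dialect.col_p_raw]) if have_raw else p_adj
        for label, v in (("p_adj", p_adj), ("p_raw", p_raw)):
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{path}, line {row_no}: {label}={v} outside [0, 1]")
        key = (a, b) if a.sort_key <= b.sort_key else (b, a)
        if key in best:
            logger.warning("%s, line %d: duplicate pair %s/%s collapsed", path, row_no, a, b)
            if p_adj < best[key][1]:
                best[key] = (p_raw, p_adj)
        else:
            best[key] = (p_raw, p_adj)
    return [
        EpistasisPair(snp_a=a, snp_b=b, p_raw=pr, p_adj=pa, encoding=encoding_label)
        for (a, b), (pr, pa) in sorted(
            best.items(), key=lambda kv: (kv[0][0].sort_key, kv[0][1].sort_key)
        )
    ]


def write_pairs(
    pairs: list[EpistasisPair],
    path: str | Path,
    dialect: PairTableDialect = DEFAULT_DIALECT,
) -> None:
    rows = []
    for p in sorted(pairs, key=lambda e: (e.p_adj, e.key[0].sort_key, e.key[1].sort_key)):
        a, b = p.key
        row = {
            dialect.col_a: format_snp_id(a, dialect.id_style),
            dialect.col_b: format_snp_id(b, dialect.id_style),
        }
        if dialect.col_p_raw is not None:
            row[dialect.col_p_raw] = p.p_raw
        row[dialect.col_p_adj] = p.p_adj
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep=dialect.delimiter, index=False)


def write_genotypes(G: GenotypeMatrix, path: str | Path) -> None:
    """TSV matrix: first column individual id, then one column per SNP id."""
    ids = G.individual_ids or [f"ind{i}" for i in range(G.n_individuals)]
    df = pd.DataFrame(
        G.codes,
        columns=[format_snp_id(s, "colon") for s in G.loci],
        index=pd.Index(ids, name="individual"),
    )
    df = df.astype(object).mask(df == MISSING, "NA")
    df.to_csv(path, sep="\t")


def read_genotypes(path: str | Path) -> GenotypeMatrix:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str, keep_default_na=False)
    loci = [parse_snp_id(c) for c in df.columns]
    codes = np.empty(df.shape, dtype=np.int8)
    values = df.to_numpy()
    for i in range(values.shape[0]):
        for j in range(values.shape[1]):
            v = values[i, j].strip()
            if v in ("NA", ""):
                codes[i, j] = MISSING
            elif v in ("0", "1", "2"):
                codes[i, j] = int(v)
            else:
                raise ValueError(f"{path}, row {i + 2}: invalid genotype code {v!r}")
    return GenotypeMatrix(loci=loci, codes=codes, individual_ids=list(df.index.astype(str)))


def write_phenotype(y: PhenotypeVector, individual_ids: list[str], path: str | Path) -> None:
    pd.DataFrame(
        {y.trait_name: y.values}, index=pd.Index(individual_ids, name="individual")
    ).to_csv(path, sep="\t")


def read_phenotype(
    path: str | Path, individual_ids: list[str] | None = None
) -> PhenotypeVector:
    """Read a phenotype TSV; if *individual_ids* is given, the file's ids
    must match it exactly (alignment error otherwise)."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.shape[1] != 1:
        raise ValueError(f"{path}: expected exactly one trait column, got {df.shape[1]}")
    if individual_ids is not None and list(df.index.astype(str)) != list(individual_ids):
        raise ValueError(f"{path}: individual ids do not align with genotype matrix")
    return PhenotypeVector(values=df.iloc[:, 0].to_numpy(float), trait_name=str(df.columns[0]))


def export_network(net: EpistaticNetwork, path: str | Path, fmt: str = "tsv") -> None:
    """Write a network as an edge-list TSV or GraphML (locus-sorted)."""
    path = Path(path)
    if fmt == "tsv":
        rows = [
            {
                "snp_a": format_snp_id(a, "colon"),
                "snp_b": format_snp_id(b, "colon"),
                "weight": w,
            }
            for (a, b), w in net.sorted_edges()
        ]
        df = pd.DataFrame(rows, columns=["snp_a", "snp_b", "weight"])
        with open(path, "w") as fh:
            fh.write(f"# tau={net.tau!r}\n")
            df.to_csv(fh, sep="\t", index=False)
    elif fmt == "graphml":
        g = nx.Graph(tau=net.tau)
        for (a, b), w in net.sorted_edges():
            for s in (a, b):
                g.add_node(str(s), chromosome=s.chrom, position=s.pos)
            g.add_edge(str(a), str(b), weight=w)
        nx.write_graphml(g, path)
    else:
        raise ValueError(f"unknown network format: {fmt!r}")


def read_network(path: str | Path) -> EpistaticNetwork:
    """Read an edge-list TSV written by :func:`export_network`."""
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
        if not first.startswith("# tau="):
            raise ValueError(f"{path}: missing '# tau=' header line")
        tau = float(first.split("=", 1)[1])
        df = pd.read_csv(fh, sep="\t")
    edges = {}
    for _, row in df.iterrows():
        a, b = parse_snp_id(row["snp_a"]), parse_snp_id(row["snp_b"])
        edges[_edge_key(a, b)] = float(row["weight"])
    return EpistaticNetwork(edges=edges, tau=tau)


def export_sweep(sweep: ThresholdSweepResult, path: str | Path) -> None:
    """One row per grid τ with metrics and modularity."""
    rows = [
        {
            "tau": p.tau,
            "n_nodes": p.metrics.n_nodes,
            "n_edges": p.metrics.n_edges,
            "n_components": p.metrics.n_components,
            "largest_component_size": p.metrics.largest_component_size,
            "largest_component_ratio": p.metrics.largest_component_ratio,
            "n_triangles": p.metrics.n_triangles,
            "modularity": p.q,
        }
        for p in sweep.grid
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def export_similarity(
    matrix_ab: np.ndarray, matrix_ba: np.ndarray, path_prefix: str | Path
) -> None:
    """Write both directional AUC_norm matrices as TSV plus a JSON bundle."""
    prefix = Path(path_prefix)
    for name, mat in (("a_to_b", matrix_ab), ("b_to_a", matrix_ba)):
        pd.DataFrame(
            mat,
            index=[f"community_{i}" for i in range(mat.shape[0])],
            columns=[f"community_{j}" for j in range(mat.shape[1])],
        ).to_csv(prefix.with_suffix(f".{name}.tsv"), sep="\t")
    with open(prefix.with_suffix(".json"), "w") as fh:
        json.dump(
            {"a_to_b": matrix_ab.tolist(), "b_to_a": matrix_ba.tolist()},
            fh,
            indent=2,
            sort_keys=True,
        )


def export_match_report(report: MatchReport, path: str | Path) -> None:
    rows = []
    for kind, results in (
        ("nodes", report.nodes_a_to_b),
        ("nodes", report.nodes_b_to_a),
        ("edges", report.edges_a_to_b),
        ("edges", report.edges_b_to_a),
    ):
        for r in results:
            rows.append(
                {
                    "kind": kind,
                    "direction": r.direction,
                    "delta_bp": r.delta,
                    "matched": r.matched_count,
                    "total": r.total_count,
                    "percentage": r.percentage,
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def export_gprofiler_ranges(
    snps: list[SnpLocus], flank: int = 1_000_000
) -> list[RangeQuery]:
    """One ``{c}:{start}:{end}`` range per SNP, ± *flank* bp, start clamped at 1.

    Degenerate ranges (end ≤ start, e.g. flank = 0) are skipped with a
    per-SNP warning.
    """
    if flank < 0:
        raise ValueError(f"flank must be >= 0, got {flank}")
    out: list[RangeQuery] = []
    for s in sorted(set(snps), key=lambda x: x.sort_key):
        start = max(1, s.pos - flank)
        end = s.pos + flank
        if end <= start:
            warnings.warn(f"degenerate range for SNP {s} (flank={flank}); skipped", UserWarning)
            continue
        out.append(RangeQuery(chrom=s.chrom, start=start, end=end))
    return out


def write_ranges(ranges: list[RangeQuery], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in ranges:
            fh.write(f"{r}\n")
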