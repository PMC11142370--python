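"""Exhaustive pairwise (and targeted three-way) epistasis scanning.

Each candidate pair is tested by ordinary least squares on
``y ~ intercept + g1 + g2 + code(g1, g2)``; the reported p-value is the
two-sided t-test on the interaction-code coefficient.  Three-way tests
add the three main effects, the three pairwise codes and the three-locus
code, and test the latter.  Raw p-values of a scan are adjusted together
by Benjamini–Hochberg FDR; the adjusted p-value is the edge weight used
downstream when networks are built.

Rank-deficient designs (constant genotype column, code collinear with the
main effects) are reported as degenerate with p = 1 rather than raised,
so a genome-wide scan never aborts on a single bad pair.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .loci import SnpLocus
from .synth import (
    MISSING,
    PAIR_CODES,
    TRIPLE_CODES,
    GenotypeMatrix,
    PhenotypeVector,
)

__all__ = [
    "TestResult",
    "EpistasisPair",
    "TripleResult",
    "maf_filter",
    "empirical_maf",
    "interaction_test",
    "threeway_test",
    "bh_adjust",
    "pairwise_scan",
]

logger = logging.getLogger(__name__)

MIN_COMPLETE = 10  # minimum pairwise-complete individuals for a test


class TestResult(NamedTuple):
    """Raw p-value for one interaction coefficient, with a degeneracy flag."""

    p: float
    degenerate: bool


@dataclass(frozen=True)
class EpistasisPair:
    """A tested SNP pair; ``p_adj`` is the edge weight ω(e) downstream."""

    snp_a: SnpLocus
    snp_b: SnpLocus
    p_raw: float
    p_adj: float
    encoding: str
    significant: bool = False

    def __post_init__(self) -> None:
        if self.snp_a == self.snp_b:
            raise ValueError("a pair must involve two distinct loci")
        for v in (self.p_raw, self.p_adj):
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"p-value outside [0, 1]: {v}")

    @property
    def key(self) -> tuple[SnpLocus, SnpLocus]:
        """Unordered pair as a sorted tuple."""
        a, b = self.snp_a, self.snp_b
        return (a, b) if a.sort_key <= b.sort_key else (b, a)


@dataclass(frozen=True)
class TripleResult:
    """A tested SNP triple with its three-way interaction p-values."""

    snps: tuple[SnpLocus, SnpLocus, SnpLocus]
    p_raw: float
    p_adj: float
    encoding: str
    significant: bool = False

    def __post_init__(self) -> None:
        if len(set(self.snps)) != 3:
            raise ValueError("a triple must involve three distinct loci")
        for v in (self.p_raw, self.p_adj):
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"p-value outside [0, 1]: {v}")


def empirical_maf(column: np.ndarray) -> float:
    """Empirical minor-allele frequency of one genotype column (missing ignored)."""
    obs = column[column != MISSING]
    if obs.size == 0:
        return 0.0
    q = obs.mean() / 2.0
    return float(min(q, 1.0 - q))


def maf_filter(G: GenotypeMatrix, min_maf: float = 0.05) -> GenotypeMatrix:
    """Drop columns with empirical MAF below ``min_maf`` (inclusive boundary).

    Column order is preserved.  An empty result is returned with a warning,
    not an error, so callers can decide how to proceed.
    """
    if not 0 <= min_maf < 0.5:
        raise ValueError(f"min_maf must be in [0, 0.5), got {min_maf}")
    keep = [j for j in range(G.n_snps) if empirical_maf(G.codes[:, j]) >= min_maf]
    if not keep:
        warnings.warn("MAF filter removed every SNP", UserWarning, stacklevel=2)
    return GenotypeMatrix(
        loci=[G.loci[j] for j in keep],
        codes=G.codes[:, keep],
        individual_ids=G.individual_ids,
    )


def _ols_last_coef_p(X: np.ndarray, y: np.ndarray) -> TestResult:
    """Two-sided p for the last column's coefficient in an OLS fit.

    Direct normal-equations solve; flags rank deficiency or a zero
    standard error as degenerate (p = 1).
    """
    n, k = X.shape
    if n <= k:
        return TestResult(1.0, True)
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < k:
        return TestResult(1.0, True)
    resid = y - X @ beta
    dof = n - k
    sigma2 = float(resid @ resid) / dof
    xtx_inv = np.linalg.inv(X.T @ X)
    var_last = sigma2 * xtx_inv[-1, -1]
    if not np.isfinite(var_last) or var_last <= 0:
        return TestResult(1.0, True)
    t = beta[-1] / np.sqrt(var_last)
    p = 2.0 * stats.t.sf(abs(t), dof)
    return TestResult(float(min(p, 1.0)), False)


def _complete_mask(y: np.ndarray, *columns: np.ndarray) -> np.ndarray:
    mask = np.isfinite(y)
    for c in columns:
        mask &= c != MISSING
    return mask


def interaction_test(
    y: PhenotypeVector | np.ndarray,
    g1: np.ndarray,
    g2: np.ndarray,
    encoding: str = "cartesian",
) -> TestResult:
    """Test one SNP pair for interaction under the given encoding.

    Fits ``y ~ 1 + g1 + g2 + code(g1, g2)`` on pairwise-complete rows and
    returns the two-sided p-value for the code coefficient.  Symmetric in
    (g1, g2) because both codes are.
    """
    yv = np.asarray(y.values if isinstance(y, PhenotypeVector) else y, dtype=float)
    g1 = np.asarray(g1)
    g2 = np.asarray(g2)
    mask = _complete_mask(yv, g1, g2)
    if mask.sum() < MIN_COMPLETE:
        raise ValueError(
            f"need >= {MIN_COMPLETE} pairwise-complete individuals, have {int(mask.sum())}"
        )
    a, b, yy = g1[mask], g2[mask], yv[mask]
    code = PAIR_CODES[encoding](a, b)
    X = np.column_stack([np.ones(a.size), a, b, code]).astype(float)
    return _ols_last_coef_p(X, yy)


def threeway_test(
    y: PhenotypeVector | np.ndarray,
    g1: np.ndarray,
    g2: np.ndarray,
    g3: np.ndarray,
    encoding: str = "cartesian",
) -> TestResult:
    """Test one SNP triple for three-way interaction.

    Fits ``y ~ 1 + g1 + g2 + g3 + code(g1,g2) + code(g1,g3) + code(g2,g3)
    + code3(g1,g2,g3)`` and returns the p-value for the three-way term.
    """
    yv = np.asarray(y.values if isinstance(y, PhenotypeVector) else y, dtype=float)
    g1, g2, g3 = np.asarray(g1), np.asarray(g2), np.asarray(g3)
    mask = _complete_mask(yv, g1, g2, g3)
    if mask.sum() < MIN_COMPLETE:
        raise ValueError(
            f"need >= {MIN_COMPLETE} pairwise-complete individuals, have {int(mask.sum())}"
        )
    a, b, c, yy = g1[mask], g2[mask], g3[mask], yv[mask]
    pair = PAIR_CODES[encoding]
    X = np.column_stack(
        [
            np.ones(a.size),
            a,
            b,
            c,
            pair(a, b),
            pair(a, c),
            pair(b, c),
            TRIPLE_CODES[encoding](a, b, c),
        ]
    ).astype(float)
    return _ols_last_coef_p(X, yy)


def bh_adjust(p: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, input order preserved."""
    arr = np.asarray(p, dtype=float)
    if arr.size == 0:
        return arr.copy()
    if np.any(arr < 0) or np.any(arr > 1) or not np.all(np.isfinite(arr)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(arr, method="fdr_bh")[1]


def pairwise_scan(
    G: GenotypeMatrix,
    y: PhenotypeVector,
    encoding: str = "cartesian",
    min_maf: float = 0.05,
    alpha: float = 0.05,
) -> list[EpistasisPair]:
    """Exhaustive scan of all unordered SNP pairs under one encoding.

    All C(m, 2) pairs of the MAF-filtered matrix are tested; BH-FDR is
    applied across the full set; pairs with ``p_adj < alpha`` are flagged
    significant.  Results are sorted by (p_adj, locus keys) so output is
    deterministic.
    """
    if len(y) != G.n_individuals:
        raise ValueError("phenotype length does not match genotype rows")
    Gf = maf_filter(G, min_maf)
    m = Gf.n_snps
    if m < 2:
        raise ValueError(f"need >= 2 SNPs after MAF filtering, have {m}")
    idx_pairs = [(i, j) for i in range(m) for j in range(i + 1, m)]
    raws = np.empty(len(idx_pairs))
    degen = 0
    for t, (i, j) in enumerate(idx_pairs):
        res = interaction_test(y, Gf.codes[:, i], Gf.codes[:, j], encoding)
        raws[t] = res.p
        degen += res.degenerate
    if degen:
        logger.warning("%d of %d pair tests were degenerate (p set to 1)", degen, len(idx_pairs))
    adj = bh_adjust(raws)
    pairs = [
        EpistasisPair(
            snp_a=Gf.loci[i],
            snp_b=Gf.loci[j],
            p_raw=float(raws[t]),
            p_adj=float(adj[t]),
            encoding=encoding,
            significant=bool(adj[t] < alpha),
        )
        for t, (i, j) in enumerate(idx_pairs)
    ]
    pairs.sort(key=lambda e: (e.p_adj, e.key[0].sort_key, e.key[1].sort_key))
    return pairs
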