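"""Synthetic genotype/phenotype generation with planted epistasis.

Genotypes are drawn per locus under Hardy–Weinberg equilibrium at a
configurable minor-allele frequency and coded as minor-allele counts
0/1/2.  Quantitative phenotypes are built from planted two- and
three-locus interaction effects under either of two penetrance encodings:

* **Cartesian** — the multiplicative product of genotype codes
  (``g1 * g2``), which leaves a marginal single-locus signal.
* **XOR** — the parity of heterozygosity indicators
  (``1[g1==1] ^ 1[g2==1]``), whose marginal effect cancels exactly at
  MAF 0.5 under HWE, so no single-locus test can see it.

Gaussian noise is added on top; there is no case/control mode (the
motivating trait, body-mass index, is quantitative).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .loci import SnpLocus

__all__ = [
    "MISSING",
    "GenotypeMatrix",
    "PhenotypeVector",
    "PlantedEffect",
    "ArchitectureSpec",
    "simulate_genotypes",
    "xor_code",
    "cartesian_code",
    "xor3_code",
    "cartesian3_code",
    "apply_architecture",
    "simulate_dataset",
]

#: Sentinel for a missing genotype call in the integer code matrix.
MISSING: int = -1

_VALID_MODELS = ("cartesian", "xor")


@dataclass
class GenotypeMatrix:
    """Individuals × SNPs matrix of minor-allele counts.

    Entries are 0/1/2, or :data:`MISSING` (−1) for a missing call.  The
    simulator never emits missing calls; readers may.
    """

    loci: list[SnpLocus]
    codes: np.ndarray
    individual_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes)
        if self.codes.ndim != 2:
            raise ValueError("genotype codes must be a 2-D matrix")
        if self.codes.shape[1] != len(self.loci):
            raise ValueError(
                f"{self.codes.shape[1]} columns but {len(self.loci)} loci"
            )
        if not np.issubdtype(self.codes.dtype, np.integer):
            raise ValueError("genotype codes must be integers")
        bad = ~np.isin(self.codes, (MISSING, 0, 1, 2))
        if bad.any():
            raise ValueError(
                f"genotype codes outside {{0,1,2,missing}}: "
                f"{np.unique(self.codes[bad])[:5].tolist()}"
            )
        if len(set(self.loci)) != len(self.loci):
            raise ValueError("duplicate (chromosome, position) keys among loci")
        if self.individual_ids is not None and len(self.individual_ids) != self.codes.shape[0]:
            raise ValueError("individual_ids length does not match row count")

    @property
    def n_individuals(self) -> int:
        return self.codes.shape[0]

    @property
    def n_snps(self) -> int:
        return self.codes.shape[1]

    def column(self, locus: SnpLocus) -> np.ndarray:
        """Genotype column for *locus* (raises KeyError if absent)."""
        try:
            j = self.loci.index(locus)
        except ValueError:
            raise KeyError(f"locus {locus} not in genotype matrix") from None
        return self.codes[:, j]


@dataclass
class PhenotypeVector:
    """Quantitative trait values, one per individual."""

    values: np.ndarray
    trait_name: str = "trait"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("phenotype must be a 1-D vector")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("phenotype contains non-finite values")

    def __len__(self) -> int:
        return self.values.shape[0]


@dataclass(frozen=True)
class PlantedEffect:
    """One planted interaction: SNP column indices, encoding, effect size."""

    indices: tuple[int, ...]
    model: str
    beta: float

    def __post_init__(self) -> None:
        if self.model not in _VALID_MODELS:
            raise ValueError(f"model must be one of {_VALID_MODELS}, got {self.model!r}")
        if len(set(self.indices)) != len(self.indices):
            raise ValueError(f"planted indices must be distinct: {self.indices}")
        if not np.isfinite(self.beta):
            raise ValueError("effect size must be finite")


@dataclass
class ArchitectureSpec:
    """Planted genetic architecture for a synthetic phenotype.

    Parameters
    ----------
    planted_pairs, planted_triples
        Interactions as :class:`PlantedEffect` (2 and 3 indices respectively).
    noise_sd
        Standard deviation σ of the additive Gaussian noise; must be > 0.
    maf
        Per-SNP minor-allele frequency in (0, 0.5], scalar or per-locus.
    seed
        RNG seed; identical spec + seed reproduce bit-identical data.
    """

    planted_pairs: list[PlantedEffect] = field(default_factory=list)
    planted_triples: list[PlantedEffect] = field(default_factory=list)
    noise_sd: float = 1.0
    maf: float | Sequence[float] = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd <= 0:
            raise ValueError(f"noise_sd must be > 0, got {self.noise_sd}")
        for eff in self.planted_pairs:
            if len(eff.indices) != 2:
                raise ValueError(f"pair effect needs 2 indices: {eff.indices}")
        for eff in self.planted_triples:
            if len(eff.indices) != 3:
                raise ValueError(f"triple effect needs 3 indices: {eff.indices}")


def _check_genotypes(*gs: np.ndarray) -> list[np.ndarray]:
    out = []
    for g in gs:
        a = np.asarray(g)
        if not np.isin(a, (0, 1, 2)).all():
            raise ValueError("genotype codes must be in {0, 1, 2}")
        out.append(a)
    return out


def xor_code(g1, g2):
    """Two-locus XOR interaction code: ``1[g1==1] XOR 1[g2==1]``.

    The penetrance table over (g1, g2) is ``[[0,1,0],[1,0,1],[0,1,0]]``:
    the code fires when exactly one locus is heterozygous.  At MAF 0.5
    under HWE the conditional mean of the code given either genotype is
    0.5 for every genotype value, so the model is marginally invisible.
    Accepts scalars or arrays; returns the same shape.
    """
    a, b = _check_genotypes(g1, g2)
    code = ((a == 1) ^ (b == 1)).astype(np.int64)
    return code if code.ndim else int(code)


def cartesian_code(g1, g2):
    """Two-locus Cartesian (multiplicative) interaction code: ``g1 * g2``."""
    a, b = _check_genotypes(g1, g2)
    code = (a * b).astype(np.int64)
    return code if code.ndim else int(code)


def xor3_code(g1, g2, g3):
    """Three-locus XOR code: parity of the three heterozygosity indicators."""
    a, b, c = _check_genotypes(g1, g2, g3)
    code = ((a == 1) ^ (b == 1) ^ (c == 1)).astype(np.int64)
    return code if code.ndim else int(code)


def cartesian3_code(g1, g2, g3):
    """Three-locus Cartesian code: ``g1 * g2 * g3``."""
    a, b, c = _check_genotypes(g1, g2, g3)
    code = (a * b * c).astype(np.int64)
    return code if code.ndim else int(code)


#: Encoding registry; pluggable so an alternative penetrance table can be
#: configured without touching callers.
PAIR_CODES = {"xor": xor_code, "cartesian": cartesian_code}
TRIPLE_CODES = {"xor": xor3_code, "cartesian": cartesian3_code}


def simulate_genotypes(
    n_individuals: int,
    loci: Sequence[SnpLocus],
    maf: float | Sequence[float] = 0.5,
    seed: int = 0,
) -> GenotypeMatrix:
    """Draw an HWE genotype matrix.

    Each column is i.i.d. with genotype probabilities
    ((1−q)², 2q(1−q), q²) for its minor-allele frequency q.  Deterministic
    given *seed*.

    Parameters
    ----------
    n_individuals
        Number of rows; must be ≥ 1.
    loci
        Coordinates for the columns, unique (chromosome, position) keys.
    maf
        Scalar or per-locus frequency, each in (0, 0.5].
    """
    if n_individuals < 1:
        raise ValueError(f"n_individuals must be >= 1, got {n_individuals}")
    loci = list(loci)
    q = np.broadcast_to(np.asarray(maf, dtype=float), (len(loci),))
    if np.any(q <= 0) or np.any(q > 0.5):
        raise ValueError("minor-allele frequencies must lie in (0, 0.5]")
    rng = np.random.default_rng(seed)
    # two independent allele draws per individual per locus
    alleles = rng.random((2, n_individuals, len(loci))) < q
    codes = alleles.sum(axis=0).astype(np.int8)
    ids = [f"ind{i}" for i in range(n_individuals)]
    return GenotypeMatrix(loci=loci, codes=codes, individual_ids=ids)


def apply_architecture(G: GenotypeMatrix, spec: ArchitectureSpec) -> PhenotypeVector:
    """Build a phenotype from planted interactions plus Gaussian noise.

    ``y = Σ_pairs β·code(g_i, g_j) + Σ_triples β·code3(g_i, g_j, g_k) + ε``
    with ``ε ~ Normal(0, σ²)`` seeded from ``spec.seed``.
    """
    n = G.n_individuals
    y = np.zeros(n, dtype=float)
    for eff in spec.planted_pairs:
        for j in eff.indices:
            if not 0 <= j < G.n_snps:
                raise IndexError(f"planted SNP index {j} out of range")
        i, j = eff.indices
        y += eff.beta * PAIR_CODES[eff.model](G.codes[:, i], G.codes[:, j])
    for eff in spec.planted_triples:
        for j in eff.indices:
            if not 0 <= j < G.n_snps:
                raise IndexError(f"planted SNP index {j} out of range")
        i, j, k = eff.indices
        y += eff.beta * TRIPLE_CODES[eff.model](
            G.codes[:, i], G.codes[:, j], G.codes[:, k]
        )
    rng = np.random.default_rng(spec.seed)
    y += rng.normal(0.0, spec.noise_sd, size=n)
    return PhenotypeVector(values=y, trait_name="synthetic_trait")


def default_loci(n_snps: int, n_chromosomes: int = 5, spacing: int = 5_000_000) -> list[SnpLocus]:
    """Evenly spaced loci cycled across chromosomes (convenience for simulations)."""
    return [
        SnpLocus(str(1 + i % n_chromosomes), 1_000_000 + (i // n_chromosomes) * spacing)
        for i in range(n_snps)
    ]


def simulate_dataset(
    spec: ArchitectureSpec,
    n_individuals: int,
    loci: Sequence[SnpLocus] | int,
) -> tuple[GenotypeMatrix, PhenotypeVector]:
    """Genotypes + phenotype in one call, both seeded from ``spec.seed``."""
    if isinstance(loci, int):
        loci = default_loci(loci)
    G = simulate_genotypes(n_individuals, loci, maf=spec.maf, seed=spec.seed)
    # offset the phenotype noise stream from the genotype stream
    noise_spec = ArchitectureSpec(
        planted_pairs=spec.planted_pairs,
        planted_triples=spec.planted_triples,
        noise_sd=spec.noise_sd,
        maf=spec.maf,
        seed=spec.seed + 1_000_003,
    )
    y = apply_architecture(G, noise_spec)
    return G, y
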