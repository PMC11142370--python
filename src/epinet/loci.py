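"""SNP locus identifiers.

A SNP is identified by its genomic coordinate: a chromosome label and a
1-based base-pair position.  Two id syntaxes circulate in epistasis result
tables — ``chr1.281788173`` and ``1:281788173`` — and both parse to the
same :class:`SnpLocus`.  Chromosome labels are normalized by stripping any
``chr`` prefix, so ``"chr1"`` and ``"1"`` compare equal.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

__all__ = ["SnpLocus", "normalize_chrom", "parse_snp_id", "format_snp_id"]

_CHR_PREFIX = re.compile(r"^chr", re.IGNORECASE)
_DOT_STYLE = re.compile(r"^chr(?P<c>[A-Za-z0-9_]+)\.(?P<p>\d+)$", re.IGNORECASE)
_COLON_STYLE = re.compile(r"^(?P<c>[A-Za-z0-9_]+):(?P<p>\d+)$")


def normalize_chrom(label: object) -> str:
    """Normalize a chromosome label: strip a ``chr`` prefix, keep the rest."""
    s = _CHR_PREFIX.sub("", str(label).strip())
    if not s:
        raise ValueError(f"empty chromosome label: {label!r}")
    return s


@dataclass(frozen=True)
class SnpLocus:
    """A SNP as a (chromosome, position) coordinate.

    Positions are 1-based base pairs.  Ordering is numeric-aware on the
    chromosome label (chr2 sorts before chr10) so that sorted outputs are
    deterministic and human-readable.
    """

    chrom: str
    pos: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "chrom", normalize_chrom(self.chrom))
        if not isinstance(self.pos, (int,)) or isinstance(self.pos, bool):
            raise TypeError(f"position must be an integer, got {self.pos!r}")
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")

    @property
    def sort_key(self) -> tuple:
        c = self.chrom
        return (0, int(c), "", self.pos) if c.isdigit() else (1, 0, c, self.pos)

    def __lt__(self, other: "SnpLocus") -> bool:
        if not isinstance(other, SnpLocus):
            return NotImplemented
        return self.sort_key < other.sort_key

    def __le__(self, other: "SnpLocus") -> bool:
        if not isinstance(other, SnpLocus):
            return NotImplemented
        return self.sort_key <= other.sort_key

    def __str__(self) -> str:
        return f"{self.chrom}:{self.pos}"


def parse_snp_id(text: str) -> SnpLocus:
    """Parse a SNP id in either ``chr{c}.{pos}`` or ``{c}:{pos}`` syntax."""
    s = text.strip()
    m = _DOT_STYLE.match(s) or _COLON_STYLE.match(s)
    if m is None:
        raise ValueError(f"unrecognized SNP id: {text!r}")
    return SnpLocus(m.group("c"), int(m.group("p")))


def format_snp_id(locus: SnpLocus, style: str = "colon") -> str:
    """Render a locus as ``{c}:{pos}`` (``colon``) or ``chr{c}.{pos}`` (``dot``)."""
    if style == "colon":
        return f"{locus.chrom}:{locus.pos}"
    if style == "dot":
        return f"chr{locus.chrom}.{locus.pos}"
    raise ValueError(f"unknown SNP id style: {style!r}")
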