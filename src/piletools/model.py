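"""Data model shared by every tool: GP records, pileup records, IUPAC
genotypes and the coordinate comparator.

A *genomic-position (GP) file* is tab-delimited text whose first two columns
are a sequence (chromosome) name and a 1-based coordinate; everything after
the second tab is carried opaquely and reproduced byte-exact on output.
Pileup files are the SAMtools consensus dialect: a GP file whose next six
columns are reference base, IUPAC consensus call, consensus quality, SNP
quality, max mapping quality and read depth.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Iterator

from .errors import MalformedLineError, NoGenotypeError, OrderingMismatchError

# Two-allele IUPAC ambiguity codes denote heterozygous consensus genotypes;
# single bases denote homozygous ones. N (all four bases) carries no genotype.
_IUPAC: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
}

ALLELES_TO_IUPAC: dict[frozenset[str], str] = {v: k for k, v in _IUPAC.items()}

VALID_CONSENSUS = frozenset(_IUPAC) | {"N"}
VALID_REF = frozenset("ACGTN")


def iupac_alleles(code: str) -> frozenset[str]:
    """Decode an IUPAC consensus code into its set of 1-2 alleles.

    ``N`` (and anything else outside the ten genotype-bearing codes) raises
    :class:`NoGenotypeError`; the caller decides whether to skip or flag.
    """
    try:
        return _IUPAC[code]
    except KeyError:
        raise NoGenotypeError(f"IUPAC code {code!r} does not encode a 1- or 2-allele genotype") from None


@dataclass(frozen=True)
class GPRecord:
    """One parsed line of a GP file."""

    chrom: str
    pos: int
    rest: tuple[str, ...]
    raw_line: str

    def serialize(self) -> str:
        return "\t".join((self.chrom, str(self.pos)) + self.rest)


def parse_gp_line(line: str, line_no: int = 0, path: str | None = None) -> GPRecord:
    """Parse one GP line: ``chrom \\t pos [\\t trailing fields...]``.

    The position must be a positive integer. Trailing fields are preserved
    byte-exact in ``rest``.
    """
    stripped = line.rstrip("\n")
    fields = stripped.split("\t")
    if len(fields) < 2:
        raise MalformedLineError(
            f"expected at least 2 tab-separated fields, got {len(fields)}", line_no, path
        )
    chrom = fields[0]
    if not chrom:
        raise MalformedLineError("empty chromosome name", line_no, path)
    try:
        pos = int(fields[1])
    except ValueError:
        raise MalformedLineError(f"position {fields[1]!r} is not an integer", line_no, path) from None
    if pos < 1:
        raise MalformedLineError(f"position {pos} is not >= 1", line_no, path)
    return GPRecord(chrom, pos, tuple(fields[2:]), stripped)


@dataclass(frozen=True)
class PileupRecord:
    """One parsed line of a SAMtools consensus pileup.

    Column layout (10-column consensus dialect): chrom, pos, reference base,
    IUPAC consensus, consensus quality, SNP quality, max mapping quality,
    read depth; read bases and base qualities (and anything further) are kept
    opaquely in ``rest``.
    """

    chrom: str
    pos: int
    ref_base: str
    consensus: str
    consensus_quality: float
    snp_quality: float
    coverage: int
    rest: tuple[str, ...]
    raw_line: str

    @property
    def is_variant(self) -> bool:
        return self.consensus != self.ref_base

    @property
    def alleles(self) -> frozenset[str]:
        """Genotype as an allele set; raises NoGenotypeError for consensus N."""
        return iupac_alleles(self.consensus)


def parse_pileup_line(line: str, line_no: int = 0, path: str | None = None) -> PileupRecord:
    stripped = line.rstrip("\n")
    fields = stripped.split("\t")
    if len(fields) < 8:
        raise MalformedLineError(
            f"pileup line needs at least 8 columns, got {len(fields)}", line_no, path
        )
    chrom = fields[0]
    try:
        pos = int(fields[1])
    except ValueError:
        raise MalformedLineError(f"position {fields[1]!r} is not an integer", line_no, path) from None
    if pos < 1:
        raise MalformedLineError(f"position {pos} is not >= 1", line_no, path)
    ref = fields[2].upper()
    if ref not in VALID_REF:
        raise MalformedLineError(f"reference base {fields[2]!r} is not one of A,C,G,T,N", line_no, path)
    cons = fields[3].upper()
    if cons not in VALID_CONSENSUS:
        raise MalformedLineError(f"consensus {fields[3]!r} is not an IUPAC code", line_no, path)
    try:
        cons_q = float(fields[4])
        snp_q = float(fields[5])
        coverage = int(fields[7])
    except ValueError:
        raise MalformedLineError("non-numeric quality or coverage column", line_no, path) from None
    if cons_q < 0 or snp_q < 0:
        raise MalformedLineError("negative quality", line_no, path)
    if coverage < 0:
        raise MalformedLineError("negative coverage", line_no, path)
    return PileupRecord(
        chrom, pos, ref, cons, cons_q, snp_q, coverage, tuple(fields[8:]), stripped
    )


_NATURAL_SPLIT = re.compile(r"(\d+)")


def natural_key(chrom: str) -> tuple:
    """Sort key under which chr2 < chr10 (digit runs compare numerically)."""
    parts = _NATURAL_SPLIT.split(chrom)
    return tuple(int(p) if i % 2 else p for i, p in enumerate(parts))


class SequenceOrdering:
    """Total order on chromosome names.

    Modes:

    * ``lex`` — plain string comparison (chr10 < chr2);
    * ``natural`` — digit runs compare numerically (chr2 < chr10);
    * ``file`` — as-encountered: a chromosome ranks by first appearance.
      Useful for inputs sorted to a BAM-header order.
    """

    MODES = ("lex", "natural", "file")

    def __init__(self, mode: str = "natural"):
        if mode not in self.MODES:
            raise ValueError(f"unknown ordering mode {mode!r}; expected one of {self.MODES}")
        self.mode = mode
        self._ranks: dict[str, int] = {}

    def rank(self, chrom: str) -> tuple:
        if self.mode == "lex":
            return (chrom,)
        if self.mode == "natural":
            return natural_key(chrom)
        return (self._ranks.setdefault(chrom, len(self._ranks)),)

    def key(self, chrom: str, pos: int) -> "CoordinateKey":
        return CoordinateKey(self.rank(chrom), pos, self)

    def __repr__(self) -> str:  # pragma: no cover
        return f"SequenceOrdering({self.mode!r})"


@dataclass(frozen=True)
class CoordinateKey:
    """Comparable (chromosome rank, position) pair under one ordering."""

    chrom_rank: tuple
    pos: int
    ordering: SequenceOrdering = field(compare=False)

    def sort_key(self) -> tuple:
        return (self.chrom_rank, self.pos)


def compare_keys(a: CoordinateKey, b: CoordinateKey) -> int:
    """Three-way comparison: chromosome rank dominates, position breaks ties."""
    if a.ordering is not b.ordering:
        raise OrderingMismatchError("coordinate keys come from different sequence orderings")
    ka, kb = (a.chrom_rank, a.pos), (b.chrom_rank, b.pos)
    if ka < kb:
        return -1
    if ka > kb:
        return 1
    return 0


def is_comment(line: str) -> bool:
    """Header/comment lines ('#', 'track', 'browser') are never records."""
    return line.startswith("#") or line.startswith("track") or line.startswith("browser")


def iter_gp_records(
    lines: Iterable[str],
    *,
    parser=parse_gp_line,
    skip_malformed: bool = False,
    path: str | None = None,
    counters: dict | None = None,
) -> Iterator:
    """Stream parsed records from an iterable of lines.

    Comment lines and blank lines are skipped (and counted when ``counters``
    is given). Malformed lines raise by default; with ``skip_malformed`` they
    are counted and dropped.
    """
    for line_no, line in enumerate(lines, 1):
        stripped = line.rstrip("\n")
        if not stripped or is_comment(stripped):
            if counters is not None:
                counters["comments"] = counters.get("comments", 0) + 1
            continue
        try:
            yield parser(stripped, line_no, path)
        except MalformedLineError:
            if not skip_malformed:
                raise
            if counters is not None:
                counters["malformed"] = counters.get("malformed", 0) + 1
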