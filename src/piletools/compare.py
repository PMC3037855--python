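"""Case/control comparison of pileup variant calls.

Two tools live here:

* :func:`two_sample_compare` — for a pair of samples (e.g. tumour vs
  normal), report every position whose consensus genotype is discrepant.
  Each sample contributes a *variant* pileup (the candidate calls) and a
  *full* pileup (every covered position, variants and reference calls
  alike); the other sample's genotype at a candidate position is looked up
  in its full file by on-disk binary search, so nothing is loaded into
  memory.

* :func:`n_sample_compare` — for two groups of samples, report per position
  which samples carry it and a two-sided Fisher's exact test on the 2x2
  presence table, to flag positions that are reproducible within one
  condition and characteristic of it.

Genotypes are compared as IUPAC allele sets: R vs R is concordant even if
qualities differ; R vs A, or R vs M, is discrepant.
"""

from __future__ import annotations

import heapq
import os
from dataclasses import dataclass
from typing import Iterable, Iterator, Sequence

import numpy as np
from scipy.stats import hypergeom

from .errors import DegenerateTableError, InconsistentInputError, NotSortedError
from .model import (
    PileupRecord,
    SequenceOrdering,
    iter_gp_records,
    iupac_alleles,
    parse_pileup_line,
)
from .search import GPFile

REASONS = (
    "variant-only-in-A",
    "variant-only-in-B",
    "different-variant",
    "no-coverage-in-other",
)


@dataclass(frozen=True)
class DiscrepantCall:
    """One position where the two samples' genotypes disagree."""

    chrom: str
    pos: int
    genotype_a: str | None  # IUPAC consensus in sample A, None if uncovered
    genotype_b: str | None
    reason: str

    def serialize(self) -> str:
        ga = self.genotype_a if self.genotype_a is not None else "."
        gb = self.genotype_b if self.genotype_b is not None else "."
        return f"{self.chrom}\t{self.pos}\t{ga}\t{gb}\t{self.reason}"


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts for one position: (a, b) cases with/without the variant,
    (c, d) controls with/without."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency cells must be non-negative")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d


def fisher_exact_2x2(table: ContingencyTable2x2) -> float:
    """Two-sided Fisher's exact test p-value.

    Conditioning on both margins, the first cell follows a hypergeometric
    law; the two-sided p-value sums the probabilities of every same-margin
    table whose point probability does not exceed the observed table's
    (point-probability ordering, the conventional two-sided rule; no mid-p).
    The <= comparison uses a 1e-7 relative cushion so that mathematically
    tied tables are never dropped to floating-point rounding.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    n = table.total
    if n == 0:
        raise DegenerateTableError("all four cells are zero")
    row1, col1 = a + b, a + c
    dist = hypergeom(n, row1, col1)
    support = np.arange(max(0, row1 + col1 - n), min(row1, col1) + 1)
    pmf = dist.pmf(support)
    p_obs = dist.pmf(a)
    mask = pmf <= p_obs * (1.0 + 1e-7)
    if mask.all():
        return 1.0  # every same-margin table counted: the mass sums to 1 exactly
    return min(1.0, float(pmf[mask].sum()))


# ---------------------------------------------------------------------------
# 2smc
# ---------------------------------------------------------------------------

def _genotype(rec: PileupRecord) -> frozenset[str] | None:
    """Allele set of a call, or None when the consensus carries no genotype (N)."""
    try:
        return iupac_alleles(rec.consensus)
    except Exception:
        return None


def _lookup(full: GPFile, chrom: str, pos: int) -> PileupRecord | None:
    lines = list(full.query(chrom, pos, pos))
    if not lines:
        return None
    return parse_pileup_line(lines[0], path=full.path)


def _merge_variant_streams(paths: Sequence[str], ordering: SequenceOrdering):
    """n-way sorted merge of pileup variant files.

    Yields (key, pos_records) where pos_records maps sample index -> record,
    one entry per position present in >= 1 file. Duplicate lines at the same
    position within one file collapse to the first.
    """
    def stream(i: int, path: str):
        prev = None
        with open(path, encoding="utf-8") as fh:
            for rec in iter_gp_records(fh, parser=parse_pileup_line, path=path):
                key = (ordering.rank(rec.chrom), rec.pos)
                if prev is not None and key < prev:
                    raise NotSortedError(f"{path}: {rec.chrom}:{rec.pos} out of order")
                prev = key
                yield key, i, rec

    merged = heapq.merge(*(stream(i, p) for i, p in enumerate(paths)), key=lambda t: (t[0], t[1]))
    cur_key = None
    cur: dict[int, PileupRecord] = {}
    for key, i, rec in merged:
        if key != cur_key:
            if cur_key is not None:
                yield cur_key, cur
            cur_key, cur = key, {}
        cur.setdefault(i, rec)
    if cur_key is not None:
        yield cur_key, cur


def two_sample_compare(
    a_full: str | os.PathLike,
    b_full: str | os.PathLike,
    a_variants: str | os.PathLike,
    b_variants: str | os.PathLike,
    ordering: SequenceOrdering | None = None,
) -> Iterator[DiscrepantCall]:
    """Report positions with discrepant genotypes between samples A and B.

    For every position present in either variant file, the other sample's
    genotype is fetched from its full pileup by binary search. Concordant
    genotypes (equal allele sets) are suppressed. A position whose line is
    missing from the *other* sample's full file is reported with reason
    ``no-coverage-in-other``; one missing from its *own* full file raises
    :class:`InconsistentInputError` (variant files must be subsets of full
    files). Calls whose consensus is N (no genotype) are skipped.
    """
    ordering = ordering or SequenceOrdering("natural")
    with GPFile(a_full) as fa, GPFile(b_full) as fb:
        for _key, recs in _merge_variant_streams(
            [os.fspath(a_variants), os.fspath(b_variants)], ordering
        ):
            ra, rb = recs.get(0), recs.get(1)
            chrom = (ra or rb).chrom
            pos = (ra or rb).pos
            # consistency: a variant line must exist in its own full file
            for rec, own in ((ra, fa), (rb, fb)):
                if rec is not None and _lookup(own, chrom, pos) is None:
                    raise InconsistentInputError(
                        f"variant position {chrom}:{pos} absent from full file {own.path}"
                    )
            if ra is None:
                ra = _lookup(fa, chrom, pos)
            if rb is None:
                rb = _lookup(fb, chrom, pos)
            ga = _genotype(ra) if ra is not None else None
            gb = _genotype(rb) if rb is not None else None
            if ra is not None and ga is None:
                continue  # consensus N in A: no genotype to compare
            if rb is not None and gb is None:
                continue
            if ra is None or rb is None:
                yield DiscrepantCall(
                    chrom,
                    pos,
                    ra.consensus if ra is not None else None,
                    rb.consensus if rb is not None else None,
                    "no-coverage-in-other",
                )
                continue
            if ga == gb:
                continue
            if ra.is_variant and rb.is_variant:
                reason = "different-variant"
            elif ra.is_variant:
                reason = "variant-only-in-A"
            else:
                reason = "variant-only-in-B"
            yield DiscrepantCall(chrom, pos, ra.consensus, rb.consensus, reason)


# ---------------------------------------------------------------------------
# nsmc
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GroupComparisonRow:
    """Per-position output of the n-sample comparison."""

    chrom: str
    pos: int
    present_in: tuple[int, ...]  # 0/1 per sample, A group then B group
    counts: ContingencyTable2x2
    p: float

    def serialize(self) -> str:
        flags = "\t".join(str(f) for f in self.present_in)
        t = self.counts
        return f"{self.chrom}\t{self.pos}\t{flags}\t{t.a}\t{t.b}\t{t.c}\t{t.d}\t{self.p:.6g}"


def n_sample_compare(
    a_samples: Sequence[str | os.PathLike],
    b_samples: Sequence[str | os.PathLike],
    ordering: SequenceOrdering | None = None,
) -> Iterator[GroupComparisonRow]:
    """Compare two groups of variant pileups position by position.

    A sample "contains" a position when that position appears in its variant
    file. For each position present in >= 1 sample, the 2x2 table (A with /
    A without / B with / B without) gets a two-sided Fisher's exact test.
    Inputs are merged as sorted streams; memory stays O(n samples) lines.
    """
    ordering = ordering or SequenceOrdering("natural")
    n_a, n_b = len(a_samples), len(b_samples)
    if n_a < 1 or n_b < 1:
        raise ValueError("both groups need at least one sample")
    paths = [os.fspath(p) for p in a_samples] + [os.fspath(p) for p in b_samples]
    for _key, recs in _merge_variant_streams(paths, ordering):
        some = next(iter(recs.values()))
        flags = tuple(1 if i in recs else 0 for i in range(n_a + n_b))
        a = sum(flags[:n_a])
        c = sum(flags[n_a:])
        table = ContingencyTable2x2(a, n_a - a, c, n_b - c)
        yield GroupComparisonRow(some.chrom, some.pos, flags, table, fisher_exact_2x2(table))
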