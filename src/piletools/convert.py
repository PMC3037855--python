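"""Emit inputs for external mutation-effect predictors from pileup variants.

Each converter is a pure line filter: variant lines (consensus differs from
the reference base) become one change record per non-reference allele, in
the batch-coordinate dialect of the downstream predictor (SIFT, PolyPhen-2
or firestar). Invariant lines and consensus-N lines produce nothing.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator

from .errors import NoGenotypeError
from .model import PileupRecord, iupac_alleles


@dataclass(frozen=True)
class VariantChange:
    """One reference-to-alternate substitution at a genomic position."""

    chrom: str
    pos: int
    ref: str
    alt: str


def extract_change(rec: PileupRecord, counters: dict | None = None) -> list[VariantChange]:
    """Non-reference alleles of one pileup line as VariantChange records.

    Returns [] for invariant lines. Heterozygous non-reference calls
    (e.g. ref A, consensus K = {G,T}) yield one record per allele — lossless;
    predictors deduplicate. Consensus N is skipped (counted when ``counters``
    is given).
    """
    if not rec.is_variant:
        return []
    try:
        alleles = iupac_alleles(rec.consensus)
    except NoGenotypeError:
        if counters is not None:
            counters["no_genotype"] = counters.get("no_genotype", 0) + 1
        return []
    return [
        VariantChange(rec.chrom, rec.pos, rec.ref_base, alt)
        for alt in sorted(alleles - {rec.ref_base})
    ]


def format_sift(v: VariantChange) -> str:
    """SIFT genome-coordinate batch line; pileup is reference-forward, so the
    strand field is always 1."""
    return f"{v.chrom},{v.pos},1,{v.ref}/{v.alt}"


def format_polyphen(v: VariantChange) -> str:
    """PolyPhen-2 batch-coordinate line."""
    return f"{v.chrom}:{v.pos} {v.ref}/{v.alt}"


def format_firestar(v: VariantChange) -> str:
    """Tab layout consumed by firestar batch uploads."""
    return f"{v.chrom}\t{v.pos}\t{v.ref}\t{v.alt}"


FORMATTERS = {
    "sift": format_sift,
    "polyphen": format_polyphen,
    "firestar": format_firestar,
}


def convert_stream(
    records: Iterable[PileupRecord], target: str, counters: dict | None = None
) -> Iterator[str]:
    """Convert a pileup record stream to predictor-input lines, order preserved."""
    fmt = FORMATTERS[target]
    for rec in records:
        for change in extract_change(rec, counters):
            yield fmt(change)
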