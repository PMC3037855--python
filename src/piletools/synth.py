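"""Deterministic synthetic-data generator.

Produces the inputs every other tool consumes — sorted pileup/GP files with
planted variants and a companion truth table, paired BED/GFF interval sets
denoting identical covered positions, and gold-standard genotype tables with
controlled error rates for the genotyping QC tool.

Determinism contract: every generator is a pure function of its spec,
including the seed — the same spec yields byte-identical files. Each file is
produced from one RNG stream seeded from the spec, and the per-line draw
order is frozen (position handling first, then reference base, variant
status, zygosity, alleles, qualities, coverage), so extending the generator
never silently changes existing fixtures.

What this emulates: per-position consensus summaries as SAMtools' variant
caller prints them, with separable SNP-quality distributions for true and
spurious calls. What it does not: read-level data, alignment artefacts,
or any particular sequencing error model — the read-bases and base-quality
columns are schematic placeholders.
"""

from __future__ import annotations

import os
import random
from dataclasses import dataclass, field
from typing import Sequence

from .errors import FixtureSpecError
from .model import ALLELES_TO_IUPAC

_BASES = "ACGT"


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one synthetic pileup/GP file.

    quality_model maps line class ("variant"/"reference") to the (mean, sd)
    of its SNP quality, drawn from a normal truncated at 0 and rounded to an
    integer — pileup quality columns are phred-scaled integers. Defaults
    describe a well-separated callset: confident variants (45 +- 5) over a
    near-zero noise floor for invariant sites.
    """

    seed: int = 0
    chroms: tuple[tuple[str, int], ...] = (("chr1", 1_000_000), ("chr2", 800_000))
    n_lines: int = 1000
    variant_rate: float = 0.1
    het_fraction: float = 0.5
    het_nonref_fraction: float = 0.05
    quality_model: tuple[tuple[str, tuple[float, float]], ...] = (
        ("variant", (45.0, 5.0)),
        ("reference", (2.0, 2.0)),
    )
    duplicate_rate: float = 0.0
    unsorted: bool = False

    def qmodel(self) -> dict[str, tuple[float, float]]:
        return dict(self.quality_model)


@dataclass(frozen=True)
class TruthRecord:
    """What was planted at one generated line."""

    chrom: str
    pos: int
    ref_base: str
    alleles: frozenset[str]
    consensus: str
    zygosity: str  # "reference" | "heterozygous" | "homozygous"
    snp_quality: int

    @property
    def is_variant(self) -> bool:
        return self.consensus != self.ref_base


def _truncnorm_int(rng: random.Random, mean: float, sd: float) -> int:
    q = rng.gauss(mean, sd)
    while q < 0:
        q = rng.gauss(mean, sd)
    return round(q)


def _allocate(n_lines: int, chroms: Sequence[tuple[str, int]]) -> list[int]:
    total_len = sum(length for _, length in chroms)
    alloc = [int(n_lines * length / total_len) for _, length in chroms]
    for i in range(n_lines - sum(alloc)):
        alloc[i % len(alloc)] += 1
    for (_name, length), n in zip(chroms, alloc):
        if n > length:
            raise FixtureSpecError(
                f"cannot place {n} distinct positions on a {length} bp chromosome"
            )
    return alloc


def _make_line(rng: random.Random, spec: FixtureSpec, chrom: str, pos: int) -> TruthRecord:
    qm = spec.qmodel()
    ref = rng.choice(_BASES)
    if rng.random() < spec.variant_rate:
        if rng.random() < spec.het_fraction:
            zyg = "heterozygous"
            if rng.random() < spec.het_nonref_fraction:
                pair = rng.sample([b for b in _BASES if b != ref], 2)
                alleles = frozenset(pair)
            else:
                alt = rng.choice([b for b in _BASES if b != ref])
                alleles = frozenset((ref, alt))
        else:
            zyg = "homozygous"
            alt = rng.choice([b for b in _BASES if b != ref])
            alleles = frozenset((alt,))
        q = _truncnorm_int(rng, *qm["variant"])
    else:
        zyg = "reference"
        alleles = frozenset((ref,))
        q = _truncnorm_int(rng, *qm["reference"])
    return TruthRecord(chrom, pos, ref, alleles, ALLELES_TO_IUPAC[alleles], zyg, q)


def pileup_line(t: TruthRecord, rng: random.Random) -> str:
    cov = max(1, round(rng.gauss(30, 8)))
    cons_q = _truncnorm_int(rng, 40, 8)
    bases = "." * cov
    quals = "I" * cov
    return (
        f"{t.chrom}\t{t.pos}\t{t.ref_base}\t{t.consensus}\t{cons_q}\t"
        f"{t.snp_quality}\t60\t{cov}\t{bases}\t{quals}"
    )


def generate_pileup(
    spec: FixtureSpec,
    out_path: str | os.PathLike,
    truth_path: str | os.PathLike | None = None,
) -> list[TruthRecord]:
    """Write a synthetic pileup (sorted unless spec.unsorted) and return the
    truth table; also written as TSV when ``truth_path`` is given."""
    if not 0 <= spec.variant_rate <= 1 or not 0 <= spec.het_fraction <= 1:
        raise FixtureSpecError("rates must lie in [0, 1]")
    rng = random.Random(spec.seed)
    alloc = _allocate(spec.n_lines, spec.chroms)
    truths: list[TruthRecord] = []
    lines: list[str] = []
    for (chrom, length), n in zip(spec.chroms, alloc):
        positions = sorted(rng.sample(range(1, length + 1), n))
        for pos in positions:
            copies = 1 + (1 if rng.random() < spec.duplicate_rate else 0)
            for _ in range(copies):
                t = _make_line(rng, spec, chrom, pos)
                truths.append(t)
                lines.append(pileup_line(t, rng))
    if spec.unsorted:
        order = list(range(len(lines)))
        rng.shuffle(order)
        lines = [lines[i] for i in order]
        truths = [truths[i] for i in order]
    with open(out_path, "w", encoding="utf-8") as fh:
        fh.writelines(line + "\n" for line in lines)
    if truth_path is not None:
        with open(truth_path, "w", encoding="utf-8") as fh:
            fh.write("#chrom\tpos\tref\talleles\tconsensus\tzygosity\tsnp_quality\n")
            for t in truths:
                fh.write(
                    f"{t.chrom}\t{t.pos}\t{t.ref_base}\t{''.join(sorted(t.alleles))}\t"
                    f"{t.consensus}\t{t.zygosity}\t{t.snp_quality}\n"
                )
    return truths


def write_variant_subset(truths: Sequence[TruthRecord], pileup_path, out_path) -> int:
    """Write the variant-lines-only companion of a generated pileup."""
    wanted = {(t.chrom, t.pos) for t in truths if t.is_variant}
    n = 0
    with open(pileup_path, encoding="utf-8") as fin, open(out_path, "w", encoding="utf-8") as fout:
        for line in fin:
            f = line.split("\t", 4)
            if (f[0], int(f[1])) in wanted:
                fout.write(line)
                n += 1
    return n


def generate_intervals(
    seed: int,
    chroms: Sequence[tuple[str, int]],
    n_intervals: int,
    bed_path: str | os.PathLike,
    gff_path: str | os.PathLike,
    mean_length: int = 500,
    overlap: bool = True,
) -> list[tuple[str, int, int, str]]:
    """Write paired BED and GFF files denoting the *same* covered positions.

    Each interval is generated once as 1-based inclusive (chrom, start, end,
    label), then serialized as BED (start-1, end: 0-based half-open) and GFF
    (start, end: 1-based closed). Returns the 1-based interval list. With
    ``overlap`` false, intervals are laid end to end without overlap.
    """
    rng = random.Random(seed)
    intervals: list[tuple[str, int, int, str]] = []
    cursor: dict[str, int] = {name: 1 for name, _ in chroms}
    for i in range(n_intervals):
        chrom, length = chroms[rng.randrange(len(chroms))]
        span = max(1, round(rng.expovariate(1 / mean_length)))
        if overlap:
            start = rng.randint(1, max(1, length - span))
        else:
            start = cursor[chrom]
            if start + span > length:
                continue
            cursor[chrom] = start + span + rng.randint(1, mean_length)
        end = min(length, start + span - 1)
        intervals.append((chrom, start, end, f"iv{i}"))
    with open(bed_path, "w", encoding="utf-8") as bed:
        for chrom, start, end, label in intervals:
            bed.write(f"{chrom}\t{start - 1}\t{end}\t{label}\n")
    with open(gff_path, "w", encoding="utf-8") as gff:
        for chrom, start, end, label in intervals:
            gff.write(f"{chrom}\tsynth\tregion\t{start}\t{end}\t.\t+\t.\tID={label}\n")
    return intervals


def generate_genotest_data(
    seed: int,
    pileup_path: str | os.PathLike,
    gold_path: str | os.PathLike,
    n_true: int = 500,
    n_false: int = 500,
    q_true: tuple[float, float] = (45.0, 5.0),
    q_false: tuple[float, float] = (8.0, 3.0),
    het_fraction: float = 0.5,
    miss_rate: float = 0.0,
    chrom: str = "chr1",
    chrom_length: int = 10_000_000,
) -> dict:
    """Experimental pileup + gold standard with planted detection errors.

    * ``n_true`` sites carry a real variant (the gold genotype): called
      correctly with SNP quality ~ N(q_true), except a ``miss_rate`` fraction
      called homozygous-reference (planted false negatives).
    * ``n_false`` sites are homozygous-reference in the gold standard but
      called variant with SNP quality ~ N(q_false) (planted false positives).

    With the default quality means (45 vs 8) the two classes are separable,
    so a SNP-quality ROC sweep has a clear optimum between the two
    distributions. Returns the planted counts for oracle checks.
    """
    rng = random.Random(seed)
    n_sites = n_true + n_false
    positions = sorted(rng.sample(range(1, chrom_length + 1), n_sites))
    roles = ["true"] * n_true + ["false"] * n_false
    rng.shuffle(roles)
    planted = {"true_total": n_true, "false_total": n_false, "missed": 0,
               "het_true": 0, "hom_true": 0}
    plines: list[str] = []
    glines: list[str] = []
    for pos, role in zip(positions, roles):
        ref = rng.choice(_BASES)
        if role == "true":
            if rng.random() < het_fraction:
                alt = rng.choice([b for b in _BASES if b != ref])
                gold_alleles = frozenset((ref, alt))
                planted["het_true"] += 1
            else:
                alt = rng.choice([b for b in _BASES if b != ref])
                gold_alleles = frozenset((alt,))
                planted["hom_true"] += 1
            if rng.random() < miss_rate:
                consensus, q = ref, _truncnorm_int(rng, *q_false)
                planted["missed"] += 1
            else:
                consensus, q = ALLELES_TO_IUPAC[gold_alleles], _truncnorm_int(rng, *q_true)
        else:
            gold_alleles = frozenset((ref,))
            alt = rng.choice([b for b in _BASES if b != ref])
            fake = frozenset((ref, alt)) if rng.random() < het_fraction else frozenset((alt,))
            consensus, q = ALLELES_TO_IUPAC[fake], _truncnorm_int(rng, *q_false)
        cov = max(1, round(rng.gauss(30, 8)))
        plines.append(
            f"{chrom}\t{pos}\t{ref}\t{consensus}\t{_truncnorm_int(rng, 40, 8)}\t{q}\t60\t{cov}\t"
            + "." * cov + "\t" + "I" * cov
        )
        glines.append(f"{chrom}\t{pos}\t{''.join(sorted(gold_alleles))}")
    with open(pileup_path, "w", encoding="utf-8") as fh:
        fh.writelines(line + "\n" for line in plines)
    with open(gold_path, "w", encoding="utf-8") as fh:
        fh.writelines(line + "\n" for line in glines)
    return planted
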