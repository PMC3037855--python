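"""Genotyping quality control against a gold-standard genotype set.

Experimental consensus calls (a pileup) are compared position by position
with externally trusted genotypes. Three detection tasks are scored
separately:

* ``any-variant`` — is the site non-reference at all?
* ``heterozygous-variant`` — is it a heterozygous variant, with the right
  alleles?
* ``homozygous-variant`` — is it a homozygous non-reference variant, with
  the right allele?

For the two zygosity classes the default is strict: a true positive needs
the allele sets to be *equal*. A call with the right zygosity but the wrong
allele(s) is simultaneously a false positive (the prediction is wrong) and a
false negative (the true genotype was missed); the laxer zygosity-only
scoring is available via ``exact_alleles=False``.

A ROC sweep over SNP-quality thresholds treats calls below the cutoff as
homozygous-reference predictions ("not detected") and reports, per class,
(threshold, TPR, FPR) rows plus the Youden-J-optimal threshold — the usual
way to pick an operating SNP-quality cutoff for a pipeline.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

from .errors import MalformedLineError, NoGenotypeError
from .model import ALLELES_TO_IUPAC, is_comment, iupac_alleles, parse_pileup_line
from .search import GPFile

CLASSES = ("any-variant", "heterozygous-variant", "homozygous-variant")

METRIC_HELP = {
    "sensitivity": "TP/(TP+FN): fraction of true class members detected (recall)",
    "specificity": "TN/(TN+FP): fraction of non-members correctly rejected",
    "ppv": "TP/(TP+FP): precision; fraction of positive calls that are right",
    "npv": "TN/(TN+FN): fraction of negative calls that are right",
    "accuracy": "(TP+TN)/(TP+FP+TN+FN): overall agreement with the gold standard",
}


@dataclass(frozen=True)
class GoldStandardCall:
    """One trusted genotype: chromosome, position and 1-2 true alleles."""

    chrom: str
    pos: int
    alleles: frozenset[str]

    @property
    def heterozygous(self) -> bool:
        return len(self.alleles) == 2


def parse_gold_line(line: str, line_no: int = 0, path: str | None = None) -> GoldStandardCall:
    """Parse ``chrom \\t pos \\t genotype`` where genotype is a two-letter
    allele string ("AG") or a single IUPAC code ("R")."""
    fields = line.rstrip("\n").split("\t")
    if len(fields) < 3:
        raise MalformedLineError("gold-standard line needs 3 columns", line_no, path)
    try:
        pos = int(fields[1])
    except ValueError:
        raise MalformedLineError(f"position {fields[1]!r} is not an integer", line_no, path) from None
    geno = fields[2].upper()
    if len(geno) == 1:
        try:
            alleles = iupac_alleles(geno)
        except NoGenotypeError:
            raise MalformedLineError(f"genotype {geno!r} carries no allele set", line_no, path) from None
    elif len(geno) == 2 and set(geno) <= set("ACGT"):
        alleles = frozenset(geno)
    else:
        raise MalformedLineError(f"cannot parse genotype {fields[2]!r}", line_no, path)
    return GoldStandardCall(fields[0], pos, alleles)


def load_gold_standard(path: str | os.PathLike) -> list[GoldStandardCall]:
    calls = []
    with open(path, encoding="utf-8") as fh:
        for line_no, line in enumerate(fh, 1):
            stripped = line.rstrip("\n")
            if not stripped or is_comment(stripped):
                continue
            calls.append(parse_gold_line(stripped, line_no, os.fspath(path)))
    return calls


@dataclass
class ConfusionTally:
    class_label: str
    tp: int = 0
    fp: int = 0
    tn: int = 0
    fn: int = 0

    def add(self, outcome: str) -> None:
        setattr(self, outcome.lower(), getattr(self, outcome.lower()) + 1)

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def classify_call(
    ref_base: str,
    call_alleles: frozenset[str],
    gold_alleles: frozenset[str],
    exact_alleles: bool = True,
) -> dict[str, tuple[str, ...]]:
    """Score one compared position for the three detection classes.

    Returns class -> tuple of outcomes ("TP"/"FP"/"TN"/"FN"). The tuple has
    one element except for the strict-mode wrong-allele case (right zygosity,
    wrong alleles), which counts as ("FP", "FN"): wrong as a prediction and
    missed as a truth.
    """
    ref = frozenset((ref_base,))
    out: dict[str, tuple[str, ...]] = {}

    truth_any = gold_alleles != ref
    pred_any = call_alleles != ref
    out["any-variant"] = (("TP" if truth_any else "FP") if pred_any
                          else ("FN" if truth_any else "TN"),)

    for label, is_member in (
        ("heterozygous-variant", lambda g: len(g) == 2),
        ("homozygous-variant", lambda g: len(g) == 1 and g != ref),
    ):
        truth, pred = is_member(gold_alleles), is_member(call_alleles)
        if truth and pred:
            if not exact_alleles or call_alleles == gold_alleles:
                out[label] = ("TP",)
            else:
                out[label] = ("FP", "FN")
        elif truth:
            out[label] = ("FN",)
        elif pred:
            out[label] = ("FP",)
        else:
            out[label] = ("TN",)
    return out


@dataclass(frozen=True)
class RocPoint:
    threshold: float
    tpr: float | None  # None when the class has no condition positives
    fpr: float | None
    tallies: dict = field(compare=False, default=None)


@dataclass
class ComparedSite:
    """One gold position matched (or not) against the experimental file."""

    gold: GoldStandardCall
    ref_base: str | None          # None when the site is uncovered
    call_alleles: frozenset[str] | None
    snp_quality: float


def collect_compared_sites(
    experimental: str | os.PathLike,
    gold: Sequence[GoldStandardCall],
) -> tuple[list[ComparedSite], int]:
    """Look up every gold position in the experimental pileup (binary search).

    Returns (sites, n_not_evaluable). Calls whose consensus is N carry no
    genotype and are excluded, counted as not evaluable. Uncovered positions
    are kept with ``ref_base=None`` — downstream decides how to score them.
    """
    sites: list[ComparedSite] = []
    skipped = 0
    with GPFile(experimental) as gp:
        for g in gold:
            lines = list(gp.query(g.chrom, g.pos, g.pos))
            if not lines:
                sites.append(ComparedSite(g, None, None, 0.0))
                continue
            rec = parse_pileup_line(lines[0], path=gp.path)
            try:
                alleles = iupac_alleles(rec.consensus)
            except NoGenotypeError:
                skipped += 1
                continue
            sites.append(ComparedSite(g, rec.ref_base, alleles, rec.snp_quality))
    return sites, skipped


def tally_sites(
    sites: Iterable[ComparedSite],
    threshold: float = 0.0,
    exact_alleles: bool = True,
    require_coverage: bool = False,
) -> dict[str, ConfusionTally]:
    """Confusion tallies per class at one SNP-quality threshold.

    Calls with snp_quality < threshold are treated as homozygous-reference
    predictions (the variant is "not detected"). Gold positions missing from
    the experimental file count as FN when the gold genotype is a class
    positive (a missed site is a miss) and are excluded otherwise; with
    ``require_coverage`` they are excluded entirely.
    """
    tallies = {c: ConfusionTally(c) for c in CLASSES}
    for s in sites:
        if s.ref_base is None:
            if require_coverage:
                continue
            # Uncovered site: there is no reference base to compare against.
            # Heterozygous gold genotypes are variants by construction;
            # homozygous ones are assumed non-reference (gold standards list
            # sites of interest). Either way a missed site is a miss: FN.
            tallies["any-variant"].add("FN")
            if s.gold.heterozygous:
                tallies["heterozygous-variant"].add("FN")
            else:
                tallies["homozygous-variant"].add("FN")
            continue
        call = s.call_alleles
        if s.snp_quality < threshold:
            call = frozenset((s.ref_base,))
        outcomes = classify_call(s.ref_base, call, s.gold.alleles, exact_alleles)
        for label, outs in outcomes.items():
            for o in outs:
                tallies[label].add(o)
    return tallies


def compute_metrics(tally: ConfusionTally) -> dict[str, float | None]:
    """Sensitivity, specificity, PPV, NPV and accuracy from one tally.

    A metric whose denominator is zero is reported as None (not available),
    never as 0.
    """
    def ratio(num: int, den: int) -> float | None:
        return num / den if den > 0 else None

    t = tally
    return {
        "sensitivity": ratio(t.tp, t.tp + t.fn),
        "specificity": ratio(t.tn, t.tn + t.fp),
        "ppv": ratio(t.tp, t.tp + t.fp),
        "npv": ratio(t.tn, t.tn + t.fn),
        "accuracy": ratio(t.tp + t.tn, t.total),
    }


@dataclass
class RocResult:
    points: dict[str, list[RocPoint]]            # class -> sweep rows
    best_threshold: dict[str, float | None]      # class -> Youden-J maximizer
    n_not_evaluable: int = 0


def roc_sweep(
    experimental: str | os.PathLike,
    gold: Sequence[GoldStandardCall],
    thresholds: Sequence[float],
    exact_alleles: bool = True,
    require_coverage: bool = False,
) -> RocResult:
    """Confusion tallies and (TPR, FPR) at each SNP-quality threshold.

    Thresholds must be sorted ascending. The suggested operating cutoff per
    class maximizes Youden's J = TPR - FPR; ties break toward the lower
    threshold (higher sensitivity).
    """
    if list(thresholds) != sorted(thresholds):
        raise ValueError("thresholds must be sorted ascending")
    sites, skipped = collect_compared_sites(experimental, gold)
    points: dict[str, list[RocPoint]] = {c: [] for c in CLASSES}
    for t in thresholds:
        tallies = tally_sites(sites, t, exact_alleles, require_coverage)
        for c in CLASSES:
            tl = tallies[c]
            tpr = tl.tp / (tl.tp + tl.fn) if (tl.tp + tl.fn) > 0 else None
            fpr = tl.fp / (tl.fp + tl.tn) if (tl.fp + tl.tn) > 0 else None
            points[c].append(RocPoint(t, tpr, fpr, {c2: tallies[c2] for c2 in CLASSES}))
    best: dict[str, float | None] = {}
    for c in CLASSES:
        best_j, best_t = None, None
        for pt in points[c]:
            if pt.tpr is None or pt.fpr is None:
                continue
            j = pt.tpr - pt.fpr
            if best_j is None or j > best_j + 1e-12:
                best_j, best_t = j, pt.threshold
        best[c] = best_t
    return RocResult(points, best, skipped)


def consensus_code(alleles: frozenset[str]) -> str:
    """Inverse of iupac_alleles, for report output."""
    return ALLELES_TO_IUPAC[alleles]
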