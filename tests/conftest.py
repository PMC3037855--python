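"""Shared helpers: independent oracles and small random-input generators.

The oracles here deliberately avoid the code paths they check: the Fisher
oracle enumerates tables in exact integer arithmetic; the range-query oracle
is a predicate filter over all lines; the join oracle is a nested loop.
"""

import math
import random

import pytest
from hypothesis import settings

settings.register_profile("suite", deadline=None, derandomize=True)
settings.load_profile("suite")


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------

CHROM_POOL = ["chr1", "chr2", "chr3", "chr10", "chrX", "scaffold_7"]


def random_sorted_gp_lines(rng: random.Random, n_lines: int, n_chroms: int = 3,
                           max_pos: int = 10**6, dup_rate: float = 0.05):
    """Sorted GP lines with ragged trailing fields and duplicate positions."""
    chroms = rng.sample(CHROM_POOL, n_chroms)
    lines = []
    per = [n_lines // n_chroms] * n_chroms
    per[0] += n_lines - sum(per)
    for chrom, n in zip(chroms, per):
        if n == 0:
            continue
        positions = sorted(rng.sample(range(1, max_pos + 1), n))
        for pos in positions:
            copies = 1 + (1 if rng.random() < dup_rate else 0)
            for c in range(copies):
                extra = "\t".join(
                    f"f{rng.randrange(1000)}" for _ in range(rng.randrange(0, 4))
                )
                line = f"{chrom}\t{pos}" + ("\t" + extra if extra else "")
                lines.append(line)
    return lines


def write_lines(path, lines):
    with open(path, "w", encoding="utf-8") as fh:
        fh.writelines(line + "\n" for line in lines)
    return str(path)


# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------

def linear_scan_range(lines, chrom, start, end):
    """Grep-style oracle for region queries: full scan with a predicate."""
    out = []
    for line in lines:
        f = line.split("\t", 2)
        if f[0] == chrom and start <= int(f[1]) <= end:
            out.append(line)
    return out


def exact_fisher_p(a, b, c, d):
    """Two-sided Fisher p by exhaustive same-margin enumeration in exact
    integer arithmetic (point-probability ordering, 1e-7 relative cushion
    applied to integer weights, so no floating-point rounding at all)."""
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    lo, hi = max(0, c1 - r2), min(r1, c1)
    weights = {k: math.comb(r1, k) * math.comb(r2, c1 - k) for k in range(lo, hi + 1)}
    w_obs = weights[a]
    # integer form of w <= w_obs * (1 + 1e-7)
    num = sum(w for w in weights.values() if w * 10**7 <= w_obs * (10**7 + 1))
    return num / math.comb(n, c1)


def nested_loop_join(a_recs, b_recs, mode):
    """O(n*m) relational join oracle on (chrom, pos) keys."""
    out = []
    b_matched = [False] * len(b_recs)
    for ra in a_recs:
        hit = False
        for j, rb in enumerate(b_recs):
            if (ra.chrom, ra.pos) == (rb.chrom, rb.pos):
                out.append(("match", ra, rb))
                hit = True
                b_matched[j] = True
        if not hit and mode == "left-outer":
            out.append(("left", ra, None))
    if mode == "right-outer":
        # right orphans appear in b order, merged into coordinate order later
        for j, rb in enumerate(b_recs):
            if not b_matched[j]:
                out.append(("right", None, rb))
    return out


def all_pairs_containment(positions, intervals):
    """Per-position covering intervals by testing every pair."""
    result = []
    for chrom, pos in positions:
        covering = [
            iv for iv in intervals
            if iv.chrom == chrom and iv.start <= pos <= iv.end
        ]
        result.append(covering)
    return result


@pytest.fixture
def rng():
    return random.Random(20260927)
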