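"""Case/control comparison of variant calls.

Two-sample mode reports every position whose consensus genotype differs
between a case and a control (looking reference calls up in the full
pileups). N-sample mode tallies, per position, which samples carry it and
runs a two-sided Fisher's exact test on the case/control presence table —
small p flags positions reproducible in one condition and rare in the other.
"""

import dataclasses
import tempfile
from pathlib import Path

from piletools import FixtureSpec, generate_pileup, n_sample_compare, two_sample_compare
from piletools.synth import write_variant_subset

workdir = Path(tempfile.mkdtemp())
spec = FixtureSpec(seed=8, n_lines=2000, variant_rate=0.05,
                   chroms=(("chr1", 2_000_000),))
samples = {}
for i, name in enumerate(["control1", "control2", "control3",
                          "case1", "case2", "case3"]):
    full = workdir / f"{name}.pileup"
    var = workdir / f"{name}.variants.pileup"
    truths = generate_pileup(dataclasses.replace(spec, seed=100 + i), full)
    write_variant_subset(truths, full, var)
    samples[name] = (full, var)

calls = list(two_sample_compare(samples["control1"][0], samples["case1"][0],
                                samples["control1"][1], samples["case1"][1]))
print(f"2-sample: {len(calls)} discrepant positions between control1 and case1")
for c in calls[:3]:
    # genotype_a/_b are IUPAC consensus codes; '.' means no line in that sample
    print("   ", c.serialize())

rows = list(n_sample_compare([samples[f"control{i}"][1] for i in (1, 2, 3)],
                             [samples[f"case{i}"][1] for i in (1, 2, 3)]))
rows.sort(key=lambda r: r.p)
print(f"\nn-sample: {len(rows)} positions seen in >=1 of 6 samples; most group-specific:")
for r in rows[:3]:
    t = r.counts
    print(f"    {r.chrom}:{r.pos}  cases with/without = {t.a}/{t.b}, "
          f"controls = {t.c}/{t.d}, Fisher p = {r.p:.3g}")
print("(independent samples here, so p-values should rarely be small:",
      f"{sum(r.p < 0.05 for r in rows)} of {len(rows)} below 0.05)")
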