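"""Genotyping QC: score consensus calls against a gold standard and pick a
SNP-quality threshold from a ROC sweep.

The fixture plants 500 real variants called at quality ~45 and 500 spurious
variant calls at quality ~8 on gold-reference sites; the sweep should place
the Youden-optimal cutoff between the two quality distributions.
"""

import tempfile
from pathlib import Path

from piletools import compute_metrics, load_gold_standard, roc_sweep
from piletools.synth import generate_genotest_data

workdir = Path(tempfile.mkdtemp())
exp, gold_path = workdir / "experiment.pileup", workdir / "gold.tsv"
generate_genotest_data(2024, exp, gold_path, n_true=500, n_false=500)

gold = load_gold_standard(gold_path)
result = roc_sweep(exp, gold, thresholds=list(range(0, 61, 5)))

print("class                  sens    spec    ppv     accuracy (threshold 0)")
first = result.points["any-variant"][0].tallies
for cls, tally in first.items():
    m = compute_metrics(tally)
    fmt = lambda v: "  NA " if v is None else f"{v:.3f}"
    print(f"{cls:22s} {fmt(m['sensitivity'])}  {fmt(m['specificity'])}  "
          f"{fmt(m['ppv'])}  {fmt(m['accuracy'])}")

best = result.best_threshold["any-variant"]
at_best = next(p for p in result.points["any-variant"] if p.threshold == best)
print(f"\nYouden-optimal SNP-quality threshold (any-variant): {best}")
print(f"at that cutoff: TPR = {at_best.tpr:.3f}, FPR = {at_best.fpr:.3f}")
print("ROC points (threshold, TPR, FPR):")
for p in result.points["any-variant"]:
    print(f"    {p.threshold:>4g}  {p.tpr:.3f}  {p.fpr:.3f}")
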