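"""Filter and annotate positions with BED/GFF intervals, and join two GP
files by coordinate.

BED is 0-based half-open, GFF 1-based closed; both are converted to the same
internal convention at the reader, so the two encodings of one interval set
keep identical positions.
"""

import tempfile
from pathlib import Path

from piletools import (
    filter_positions,
    generate_intervals,
    iter_gp_records,
    join_files,
    load_intervals,
)

workdir = Path(tempfile.mkdtemp())
chroms = (("chr1", 10_000),)
generate_intervals(5, chroms, 4, workdir / "regions.bed", workdir / "regions.gff",
                   mean_length=800)

gp_lines = [f"chr1\t{pos}\tcall{pos}" for pos in range(100, 10_000, 250)]
records = lambda: iter_gp_records(iter(gp_lines))

for src in ("regions.bed", "regions.gff"):
    intervals = load_intervals(workdir / src)
    kept = list(filter_positions(records(), intervals))
    print(f"{src}: {len(intervals)} intervals keep {len(kept)} of {len(gp_lines)} positions")

annotated = list(filter_positions(records(), load_intervals(workdir / "regions.bed"),
                                  annotate=True))
inside = [l for l in annotated if not l.endswith("\t.")]
print(f"annotate mode keeps all {len(annotated)} lines; {len(inside)} carry labels, e.g.:")
for line in inside[:2]:
    print("   ", line)

# coordinate join: attach an annotation column, keeping unmatched lines
ann = [f"chr1\t{pos}\trs{pos}" for pos in range(100, 10_000, 500)]
joined = list(join_files(iter_gp_records(iter(gp_lines)), iter_gp_records(iter(ann)),
                         mode="left-outer"))
print(f"\nleft-outer join: {len(joined)} lines ('.' pads positions without a match)")
for line in joined[:2]:
    print("   ", line)
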