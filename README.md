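# piletools

A streaming toolkit for **genomic-position (GP) flat files** — the
tab-delimited, one-line-per-covered-position text files (SAMtools consensus
pileup, BED, GFF, VCF) that NGS resequencing workflows revolve around. These
files reach billions of lines for a human genome, so piletools never loads
an input into memory and never builds an index: random access comes from
**direct binary search over byte offsets of the sorted file**, costing
O(log₂ N) line reads per query, and every other operation is a single
sorted-stream pass.

It is aimed at people running variant-calling pipelines from the shell or
from Python: extracting regions, sorting and joining per-position tables,
filtering against interval sets, comparing case/control samples at variant
level, QC-ing genotype calls against a trusted reference set, and preparing
batch inputs for mutation-effect predictors.

## What's inside

| tool | does |
|---|---|
| `fastseek` | print all lines in `chrom:start:end` of a sorted GP file, no index |
| `sort` | external-merge sort by genomic coordinate, bounded memory |
| `fastjoin` | merge-join two sorted GP files on (chrom, pos); inner/left/right outer |
| `rfilter` | keep positions inside BED/GFF intervals, or annotate all positions with covering intervals |
| `2smc` | two-sample (case vs control) discrepant-genotype report |
| `nsmc` | n-sample comparison: per-position presence flags + two-sided Fisher's exact test |
| `genotest` | genotyping QC vs a gold standard: sensitivity/specificity/PPV/NPV/accuracy per class + ROC over SNP-quality thresholds with Youden-optimal cutoff |
| `pileup2sift` / `pileup2polyphen` / `pileup2firestar` | predictor batch inputs from variant lines |
| `fixtures` | deterministic synthetic pileups/intervals/gold standards |

Statistics in brief: `nsmc` tests each position's 2×2 presence table
(a = cases with the variant, b = cases without; c, d likewise for controls)
with the exact two-sided Fisher test — p = Σ P(T) over all same-margin
tables T with P(T) ≤ P(observed), P hypergeometric. `genotest` scores three
detection classes (any-variant, heterozygous, homozygous; exact allele match
required for the zygosity classes) and sweeps SNP-quality cutoffs t, scoring
calls with quality < t as "not detected", to report (t, TPR, FPR) and the
t maximizing Youden's J = TPR − FPR.

## Worked example

```bash
# deterministic synthetic sample: sorted pileup + variant subset + intervals
cat > spec.cfg <<EOF
seed=5
n_lines=120
variant_rate=0.2
chroms=chr1:50000,chr2:40000
n_intervals=4
EOF
piletools fixtures --spec spec.cfg --out-dir demo

# a) region extraction without an index (read-bases/quals columns trimmed here)
piletools fastseek -p demo/sample.pileup -s chr1:1:20000 | head -3 | cut -f1-8
```
```
chr1	117	G	K	39	43	60	38
chr1	349	A	A	46	1	60	25
chr1	860	T	T	45	2	60	29
```
Each line is one covered position: reference base, IUPAC consensus, consensus
quality, SNP quality, max mapping quality, depth. The first line is a
heterozygous G/T variant (consensus K) with SNP quality 43; the other two are
reference calls with near-zero SNP quality.

```bash
# b) SIFT batch input from the variant calls
piletools pileup2sift -i demo/sample.variants.pileup | head -3
```
```
chr1,117,1,G/T
chr1,1414,1,C/G
chr1,1901,1,T/C
```

```bash
# c) which variant positions fall inside the interval set?
piletools rfilter -i demo/sample.variants.pileup -r demo/regions.bed | wc -l
```
Piping works because every tool writes pure records to stdout and reads
stdin when `-i` is omitted:

```bash
piletools fastseek -p demo/sample.variants.pileup -s chr1:1:50000 | piletools pileup2sift
```

converts exactly the variants of the extracted region (`chr1,117,1,G/T`, ...).

From Python the same operations are plain functions (see `examples/` for
runnable walkthroughs of region queries, case/control comparison,
genotyping QC, interval annotation and predictor-input generation):

```python
from piletools import GPFile, n_sample_compare

with GPFile("demo/sample.pileup") as gp:
    lines = list(gp.query("chr1", 1, 20_000))   # O(log N) probes, O(1) memory
```

Running `python examples/genotyping_qc.py` prints, for a fixture with 500
true variant calls (SNP quality ≈ 45 ± 5) and 500 spurious calls
(≈ 8 ± 3):

```
Youden-optimal SNP-quality threshold (any-variant): 20
at that cutoff: TPR = 1.000, FPR = 0.000
```

i.e. the sweep recovers a cutoff between the two quality distributions that
keeps every true variant and rejects every spurious call.

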