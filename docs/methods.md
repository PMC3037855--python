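# Methods

## The problem

Resequencing pipelines reduce alignments to *genomic-position (GP) files*:
tab-delimited text with one line per covered position, chromosome name and
1-based coordinate in the first two columns (SAMtools consensus pileup, BED,
GFF and VCF all fit this shape structurally). A human whole-genome pileup
runs to billions of lines, so anything that loads a file — or builds and
maintains an index — is already a bottleneck. piletools operates on these
files directly on disk: every tool streams, and random access is obtained by
binary search over byte offsets of the already-sorted file.

## Index-free region queries

A region query `chrom:start:end` proceeds in two stages on a sorted file.

1. **Block discovery.** In a coordinate-sorted file all lines of one
   chromosome are contiguous. The byte extent of each block is found by a
   boundary binary search on the predicate "this line still belongs to the
   current chromosome": start from the block's first line, probe the
   midpoint of the remaining byte range, realign the probe to the start of
   the line containing it (scan back to the previous newline), and halve.
   This costs O(#chromosomes · log₂ N) line reads instead of a full scan and
   is cached per open file (invalidated when the file size changes).
2. **Within-block search.** Binary search over byte offsets of the block for
   the first line with position ≥ start, then stream lines until position >
   end. Ties (duplicate positions) are resolved by continuing the search
   toward the lowest offset, so a run of same-position lines at a range
   boundary is never split.

Realignment to line starts makes the search indifferent to variable-length
lines; no fixed-width assumption is made anywhere. Memory per query is O(1)
lines. Probe counts (line-resolution reads) are exposed via `SearchStats`;
the test suite asserts the logarithmic form directly — growing a file 16×
adds about log₂ 16 = 4 probes per query — rather than wall-clock figures,
which depend on hardware.

**Sortedness is trusted, not verified.** A global check would cost the O(N)
scan the design exists to avoid. Violations are surfaced when encountered:
positions that decrease while streaming raise a not-sorted error, a
chromosome whose block reappears later is rejected during discovery, and
blocks smaller than a fixed byte budget (8 KiB) are verified exhaustively —
constant work per block, which keeps discovery o(N) while catching
violations in small files deterministically. A foreign line hiding between
probes deep inside a large block is not detectable without a linear scan;
this is an accepted limit of the design.

Coordinates are 1-based and inclusive on both ends everywhere internally
(the pileup convention); the query syntax is `chrom:start:end`.

## Chromosome ordering

Sorted GP files in the wild follow different chromosome orders (BAM-header
order, lexicographic, karyotype order). Region queries only need
*contiguity*, not any global order, so they accept all of them. Operations
that must compare chromosomes across inputs (sort, join, n-way merge) take a
`SequenceOrdering` with three modes: `natural` (digit runs compare
numerically: chr2 < chr10; the default for output), `lex` (plain string
order), and `file` (rank by first appearance, matching BAM-header-ordered
inputs). Merging tools require both inputs sorted under the same mode and
raise a not-sorted error with line numbers otherwise.

## Joins, interval filtering, external sort

**Join** is a streaming merge-join on (chromosome, position). Matched keys
emit the left line followed by the right line's trailing fields; duplicate
keys produce the Cartesian product of the two groups (standard relational
semantics — the only buffering beyond O(1) lines). In outer modes, orphan
lines of the preserved side are printed with the missing side padded by a
single `.` field by default: GP files have ragged trailing columns, so
rectangular padding would be a guess. `--pad-columns K` yields strict
rectangular output when the consumer needs it.

**Interval filtering** reads BED (0-based half-open) or GFF (1-based closed)
at the file boundary and converts both to internal 1-based inclusive
intervals, so a BED record `chr1 99 100` and a GFF record with start=end=100
cover the same single position. Filtering sweeps the sorted GP stream
against start-sorted intervals with an active set, O(overlapping intervals)
memory. Annotation mode appends one column: the `;`-joined labels of all
covering intervals in (start, end, input-order) order, `.` when none — output
stays strictly tab-delimited.

**Sort** is an external merge sort keyed on (chromosome rank, position)
only; trailing fields never participate. Runs of at most `memory_budget`
lines are sorted in memory and spilled to temporary files, then k-way
merged; equal keys keep input order (stable) via (run, within-run) sequence
numbers. Default budget is 500 000 lines (~50 MB of text) — small enough for
any workstation, large enough that files below ~10⁷ lines sort in one run.

## Two-sample and n-sample variant comparison

Genotypes are IUPAC allele sets: a consensus code maps to its 1–2 alleles
(R = {A,G} …), two calls are *concordant* iff the sets are equal —
qualities are deliberately ignored, and consensus N carries no genotype
(such calls are skipped, counted). The two-sample tool walks the union of
the two variant files and fetches the other sample's call at each position
from its *full* pileup by binary search, classifying each discrepancy as
`variant-only-in-A/B`, `different-variant`, or `no-coverage-in-other` when
the other full file has no line there — absence of evidence is flagged, not
assumed homozygous reference. A variant position missing from its own full
file is an input inconsistency and is a hard error.

The n-sample tool merges all variant files in one sorted pass; "sample
contains the position" means the position appears in that sample's variant
file (no quality gate here — upstream filtering owns that). Per position it
reports per-sample presence flags and the 2×2 table (cases with/without,
controls with/without) with a two-sided Fisher's exact test.

**Fisher's exact test.** Conditioned on both margins the first cell is
hypergeometric; the two-sided p-value sums the probabilities of all
same-margin tables whose point probability is ≤ the observed one (the
conventional rule; no mid-p). The ≤ comparison carries a 1e-7 relative
cushion so mathematically tied tables are never dropped to rounding, and
when every table qualifies the result is exactly 1 (the mass sums to 1 by
definition). Probabilities come from `scipy.stats.hypergeom`; the test suite
checks every table with total ≤ 30 against an exact integer-arithmetic
enumeration, and random tables against `scipy.stats.fisher_exact`. P-values
are reported raw, one per position; multiple-testing correction is a
downstream concern.

## Genotyping QC

Experimental consensus calls are compared with a gold-standard genotype
table (`chrom TAB pos TAB genotype`, genotype as a two-letter allele string
or one IUPAC code). Three detection tasks are scored: *any-variant*
(site non-reference at all), *heterozygous-variant* and *homozygous-variant*.
For the zygosity classes the default is strict: a true positive requires the
allele sets to be equal, and a right-zygosity wrong-allele call counts both
as a false positive (the prediction is wrong) and a false negative (the
truth was missed) — the only scoring under which allele errors and zygosity
errors stay distinguishable. Consequently a class tally's total can exceed
the number of compared positions by the number of such double-fault calls.
`--zygosity-only` restores the laxer zygosity-match scoring.

Gold positions absent from the experimental file count as false negatives (a
missed site is a miss); at an uncovered site no reference base exists, so
gold genotypes there are assumed non-reference (gold tables list sites of
interest). `--require-coverage` excludes them instead.

Metrics per class: sensitivity TP/(TP+FN), specificity TN/(TN+FP), PPV,
NPV, accuracy; a zero denominator reports NA, never 0. The ROC sweep
re-scores at each SNP-quality cutoff t, treating calls with quality < t as
homozygous-reference ("not detected"), and suggests the cutoff maximizing
Youden's J = TPR − FPR, ties broken toward the lower threshold (higher
sensitivity). Raising t only moves TP→FN and FP→TN, so TPR and FPR are
non-increasing in t and condition positives are constant — both asserted in
tests. Output is the raw (threshold, TPR, FPR) table; plotting is out of
scope.

## Predictor-input converters

Variant lines yield one `ref→alt` change per non-reference allele of the
consensus (a heterozygous call with two non-reference alleles yields two
records — lossless; predictors deduplicate). Dialects: SIFT batch
`chrom,pos,1,ref/alt` (strand constant 1: pileup is reference-forward),
PolyPhen-2 `chrom:pos ref/alt`, and a plain `chrom TAB pos TAB ref TAB alt`
layout for firestar (that service's exact batch dialect is not publicly
pinned down; this column layout is the package's own choice and trivially
reshaped downstream).

## Synthetic data

The generator emulates per-position consensus summaries: sorted pileups with
planted variants (configurable variant rate, het fraction, a small fraction
of heterozygous calls with no reference allele), SNP qualities from
truncated normals rounded to integers, optional duplicated positions and
optional shuffling. Defaults describe a well-separated callset — variant
calls at quality 45 ± 5 over a near-zero noise floor (2 ± 2) for invariant
sites; the genotyping-QC fixture plants 500 true calls at 45 ± 5 against
500 spurious calls at 8 ± 3, values chosen so the classes are separable and
a quality threshold between the distributions is recoverable. Every file
comes from a single RNG stream seeded by the spec with a frozen per-line
draw order, so identical specs give byte-identical files and extending the
generator cannot silently change existing fixtures. A companion truth table
records every planted genotype for oracle checks.

What the generator does *not* model: reads, alignment artefacts, indels,
GC- or mappability-structured error, linkage between neighbouring sites. The
read-bases and base-quality pileup columns are schematic placeholders.
Passing tests therefore demonstrate the correctness of the file mechanics
and statistics on well-formed inputs, not robustness to real-world caller
misbehaviour.

## Problem sizes and numerical choices

The scale-bearing checks run on generated files of 10³–10⁶ lines (twenty
sizes, geometrically spaced), 1000 random range queries per file against a
scan oracle; probe growth is measured between 62 500- and 10⁶-line files
(16×, expecting ≈ +4 probes); memory high-water marks are measured with
tracemalloc on the 10⁶-line file (a query must stay under 8 MiB, the
external sort under 32 MiB at a 10 000-line budget). Fisher exactness is
checked exhaustively for all 46 376 tables with total ≤ 30 at 1e-12 relative
tolerance. These sizes are the package's own test design: large enough that
asymptotic behaviour is visible, small enough to run on a laptop in a couple
of minutes.

Degenerate inputs: empty query results are success, not errors; an all-zero
contingency table is a degenerate-table error; a 0/0 metric is NA; malformed
lines are hard errors by default, downgradable to counted warnings with
`--skip-malformed` — silent corruption of position data is worse than
failure.

## Known limitations

- Sortedness of large chromosome blocks is trusted (see above).
- Compressed files are out of scope: binary search needs byte-addressable
  text (no BGZF/tabix interplay).
- Join matches on coordinates only, not on reference base agreement.
- The n-sample Fisher test treats samples as independent and presence as
  binary; it is a screening statistic, not a genotype-likelihood model.
- Header lines are expected at the top of a file only; a comment line in the
  middle of a sorted file will break block discovery.
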