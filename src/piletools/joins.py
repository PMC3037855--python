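"""Coordinate joins, interval filtering/annotation and external sorting.

All three operations stream: they hold O(1) lines (plus duplicate-key groups
or the configured sort buffer) no matter how large the inputs are.
"""

from __future__ import annotations

import heapq
import os
import tempfile
from dataclasses import dataclass
from typing import Iterable, Iterator, Sequence

from .errors import MalformedIntervalError, MalformedLineError, NotSortedError, UsageError
from .model import GPRecord, SequenceOrdering, is_comment, parse_gp_line

JOIN_MODES = ("inner", "left-outer", "right-outer")


@dataclass(frozen=True)
class GenomicInterval:
    """A 1-based, both-ends-inclusive interval with a display label.

    BED's 0-based half-open records are converted at the reader boundary
    (:func:`load_intervals`); internally every interval covers exactly
    ``end - start + 1`` positions.
    """

    chrom: str
    start: int
    end: int
    label: str

    def covers(self, pos: int) -> bool:
        return self.start <= pos <= self.end


# ---------------------------------------------------------------------------
# fastjoin
# ---------------------------------------------------------------------------

def _keyed_groups(records: Iterable[GPRecord], ordering: SequenceOrdering, name: str):
    """Yield (sort_key, [records]) groups of consecutive equal coordinates,
    raising NotSortedError (with line numbers) on order violations."""
    group: list[GPRecord] = []
    group_key = None
    prev_key = None
    line_no = 0
    for rec in records:
        line_no += 1
        key = (ordering.rank(rec.chrom), rec.pos)
        if prev_key is not None and key < prev_key:
            raise NotSortedError(
                f"{name}: record {line_no} ({rec.chrom}:{rec.pos}) out of order"
            )
        prev_key = key
        if key == group_key:
            group.append(rec)
        else:
            if group:
                yield group_key, group
            group, group_key = [rec], key
    if group:
        yield group_key, group


def join_files(
    a: Iterable[GPRecord],
    b: Iterable[GPRecord],
    mode: str = "inner",
    ordering: SequenceOrdering | None = None,
    pad_columns: int = 1,
) -> Iterator[str]:
    """Merge-join two sorted GP streams on (chromosome, position).

    Matched keys emit a's full line followed by b's trailing fields; within a
    duplicate-key group the Cartesian product is emitted (standard relational
    semantics). In ``left-outer`` (resp. ``right-outer``) mode, unmatched
    lines of a (resp. b) are also printed, with the missing side's fields
    padded by ``pad_columns`` "." placeholder fields.
    """
    if mode not in JOIN_MODES:
        raise UsageError(f"unknown join mode {mode!r}; expected one of {JOIN_MODES}")
    ordering = ordering or SequenceOrdering("natural")
    pad = ("." ,) * pad_columns
    ga = _keyed_groups(a, ordering, "left input")
    gb = _keyed_groups(b, ordering, "right input")
    ka, grp_a = next(ga, (None, None))
    kb, grp_b = next(gb, (None, None))
    while grp_a is not None or grp_b is not None:
        if grp_b is None or (grp_a is not None and ka < kb):
            if mode == "left-outer":
                for ra in grp_a:
                    yield "\t".join((ra.chrom, str(ra.pos)) + ra.rest + pad)
            ka, grp_a = next(ga, (None, None))
        elif grp_a is None or kb < ka:
            if mode == "right-outer":
                for rb in grp_b:
                    yield "\t".join((rb.chrom, str(rb.pos)) + pad + rb.rest)
            kb, grp_b = next(gb, (None, None))
        else:
            for ra in grp_a:
                for rb in grp_b:
                    yield "\t".join((ra.chrom, str(ra.pos)) + ra.rest + rb.rest)
            ka, grp_a = next(ga, (None, None))
            kb, grp_b = next(gb, (None, None))


# ---------------------------------------------------------------------------
# rfilter
# ---------------------------------------------------------------------------

def load_intervals(path: str | os.PathLike, fmt: str | None = None) -> list[GenomicInterval]:
    """Read a BED or GFF file into 1-based inclusive intervals.

    Format is inferred from the extension unless forced. BED records are
    0-based half-open, so (chrom, s, e) covers 1-based positions s+1..e; GFF
    records are 1-based closed and map verbatim. Labels come from BED column
    4 / the GFF attributes column when present, else "chrom:start-end".
    """
    path = os.fspath(path)
    if fmt is None:
        ext = os.path.splitext(path)[1].lower()
        if ext == ".bed":
            fmt = "bed"
        elif ext in (".gff", ".gff3", ".gtf"):
            fmt = "gff"
        else:
            raise UsageError(f"cannot infer interval format from {path!r}; pass fmt explicitly")
    if fmt not in ("bed", "gff"):
        raise UsageError(f"unknown interval format {fmt!r}")
    intervals: list[GenomicInterval] = []
    with open(path, encoding="utf-8") as fh:
        for line_no, line in enumerate(fh, 1):
            stripped = line.rstrip("\n")
            if not stripped or is_comment(stripped):
                continue
            fields = stripped.split("\t")
            if fmt == "bed":
                if len(fields) < 3:
                    raise MalformedLineError("BED line needs >= 3 columns", line_no, path)
                chrom, s, e = fields[0], int(fields[1]), int(fields[2])
                if s >= e:
                    raise MalformedIntervalError(
                        f"{path}:line {line_no}: empty BED interval [{s}, {e})"
                    )
                start, end = s + 1, e
                label = fields[3] if len(fields) > 3 and fields[3] else f"{chrom}:{start}-{end}"
            else:
                if len(fields) < 5:
                    raise MalformedLineError("GFF line needs >= 5 columns", line_no, path)
                chrom, start, end = fields[0], int(fields[3]), int(fields[4])
                if start > end:
                    raise MalformedIntervalError(
                        f"{path}:line {line_no}: inverted GFF interval {start}..{end}"
                    )
                label = fields[8] if len(fields) > 8 and fields[8] not in ("", ".") else f"{chrom}:{start}-{end}"
            intervals.append(GenomicInterval(chrom, start, end, label))
    return intervals


def filter_positions(
    gp: Iterable[GPRecord],
    intervals: Sequence[GenomicInterval],
    annotate: bool = False,
) -> Iterator[str]:
    """Keep (or annotate) GP lines covered by at least one interval.

    Filter mode emits exactly the input lines whose position falls inside
    >= 1 interval. Annotate mode emits *every* line with one extra
    tab-separated column: the ';'-joined labels of all covering intervals,
    or "." when none cover.

    The GP stream must be sorted (contiguous chromosome blocks,
    non-decreasing positions); intervals may overlap arbitrarily and are
    swept with O(active intervals) memory. Covering labels are reported in
    (start, end, input order) of the intervals.
    """
    by_chrom: dict[str, list[tuple[int, int, int, str]]] = {}
    for i, iv in enumerate(intervals):
        by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end, i, iv.label))
    for lst in by_chrom.values():
        lst.sort(key=lambda t: (t[0], t[1], t[2]))

    done_chroms: set[str] = set()
    cur_chrom: str | None = None
    pending: list[tuple[int, int, int, str]] = []
    idx = 0
    active: list[tuple[int, int, int, str]] = []
    prev_pos = 0

    for rec in gp:
        if rec.chrom != cur_chrom:
            if rec.chrom in done_chroms:
                raise NotSortedError(
                    f"chromosome {rec.chrom!r} occurs in non-contiguous blocks"
                )
            if cur_chrom is not None:
                done_chroms.add(cur_chrom)
            cur_chrom = rec.chrom
            pending = by_chrom.get(cur_chrom, [])
            idx = 0
            active = []
            prev_pos = 0
        if rec.pos < prev_pos:
            raise NotSortedError(
                f"positions decrease within chromosome {cur_chrom!r} "
                f"({prev_pos} then {rec.pos})"
            )
        prev_pos = rec.pos
        while idx < len(pending) and pending[idx][0] <= rec.pos:
            active.append(pending[idx])
            idx += 1
        if active:
            active = [iv for iv in active if iv[1] >= rec.pos]
        covering = [iv for iv in active if iv[0] <= rec.pos]
        if annotate:
            labels = ";".join(iv[3] for iv in covering) if covering else "."
            yield rec.raw_line + "\t" + labels
        elif covering:
            yield rec.raw_line


# ---------------------------------------------------------------------------
# sort
# ---------------------------------------------------------------------------

def sort_gp_lines(
    lines: Iterable[str],
    ordering: SequenceOrdering | None = None,
    memory_budget: int = 500_000,
    skip_malformed: bool = False,
) -> Iterator[str]:
    """Sort GP lines by (chromosome rank, position), stably, in bounded memory.

    At most ``memory_budget`` lines are held at once; larger inputs spill
    sorted runs to temporary files that are k-way merged. Ties (equal
    coordinates) preserve input order, and trailing fields never participate
    in the comparison. Comment lines are dropped (they have no coordinate to
    sort by); malformed lines raise unless ``skip_malformed``.
    """
    if memory_budget < 2:
        raise UsageError("memory_budget must be >= 2 lines")
    ordering = ordering or SequenceOrdering("natural")

    def keyed(raw_lines: Iterable[str]):
        for line_no, line in enumerate(raw_lines, 1):
            stripped = line.rstrip("\n")
            if not stripped or is_comment(stripped):
                continue
            head = stripped.split("\t", 2)
            try:
                if len(head) < 2:
                    raise MalformedLineError("fewer than 2 columns", line_no)
                try:
                    pos = int(head[1])
                except ValueError:
                    raise MalformedLineError(
                        f"position {head[1]!r} is not an integer", line_no
                    ) from None
                if pos < 1:
                    raise MalformedLineError(f"position {pos} is not >= 1", line_no)
            except MalformedLineError:
                if skip_malformed:
                    continue
                raise
            yield (ordering.rank(head[0]), pos), stripped

    with tempfile.TemporaryDirectory(prefix="piletools-sort-") as tmpdir:
        run_paths: list[str] = []
        buf: list[tuple[tuple, int, str]] = []
        seq = 0
        for key, line in keyed(lines):
            buf.append((key, seq, line))
            seq += 1
            if len(buf) >= memory_budget:
                buf.sort(key=lambda t: (t[0], t[1]))
                run_path = os.path.join(tmpdir, f"run{len(run_paths)}.gp")
                with open(run_path, "w", encoding="utf-8") as out:
                    out.writelines(t[2] + "\n" for t in buf)
                run_paths.append(run_path)
                buf = []
        buf.sort(key=lambda t: (t[0], t[1]))
        if not run_paths:
            for _, _, line in buf:
                yield line
            return
        if buf:
            run_path = os.path.join(tmpdir, f"run{len(run_paths)}.gp")
            with open(run_path, "w", encoding="utf-8") as out:
                out.writelines(t[2] + "\n" for t in buf)
            run_paths.append(run_path)
        buf = []

        def run_iter(path: str, run_idx: int):
            with open(path, encoding="utf-8") as fh:
                for within, (key, line) in enumerate(keyed(fh)):
                    # (run index, within-run sequence) reproduces input order
                    # for equal coordinates: runs are cut in input order
                    yield (key, run_idx, within, line)

        for _, _, _, line in heapq.merge(
            *(run_iter(p, i) for i, p in enumerate(run_paths))
        ):
            yield line


def sort_gp_file(
    in_path: str | os.PathLike,
    out_path: str | os.PathLike,
    ordering: SequenceOrdering | None = None,
    memory_budget: int = 500_000,
    skip_malformed: bool = False,
) -> None:
    """File-to-file wrapper around :func:`sort_gp_lines`."""
    with open(in_path, encoding="utf-8") as fin, open(out_path, "w", encoding="utf-8") as fout:
        for line in sort_gp_lines(fin, ordering, memory_budget, skip_malformed):
            fout.write(line + "\n")
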