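"""Index-free region queries on sorted GP files.

The central idea: a coordinate-sorted GP file can be range-queried without
building any auxiliary index by binary-searching directly over byte offsets.
Any byte offset is realigned to the start of the line containing it by
scanning back to the previous newline, so variable-length lines cost nothing.

A query proceeds in two stages:

1. discover the byte extent of each chromosome's contiguous block of lines
   (:func:`scan_sequence_bounds`), by galloping from block start to block
   end with a boundary binary search — o(N) probes, cached per open file;
2. binary-search within the queried chromosome's block for the first line
   whose position reaches the range start (:func:`seek_first_ge`), then
   stream lines forward until the range end.

Total cost is O(log2 N) line reads per query where N is the number of lines,
and memory stays at O(1) lines regardless of file size. Sortedness is
trusted, not verified up front (a global check would cost the linear scan
this design avoids); violations encountered while streaming raise
:class:`~piletools.errors.NotSortedError`.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterator

from .errors import NotSortedError, UsageError
from .model import GPRecord, is_comment, parse_gp_line

_CHUNK = 4096


@dataclass
class SearchStats:
    """Counts line-resolution disk reads (probes) performed by searches."""

    probes: int = 0
    file_lines: int | None = None

    def reset(self) -> None:
        self.probes = 0


@dataclass(frozen=True)
class SequenceBounds:
    """Byte extent of one chromosome's contiguous block of lines.

    ``first_offset``/``last_offset`` are the byte offsets of the first byte
    of the block's first and last lines; ``end_offset`` is one past the
    block's final byte (i.e. the next block's first_offset, or file size).
    """

    chrom: str
    first_offset: int
    last_offset: int
    end_offset: int


class GPFile:
    """Random-access wrapper over one sorted GP file on disk.

    Keeps a single read-only binary handle, a probe counter
    (:class:`SearchStats`) and a cached chromosome-bounds map invalidated
    when the file size changes.
    """

    def __init__(self, path: str | os.PathLike):
        self.path = os.fspath(path)
        self._fh = open(self.path, "rb")
        self.size = os.fstat(self._fh.fileno()).st_size
        self.stats = SearchStats()
        self._bounds: list[SequenceBounds] | None = None
        self._bounds_size: int | None = None

    def close(self) -> None:
        self._fh.close()

    def __enter__(self) -> "GPFile":
        return self

    def __exit__(self, *exc) -> None:
        self.close()

    # -- line-resolution access ------------------------------------------

    def read_line_at(self, offset: int) -> tuple[GPRecord, int, int]:
        """Return the record of the line *containing* ``offset``.

        Scans back to the previous newline (or file start) and forward to the
        line's end. Returns ``(record, line_start, next_line_start)``. Counts
        as one probe.
        """
        if offset < 0 or offset >= self.size:
            raise UsageError(f"offset {offset} outside file of {self.size} bytes")
        self.stats.probes += 1
        raw, start, nxt = self._raw_line_at(offset)
        return parse_gp_line(raw, path=self.path), start, nxt

    def _raw_line_at(self, offset: int) -> tuple[str, int, int]:
        fh = self._fh
        # scan back for the newline that terminates the previous line
        start = 0
        hi = offset
        while hi > 0:
            lo = max(0, hi - _CHUNK)
            fh.seek(lo)
            chunk = fh.read(hi - lo)
            idx = chunk.rfind(b"\n")
            if idx >= 0:
                start = lo + idx + 1
                break
            hi = lo
        # read forward to the line's end
        fh.seek(start)
        pieces = []
        pos = start
        while True:
            chunk = fh.read(_CHUNK)
            if not chunk:
                nxt = pos
                break
            idx = chunk.find(b"\n")
            if idx >= 0:
                pieces.append(chunk[:idx])
                nxt = pos + idx + 1
                break
            pieces.append(chunk)
            pos += len(chunk)
        raw = b"".join(pieces).decode("utf-8", errors="replace")
        return raw, start, nxt

    # -- block discovery --------------------------------------------------

    def sequence_bounds(self) -> list[SequenceBounds]:
        """Cached :func:`scan_sequence_bounds`; re-scanned if the file grew."""
        size = os.fstat(self._fh.fileno()).st_size
        if self._bounds is None or self._bounds_size != size:
            self.size = size
            self._bounds = scan_sequence_bounds(self)
            self._bounds_size = size
        return self._bounds

    def bounds_for(self, chrom: str) -> SequenceBounds | None:
        for b in self.sequence_bounds():
            if b.chrom == chrom:
                return b
        return None

    def query(self, chrom: str, start: int, end: int) -> Iterator[str]:
        """See :func:`query_range`."""
        return query_range(self, chrom, start, end)


def scan_sequence_bounds(gp: GPFile) -> list[SequenceBounds]:
    """Find the byte extent of every chromosome block by galloping probes.

    The file must be block-sorted: all lines of one chromosome contiguous.
    For each block the end boundary is located by binary search on the
    predicate "line still belongs to this chromosome", so the probe count is
    O(#chromosomes * log2 N), never a full scan. A chromosome whose block
    reappears later in the file raises :class:`NotSortedError` naming it and
    the offending offsets.
    """
    bounds: list[SequenceBounds] = []
    first_seen: dict[str, int] = {}
    off = _skip_leading_comments(gp)
    while off < gp.size:
        rec, start, line_end = gp.read_line_at(off)
        chrom = rec.chrom
        if chrom in first_seen:
            raise NotSortedError(
                f"{gp.path}: chromosome {chrom!r} occurs in non-contiguous blocks "
                f"(offsets {first_seen[chrom]} and {start})"
            )
        first_seen[chrom] = start
        # binary search over bytes for the start of the first line of a
        # different chromosome; lo is always just past a known same-chrom
        # line, hi is a known boundary-or-later byte
        lo, hi = line_end, gp.size
        while lo < hi:
            mid = (lo + hi) // 2
            mrec, mstart, mend = gp.read_line_at(mid)
            if mrec.chrom == chrom:
                lo = mend
            else:
                hi = mstart
        block_end = lo
        last_rec, last_start, _ = gp.read_line_at(block_end - 1)
        if last_rec.chrom != chrom:  # pragma: no cover - needs a mid-block chrom switchback
            raise NotSortedError(
                f"{gp.path}: chromosome {chrom!r} block at offset {start} is interleaved "
                f"with {last_rec.chrom!r}"
            )
        # Binary probing cannot see every line, so a foreign chromosome hiding
        # between probes inside a small block could go unnoticed. Blocks up to
        # a fixed byte budget are verified exhaustively — constant work per
        # block, so discovery stays o(N) overall; larger blocks are trusted
        # per the no-global-verification design.
        if block_end - start <= _VERIFY_BLOCK_BYTES:
            _verify_block(gp, chrom, start, block_end)
        bounds.append(SequenceBounds(chrom, start, last_start, block_end))
        off = block_end
    return bounds


_VERIFY_BLOCK_BYTES = 8192


def _verify_block(gp: GPFile, chrom: str, start: int, end: int) -> None:
    gp._fh.seek(start)
    off = start
    prev_pos = None
    while off < end:
        raw = gp._fh.readline()
        if not raw:
            break
        rec = parse_gp_line(raw.decode("utf-8", errors="replace").rstrip("\n"), path=gp.path)
        if rec.chrom != chrom:
            raise NotSortedError(
                f"{gp.path}: chromosome {rec.chrom!r} interrupts the {chrom!r} block "
                f"(offsets {start} and {off})"
            )
        if prev_pos is not None and rec.pos < prev_pos:
            raise NotSortedError(
                f"{gp.path}: positions decrease within chromosome {chrom!r} at offset {off}"
            )
        prev_pos = rec.pos
        off += len(raw)


def _skip_leading_comments(gp: GPFile) -> int:
    """Byte offset of the first record line (headers allowed at top only)."""
    off = 0
    while off < gp.size:
        raw, start, nxt = gp._raw_line_at(off)
        if raw and not is_comment(raw):
            return start
        off = nxt
    return off


def seek_first_ge(gp: GPFile, bounds: SequenceBounds, target_pos: int) -> int | None:
    """Offset of the first line in the block with position >= target_pos.

    Returns None when every position in the block is below the target.
    Duplicate positions resolve to the lowest offset among equal keys, so a
    range never splits a run of same-position lines. Probe count grows as
    log2 of the block's line count.
    """
    answer: int | None = None
    lo, hi = bounds.first_offset, bounds.end_offset
    while lo < hi:
        mid = (lo + hi) // 2
        rec, start, line_end = gp.read_line_at(mid)
        if rec.pos >= target_pos:
            answer = start
            hi = start
        else:
            lo = line_end
    return answer


def query_range(gp: GPFile, chrom: str, start: int, end: int) -> Iterator[str]:
    """Stream the raw lines with the given chromosome and start <= pos <= end.

    Endpoints are 1-based and inclusive on both sides. An absent chromosome
    yields an empty stream. Lines are yielded unchanged (no trailing
    newline), in file order, holding O(1) lines in memory.
    """
    if start > end or start < 1:
        raise UsageError(f"bad range {chrom}:{start}:{end} (need 1 <= start <= end)")
    b = gp.bounds_for(chrom)
    if b is None:
        return
    off = seek_first_ge(gp, b, start)
    if off is None:
        return
    fh = gp._fh
    fh.seek(off)
    pos_cursor = off
    prev_pos = None
    while pos_cursor < b.end_offset:
        raw = fh.readline()
        if not raw:
            break
        pos_cursor += len(raw)
        line = raw.decode("utf-8", errors="replace").rstrip("\n")
        rec = parse_gp_line(line, path=gp.path)
        if prev_pos is not None and rec.pos < prev_pos:
            raise NotSortedError(
                f"{gp.path}: positions decrease within chromosome {chrom!r} "
                f"({prev_pos} then {rec.pos})"
            )
        prev_pos = rec.pos
        if rec.pos > end:
            break
        yield line


def parse_range(text: str) -> tuple[str, int, int]:
    """Parse the ``chrom:start:end`` range syntax used by the fastseek CLI."""
    parts = text.rsplit(":", 2)
    if len(parts) != 3:
        raise UsageError(f"range {text!r} is not of the form chrom:start:end")
    chrom, s, e = parts
    try:
        start, end = int(s), int(e)
    except ValueError:
        raise UsageError(f"range {text!r} has non-integer endpoints") from None
    if not chrom or start < 1 or start > end:
        raise UsageError(f"range {text!r} must satisfy 1 <= start <= end with a chromosome name")
    return chrom, start, end
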