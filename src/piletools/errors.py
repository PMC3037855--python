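"""Exception hierarchy shared by all tools.

Every error carries enough context (path, line number, offsets) to be
actionable from a shell. ``exit_code`` is the process status the CLI maps
the exception to: 1 for usage problems, 2 for data problems.
"""

from __future__ import annotations


class PiletoolsError(Exception):
    """Base class for all toolbox errors. Data errors exit with status 2."""

    exit_code = 2


class UsageError(PiletoolsError):
    """Bad command line or bad API arguments. Exits with status 1."""

    exit_code = 1


class MalformedLineError(PiletoolsError):
    """A line of a GP/pileup file violates the expected column layout."""

    def __init__(self, message: str, line_no: int | None = None, path: str | None = None):
        self.line_no = line_no
        self.path = path
        where = ""
        if path is not None:
            where += f"{path}:"
        if line_no is not None:
            where += f"line {line_no}: "
        super().__init__(where + message)


class MalformedIntervalError(PiletoolsError):
    """A BED/GFF record denotes an empty or inverted interval."""


class NotSortedError(PiletoolsError):
    """Input that must be coordinate-sorted is not."""


class OrderingMismatchError(PiletoolsError):
    """Coordinate keys built under different sequence orderings were compared."""


class NoGenotypeError(PiletoolsError):
    """An IUPAC code that does not encode a 1- or 2-allele genotype (e.g. N)."""


class InconsistentInputError(PiletoolsError):
    """Companion files disagree (e.g. a variant position missing from its full file)."""


class DegenerateTableError(PiletoolsError):
    """A 2x2 contingency table with zero total; no test is possible."""


class FixtureSpecError(PiletoolsError):
    """A synthetic-data specification is infeasible."""
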