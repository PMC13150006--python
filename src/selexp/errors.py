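"""Exception hierarchy shared across the toolkit.

Every error carries a short machine-readable ``category`` so the CLI can map
failures to exit diagnostics without string matching.
"""

from __future__ import annotations


class SelexpError(Exception):
    """Base class for all toolkit errors."""

    category: str = "error"


class InputError(SelexpError):
    """A file or table could not be read or is malformed."""

    category = "io"


class AlignmentShapeError(InputError):
    """Sequences in an alignment do not share a common length."""

    category = "alignment-shape"


class ParseError(InputError):
    """A record contains characters or fields that cannot be interpreted."""

    category = "parse"


class UnknownReferenceError(SelexpError):
    """A named reference record is absent from the alignment."""

    category = "unknown-reference"


class AnnotationRangeError(SelexpError):
    """An annotation addresses a residue position beyond the reference sequence."""

    category = "annotation-range"


class DuplicateGenericNumberError(SelexpError):
    """Two annotation rows map distinct positions to the same generic number."""

    category = "duplicate-generic-number"


class NoSharedPositionsError(SelexpError):
    """Two consensus profiles have no generic number in common."""

    category = "no-shared-positions"


class DomainError(SelexpError):
    """An argument lies outside the mathematical domain of an operation."""

    category = "domain"


class SelectionError(SelexpError):
    """An atom/residue selector matched nothing."""

    category = "selection"


class DegenerateStatisticsError(SelexpError):
    """A statistic is undefined for the given data (e.g. zero variance)."""

    category = "degenerate-statistics"


class FitError(SelexpError):
    """Concentration-response data cannot be fitted."""

    category = "fit"


class SimulationSpecError(SelexpError):
    """A synthetic-data specification is internally inconsistent."""

    category = "simulation-spec"
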