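"""Alignment containers, generic residue numbering, and column statistics.

The comparison of two receptor subfamilies starts from one gapped multiple
sequence alignment per group.  Cross-receptor positions are identified by
generic residue numbers of the GPCRdb/Ballesteros–Weinstein form ``"3x36"``
(helix or segment, then position; segment ``45`` denotes extracellular loop
2).  Because the numbering of a column is a property of the reference
receptor rather than of the alignment, the map from columns to generic
numbers is built from a user-supplied annotation table expressed in
reference-residue coordinates: ``position`` counts the non-gap characters of
the chosen reference row, 1-based, so the same table remains valid however
the alignment is gapped.

Conventions used throughout the package:

* alignment columns are 0-based internally and reported 1-based in outputs;
* reference residue positions are 1-based over non-gap characters;
* ``.`` is accepted as a gap synonym and normalised to ``-``;
* lowercase letters are upper-cased; ambiguity codes (B, Z, X, J, O, U) are
  rejected unless ``ambiguous_to_gap=True`` maps them to gaps.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

from .errors import (
    AlignmentShapeError,
    AnnotationRangeError,
    DuplicateGenericNumberError,
    InputError,
    ParseError,
    UnknownReferenceError,
)

GAP = "-"
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"  # alphabetical one-letter codes
#: channel order for one-hot encoding: 20 amino acids then the gap
ONE_HOT_ALPHABET = AMINO_ACIDS + GAP

_AMBIGUOUS = set("BZXJOU")
_GENERIC_NUMBER_RE = re.compile(r"^\d+x\d+$")


def _normalise_residues(
    raw: str, identifier: str, ambiguous_to_gap: bool = False
) -> str:
    """Upper-case, map ``.``→``-``, and validate the residue alphabet."""
    seq = raw.upper().replace(".", GAP)
    cleaned = []
    for pos, ch in enumerate(seq, start=1):
        if ch in AMINO_ACIDS or ch == GAP:
            cleaned.append(ch)
        elif ch in _AMBIGUOUS:
            if ambiguous_to_gap:
                cleaned.append(GAP)
            else:
                raise ParseError(
                    f"record {identifier!r}: ambiguous residue code {ch!r} at "
                    f"position {pos} (pass ambiguous_to_gap=True to map it to a gap)"
                )
        else:
            raise ParseError(
                f"record {identifier!r}: illegal character {ch!r} at position {pos}"
            )
    return "".join(cleaned)


@dataclass(frozen=True)
class SequenceRecord:
    """One aligned sequence: an identifier and a gapped residue string."""

    identifier: str
    residues: str

    def __post_init__(self) -> None:
        if not self.residues:
            raise ParseError(f"record {self.identifier!r}: empty sequence")
        object.__setattr__(
            self, "residues", _normalise_residues(self.residues, self.identifier)
        )

    def __len__(self) -> int:
        return len(self.residues)

    def ungapped(self) -> str:
        return self.residues.replace(GAP, "")


@dataclass(frozen=True)
class Alignment:
    """An ordered set of equal-length :class:`SequenceRecord` rows."""

    records: tuple[SequenceRecord, ...]

    def __post_init__(self) -> None:
        if not self.records:
            raise AlignmentShapeError("alignment must contain at least one record")
        object.__setattr__(self, "records", tuple(self.records))
        length = len(self.records[0])
        for rec in self.records:
            if len(rec) != length:
                raise AlignmentShapeError(
                    f"record {rec.identifier!r} has length {len(rec)}, "
                    f"expected {length} (from {self.records[0].identifier!r})"
                )

    @property
    def length(self) -> int:
        return len(self.records[0])

    @property
    def n_sequences(self) -> int:
        return len(self.records)

    def column(self, index: int) -> str:
        """All residues of one column, in record order."""
        if not 0 <= index < self.length:
            raise IndexError(f"column {index} outside [0, {self.length})")
        return "".join(rec.residues[index] for rec in self.records)

    def record(self, identifier: str) -> SequenceRecord:
        for rec in self.records:
            if rec.identifier == identifier:
                return rec
        raise UnknownReferenceError(
            f"no record named {identifier!r} in alignment "
            f"(have {', '.join(r.identifier for r in self.records[:5])}"
            f"{', ...' if self.n_sequences > 5 else ''})"
        )


@dataclass(frozen=True)
class GenericNumberMap:
    """Injective map from 0-based alignment columns to generic numbers."""

    entries: Mapping[int, str]
    reference_id: str

    def __post_init__(self) -> None:
        entries = dict(self.entries)
        seen: dict[str, int] = {}
        for col, gn in entries.items():
            if not _GENERIC_NUMBER_RE.match(gn):
                raise ParseError(
                    f"generic number {gn!r} (column {col}) does not match "
                    "the digits'x'digits pattern"
                )
            if gn in seen:
                raise DuplicateGenericNumberError(
                    f"generic number {gn!r} assigned to columns {seen[gn]} and {col}"
                )
            seen[gn] = col
        object.__setattr__(self, "entries", entries)

    def __len__(self) -> int:
        return len(self.entries)

    def columns(self) -> list[int]:
        return sorted(self.entries)

    def generic_numbers(self) -> list[str]:
        return [self.entries[c] for c in self.columns()]

    def column_of(self, generic_number: str) -> int:
        for col, gn in self.entries.items():
            if gn == generic_number:
                return col
        raise KeyError(generic_number)


@dataclass(frozen=True)
class ColumnProfile:
    """Residue occurrence counts for one alignment column (gaps separate)."""

    column: int
    counts: Mapping[str, int]
    gap_count: int
    n_sequences: int

    def __post_init__(self) -> None:
        if sum(self.counts.values()) + self.gap_count != self.n_sequences:
            raise ValueError(
                f"column {self.column}: counts + gaps != n_sequences"
            )


def parse_generic_number(gn: str) -> tuple[int, int, str]:
    """Sort key (segment, position, suffix) for labels like ``3x36``.

    Tolerates a trailing ``+n`` suffix (GPCRdb loop offsets such as
    ``45x52+2``) so region whitelists containing such labels still sort.
    """
    m = re.match(r"^(\d+)x(\d+)(.*)$", gn)
    if not m:
        return (10**6, 10**6, gn)
    return (int(m.group(1)), int(m.group(2)), m.group(3))


# ---------------------------------------------------------------------------
# I/O


def read_alignment(
    path: str | Path, format: str = "fasta", ambiguous_to_gap: bool = False
) -> Alignment:
    """Read an aligned FASTA file into an :class:`Alignment`.

    Raises :class:`AlignmentShapeError` naming the offending record when the
    sequences are ragged and :class:`ParseError` (with position) on illegal
    characters.
    """
    if format != "fasta":
        raise InputError(f"unsupported alignment format {format!r}")
    path = Path(path)
    if not path.exists():
        raise InputError(f"alignment file not found: {path}")
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        residues = _normalise_residues(str(rec.seq), rec.id, ambiguous_to_gap)
        records.append(SequenceRecord(rec.id, residues))
    if not records:
        raise InputError(f"no FASTA records in {path}")
    return Alignment(tuple(records))


def write_alignment(aln: Alignment, path: str | Path) -> None:
    """Write an alignment as FASTA (round-trips with :func:`read_alignment`)."""
    bio = [
        _BioSeqRecord(Seq(rec.residues), id=rec.identifier, description="")
        for rec in aln.records
    ]
    SeqIO.write(bio, str(path), "fasta")


def read_annotation(path: str | Path) -> list[tuple[int, str]]:
    """Read a 2-column TSV ``position<TAB>generic_number`` ('#' comments)."""
    path = Path(path)
    if not path.exists():
        raise InputError(f"annotation file not found: {path}")
    rows: list[tuple[int, str]] = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        stripped = line.split("#", 1)[0].strip()
        if not stripped:
            continue
        parts = stripped.split("\t") if "\t" in stripped else stripped.split()
        if len(parts) != 2:
            raise ParseError(f"{path}:{lineno}: expected 2 columns, got {len(parts)}")
        try:
            pos = int(parts[0])
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: position {parts[0]!r} not an integer") from exc
        rows.append((pos, parts[1]))
    return rows


# ---------------------------------------------------------------------------
# Numbering


def attach_numbering(
    aln: Alignment,
    annotation: Iterable[tuple[int, str]],
    reference_id: str,
) -> GenericNumberMap:
    """Map annotated reference residue positions to alignment columns.

    ``annotation`` rows are ``(position, generic_number)`` with ``position``
    1-based over the non-gap characters of the reference row, which makes the
    map invariant to how the alignment is gapped.
    """
    ref = aln.record(reference_id)
    # ungapped residue index (1-based) -> alignment column (0-based)
    residue_to_column: dict[int, int] = {}
    residue_index = 0
    for col, ch in enumerate(ref.residues):
        if ch != GAP:
            residue_index += 1
            residue_to_column[residue_index] = col
    entries: dict[int, str] = {}
    for pos, gn in annotation:
        if pos not in residue_to_column:
            raise AnnotationRangeError(
                f"annotation position {pos} outside reference {reference_id!r} "
                f"(has {residue_index} residues)"
            )
        entries[residue_to_column[pos]] = gn
    return GenericNumberMap(entries, reference_id)


# ---------------------------------------------------------------------------
# Column statistics


def column_profiles(aln: Alignment) -> list[ColumnProfile]:
    """One :class:`ColumnProfile` per column; gaps counted separately."""
    profiles = []
    for col in range(aln.length):
        counter = Counter(aln.column(col))
        gap_count = counter.pop(GAP, 0)
        profiles.append(
            ColumnProfile(col, dict(counter), gap_count, aln.n_sequences)
        )
    return profiles


def profiles_to_frame(profiles: Sequence[ColumnProfile]) -> pd.DataFrame:
    """Tabulate profiles as a DataFrame (column is reported 1-based)."""
    rows = []
    for p in profiles:
        row = {"column": p.column + 1, "gap_count": p.gap_count,
               "n_sequences": p.n_sequences}
        for aa in AMINO_ACIDS:
            row[aa] = p.counts.get(aa, 0)
        rows.append(row)
    return pd.DataFrame(rows)


def one_hot_encode(aln: Alignment) -> np.ndarray:
    """Encode each residue as a binary vector of length 21 (20 AAs + gap).

    Returns an array of shape ``(n_sequences, length * 21)``; every 21-block
    sums to 1 and every row sums to the alignment length.
    """
    index = {ch: i for i, ch in enumerate(ONE_HOT_ALPHABET)}
    out = np.zeros((aln.n_sequences, aln.length * 21), dtype=np.uint8)
    for r, rec in enumerate(aln.records):
        for c, ch in enumerate(rec.residues):
            out[r, c * 21 + index[ch]] = 1
    return out
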