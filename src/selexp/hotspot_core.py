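"""The selectivity-hotspot statistic.

A selectivity hotspot is an alignment position that is conserved within each
of two receptor subfamilies but occupied by chemically dissimilar residues
between them.  Concretely, a position labelled by a generic residue number is
called a hotspot when

* the within-group consensus residue reaches a conservation fraction of at
  least ``theta`` (default 0.80) in *both* groups, and
* the BLOSUM62 substitution score of the two consensus residues is negative.

Because the BLOSUM62 diagonal is non-negative for all 20 standard residues,
identical consensus residues can never be called; the statistic only fires on
positions where the two subfamilies each settled on a different residue type.

The module also provides the combinatorial chance-probability helper: the
number of ways to pick ``k`` specific positions out of ``n`` candidates,
``C(n, k)``, whose reciprocal quantifies how unlikely the selected hotspot
set would be under uniform random choice.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import DomainError, NoSharedPositionsError
from .msa_numbering import (
    GAP,
    Alignment,
    GenericNumberMap,
    parse_generic_number,
)

# ---------------------------------------------------------------------------
# Substitution matrix

_BLOSUM62_ORDER = "ARNDCQEGHILKMFPSTWYV"
# Standard NCBI BLOSUM62 half-bit scores, row/column order as above.
_BLOSUM62_ROWS = (
    (  4,  -1,  -2,  -2,   0,  -1,  -1,   0,  -2,  -1,  -1,  -1,  -1,  -2,  -1,   1,   0,  -3,  -2,   0),  # A
    ( -1,   5,   0,  -2,  -3,   1,   0,  -2,   0,  -3,  -2,   2,  -1,  -3,  -2,  -1,  -1,  -3,  -2,  -3),  # R
    ( -2,   0,   6,   1,  -3,   0,   0,   0,   1,  -3,  -3,   0,  -2,  -3,  -2,   1,   0,  -4,  -2,  -3),  # N
    ( -2,  -2,   1,   6,  -3,   0,   2,  -1,  -1,  -3,  -4,  -1,  -3,  -3,  -1,   0,  -1,  -4,  -3,  -3),  # D
    (  0,  -3,  -3,  -3,   9,  -3,  -4,  -3,  -3,  -1,  -1,  -3,  -1,  -2,  -3,  -1,  -1,  -2,  -2,  -1),  # C
    ( -1,   1,   0,   0,  -3,   5,   2,  -2,   0,  -3,  -2,   1,   0,  -3,  -1,   0,  -1,  -2,  -1,  -2),  # Q
    ( -1,   0,   0,   2,  -4,   2,   5,  -2,   0,  -3,  -3,   1,  -2,  -3,  -1,   0,  -1,  -3,  -2,  -2),  # E
    (  0,  -2,   0,  -1,  -3,  -2,  -2,   6,  -2,  -4,  -4,  -2,  -3,  -3,  -2,   0,  -2,  -2,  -3,  -3),  # G
    ( -2,   0,   1,  -1,  -3,   0,   0,  -2,   8,  -3,  -3,  -1,  -2,  -1,  -2,  -1,  -2,  -2,   2,  -3),  # H
    ( -1,  -3,  -3,  -3,  -1,  -3,  -3,  -4,  -3,   4,   2,  -3,   1,   0,  -3,  -2,  -1,  -3,  -1,   3),  # I
    ( -1,  -2,  -3,  -4,  -1,  -2,  -3,  -4,  -3,   2,   4,  -2,   2,   0,  -3,  -2,  -1,  -2,  -1,   1),  # L
    ( -1,   2,   0,  -1,  -3,   1,   1,  -2,  -1,  -3,  -2,   5,  -1,  -3,  -1,   0,  -1,  -3,  -2,  -2),  # K
    ( -1,  -1,  -2,  -3,  -1,   0,  -2,  -3,  -2,   1,   2,  -1,   5,   0,  -2,  -1,  -1,  -1,  -1,   1),  # M
    ( -2,  -3,  -3,  -3,  -2,  -3,  -3,  -3,  -1,   0,   0,  -3,   0,   6,  -4,  -2,  -2,   1,   3,  -1),  # F
    ( -1,  -2,  -2,  -1,  -3,  -1,  -1,  -2,  -2,  -3,  -3,  -1,  -2,  -4,   7,  -1,  -1,  -4,  -3,  -2),  # P
    (  1,  -1,   1,   0,  -1,   0,   0,   0,  -1,  -2,  -2,   0,  -1,  -2,  -1,   4,   1,  -3,  -2,  -2),  # S
    (  0,  -1,   0,  -1,  -1,  -1,  -1,  -2,  -2,  -1,  -1,  -1,  -1,  -2,  -1,   1,   5,  -2,  -2,   0),  # T
    ( -3,  -3,  -4,  -4,  -2,  -2,  -3,  -2,  -2,  -3,  -2,  -3,  -1,   1,  -4,  -3,  -2,  11,   2,  -3),  # W
    ( -2,  -2,  -2,  -3,  -2,  -1,  -2,  -3,   2,  -1,  -1,  -2,  -1,   3,  -3,  -2,  -2,   2,   7,  -1),  # Y
    (  0,  -3,  -3,  -3,  -1,  -2,  -2,  -3,  -3,   3,   1,  -2,   1,  -1,  -2,  -2,   0,  -3,  -1,   4),  # V
)


@dataclass(frozen=True)
class SubstitutionMatrix:
    """Symmetric integer substitution scores over the 20 standard residues."""

    scores: Mapping[tuple[str, str], int]
    name: str

    def __post_init__(self) -> None:
        for (a, b), s in self.scores.items():
            if self.scores[(b, a)] != s:
                raise ValueError(f"{self.name}: asymmetric at ({a},{b})")
        object.__setattr__(self, "scores", dict(self.scores))

    def score(self, a: str, b: str) -> int:
        try:
            return self.scores[(a, b)]
        except KeyError as exc:
            raise DomainError(
                f"{self.name} has no entry for residue pair ({a!r}, {b!r})"
            ) from exc


def _build_blosum62() -> SubstitutionMatrix:
    scores = {}
    for i, a in enumerate(_BLOSUM62_ORDER):
        for j, b in enumerate(_BLOSUM62_ORDER):
            scores[(a, b)] = _BLOSUM62_ROWS[i][j]
    return SubstitutionMatrix(scores, "BLOSUM62")


BLOSUM62 = _build_blosum62()


# ---------------------------------------------------------------------------
# Consensus

@dataclass(frozen=True)
class ConsensusPosition:
    generic_number: str
    consensus_residue: str | None  # None only for an all-gap column
    conservation: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.conservation <= 1.0:
            raise ValueError("conservation outside [0, 1]")


@dataclass(frozen=True)
class ConsensusProfile:
    """Per-generic-number consensus residue and conservation fraction."""

    positions: Mapping[str, ConsensusPosition]

    def __post_init__(self) -> None:
        object.__setattr__(self, "positions", dict(self.positions))

    def generic_numbers(self) -> set[str]:
        return set(self.positions)

    def __getitem__(self, gn: str) -> ConsensusPosition:
        return self.positions[gn]


def compute_consensus(
    aln: Alignment,
    gmap: GenericNumberMap,
    gaps_in_denominator: bool = True,
) -> ConsensusProfile:
    """Consensus residue and conservation for every annotated column.

    The consensus residue is the most frequent non-gap residue (ties broken
    alphabetically).  Conservation is its count divided by the total number
    of sequences — a gap counts as evidence against conservation by default;
    pass ``gaps_in_denominator=False`` to divide by non-gap counts instead.
    An all-gap column yields consensus ``None`` with conservation 0.
    """
    positions: dict[str, ConsensusPosition] = {}
    for col in gmap.columns():
        gn = gmap.entries[col]
        column = aln.column(col)
        counts: dict[str, int] = {}
        for ch in column:
            if ch != GAP:
                counts[ch] = counts.get(ch, 0) + 1
        if not counts:
            positions[gn] = ConsensusPosition(gn, None, 0.0)
            continue
        # max count, alphabetical tie-break
        consensus = min(counts, key=lambda aa: (-counts[aa], aa))
        denom = aln.n_sequences if gaps_in_denominator else sum(counts.values())
        positions[gn] = ConsensusPosition(gn, consensus, counts[consensus] / denom)
    return ConsensusProfile(positions)


# ---------------------------------------------------------------------------
# Hotspot calling

REGION_LABELS = ("orthosteric", "TM2-TM7", "TM3-TM4-TM5", "other", "unassigned")
PRIORITY_LABELS = ("prioritized", "deprioritized", "unset")


@dataclass
class HotspotCall:
    """One candidate position compared between the two groups."""

    generic_number: str
    consensus_a: str | None
    conservation_a: float
    consensus_b: str | None
    conservation_b: float
    blosum_score: int | None
    is_hotspot: bool
    region: str = "unassigned"
    priority: str = "unset"
    flag: str = ""  # e.g. "no-consensus" for all-gap columns

    def __post_init__(self) -> None:
        if self.region not in REGION_LABELS:
            raise ValueError(f"unknown region label {self.region!r}")
        if self.priority not in PRIORITY_LABELS:
            raise ValueError(f"unknown priority label {self.priority!r}")


@dataclass(frozen=True)
class HotspotConfig:
    """Thresholds for hotspot calling.

    ``conservation_threshold`` is compared with ``>=`` by default
    (``conservation_strict=True`` switches to ``>``); the substitution score
    must be strictly below ``score_threshold``.  ``eligible_positions``, when
    given, restricts calling to that set of generic numbers (e.g. the
    transmembrane + binding-site whitelist).
    """

    conservation_threshold: float = 0.80
    conservation_strict: bool = False
    score_threshold: int = 0
    eligible_positions: frozenset[str] | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.conservation_threshold <= 1.0:
            raise DomainError("conservation_threshold must be in (0, 1]")
        if self.eligible_positions is not None:
            object.__setattr__(
                self, "eligible_positions", frozenset(self.eligible_positions)
            )

    def conserved(self, fraction: float) -> bool:
        if self.conservation_strict:
            return fraction > self.conservation_threshold
        return fraction >= self.conservation_threshold


#: Binding-site generic numbers (residues within 4 Å of the bound agonist in
#: the reference adrenaline/dopamine complexes).  "45x52+2" is the EL2
#: position two residues C-terminal of 45x52.
BINDING_SITE_POSITIONS = (
    "3x28", "3x32", "3x33", "3x36", "45x52", "45x52+2", "5x43", "5x461",
    "6x51", "6x52", "6x55", "7x38", "7x42",
)


def tm_binding_site_whitelist(
    tm_positions: Iterable[str] = (),
) -> frozenset[str]:
    """Whitelist of transmembrane positions plus the binding-site set.

    The transmembrane part must be supplied by the caller (helix boundaries
    differ between numbering schemes and receptors; the packaged default is
    the binding-site set alone plus any positions whose segment is 1–7,
    which the caller's generic-number map implies)."""
    return frozenset(tm_positions) | frozenset(BINDING_SITE_POSITIONS)


def default_eligible(generic_numbers: Iterable[str]) -> frozenset[str]:
    """Approximate "TMs + binding site" restriction: keep positions whose
    segment is a helix (1–7) plus the packaged binding-site list."""
    keep = set(BINDING_SITE_POSITIONS)
    for gn in generic_numbers:
        seg = parse_generic_number(gn)[0]
        if 1 <= seg <= 7:
            keep.add(gn)
    return frozenset(keep)


def call_hotspots(
    prof_a: ConsensusProfile,
    prof_b: ConsensusProfile,
    matrix: SubstitutionMatrix = BLOSUM62,
    cfg: HotspotConfig | None = None,
) -> list[HotspotCall]:
    """Compare two consensus profiles position by position.

    Returns one :class:`HotspotCall` per shared (and eligible) generic
    number, sorted by generic number (segment, then position).  A position
    where either group lacks a consensus residue is reported with
    ``is_hotspot=False`` and flag ``"no-consensus"``.
    """
    cfg = cfg or HotspotConfig()
    shared = prof_a.generic_numbers() & prof_b.generic_numbers()
    if cfg.eligible_positions is not None:
        shared &= cfg.eligible_positions
    if not shared:
        raise NoSharedPositionsError(
            "the two consensus profiles share no eligible generic numbers"
        )
    calls = []
    for gn in sorted(shared, key=parse_generic_number):
        pa, pb = prof_a[gn], prof_b[gn]
        if pa.consensus_residue is None or pb.consensus_residue is None:
            calls.append(
                HotspotCall(gn, pa.consensus_residue, pa.conservation,
                            pb.consensus_residue, pb.conservation,
                            None, False, flag="no-consensus")
            )
            continue
        score = matrix.score(pa.consensus_residue, pb.consensus_residue)
        is_hotspot = (
            cfg.conserved(pa.conservation)
            and cfg.conserved(pb.conservation)
            and score < cfg.score_threshold
        )
        calls.append(
            HotspotCall(gn, pa.consensus_residue, pa.conservation,
                        pb.consensus_residue, pb.conservation,
                        score, is_hotspot)
        )
    return calls


def calls_to_frame(calls: Sequence[HotspotCall]) -> pd.DataFrame:
    """Tabulate calls with the documented TSV column order."""
    return pd.DataFrame(
        [
            {
                "generic_number": c.generic_number,
                "consensus_a": c.consensus_a or "",
                "conservation_a": c.conservation_a,
                "consensus_b": c.consensus_b or "",
                "conservation_b": c.conservation_b,
                "blosum62": "" if c.blosum_score is None else c.blosum_score,
                "is_hotspot": c.is_hotspot,
                "region": c.region,
                "priority": c.priority,
            }
            for c in calls
        ]
    )


def sweep_thresholds(
    prof_a: ConsensusProfile,
    prof_b: ConsensusProfile,
    matrix: SubstitutionMatrix = BLOSUM62,
    theta_grid: Sequence[float] = (),
    cfg: HotspotConfig | None = None,
) -> pd.DataFrame:
    """Hotspot count as a function of the conservation threshold.

    Returns a DataFrame with columns ``theta`` and ``n_hotspots``; the count
    is non-increasing in theta by construction.
    """
    if not theta_grid:
        raise DomainError("theta_grid must be non-empty")
    base = cfg or HotspotConfig()
    rows = []
    for theta in theta_grid:
        c = HotspotConfig(
            conservation_threshold=theta,
            conservation_strict=base.conservation_strict,
            score_threshold=base.score_threshold,
            eligible_positions=base.eligible_positions,
        )
        calls = call_hotspots(prof_a, prof_b, matrix, c)
        rows.append({"theta": theta, "n_hotspots": sum(x.is_hotspot for x in calls)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Chance probability


def chance_one_in(n_positions: int, k_selected: int) -> int:
    """Number of ways to choose ``k`` specific positions out of ``n``.

    The reciprocal, 1/C(n, k), is the probability of hitting one particular
    k-subset by uniform random choice.  Computed exactly in integers.
    """
    if n_positions < 0 or k_selected < 0:
        raise DomainError("n_positions and k_selected must be non-negative")
    if k_selected > n_positions:
        raise DomainError(
            f"cannot choose {k_selected} positions out of {n_positions}"
        )
    return math.comb(n_positions, k_selected)


def format_one_in_billions(count: int) -> str:
    """Render a combination count as "one in ≈X billion"."""
    billions = round(count / 1_000_000_000)
    return f"one in ≈{billions} billion"
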