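"""Core domain containers shared across the package.

A *locus* here is a short non-coding region (a few hundred bp) carrying a
stem-loop: two arms that are exact or near-exact reverse complements of one
another ("inverted repeats"), flanking a short loop that is prone to being
replaced by its own reverse complement during evolution.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

IUPAC_CODES = set("ACGTNRYSWKMBDHV")
GAP = "-"


@dataclass(frozen=True)
class SequenceRecord:
    """One barcode sequence with its species label.

    ``orientation_truth`` is only populated by the simulator (planted loop
    orientation, "A" or "B"); it is never consulted by the analysis itself.
    """

    id: str
    species: str
    seq: str
    locality: Optional[str] = None
    orientation_truth: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.seq:
            raise ValueError(f"record {self.id!r}: empty sequence")
        if GAP in self.seq:
            raise ValueError(f"record {self.id!r}: gap symbol in unaligned sequence")
        bad = set(self.seq.upper()) - IUPAC_CODES
        if bad:
            raise ValueError(
                f"record {self.id!r}: non-IUPAC characters {sorted(bad)!r}"
            )
        object.__setattr__(self, "seq", self.seq.upper())

    def with_seq(self, seq: str) -> "SequenceRecord":
        return replace(self, seq=seq)


@dataclass
class Alignment:
    """A multiple alignment: ordered rows of equal-length gapped strings."""

    rows: list[tuple[str, str]]

    def __post_init__(self) -> None:
        if self.rows:
            n = len(self.rows[0][1])
            for rid, row in self.rows:
                if len(row) != n:
                    raise ValueError(
                        f"row {rid!r} has length {len(row)}, expected {n}"
                    )
        ids = [rid for rid, _ in self.rows]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate row ids in alignment")

    @property
    def n_columns(self) -> int:
        return len(self.rows[0][1]) if self.rows else 0

    @property
    def ids(self) -> list[str]:
        return [rid for rid, _ in self.rows]

    def row(self, rid: str) -> str:
        for r, s in self.rows:
            if r == rid:
                return s
        raise KeyError(rid)

    def degap(self, rid: str) -> str:
        return self.row(rid).replace(GAP, "")

    def subset(self, ids: list[str]) -> "Alignment":
        wanted = set(ids)
        return Alignment([(r, s) for r, s in self.rows if r in wanted])


@dataclass(frozen=True)
class Interval:
    """0-based, half-open interval."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError(f"inverted interval ({self.start}, {self.end})")

    def __len__(self) -> int:
        return self.end - self.start

    def as_tuple(self) -> tuple[int, int]:
        return (self.start, self.end)


@dataclass
class HairpinAnnotation:
    """Coordinates of a stem-loop within one sequence.

    The left arm, loop and right arm are contiguous:
    ``left_arm.end == loop.start`` and ``loop.end == right_arm.start``.
    ``arm_mismatches`` counts positions at which the reverse complement of
    the left arm differs from the right arm. ``degenerate`` marks loops too
    short to orient (e.g. after a large deletion).
    """

    seq_id: str
    left_arm: Interval
    loop: Interval
    right_arm: Interval
    arm_len: int
    arm_mismatches: int
    degenerate: bool = False

    def __post_init__(self) -> None:
        if len(self.left_arm) or len(self.right_arm):
            if self.left_arm.end != self.loop.start:
                raise ValueError("left arm not adjacent to loop")
            if self.loop.end != self.right_arm.start:
                raise ValueError("loop not adjacent to right arm")
            if len(self.left_arm) != len(self.right_arm):
                raise ValueError("arm lengths differ")
            if self.arm_len != len(self.left_arm):
                raise ValueError("arm_len inconsistent with intervals")

    @property
    def loop_len(self) -> int:
        return len(self.loop)


@dataclass
class OrientationCall:
    """A sequence's loop orientation relative to the dataset reference loop.

    ``configuration`` is "A" when the loop is closer (Levenshtein) to the
    reference loop than to its reverse complement, "B" when farther, and
    "undetermined" on ties or degenerate loops.
    """

    seq_id: str
    configuration: str  # "A" | "B" | "undetermined"
    distance_to_ref: Optional[int]
    distance_to_flipped_ref: Optional[int]

    @property
    def margin(self) -> Optional[int]:
        if self.distance_to_ref is None or self.distance_to_flipped_ref is None:
            return None
        return self.distance_to_flipped_ref - self.distance_to_ref


@dataclass
class MatrixPair:
    """The raw dataset and its orientation-normalized ("uniform") twin."""

    raw: list[SequenceRecord]
    uniform: list[SequenceRecord]
    flipped_ids: set[str] = field(default_factory=set)
    inversion_character: dict[str, str] = field(default_factory=dict)
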