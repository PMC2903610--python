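"""Orientation calling and construction of the raw/uniform matrix pair.

Each sequence's loop is compared (Levenshtein edit distance, robust to the
1-bp indels common in these loops) against a dataset reference loop and its
reverse complement. Sequences closer to the reference are labelled "A",
closer to the flipped reference "B"; ties and degenerate loops are
"undetermined". The labels are dataset-relative and arbitrary, which is all
that orientation normalization requires. The "uniform" matrix replaces the
loop of every sequence not already in the target configuration with its
reverse complement, and the flip is additionally recorded as a single
binary character so the inversion event itself is not lost to analysis.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Union

import edlib

from .hairpin import MIN_CALLABLE_LOOP, reverse_complement
from .records import (
    HairpinAnnotation,
    MatrixPair,
    OrientationCall,
    SequenceRecord,
)

logger = logging.getLogger(__name__)


def _edit_distance(a: str, b: str) -> int:
    if not a and not b:
        return 0
    return edlib.align(a, b, task="distance")["editDistance"]


def choose_reference_orientation(
    records: list[SequenceRecord],
    annotations: dict[str, HairpinAnnotation],
) -> str:
    """Reference loop: that of the lexicographically first non-degenerate id.

    Deterministic under permutation of the input, so orientation labels do
    not depend on file order.
    """
    eligible = sorted(
        r.id for r in records if not annotations[r.id].degenerate
    )
    if not eligible:
        raise ValueError("all loops degenerate; no reference orientation")
    rid = eligible[0]
    ann = annotations[rid]
    seq = next(r.seq for r in records if r.id == rid)
    return seq[ann.loop.start : ann.loop.end]


def call_orientation(
    annotation: HairpinAnnotation,
    record: SequenceRecord,
    reference_loop: str,
    min_callable_loop: int = MIN_CALLABLE_LOOP,
) -> OrientationCall:
    if annotation.seq_id != record.id:
        raise ValueError("annotation does not belong to record")
    loop = record.seq[annotation.loop.start : annotation.loop.end]
    if annotation.degenerate or len(loop) < min_callable_loop:
        return OrientationCall(record.id, "undetermined", None, None)
    d_ref = _edit_distance(loop, reference_loop)
    d_flip = _edit_distance(loop, reverse_complement(reference_loop))
    if d_ref < d_flip:
        config = "A"
    elif d_ref > d_flip:
        config = "B"
    else:
        config = "undetermined"
    return OrientationCall(record.id, config, d_ref, d_flip)


def call_all(
    records: list[SequenceRecord],
    annotations: dict[str, HairpinAnnotation],
    min_callable_loop: int = MIN_CALLABLE_LOOP,
) -> tuple[list[OrientationCall], dict[str, int]]:
    """Orientation call per record plus configuration counts."""
    reference = choose_reference_orientation(records, annotations)
    calls = [
        call_orientation(annotations[r.id], r, reference, min_callable_loop)
        for r in records
    ]
    counts = {"A": 0, "B": 0, "undetermined": 0}
    for c in calls:
        counts[c.configuration] += 1
    return calls, counts


def flip_loop(record: SequenceRecord, annotation: HairpinAnnotation) -> SequenceRecord:
    """Replace the loop with its reverse complement (an involution)."""
    s = record.seq
    loop = s[annotation.loop.start : annotation.loop.end]
    return record.with_seq(
        s[: annotation.loop.start] + reverse_complement(loop) + s[annotation.loop.end :]
    )


def build_matrix_pair(
    records: list[SequenceRecord],
    annotations: dict[str, HairpinAnnotation],
    calls: list[OrientationCall],
    target_configuration: str = "B",
) -> MatrixPair:
    """Raw records plus the uniform (orientation-normalized) set.

    Sequences called in the non-target configuration have their loop
    replaced by its reverse complement; undetermined/degenerate sequences
    enter both matrices unaltered. The binary inversion character is 0 for
    sequences already in the target form, 1 for flipped ones and '?' for
    undetermined.
    """
    if target_configuration not in ("A", "B"):
        raise ValueError("target_configuration must be 'A' or 'B'")
    call_by_id = {c.seq_id: c for c in calls}
    uniform: list[SequenceRecord] = []
    flipped: set[str] = set()
    character: dict[str, str] = {}
    for rec in records:
        call = call_by_id[rec.id]
        if call.configuration == "undetermined":
            uniform.append(rec)
            character[rec.id] = "?"
        elif call.configuration == target_configuration:
            uniform.append(rec)
            character[rec.id] = "0"
        else:
            uniform.append(flip_loop(rec, annotations[rec.id]))
            flipped.add(rec.id)
            character[rec.id] = "1"
    logger.info("build_matrix_pair: flipped %d of %d sequences", len(flipped), len(records))
    return MatrixPair(
        raw=list(records),
        uniform=uniform,
        flipped_ids=flipped,
        inversion_character=character,
    )


def write_orientation_report(
    calls: list[OrientationCall], path: Union[str, Path]
) -> None:
    with open(path, "w") as fh:
        fh.write("seq_id\tconfiguration\tdistance_to_ref\tdistance_to_flipped_ref\tmargin\n")
        for c in calls:
            fh.write(
                f"{c.seq_id}\t{c.configuration}\t"
                f"{'' if c.distance_to_ref is None else c.distance_to_ref}\t"
                f"{'' if c.distance_to_flipped_ref is None else c.distance_to_flipped_ref}\t"
                f"{'' if c.margin is None else c.margin}\n"
            )


def write_inversion_character(
    pair: MatrixPair, path: Union[str, Path]
) -> None:
    """One-column character matrix (relaxed PHYLIP-like TSV)."""
    with open(path, "w") as fh:
        fh.write(f"{len(pair.raw)}\t1\n")
        for rec in pair.raw:
            fh.write(f"{rec.id}\t{pair.inversion_character[rec.id]}\n")
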