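"""Detection of inversion-prone stem-loops (inverted repeats flanking a loop).

The detector looks for a pair of arms that read as reverse complements of
one another across a short intervening loop. Such hairpins mark regions in
non-coding plastid DNA where the loop is recurrently replaced by its own
reverse complement, confounding naive alignment of the locus.
"""

from __future__ import annotations

import logging
from collections import Counter
from pathlib import Path
from typing import Optional, Union

from .records import HairpinAnnotation, Interval, SequenceRecord

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans(
    "ACGTNRYSWKMBDHV",
    "TGCANYRSWMKVHDB",
)

# Defaults sized for a trnH-psbA-like hairpin: arms of >=18 bp around a
# loop of a few tens of bp; loops shorter than min_callable_loop cannot be
# oriented reliably and are flagged degenerate.
MIN_ARM = 18
MAX_LOOP = 40
MAX_ARM_MISMATCH = 2
MIN_CALLABLE_LOOP = 10


def reverse_complement(seq: str) -> str:
    """IUPAC-aware reverse complement; involution by construction."""
    seq = seq.upper()
    bad = set(seq) - set("ACGTNRYSWKMBDHV")
    if bad:
        raise ValueError(f"non-IUPAC characters: {sorted(bad)!r}")
    return seq.translate(_COMPLEMENT)[::-1]


def _is_wc_pair(a: str, b: str) -> bool:
    """True if b is the exact Watson-Crick complement of a (ACGT only)."""
    return (a + b) in ("AT", "TA", "CG", "GC")


def find_inverted_repeats(
    seq: str,
    min_arm: int = MIN_ARM,
    max_loop: int = MAX_LOOP,
    max_arm_mismatch: int = MAX_ARM_MISMATCH,
    seq_id: str = "",
) -> list[HairpinAnnotation]:
    """All maximal hairpins in one sequence.

    A hairpin is a triple (left arm, loop, right arm) with equal-length arms
    whose reverse-complement disagreement is at most ``max_arm_mismatch``
    and a loop of at most ``max_loop`` bp. Arms must begin and end on an
    exactly complementary base pair (mismatches are interior only), so a
    mismatched pair at the loop boundary belongs to the loop, not the stem.
    For a fixed loop interval the interior mismatch count is non-decreasing
    in arm length, so exactly one maximal valid arm length exists per loop
    interval; only that maximal hairpin is reported (no nested duplicates).
    Ambiguity codes never pair. Results are sorted by (arm length desc,
    loop length asc, leftmost loop).
    """
    if min_arm < 4:
        raise ValueError("min_arm must be >= 4")
    if max_loop < 0:
        raise ValueError("max_loop must be >= 0")
    seq = seq.upper()
    n = len(seq)
    hits: list[HairpinAnnotation] = []
    for loop_start in range(1, n):
        for loop_len in range(0, max_loop + 1):
            loop_end = loop_start + loop_len
            if loop_end >= n:
                break
            # grow arms outward from the loop boundary; an arm is valid only
            # if its innermost and outermost pairs are complementary
            mism = 0
            arm = 0
            best_arm = 0
            best_mism = 0
            while True:
                li = loop_start - arm - 1
                ri = loop_end + arm
                if li < 0 or ri >= n:
                    break
                if _is_wc_pair(seq[li], seq[ri]):
                    arm += 1
                    best_arm, best_mism = arm, mism
                else:
                    if arm == 0:
                        break  # innermost pair must be complementary
                    mism += 1
                    if mism > max_arm_mismatch:
                        break
                    arm += 1
            if best_arm >= min_arm:
                la = Interval(loop_start - best_arm, loop_start)
                ra = Interval(loop_end, loop_end + best_arm)
                hits.append(
                    HairpinAnnotation(
                        seq_id=seq_id,
                        left_arm=la,
                        loop=Interval(loop_start, loop_end),
                        right_arm=ra,
                        arm_len=best_arm,
                        arm_mismatches=best_mism,
                    )
                )
    hits.sort(key=lambda h: (-h.arm_len, h.loop_len, h.loop.start))
    return hits


def _empty_annotation(seq_id: str) -> HairpinAnnotation:
    z = Interval(0, 0)
    return HairpinAnnotation(
        seq_id=seq_id,
        left_arm=z,
        loop=z,
        right_arm=z,
        arm_len=0,
        arm_mismatches=0,
        degenerate=True,
    )


def _arm_consensus(
    annotations: dict[str, HairpinAnnotation], seqs: dict[str, str]
) -> Optional[str]:
    """Majority consensus of left arms, anchored at the loop boundary.

    Built from exact (zero-mismatch) arm hits of the modal arm length; a
    simple per-position majority with no refinement.
    """
    exact = [
        a for a in annotations.values() if not a.degenerate and a.arm_mismatches == 0
    ]
    if not exact:
        exact = [a for a in annotations.values() if not a.degenerate]
    if not exact:
        return None
    modal_len = Counter(a.arm_len for a in exact).most_common(1)[0][0]
    arms = []
    for a in exact:
        if a.arm_len >= modal_len:
            s = seqs[a.seq_id]
            # right-justify at the loop boundary
            arms.append(s[a.left_arm.end - modal_len : a.left_arm.end])
    cons = []
    for i in range(modal_len):
        cons.append(Counter(arm[i] for arm in arms).most_common(1)[0][0])
    return "".join(cons)


def _consensus_score(ann: HairpinAnnotation, seq: str, consensus: str) -> int:
    """Mismatches of this hairpin's left arm against the dataset consensus."""
    k = min(ann.arm_len, len(consensus))
    arm = seq[ann.left_arm.end - k : ann.left_arm.end]
    ref = consensus[len(consensus) - k :]
    return sum(1 for a, b in zip(arm, ref) if a != b) + (len(consensus) - k)


def anchor_shared_hairpin(
    records: list[SequenceRecord],
    min_arm: int = MIN_ARM,
    max_loop: int = MAX_LOOP,
    max_arm_mismatch: int = MAX_ARM_MISMATCH,
    min_callable_loop: int = MIN_CALLABLE_LOOP,
) -> dict[str, HairpinAnnotation]:
    """Pick one homologous hairpin per record across a dataset.

    Each record's candidate hairpins are rescored against a dataset-wide arm
    consensus so that all records anchor the same stem, even when a record's
    top scoring hairpin by arm length alone would differ. Records whose best
    loop is shorter than ``min_callable_loop`` (e.g. carrying a large loop
    deletion) are flagged degenerate; records without detectable arms get a
    degenerate annotation with empty intervals.
    """
    seqs = {r.id: r.seq for r in records}
    candidates: dict[str, list[HairpinAnnotation]] = {}
    best_exact: dict[str, HairpinAnnotation] = {}
    for rec in records:
        hits = find_inverted_repeats(
            rec.seq, min_arm, max_loop, max_arm_mismatch, seq_id=rec.id
        )
        candidates[rec.id] = hits
        for h in hits:  # best exact hit anchors the consensus
            if h.arm_mismatches == 0:
                best_exact[rec.id] = h
                break
        else:
            if hits:
                best_exact[rec.id] = hits[0]

    consensus = _arm_consensus(best_exact, seqs)
    out: dict[str, HairpinAnnotation] = {}
    for rec in records:
        hits = candidates[rec.id]
        if not hits:
            logger.warning("anchor_shared_hairpin: no arms found in %s", rec.id)
            out[rec.id] = _empty_annotation(rec.id)
            continue
        if consensus is not None:
            chosen = min(
                hits,
                key=lambda h: (
                    _consensus_score(h, rec.seq, consensus),
                    -h.arm_len,
                    h.loop_len,
                    h.loop.start,
                ),
            )
        else:
            chosen = hits[0]
        if chosen.loop_len < min_callable_loop:
            chosen.degenerate = True
        out[rec.id] = chosen
    return out


def write_hairpin_report(
    annotations: dict[str, HairpinAnnotation], path: Union[str, Path]
) -> None:
    with open(path, "w") as fh:
        fh.write(
            "seq_id\tleft_arm_start\tleft_arm_end\tloop_start\tloop_end\t"
            "right_arm_start\tright_arm_end\tarm_len\tarm_mismatches\tdegenerate\n"
        )
        for sid in sorted(annotations):
            a = annotations[sid]
            fh.write(
                f"{sid}\t{a.left_arm.start}\t{a.left_arm.end}\t{a.loop.start}\t"
                f"{a.loop.end}\t{a.right_arm.start}\t{a.right_arm.end}\t"
                f"{a.arm_len}\t{a.arm_mismatches}\t{int(a.degenerate)}\n"
            )


def write_loop_bed(
    annotations: dict[str, HairpinAnnotation], path: Union[str, Path]
) -> None:
    with open(path, "w") as fh:
        for sid in sorted(annotations):
            a = annotations[sid]
            if not a.degenerate or a.loop_len > 0:
                fh.write(f"{sid}\t{a.loop.start}\t{a.loop.end}\tloop\n")
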