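"""FASTA input/output and primer trimming.

Headers follow an ``id|species|locality`` convention by default (the
species field is what downstream barcode statistics group by); a header
without pipes falls back to using the whole header as both id and species.
Readers transparently accept gzip-compressed files.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Union

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as BioSeqRecord

from .records import GAP, Alignment, Interval, SequenceRecord

logger = logging.getLogger(__name__)


class FastaFormatError(ValueError):
    pass


def _open_text(path: Union[str, Path], mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def parse_header(header: str) -> tuple[str, str, Optional[str]]:
    """Split ``id|species|locality`` (locality optional) from a FASTA header."""
    fields = header.split("|")
    if len(fields) >= 3:
        return fields[0], fields[1], fields[2] or None
    if len(fields) == 2:
        return fields[0], fields[1], None
    return header, header, None


def read_fasta(
    path: Union[str, Path], keep_gaps: bool = False
) -> list[SequenceRecord]:
    """Read unaligned sequences; errors on duplicate ids or empty entries."""
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    with _open_text(path) as handle:
        for entry in SeqIO.parse(handle, "fasta"):
            rid, species, locality = parse_header(entry.description)
            seq = str(entry.seq).upper()
            if keep_gaps is False and GAP in seq:
                raise FastaFormatError(
                    f"{path}: record {rid!r} contains gap characters; "
                    "use read_aligned_fasta for alignments"
                )
            if not seq:
                raise FastaFormatError(f"{path}: record {rid!r} is empty")
            if rid in seen:
                raise FastaFormatError(f"{path}: duplicate id {rid!r}")
            seen.add(rid)
            records.append(
                SequenceRecord(id=rid, species=species, seq=seq, locality=locality)
            )
    return records


def read_aligned_fasta(path: Union[str, Path]) -> Alignment:
    rows: list[tuple[str, str]] = []
    seen: set[str] = set()
    with _open_text(path) as handle:
        for entry in SeqIO.parse(handle, "fasta"):
            rid = entry.description
            if rid in seen:
                raise FastaFormatError(f"{path}: duplicate id {rid!r}")
            seen.add(rid)
            rows.append((rid, str(entry.seq).upper()))
    return Alignment(rows)


def _format_header(rec: SequenceRecord) -> str:
    parts = [rec.id, rec.species]
    if rec.locality:
        parts.append(rec.locality)
    if rec.orientation_truth:
        while len(parts) < 3:
            parts.append("")
        parts.append(f"truth={rec.orientation_truth}")
    return "|".join(parts)


def write_fasta(
    data: Union[Iterable[SequenceRecord], Alignment], path: Union[str, Path]
) -> None:
    """Write records (headers re-encoded as id|species|locality) or an alignment."""
    path = Path(path)
    if isinstance(data, Alignment):
        entries = [
            BioSeqRecord(Seq(row), id=rid, description="") for rid, row in data.rows
        ]
    else:
        data = list(data)
        if not data:
            logger.warning("write_fasta: writing empty file %s", path)
        entries = [
            BioSeqRecord(Seq(rec.seq), id=_format_header(rec), description="")
            for rec in data
        ]
    with _open_text(path, "wt") as handle:
        SeqIO.write(entries, handle, "fasta-2line")


@dataclass
class TrimResult:
    record: SequenceRecord
    trimmed5: Optional[Interval]  # removed span, input coordinates
    trimmed3: Optional[Interval]
    ok: bool
    message: str = ""


def _best_hamming_hit(seq: str, probe: str, max_mismatch: int, from_end: bool):
    """Leftmost (or rightmost) occurrence of probe within max_mismatch."""
    n, m = len(seq), len(probe)
    positions = range(n - m, -1, -1) if from_end else range(0, n - m + 1)
    for start in positions:
        mism = 0
        for a, b in zip(seq[start : start + m], probe):
            if a != b:
                mism += 1
                if mism > max_mismatch:
                    break
        if mism <= max_mismatch:
            return start
    return None


def trim_primers(
    record: SequenceRecord,
    primer5: str,
    primer3: str,
    max_mismatch: int = 2,
    policy: str = "keep",
) -> TrimResult:
    """Remove amplification primers so sequences start/end at homologous sites.

    ``primer5`` is matched directly near the 5' end; ``primer3`` is given
    5'->3' on the opposite strand, so its reverse complement is matched at
    the 3' end. Ambiguity codes count as mismatches. If a primer is not
    found, the record passes through untrimmed under ``policy='keep'`` or
    raises under ``policy='error'``.
    """
    from .hairpin import reverse_complement

    seq = record.seq
    p5 = primer5.upper()
    p3rc = reverse_complement(primer3.upper())
    start5 = _best_hamming_hit(seq, p5, max_mismatch, from_end=False)
    start3 = _best_hamming_hit(seq, p3rc, max_mismatch, from_end=True)

    msgs = []
    if start5 is None:
        msgs.append("5' primer not found")
    if start3 is None:
        msgs.append("3' primer not found")
    if msgs:
        message = "; ".join(msgs)
        if policy == "error":
            raise ValueError(f"record {record.id!r}: {message}")
        logger.warning("trim_primers: %s: %s (kept untrimmed)", record.id, message)
        return TrimResult(record, None, None, ok=False, message=message)

    cut5 = start5 + len(p5)
    cut3 = start3
    if cut3 <= cut5:
        message = "primers overlap or are out of order"
        if policy == "error":
            raise ValueError(f"record {record.id!r}: {message}")
        return TrimResult(record, None, None, ok=False, message=message)
    trimmed = record.with_seq(seq[cut5:cut3])
    logger.info(
        "trim_primers: %s removed [%d,%d) and [%d,%d)",
        record.id,
        start5,
        cut5,
        cut3,
        start3 + len(p3rc),
    )
    return TrimResult(
        trimmed,
        Interval(start5, cut5),
        Interval(cut3, start3 + len(p3rc)),
        ok=True,
    )


def trim_dataset(
    records: list[SequenceRecord],
    primer5: str,
    primer3: str,
    max_mismatch: int = 2,
) -> tuple[list[SequenceRecord], list[TrimResult]]:
    """Trim every record; failures are kept untrimmed and listed as rejects."""
    out, rejects = [], []
    for rec in records:
        res = trim_primers(rec, primer5, primer3, max_mismatch, policy="keep")
        out.append(res.record)
        if not res.ok:
            rejects.append(res)
    return out, rejects


def write_rejects_report(rejects: list[TrimResult], path: Union[str, Path]) -> None:
    with open(path, "w") as fh:
        fh.write("seq_id\tmessage\n")
        for res in rejects:
            fh.write(f"{res.record.id}\t{res.message}\n")
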