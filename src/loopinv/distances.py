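"""Uncorrected p-distances, variable sites, and the barcode-gap report.

All statistics exclude gapped characters: under ``pairwise_deletion`` a
column is dropped only for the pair being compared; under
``complete_deletion_within_set`` any column gapped in any member of the
compared set is dropped for the whole set. Ambiguity codes (anything other
than A/C/G/T) are treated like gaps, i.e. excluded from comparisons.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

from .records import Alignment

logger = logging.getLogger(__name__)

PAIRWISE = "pairwise_deletion"
COMPLETE = "complete_deletion_within_set"


def _encode_acgt(row: str) -> np.ndarray:
    """A,C,G,T -> 0..3; everything else (gaps, ambiguity codes) -> -1."""
    arr = np.frombuffer(row.encode(), dtype=np.uint8)
    out = np.full(arr.shape, -1, dtype=np.int8)
    for i, c in enumerate("ACGT"):
        out[arr == ord(c)] = i
    return out


def p_distance(
    row_a: str, row_b: str, mask: Optional[np.ndarray] = None
) -> tuple[float, int]:
    """Proportion of differing sites over comparable (ungapped) sites.

    ``mask`` optionally restricts the comparison to a set-level column
    selection (complete deletion within a set). Returns (nan, 0) when no
    site is comparable.
    """
    if len(row_a) != len(row_b):
        raise ValueError("rows differ in length")
    a, b = _encode_acgt(row_a), _encode_acgt(row_b)
    ok = (a >= 0) & (b >= 0)
    if mask is not None:
        ok &= mask
    sites = int(ok.sum())
    if sites == 0:
        logger.warning("p_distance: no comparable sites")
        return math.nan, 0
    mism = int((a[ok] != b[ok]).sum())
    return mism / sites, sites


def complete_deletion_mask(rows: list[str]) -> np.ndarray:
    """Columns free of gaps/ambiguity in every row of the set."""
    mask = np.ones(len(rows[0]), dtype=bool)
    for row in rows:
        mask &= _encode_acgt(row) >= 0
    return mask


def variable_sites(
    rows: list[str], gap_mode: str = COMPLETE
) -> tuple[int, list[int]]:
    """Count of comparable columns with >=2 distinct nucleotides.

    Under pairwise deletion a column is counted when any two members both
    have a nucleotide there and disagree.
    """
    if len(rows) < 2:
        raise ValueError("need >=2 rows")
    enc = np.stack([_encode_acgt(r) for r in rows])
    if gap_mode == COMPLETE:
        mask = complete_deletion_mask(rows)
        var = mask & (np.array(
            [len(set(col[col >= 0])) > 1 for col in enc.T]
        ))
    elif gap_mode == PAIRWISE:
        var = np.array(
            [len(set(col[col >= 0])) > 1 for col in enc.T]
        )
    else:
        raise ValueError(f"unknown gap_mode {gap_mode!r}")
    positions = [int(i) for i in np.flatnonzero(var)]
    return len(positions), positions


def substitution_differences(row_a: str, row_b: str) -> int:
    """Mismatch count over columns where neither row is gapped (indels excluded)."""
    a, b = _encode_acgt(row_a), _encode_acgt(row_b)
    if len(a) != len(b):
        raise ValueError("rows differ in length")
    ok = (a >= 0) & (b >= 0)
    return int((a[ok] != b[ok]).sum())


@dataclass
class DistanceMatrix:
    ids: list[str]
    d: np.ndarray  # symmetric, zero diagonal, nan where undefined
    sites: np.ndarray

    def pair(self, a: str, b: str) -> float:
        i, j = self.ids.index(a), self.ids.index(b)
        return float(self.d[i, j])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.d, index=self.ids, columns=self.ids)

    def write_tsv(self, path: Union[str, Path]) -> None:
        self.to_dataframe().to_csv(path, sep="\t", float_format="%.6f")


def distance_matrix(
    alignment: Alignment, gap_mode: str = PAIRWISE
) -> DistanceMatrix:
    ids = alignment.ids
    rows = [row for _, row in alignment.rows]
    n = len(ids)
    d = np.zeros((n, n))
    sites = np.zeros((n, n), dtype=int)
    mask = complete_deletion_mask(rows) if gap_mode == COMPLETE else None
    for i, j in combinations(range(n), 2):
        dist, ns = p_distance(rows[i], rows[j], mask)
        d[i, j] = d[j, i] = dist
        sites[i, j] = sites[j, i] = ns
    return DistanceMatrix(ids, d, sites)


@dataclass
class BarcodeGapRow:
    species: str
    n: int
    variable_sites: Optional[int]
    variable_sites_pct: Optional[float]
    max_intra: Optional[float]
    min_inter: Optional[float]

    @property
    def gap_violated(self) -> bool:
        if self.max_intra is None or self.min_inter is None:
            return False
        return self.max_intra > self.min_inter


def barcode_gap_table(
    alignment: Alignment,
    species_map: dict[str, str],
    gap_mode: str = COMPLETE,
) -> list[BarcodeGapRow]:
    """Per-species barcode-gap statistics.

    Intraspecific statistics (variable sites, maximum intraspecific
    p-distance) use the given gap mode *within the conspecific set*; the
    minimum interspecific distance compares each sequence of the species
    against every sequence of every other species with pairwise deletion.
    NA distances are excluded from the max/min with a logged count.
    """
    rows_by_id = dict(alignment.rows)
    species_order: list[str] = []
    members: dict[str, list[str]] = {}
    for rid in alignment.ids:
        sp = species_map[rid]
        if sp not in members:
            members[sp] = []
            species_order.append(sp)
        members[sp].append(rid)

    out = []
    n_na = 0
    for sp in species_order:
        ids = members[sp]
        rows = [rows_by_id[r] for r in ids]
        if len(ids) >= 2:
            var, _ = variable_sites(rows, gap_mode)
            mask = (
                complete_deletion_mask(rows) if gap_mode == COMPLETE else None
            )
            intra = []
            for a, b in combinations(range(len(ids)), 2):
                dist, _ = p_distance(rows[a], rows[b], mask)
                if math.isnan(dist):
                    n_na += 1
                else:
                    intra.append(dist)
            max_intra = max(intra) if intra else None
            mean_len = float(np.mean([len(r.replace("-", "")) for r in rows]))
            var_pct = 100.0 * var / mean_len
        else:
            var, var_pct, max_intra = None, None, None
        inter = []
        for other_sp in species_order:
            if other_sp == sp:
                continue
            for rid_o in members[other_sp]:
                for rid_s in ids:
                    dist, _ = p_distance(rows_by_id[rid_s], rows_by_id[rid_o])
                    if math.isnan(dist):
                        n_na += 1
                    else:
                        inter.append(dist)
        min_inter = min(inter) if inter else None
        out.append(BarcodeGapRow(sp, len(ids), var, var_pct, max_intra, min_inter))
    if n_na:
        logger.info("barcode_gap_table: %d NA distances excluded", n_na)
    return out


def barcode_gap_dataframe(rows: list[BarcodeGapRow]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "species": [r.species for r in rows],
            "n": [r.n for r in rows],
            "variable_sites": [r.variable_sites for r in rows],
            "variable_sites_pct": [r.variable_sites_pct for r in rows],
            "max_intra": [r.max_intra for r in rows],
            "min_inter": [r.min_inter for r in rows],
            "gap_violated": [r.gap_violated for r in rows],
        }
    )
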