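"""SYNTHETIC stand-in for a 35-sequence Gentianaceae trnH-psbA dataset.

This module constructs, fully deterministically and in code, a synthetic
dataset with the structure of the published Gentianaceae study design: 35
sequences from 21 species, six species (3-4 sequences each) polymorphic for
the orientation of a 25-27 bp loop flanked by 18 bp inverted repeats, and
15 further species with one sequence each. It is NOT the real GenBank data;
it is a synthetic emulation whose planted features make the pipeline's
study-shaped checks self-contained:

* 19 sequences carry the "A" loop orientation and 15 the "B" orientation;
  one sequence (the Comastoma analogue) carries a deletion of all but 3 bp
  of the loop plus 1 bp of the flanking arm, so its orientation cannot be
  called.
* Within the six polymorphic species the raw (as-sequenced) variable-site
  counts are 17, 17, 17, 21, 23 and 25; after orientation normalization
  they drop to 0, 0, 0, 0, 2 and 4.
* Same-orientation sequences of the crinita- and thermalis-like species
  differ by exactly 5 substitutions, all outside the loop; conspecific
  crinita-like sequences with opposite orientations differ at 17 sites, all
  inside the loop.
* The macrantha-like species is identical to the lanceolata-like singleton
  once orientations are normalized; the thermalis-like species carries a
  1 bp mononucleotide-repeat length variant.
* In the raw matrix the barcode gap (max intraspecific vs min interspecific
  p-distance) is violated for five of the six polymorphic species (all but
  the algida analogue); in the uniform matrix it is violated for none.

Sequence lengths span 214-489 bp. All coordinates below are 0-based,
half-open, in the 448 bp master locus: 5' flank [0,170), left arm
[170,188), loop [188,215), right arm [215,233), 3' flank [233,448).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .hairpin import reverse_complement
from .records import SequenceRecord

_SEED = 20100713  # the dataset is a fixed constant, not a tunable input

MASTER_LEN = 448
ARM5 = (170, 188)
LOOP = (188, 215)
ARM3 = (215, 233)
POLY_A = (100, 106)

# positions never deleted by any species: reserved for exact substitutions
_SAFE = list(range(130, 167)) + list(range(240, 280)) + list(range(440, 448))

_THERMALIS = _SAFE[0:5]  # 5 subs separating thermalis from crinita
_HOLOPETALA = _SAFE[5:9]  # +4 subs: thermalis' nearest neighbour
_PROSTRATA = _SAFE[9:28]  # 19 subs: fremontii's nearest neighbour
_SPECIOSA_VAR = _SAFE[28:32]  # s1,s2 on the B pair; s3,s4 on one A sequence
_ALGIDA_B = _SAFE[32:34]  # 2 subs private to the algida B sequence
_CHONDRO = _SAFE[34:49]  # 15 subs shared by the short Gentiana group
_ALGIDA_SP = _SAFE[49:67]  # 18 algida species subs
_PARRYI = _SAFE[67:76]
_AFFINIS = _SAFE[76:85]

_GPSIS_GROUP = list(range(0, 10)) + [125, 126]  # 12 Gentianopsis subs
_FRASERA_GROUP = list(range(106, 116))
_SPECIOSA_BASE = list(range(116, 122))
_CAROLINIENSIS = list(range(428, 440))  # speciosa's nearest congener: +12
_MACRANTHA = list(range(91, 99))  # 8 subs from the crinita baseline

# loop pair tweaks (see _make_loops): one complementary pair broken per
# species raises the flip-difference count from 19 to 21
_TWEAK_SPECIOSA = LOOP[0] + 23
_TWEAK_ALGIDA = LOOP[0] + 20
_TWEAK_FREMONTII = LOOP[0] + 17

POLYMORPHIC_SPECIES = [
    "Gentianopsis_crinita",
    "Gentianopsis_thermalis",
    "Gentianopsis_macrantha",
    "Frasera_speciosa",
    "Gentiana_algida",
    "Gentiana_fremontii",
]


def _make_loop25(rng: np.random.Generator) -> str:
    """25 bp loop whose reverse complement differs from it at exactly 17
    positions: the centre plus 8 of the 12 symmetric pairs."""
    comp = dict(zip("ACGT", "TGCA"))
    bases = "ACGT"
    comp_pairs = {2, 5, 8, 11}
    loop = [""] * 25
    for i in range(12):
        left = bases[rng.integers(0, 4)]
        loop[i] = left
        if i in comp_pairs:
            loop[24 - i] = comp[left]
        else:
            choices = [b for b in bases if b != comp[left]]
            loop[24 - i] = choices[rng.integers(0, 3)]
    loop[12] = bases[rng.integers(0, 4)]
    return "".join(loop)


def _make_master(rng: np.random.Generator) -> tuple[str, str]:
    """(master sequence, 25 bp Gentianopsis loop).

    The master carries the 27 bp loop (the 25 bp loop with one extra,
    non-complementary base at each end, so its flip-difference count is 19);
    the three outermost flank base pairs around the arms are forced
    non-complementary so arm extension terminates quickly, and a 6 bp poly-A
    tract sits in the 5' flank for the thermalis length variant.
    """
    bases = "ACGT"
    loop25 = _make_loop25(rng)
    loop27 = "G" + loop25 + "A"
    arm = "".join(bases[rng.integers(0, 4)] for _ in range(18))
    f5 = ["ACGT"[rng.integers(0, 4)] for _ in range(170)]
    f3 = ["ACGT"[rng.integers(0, 4)] for _ in range(215)]
    for k, ch in enumerate("AAAAAA"):
        f5[POLY_A[0] + k] = ch
    f5[POLY_A[0] - 1] = "C"
    f5[POLY_A[1]] = "G"
    # non-complementary outer pairs: (169,233)=(A,A), (168,234)=(C,C), (167,235)=(G,G)
    f5[167], f5[168], f5[169] = "G", "C", "A"
    f3[0], f3[1], f3[2] = "A", "C", "G"
    master = "".join(f5) + arm + loop27 + reverse_complement(arm) + "".join(f3)
    assert len(master) == MASTER_LEN
    return master, loop25


def _sub_map(
    rng: np.random.Generator, master: str, positions: list[int]
) -> dict[int, str]:
    out = {}
    for p in positions:
        choices = [b for b in "ACGT" if b != master[p]]
        out[p] = choices[rng.integers(0, 3)]
    return out


def _bulk(rng: np.random.Generator, pool: list[int], n: int) -> list[int]:
    return sorted(int(x) for x in rng.choice(pool, size=n, replace=False))


@dataclass
class _SeqDef:
    sid: str
    species: str
    locality: str
    orientation: Optional[str]  # planted truth; None = uncallable
    subs: dict[int, str]
    dels: list[tuple[int, int]] = field(default_factory=list)
    ins: list[tuple[int, str]] = field(default_factory=list)
    gentianopsis_loop: bool = False  # drop the two outer loop bases (27 -> 25)


def _materialize(master: str, d: _SeqDef) -> str:
    items: list[tuple[Optional[int], str]] = [
        (i, d.subs.get(i, ch)) for i, ch in enumerate(master)
    ]
    for pos, ins_seq in sorted(d.ins, reverse=True):
        k = next((n for n, (i, _) in enumerate(items) if i is not None and i >= pos), len(items))
        items[k:k] = [(None, ch) for ch in ins_seq]
    dels = list(d.dels)
    if d.gentianopsis_loop:
        dels += [(LOOP[0], LOOP[0] + 1), (LOOP[1] - 1, LOOP[1])]
    if dels:
        items = [
            (i, ch)
            for i, ch in items
            if i is None or not any(s <= i < e for s, e in dels)
        ]
    if d.orientation == "B":
        loop_idx = [
            n for n, (i, _) in enumerate(items) if i is not None and LOOP[0] <= i < LOOP[1]
        ]
        lo, hi = loop_idx[0], loop_idx[-1] + 1
        seq = "".join(ch for _, ch in items)
        return seq[:lo] + reverse_complement(seq[lo:hi]) + seq[hi:]
    return "".join(ch for _, ch in items)


def build_study_standin() -> list[SequenceRecord]:
    """The 35-record synthetic dataset (deterministic; see module docstring)."""
    rng = np.random.default_rng(_SEED)
    master, _loop25 = _make_master(rng)

    sub = lambda pos: _sub_map(rng, master, list(pos))  # noqa: E731

    gpsis = sub(_GPSIS_GROUP)
    therm = sub(_THERMALIS)
    holo = sub(_HOLOPETALA)
    macr = sub(_MACRANTHA)
    frasera = sub(_FRASERA_GROUP)
    spec_base = sub(_SPECIOSA_BASE)
    s1s2 = sub(_SPECIOSA_VAR[:2])
    s3s4 = sub(_SPECIOSA_VAR[2:])
    carol = sub(_CAROLINIENSIS)
    prost = sub(_PROSTRATA)
    chondro = sub(_CHONDRO)
    algida_sp = sub(_ALGIDA_SP)
    algida_b = sub(_ALGIDA_B)
    parryi = sub(_PARRYI)
    affinis = sub(_AFFINIS)

    # break one complementary loop pair per taxon (flip differences 19 -> 21)
    tweak = lambda p: _sub_map(rng, master, [p])  # noqa: E731
    spec_loop = tweak(_TWEAK_SPECIOSA)
    alg_loop = tweak(_TWEAK_ALGIDA)
    fre_loop = tweak(_TWEAK_FREMONTII)

    pool = [
        p
        for p in list(range(10, 91)) + list(range(236, 240)) + list(range(280, 428))
        if not (POLY_A[0] <= p < POLY_A[1])
    ]
    gentiana = sub(_bulk(rng, pool, 45))
    frasera_single_pool = [p for p in pool if p < 290]
    albic = sub(_bulk(rng, frasera_single_pool, 16))
    mont = sub(_bulk(rng, frasera_single_pool, 18))
    puber = sub(_bulk(rng, frasera_single_pool, 15))
    swertia = sub(_bulk(rng, [p for p in pool if not 400 <= p < 420], 30))
    lomato = sub(_bulk(rng, pool, 32))
    gentianella = sub(_bulk(rng, [p for p in pool if not 420 <= p < 428], 35))
    comastoma = sub(_bulk(rng, pool, 30))
    doug_pool = [p for p in pool if p < 91 or 236 <= p < 240 or 280 <= p < 290 or 392 <= p < 400 or 412 <= p < 428]
    doug = sub(_bulk(rng, doug_pool, 25))
    nutans_own = sub(_bulk(rng, [p for p in pool if 280 <= p < 314], 10))

    ins_b = "".join("ACGT"[rng.integers(0, 4)] for _ in range(26))
    ins_pub = "".join("ACGT"[rng.integers(0, 4)] for _ in range(41))

    therm_dels = [(380, 401)]
    macr_dels = [(10, 90), (300, 382)]

    defs = [
        # --- Gentianopsis crinita: 3 seqs, identical up to orientation
        _SeqDef("SYN01", "Gentianopsis_crinita", "MA", "A", gpsis, [(300, 302)], [], True),
        _SeqDef("SYN02", "Gentianopsis_crinita", "NY", "B", gpsis, [(300, 302)], [], True),
        _SeqDef("SYN03", "Gentianopsis_crinita", "VT", "B", gpsis, [(300, 302)], [], True),
        # --- Gentianopsis thermalis: crinita + 5 subs; one poly-A length variant
        _SeqDef("SYN04", "Gentianopsis_thermalis", "WY", "A", {**gpsis, **therm}, therm_dels, [], True),
        _SeqDef("SYN05", "Gentianopsis_thermalis", "CO1", "A", {**gpsis, **therm}, therm_dels, [], True),
        _SeqDef("SYN06", "Gentianopsis_thermalis", "CO2", "B", {**gpsis, **therm}, therm_dels + [(105, 106)], [], True),
        # --- Gentianopsis macrantha: short; uniform-identical to lanceolata
        _SeqDef("SYN07", "Gentianopsis_macrantha", "AZ", "A", {**gpsis, **macr}, macr_dels, [], True),
        _SeqDef("SYN08", "Gentianopsis_macrantha", "NM", "B", {**gpsis, **macr}, macr_dels, [], True),
        _SeqDef("SYN09", "Gentianopsis_macrantha", "TX", "B", {**gpsis, **macr}, macr_dels, [], True),
        # --- Frasera speciosa: 2 A + 2 B; B pair shares 2 subs and 2 indels
        _SeqDef("SYN10", "Frasera_speciosa", "CO", "A", {**frasera, **spec_base, **spec_loop}, [(360, 428)]),
        _SeqDef("SYN11", "Frasera_speciosa", "UT", "A", {**frasera, **spec_base, **spec_loop, **s3s4}, [(360, 428)]),
        _SeqDef("SYN12", "Frasera_speciosa", "WY", "B", {**frasera, **spec_base, **spec_loop, **s1s2}, [(360, 428), (60, 69)], [(310, ins_b)]),
        _SeqDef("SYN13", "Frasera_speciosa", "MT", "B", {**frasera, **spec_base, **spec_loop, **s1s2}, [(360, 428), (60, 69)], [(310, ins_b)]),
        # --- Gentiana algida: distant from everything; clusters even raw
        _SeqDef("SYN14", "Gentiana_algida", "AK", "A", {**gentiana, **algida_sp, **alg_loop}, [(290, 364)]),
        _SeqDef("SYN15", "Gentiana_algida", "CO", "A", {**gentiana, **algida_sp, **alg_loop}, [(290, 364), (60, 91)]),
        _SeqDef("SYN16", "Gentiana_algida", "MT", "B", {**gentiana, **algida_sp, **alg_loop, **algida_b}, [(290, 364)]),
        # --- Gentiana fremontii: short; prostrata sits inside the raw gap
        _SeqDef("SYN17", "Gentiana_fremontii", "CO", "A", {**gentiana, **chondro, **fre_loop}, [(5, 125), (290, 392)]),
        _SeqDef("SYN18", "Gentiana_fremontii", "WY", "A", {**gentiana, **chondro, **fre_loop}, [(5, 125), (290, 392)]),
        _SeqDef("SYN19", "Gentiana_fremontii", "UT", "B", {**gentiana, **chondro, **fre_loop}, [(5, 125), (290, 392)]),
        _SeqDef("SYN20", "Gentiana_fremontii", "NM", "B", {**gentiana, **chondro, **fre_loop}, [(5, 125), (290, 392)]),
        # --- singletons
        _SeqDef("SYN21", "Gentianopsis_holopetala", "CA", "A", {**gpsis, **therm, **holo}, therm_dels, [], True),
        _SeqDef("SYN22", "Gentianopsis_lanceolata", "GA", "B", {**gpsis, **macr}, macr_dels, [], True),
        _SeqDef("SYN23", "Frasera_puberulenta", "CA", "A", {**frasera, **puber}, [], [(350, ins_pub)]),
        _SeqDef("SYN24", "Frasera_albicaulis", "ID", "A", {**frasera, **albic}),
        _SeqDef("SYN25", "Frasera_montana", "NM", "A", {**frasera, **mont}),
        _SeqDef("SYN26", "Frasera_caroliniensis", "TN", "A", {**frasera, **spec_base, **carol}),
        _SeqDef("SYN27", "Swertia_perennis", "CO", "A", swertia, [(400, 420)]),
        _SeqDef("SYN28", "Lomatogonium_rotatum", "AK", "A", lomato),
        _SeqDef("SYN29", "Gentianella_amarella", "CO", "A", gentianella, [(420, 440)]),
        # loop deleted down to 3 bp plus 1 bp of the right arm: uncallable
        _SeqDef("SYN30", "Comastoma_tenellum", "AK", None, comastoma, [(191, 216)]),
        _SeqDef("SYN31", "Gentiana_prostrata", "CO", "B", {**gentiana, **chondro, **prost}, [(5, 125), (314, 392)]),
        _SeqDef("SYN32", "Gentiana_nutans", "AK", "B", {**gentiana, **chondro, **prost, **nutans_own}, [(5, 125), (314, 392)]),
        _SeqDef("SYN33", "Gentiana_douglasiana", "AK", "B", {**gentiana, **chondro, **doug}, [(5, 125), (290, 392), (400, 412)]),
        _SeqDef("SYN34", "Gentiana_affinis", "CO", "B", {**gentiana, **affinis}, [(420, 438)]),
        _SeqDef("SYN35", "Gentiana_parryi", "CO", "A", {**gentiana, **parryi}, [(420, 438)]),
    ]

    records = []
    for d in defs:
        records.append(
            SequenceRecord(
                id=d.sid,
                species=d.species,
                seq=_materialize(master, d),
                locality=d.locality,
                orientation_truth=d.orientation,
            )
        )
    return records


def species_map(records: list[SequenceRecord]) -> dict[str, str]:
    return {r.id: r.species for r in records}
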