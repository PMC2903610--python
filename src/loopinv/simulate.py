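"""Truth-labelled simulation of a stem-loop locus with loop inversions.

The generator grows a pure-birth (Yule) species tree, hangs a shallow star
of conspecific samples under each species, and evolves a locus of the form
``flank5 + arm + loop + reverse_complement(arm) + flank3`` along it with
point substitutions (equal-rate replacement), short indels (1-3 bp, never
touching the arms, so planted coordinates stay well defined), length
slippage in mononucleotide tracts, and Poisson loop-inversion events, each
of which replaces the current loop with its reverse complement. Leaf labels
record the planted orientation ("A" = the root's form).

Defaults mirror a Gentianaceae-like trnH-psbA study design: 21 species,
a ~380 bp locus with 18 bp arms and a 27 bp loop, a few percent root-to-tip
substitution divergence, and inversion events frequent enough that several
species are orientation-polymorphic in a typical draw.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass
from typing import Optional

import dendropy
import numpy as np

from .hairpin import reverse_complement
from .records import SequenceRecord

logger = logging.getLogger(__name__)

_BASES = np.array(list("ACGT"))


@dataclass
class SimConfig:
    n_species: int = 21
    n_per_species: int = 3
    root_length: int = 380  # total locus length, bp
    arm_len: int = 18
    loop_len: int = 27
    sub_rate: float = 0.03  # per site per branch-length unit
    indel_rate: float = 0.001  # per site per unit; lengths 1-3 bp
    slippage_rate: float = 0.05  # per mononucleotide tract (>=5 bp) per unit
    inversion_rate: float = 2.0  # loop flips per unit
    within_species_depth: float = 0.1  # tip branch length under each species
    protect_arms: bool = True  # arms are under structural selection: no
    # substitutions land in them (they are invariant across real datasets)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("sub_rate", "indel_rate", "slippage_rate", "inversion_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.arm_len < 1:
            raise ValueError("arm_len must be >= 1")
        if self.loop_len < 1:
            raise ValueError("loop_len must be >= 1")
        if self.root_length < 2 * self.arm_len + self.loop_len + 2:
            raise ValueError("root_length too small for the hairpin")

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "SimConfig":
        return cls(**json.loads(text))


@dataclass
class SimResult:
    records: list[SequenceRecord]
    tree: dendropy.Tree
    species_map: dict[str, str]
    events: list[dict]
    config: SimConfig
    seed: int


def simulate_tree(
    config: SimConfig, rng: Optional[np.random.Generator] = None
) -> tuple[dendropy.Tree, dict[str, str]]:
    """Yule species tree (height normalized to 1) with star subtrees of
    ``n_per_species`` samples (tip branches ``within_species_depth``)."""
    rng = rng or np.random.default_rng(config.seed)
    n = config.n_species
    species = [f"sp{k+1:02d}" for k in range(n)]

    # forward pure-birth: split a random active lineage at Exp(k) intervals
    tns = dendropy.TaxonNamespace()
    root = dendropy.Node()
    active = [root]
    t = 0.0
    while len(active) < n:
        k = len(active)
        t += rng.exponential(1.0 / k)
        idx = int(rng.integers(0, k))
        node = active.pop(idx)
        node.split_depth = t  # type: ignore[attr-defined]
        for _ in range(2):
            child = dendropy.Node()
            node.add_child(child)
            active.append(child)
    total = t + rng.exponential(1.0 / n)  # extend tips a final stretch
    # assign depths: leaves at `total`; normalize heights to 1
    scale = 1.0 / total if total > 0 else 1.0

    for i, node in enumerate(active):
        node.species_name = species[i]  # type: ignore[attr-defined]

    def assign(node, parent_depth):
        node_depth = getattr(node, "split_depth", total)
        node.edge.length = max(node_depth - parent_depth, 0.0) * scale
        for c in node.child_nodes():
            assign(c, node_depth)

    for c in root.child_nodes():
        assign(c, getattr(root, "split_depth", 0.0))
    root.edge.length = None

    species_map: dict[str, str] = {}
    if config.n_per_species == 1:
        for node in active:
            label = f"{node.species_name}_1"
            node.taxon = dendropy.Taxon(label)
            tns.add_taxon(node.taxon)
            species_map[label] = node.species_name
    else:
        for node in active:
            for r in range(config.n_per_species):
                label = f"{node.species_name}_{r+1}"
                child = dendropy.Node()
                child.taxon = dendropy.Taxon(label)
                tns.add_taxon(child.taxon)
                child.edge.length = config.within_species_depth
                node.add_child(child)
                species_map[label] = node.species_name

    tree = dendropy.Tree(taxon_namespace=tns, seed_node=root)
    tree.is_rooted = True
    return tree, species_map


@dataclass
class _LineageState:
    seq: str
    arm5: tuple[int, int]
    loop: tuple[int, int]
    arm3: tuple[int, int]
    flips: int = 0


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(_BASES, size=n))


def _non_pairing_loop(rng: np.random.Generator, n: int) -> str:
    """Random loop whose three outermost base pairs cannot pair, so the
    stem-loop boundary is well defined (the stem cannot creep into the loop
    even with the default mismatch budget)."""
    comp = dict(zip("ACGT", "TGCA"))
    loop = list(_random_seq(rng, n))
    for k in range(min(3, n // 2)):
        while loop[n - 1 - k] == comp[loop[k]]:
            loop[n - 1 - k] = "ACGT"[rng.integers(0, 4)]
    return "".join(loop)


def _root_state(config: SimConfig, rng: np.random.Generator) -> _LineageState:
    flank_total = config.root_length - 2 * config.arm_len - config.loop_len
    f5 = flank_total // 2
    f3 = flank_total - f5
    arm = _random_seq(rng, config.arm_len)
    loop = _non_pairing_loop(rng, config.loop_len)
    seq = _random_seq(rng, f5) + arm + loop + reverse_complement(arm) + _random_seq(rng, f3)
    a5 = (f5, f5 + config.arm_len)
    lp = (a5[1], a5[1] + config.loop_len)
    a3 = (lp[1], lp[1] + config.arm_len)
    return _LineageState(seq, a5, lp, a3)


def _mono_tracts(seq: str, excl_ranges) -> list[tuple[int, int]]:
    """Mononucleotide tracts >= 5 bp fully outside the excluded ranges."""
    tracts = []
    i = 0
    n = len(seq)
    while i < n:
        j = i
        while j < n and seq[j] == seq[i]:
            j += 1
        if j - i >= 5:
            if not any(i < e and s < j for s, e in excl_ranges):
                tracts.append((i, j))
        i = j
    return tracts


def _shift_state(state: _LineageState, pos: int, delta: int) -> None:
    """Update hairpin coordinates after an indel of signed length delta at pos."""
    def sh(iv):
        s, e = iv
        if pos <= s:
            return (s + delta, e + delta)
        if pos < e:
            return (s, e + delta)
        return iv
    state.arm5 = sh(state.arm5)
    state.loop = sh(state.loop)
    state.arm3 = sh(state.arm3)


def _evolve_branch(
    state: _LineageState,
    brlen: float,
    config: SimConfig,
    rng: np.random.Generator,
    branch_label: str,
    events: list[dict],
) -> _LineageState:
    seq = list(state.seq)
    st = _LineageState(state.seq, state.arm5, state.loop, state.arm3, state.flips)

    # substitutions
    n_sub = rng.poisson(config.sub_rate * len(seq) * brlen)
    for _ in range(n_sub):
        for _attempt in range(50):
            pos = int(rng.integers(0, len(seq)))
            if not config.protect_arms:
                break
            if not any(s <= pos < e for s, e in (st.arm5, st.arm3)):
                break
        else:
            continue
        old = seq[pos]
        choices = [b for b in "ACGT" if b != old]
        seq[pos] = choices[int(rng.integers(0, 3))]
        events.append({"type": "substitution", "branch": branch_label, "pos": pos})

    # indels, 1-3 bp, never touching the arms
    n_indel = rng.poisson(config.indel_rate * len(seq) * brlen)
    for _ in range(n_indel):
        length = int(rng.integers(1, 4))
        is_del = bool(rng.integers(0, 2))
        arms = [st.arm5, st.arm3]
        for _attempt in range(20):
            pos = int(rng.integers(0, len(seq) + (0 if is_del else 1)))
            span = (pos, pos + (length if is_del else 0))
            if is_del and span[1] > len(seq):
                continue
            if any(span[0] < e and s < span[1] for s, e in arms):
                continue
            if not is_del and any(s < pos < e for s, e in arms):
                continue
            break
        else:
            continue
        if is_del:
            del seq[pos : pos + length]
            _shift_state(st, pos, -length)
            events.append(
                {"type": "deletion", "branch": branch_label, "pos": pos, "len": length}
            )
        else:
            ins = _random_seq(rng, length)
            seq[pos:pos] = list(ins)
            _shift_state(st, pos, length)
            events.append(
                {"type": "insertion", "branch": branch_label, "pos": pos, "len": length}
            )

    # mononucleotide-repeat slippage (+-1 bp on tracts >= 5 bp)
    tracts = _mono_tracts("".join(seq), [st.arm5, st.arm3])
    if tracts:
        n_slip = rng.poisson(config.slippage_rate * len(tracts) * brlen)
        for _ in range(n_slip):
            tracts = _mono_tracts("".join(seq), [st.arm5, st.arm3])
            if not tracts:
                break
            s, e = tracts[int(rng.integers(0, len(tracts)))]
            if rng.integers(0, 2):
                seq[s:s] = [seq[s]]
                _shift_state(st, s, 1)
                events.append({"type": "slippage", "branch": branch_label, "pos": s, "len": 1})
            else:
                del seq[s]
                _shift_state(st, s, -1)
                events.append({"type": "slippage", "branch": branch_label, "pos": s, "len": -1})

    # loop inversions
    n_inv = rng.poisson(config.inversion_rate * brlen)
    for _ in range(n_inv):
        ls, le = st.loop
        loop = "".join(seq[ls:le])
        seq[ls:le] = list(reverse_complement(loop)) if loop else []
        st.flips += 1
        events.append(
            {"type": "inversion", "branch": branch_label, "loop": [ls, le]}
        )

    st.seq = "".join(seq)
    return st


def evolve_locus(
    tree: dendropy.Tree,
    config: SimConfig,
    species_map: dict[str, str],
    rng: Optional[np.random.Generator] = None,
) -> tuple[list[SequenceRecord], list[dict]]:
    """Evolve the locus along the tree; leaves carry planted orientation truth."""
    rng = rng or np.random.default_rng(config.seed + 1)
    events: list[dict] = []
    root_state = _root_state(config, rng)
    states: dict[int, _LineageState] = {id(tree.seed_node): root_state}
    records: list[SequenceRecord] = []
    counter = 0
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        counter += 1
        parent_state = states[id(node.parent_node)]
        label = (
            node.taxon.label if node.is_leaf() and node.taxon else f"edge{counter}"
        )
        st = _evolve_branch(
            parent_state, node.edge.length or 0.0, config, rng, label, events
        )
        states[id(node)] = st
        if node.is_leaf():
            truth = "A" if st.flips % 2 == 0 else "B"
            events.append(
                {
                    "type": "leaf_state",
                    "leaf": label,
                    "arm5": list(st.arm5),
                    "loop": list(st.loop),
                    "arm3": list(st.arm3),
                    "flips": st.flips,
                }
            )
            records.append(
                SequenceRecord(
                    id=label,
                    species=species_map[label],
                    seq=st.seq,
                    orientation_truth=truth,
                )
            )
    return records, events


def simulate(config: SimConfig) -> SimResult:
    rng = np.random.default_rng(config.seed)
    tree, species_map = simulate_tree(config, rng)
    records, events = evolve_locus(tree, config, species_map, rng)
    return SimResult(records, tree, species_map, events, config, config.seed)


def polymorphic_species(records: list[SequenceRecord]) -> set[str]:
    forms: dict[str, set[str]] = {}
    for r in records:
        forms.setdefault(r.species, set()).add(r.orientation_truth)
    return {sp for sp, f in forms.items() if {"A", "B"} <= f}


def canonical_sequences(result: SimResult) -> dict[str, str]:
    """Leaf sequences with every loop in the root ("A") orientation, using
    the planted coordinates from the event log."""
    states = {
        ev["leaf"]: ev for ev in result.events if ev["type"] == "leaf_state"
    }
    out = {}
    for rec in result.records:
        st = states[rec.id]
        if st["flips"] % 2:
            ls, le = st["loop"]
            out[rec.id] = (
                rec.seq[:ls] + reverse_complement(rec.seq[ls:le]) + rec.seq[le:]
            )
        else:
            out[rec.id] = rec.seq
    return out


def _true_barcode_gap(result: SimResult) -> bool:
    """Every species' intraspecific divergence (up to loop orientation) is
    strictly below its divergence to every other species.

    This is the study-design condition: species are recognized, distinct
    lineages whose barcode gap holds once inversions are factored out; the
    analysis then asks whether unrecognized inversions *mask* that gap.
    """
    import edlib

    canon = canonical_sequences(result)
    ids = [r.id for r in result.records]
    sp = {r.id: r.species for r in result.records}
    max_intra: dict[str, int] = {}
    min_inter: dict[str, int] = {}
    for i, a in enumerate(ids):
        for b in ids[i + 1 :]:
            d = edlib.align(canon[a], canon[b], task="distance")["editDistance"]
            if sp[a] == sp[b]:
                max_intra[sp[a]] = max(max_intra.get(sp[a], 0), d)
            else:
                for s in (sp[a], sp[b]):
                    min_inter[s] = min(min_inter.get(s, 1 << 30), d)
    return all(
        max_intra.get(s, 0) < min_inter.get(s, 1 << 30) for s in set(sp.values())
    )


def make_polymorphic_fixture(
    config: SimConfig, k: int = 6, max_attempts: int = 200
) -> tuple[SimResult, int]:
    """Rejection-sample seeds until >= k species carry both loop orientations.

    Accepted fixtures additionally satisfy the true (orientation-corrected)
    barcode gap for every species, mirroring a study design that samples
    recognized, distinct species and then asks whether inversions mask the
    gap.
    """
    if k > 0 and config.inversion_rate <= 0:
        raise ValueError("inversion_rate must be > 0 to obtain polymorphic species")
    for attempt in range(max_attempts):
        seed = config.seed + attempt
        cfg = SimConfig(**{**asdict(config), "seed": seed})
        result = simulate(cfg)
        if k == 0:
            return result, seed
        if len(polymorphic_species(result.records)) >= k and _true_barcode_gap(result):
            logger.info(
                "make_polymorphic_fixture: accepted seed %d after %d attempts",
                seed,
                attempt + 1,
            )
            return result, seed
    raise RuntimeError(
        f"no seed with >= {k} polymorphic species in {max_attempts} attempts; "
        "consider a higher inversion_rate"
    )
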