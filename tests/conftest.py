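import pytest

from loopinv import (
    SimConfig,
    anchor_shared_hairpin,
    build_matrix_pair,
    call_all,
    distance_matrix,
    nj,
    progressive_align,
    upgma,
)
from loopinv.distances import barcode_gap_table
from loopinv.simulate import make_polymorphic_fixture
from loopinv.synthetic_study import build_study_standin


@pytest.fixture(scope="session")
def standin_records():
    return build_study_standin()


@pytest.fixture(scope="session")
def standin_analysis(standin_records):
    """Full raw-vs-uniform analysis of the synthetic study stand-in,
    computed once per session."""
    records = standin_records
    annotations = anchor_shared_hairpin(records)
    calls, counts = call_all(records, annotations)
    pair = build_matrix_pair(records, annotations, calls, "B")
    species_map = {r.id: r.species for r in records}
    out = {
        "records": records,
        "annotations": annotations,
        "calls": calls,
        "counts": counts,
        "pair": pair,
        "species_map": species_map,
    }
    for name, recs in (("raw", pair.raw), ("uniform", pair.uniform)):
        aln = progressive_align(recs)
        dm = distance_matrix(aln)
        out[name] = {
            "alignment": aln,
            "dm": dm,
            "table": {
                row.species: row
                for row in barcode_gap_table(aln, species_map)
            },
            "nj": nj(dm),
            "upgma": upgma(dm),
        }
    return out


# study-design-like simulation conditions used by the end-to-end checks:
# well-separated species, a few conspecific samples with modest variation,
# inversions frequent enough to yield orientation polymorphism
END_TO_END_CONFIG = dict(
    sub_rate=0.05,
    indel_rate=0.0,
    slippage_rate=0.0,
    inversion_rate=3.0,
    within_species_depth=0.05,
    n_species=6,
    n_per_species=3,
)


@pytest.fixture(scope="session")
def polymorphic_fixture():
    cfg = SimConfig(seed=42, **END_TO_END_CONFIG)
    result, seed = make_polymorphic_fixture(cfg, k=2)
    return result
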