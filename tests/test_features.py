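"""Topology, sequon, cysteine-subgroup and motif annotation."""

import math

import pytest
from hypothesis import given, settings, strategies as st

from orfish.features import (
    column_information,
    cysteine_subgroup,
    extract_conserved_motifs,
    find_sequons,
    predict_topology,
    star_msa,
)


def test_single_hydrophobic_stretch_detected_exactly():
    protein = "D" * 100 + "L" * 25 + "D" * 100
    topo = predict_topology(protein)
    assert not topo.resolved  # one helix is not a GPCR
    assert topo.helices == [(100, 125)]


def test_all_hydrophilic_protein_has_no_helices():
    topo = predict_topology("D" * 250)
    assert not topo.resolved
    assert topo.helices == []


def test_seven_helix_recovery_on_planted_templates(small_repertoire):
    truth = small_repertoire.truth
    complete = truth[truth.status == "complete"]
    for _, row in complete.iterrows():
        topo = predict_topology(row.protein)
        assert topo.resolved, row.gene_id
        assert topo.tm_count == 7
        labels = [s.label for s in topo.segments]
        assert labels == [
            "Nter", "TM1", "IN1", "TM2", "OUT1", "TM3", "IN2",
            "TM4", "OUT2", "TM5", "IN3", "TM6", "OUT3", "TM7", "Cter",
        ]
        # segments tile the protein
        pos = 0
        for seg in topo.segments:
            assert seg.start == pos
            pos = seg.end
        assert pos == len(row.protein)
        for seg in topo.segments:
            if seg.label.startswith("TM"):
                assert 17 <= seg.end - seg.start <= 30


def test_sequon_pattern_examples():
    assert [(s.position, s.context) for s in find_sequons("MNASK")] == [
        (2, "NAS")
    ]
    assert find_sequons("MNPSK") == []  # X = P excluded
    assert [s.position for s in find_sequons("MNSTNATA")] == [2, 5]


@settings(derandomize=True, max_examples=40)
@given(
    protein=st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", min_size=3, max_size=60),
    tail=st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", min_size=0, max_size=20),
)
def test_sequons_invariant_under_appending(protein, tail):
    base = find_sequons(protein)
    extended = find_sequons(protein + tail)
    positions = {s.position for s in base}
    assert positions <= {s.position for s in extended}
    if base:
        last = max(positions)
        kept = [s.position for s in extended if s.position <= last]
        assert set(kept) == positions


def test_cysteine_subgroup_calls_match_templates(small_repertoire):
    """Planted threeC templates carry MAYDRY, oneC templates MAYERY."""
    truth = small_repertoire.truth
    complete = truth[truth.status == "complete"]
    n_checked = 0
    for _, row in complete.iterrows():
        topo = predict_topology(row.protein)
        call = cysteine_subgroup(row.gene_id, row.protein, topo)
        assert call is not None
        assert call.subgroup in ("oneC", "threeC")
        n_checked += 1
        if call.subgroup == "oneC":
            assert call.ec2_cysteine_count == 1
            assert call.maydry_variant == "E"
        else:
            assert call.ec2_cysteine_count == 3
            assert call.maydry_variant == "D"
    assert n_checked >= 5


def test_unresolved_topology_gives_no_subgroup_call():
    from orfish.features import TopologyMap

    call = cysteine_subgroup("x", "M" + "A" * 250, TopologyMap(251, [], False, []))
    assert call is None


def test_column_information_extremes():
    assert column_information(["A"] * 20) == pytest.approx(
        math.log2(20) - 19 / (2 * math.log(2) * 20), abs=1e-9
    )
    uniform = list("ACDEFGHIKLMNPQRSTVWY")
    assert column_information(uniform) == 0.0  # max entropy, clamped
    assert column_information(["-"] * 5) == 0.0


def test_conserved_motif_extraction_recovers_planted_block(small_repertoire):
    truth = small_repertoire.truth
    proteins = {
        row.gene_id: row.protein
        for _, row in truth.iterrows()
        if row.status == "complete"
    }
    assert len(proteins) >= 10
    msa = star_msa(proteins)
    topologies = {
        gid: predict_topology(p) for gid, p in proteins.items()
    }
    motifs = extract_conserved_motifs(msa, k=4, topologies=topologies)
    assert len(motifs) == 4
    # deterministic, sorted by score, mutually non-overlapping
    scores = [m.score for m in motifs]
    assert scores == sorted(scores, reverse=True)
    spans = sorted((m.start, m.start + m.width) for m in motifs)
    for (_, e1), (s2, _) in zip(spans, spans[1:]):
        assert e1 <= s2
    # the MAYDRY/MAYERY block is the strongest planted signal; it sits at
    # the TM3/IN2 boundary (the predicted helix can absorb its first half)
    top = motifs[0]
    assert "Y" in top.consensus and (
        "DRY" in top.consensus or "ERY" in top.consensus
    )
    assert top.location in ("TM3", "IN2")


def test_motif_extraction_preconditions(small_repertoire):
    import pandas as pd

    tiny = pd.DataFrame([list("MAYDRY")] * 5)
    with pytest.raises(ValueError):
        extract_conserved_motifs(tiny, k=1)
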