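"""Translated homology search: frames, scores, e-values, retention rules."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from orfish.codons import translate_codon
from orfish.mining import (
    BaitSet,
    Contig,
    EvalueParams,
    bit_score,
    evalue,
    local_align,
    mine,
    six_frame_translate,
)

AAS = "ACDEFGHIKLMNPQRSTVWY"


def _rc(seq: str) -> str:
    return seq.translate(str.maketrans("ACGT", "TGCA"))[::-1]


def test_six_frames_match_codon_lookup_oracle():
    rng = np.random.default_rng(1)
    seq = "".join(rng.choice(list("ACGT"), size=300))
    frames = six_frame_translate(seq)
    assert len(frames) == 6
    for f in range(6):
        template = seq if f < 3 else _rc(seq)
        off = f % 3
        expected = "".join(
            translate_codon(template[i : i + 3])
            for i in range(off, len(template) - 2, 3)
        )
        assert frames[f] == expected


def test_six_frames_handle_n_and_reject_bad_chars():
    frames = six_frame_translate("ATGNNNTAA")
    assert frames[0] == "MX*"
    assert six_frame_translate("") == [""] * 6
    with pytest.raises(ValueError):
        six_frame_translate("ATGQ")


def test_evalue_closed_form_and_threshold_flip():
    params = EvalueParams(lambda_=0.267, K=0.041, m=1000, n=1000)
    assert evalue(0.0, params) == pytest.approx(41000.0)
    # solve for the score where E crosses 1e-50
    s_star = math.log(params.K * params.m * params.n / 1e-50) / params.lambda_
    assert evalue(s_star, params) == pytest.approx(1e-50, rel=1e-9)
    assert evalue(s_star + 1e-3, params) < 1e-50 < evalue(s_star - 1e-3, params)
    assert bit_score(s_star, params) > 0


@settings(derandomize=True, max_examples=30)
@given(
    s=st.floats(min_value=0, max_value=500),
    delta=st.floats(min_value=1e-3, max_value=100),
)
def test_evalue_strictly_decreasing_in_score(s, delta):
    params = EvalueParams(m=300, n=10000)
    assert evalue(s + delta, params) < evalue(s, params)


def test_local_align_exact_match_scores_diagonal_sum():
    from Bio.Align import substitution_matrices

    blosum = substitution_matrices.load("BLOSUM62")
    aln = local_align("MAYDRY", "MAYDRY")
    assert aln.score == sum(blosum[c][c] for c in "MAYDRY")
    assert aln.query_interval == (0, 6)


def test_local_align_self_is_optimal():
    rng = np.random.default_rng(2)
    query = "".join(rng.choice(list(AAS), size=40))
    other = "".join(rng.choice(list(AAS), size=40))
    assert local_align(query, query).score >= local_align(query, other).score


def _embed(orf_protein: str, flank: int, rng) -> str:
    from orfish.simulate import _AA_TO_CODONS

    cds = "".join(
        _AA_TO_CODONS[aa][rng.integers(len(_AA_TO_CODONS[aa]))]
        for aa in orf_protein
    )
    pad = lambda n: "".join(rng.choice(list("ACGT"), size=n))
    return pad(flank) + cds + "TAA" + pad(flank)


def test_retention_rules_positive_and_negative():
    rng = np.random.default_rng(4)
    target = "M" + "".join(rng.choice(list(AAS), size=299))
    unrelated = "M" + "".join(rng.choice(list(AAS), size=299))
    contig = Contig("c1", _embed(target, 400, rng), "Bri")
    contigs = {"c1": contig}
    # rule 1: a positive match alone retains the locus
    baits = BaitSet(positive={"p": target}, negative={"n": unrelated})
    loci, hits = mine(contigs, baits)
    assert len(loci) == 1
    assert loci[0].best_bait == "p"
    # rule 2: an overlapping negative match at the cutoff discards it
    baits2 = BaitSet(positive={"p": target}, negative={"n": target})
    loci2, _ = mine(contigs, baits2)
    assert loci2 == []


def test_mining_is_strand_symmetric():
    rng = np.random.default_rng(5)
    target = "M" + "".join(rng.choice(list(AAS), size=299))
    decoy = "M" + "".join(rng.choice(list(AAS), size=299))
    seq = _embed(target, 300, rng)
    baits = BaitSet(positive={"p": target}, negative={"n": decoy})
    fwd, _ = mine({"c": Contig("c", seq, "Bri")}, baits)
    rev, _ = mine({"c": Contig("c", _rc(seq), "Bri")}, baits)
    assert len(fwd) == len(rev) == 1
    assert fwd[0].strand != rev[0].strand
    assert rev[0].start == len(seq) - fwd[0].end
    assert rev[0].end == len(seq) - fwd[0].start


def test_empty_bait_set_rejected():
    with pytest.raises(ValueError):
        BaitSet(positive={}, negative={"n": "MAY"})
    with pytest.raises(ValueError):
        BaitSet(positive={"x": "MAY"}, negative={"x": "MAY"})


def test_decoys_rejected_and_planted_genes_found(default_pipeline):
    """On the default synthetic genome every decoy locus is discarded and
    every planted complete OR yields a retained locus."""
    rep = default_pipeline.repertoire
    loci = default_pipeline.loci
    for _, row in rep.truth.iterrows():
        starts = [int(x) for x in row.exon_starts.split(",")]
        ends = [int(x) for x in row.exon_ends.split(",")]
        overlapping = [
            l
            for l in loci
            if l.contig_id == row.contig_id
            and l.start < ends[-1]
            and starts[0] < l.end
        ]
        if row.status == "decoy":
            assert not overlapping, f"decoy {row.gene_id} was retained"
        elif row.status == "complete":
            assert overlapping, f"complete gene {row.gene_id} missed"
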