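"""Gene-model reconstruction: ORFs, splicing, status calls, reports."""

import numpy as np
import pytest

from orfish.genemodels import (
    AnnotationParams,
    IntronRecord,
    classify_edge_or_fragment,
    intron_report,
    models_to_status_table,
    pwm_consensus,
    splice_pwm_train,
    write_gff3,
)


def _truth_introns(row):
    starts = [int(x) for x in row.exon_starts.split(",")]
    ends = [int(x) for x in row.exon_ends.split(",")]
    return [(e, s) for e, s in zip(ends, starts[1:])]


@pytest.fixture(scope="module")
def annotated(small_pipeline):
    rep = small_pipeline.repertoire
    return rep, small_pipeline.models


def _match(models, row):
    starts = [int(x) for x in row.exon_starts.split(",")]
    ends = [int(x) for x in row.exon_ends.split(",")]
    hits = [
        m
        for m in models
        if m.contig_id == row.contig_id
        and m.exons[0][0] < ends[-1]
        and starts[0] < m.exons[-1][1]
    ]
    return max(hits, key=lambda m: m.bait_score) if hits else None


def test_complete_single_exon_models_match_truth(annotated):
    rep, models = annotated
    truth = rep.truth
    singles = truth[(truth.status == "complete") & (truth.phases == ".")]
    for _, row in singles.iterrows():
        m = _match(models, row)
        assert m is not None and m.status == "complete"
        assert m.strand == row.strand
        assert m.exons == [
            (int(row.exon_starts), int(row.exon_ends))
        ], row.gene_id


def test_pseudogene_lesions_recovered_near_planted_site(annotated):
    rep, models = annotated
    truth = rep.truth
    pseudo = truth[truth.status == "pseudogene"]
    for _, row in pseudo.iterrows():
        m = _match(models, row)
        assert m is not None and m.status == "pseudogene", row.gene_id
        kind, codon = row.lesion.split(":")
        got_kind, got_codon = m.lesions[0]
        assert got_kind == kind
        if kind == "frameshift":
            assert abs(got_codon - int(codon)) <= 3


def test_edge_and_fragment_status(annotated):
    rep, models = annotated
    truth = rep.truth
    for _, row in truth.iterrows():
        if row.status not in ("edge", "fragment"):
            continue
        m = _match(models, row)
        assert m is not None and m.status == row.status, row.gene_id


def test_spliced_models_recover_planted_introns_exactly(annotated):
    rep, models = annotated
    truth = rep.truth
    multi = truth[truth.phases != "."]
    assert len(multi) > 0
    for _, row in multi.iterrows():
        m = _match(models, row)
        assert m is not None and m.status == "complete", row.gene_id
        got = sorted((it.start, it.end) for it in m.introns)
        assert got == _truth_introns(row), row.gene_id
        # phases recomputed from exon lengths agree with the records
        introns = (
            m.introns if row.strand == "+" else list(m.introns)
        )
        upstream = 0
        exon_lengths = [b - a for a, b in m.exons]
        if row.strand == "-":
            exon_lengths = exon_lengths[::-1]
        for length, record in zip(exon_lengths, introns):
            upstream += length
            assert record.phase == upstream % 3
            assert record.donor == "GT" and record.acceptor == "AG"


def test_complete_models_translate_without_internal_stops(annotated):
    _, models = annotated
    assert any(m.status == "complete" for m in models)
    for m in models:
        m.validate()
        if m.status == "complete":
            assert "*" not in m.protein
            assert m.protein.startswith("M")


def test_classify_edge_or_fragment_boundary_logic():
    # ORF running off the 3' contig end on the plus strand
    assert (
        classify_edge_or_fragment(
            missing_5p=False,
            missing_3p=True,
            gene_start_fwd=5000,
            gene_end_fwd=5998,
            strand="+",
            contig_len=6000,
        )
        == "edge"
    )
    # internal partial copy with intact flanks
    assert (
        classify_edge_or_fragment(
            missing_5p=True,
            missing_3p=True,
            gene_start_fwd=2000,
            gene_end_fwd=2500,
            strand="+",
            contig_len=6000,
        )
        == "fragment"
    )
    # minus strand: the gene's 5' end maps to the interval end
    assert (
        classify_edge_or_fragment(
            missing_5p=True,
            missing_3p=False,
            gene_start_fwd=4000,
            gene_end_fwd=5995,
            strand="-",
            contig_len=6000,
        )
        == "edge"
    )


def _intron(donor_window="CAGGTAAGT", acceptor_window="TTTTTTTTTTTCAGG"):
    return IntronRecord(
        start=0,
        end=100,
        phase=0,
        donor="GT",
        acceptor="AG",
        last_codon_context="CAA.CAG",
        codon_position=50,
        donor_window=donor_window,
        acceptor_window=acceptor_window,
    )


def test_splice_pwm_training():
    with pytest.raises(ValueError):
        splice_pwm_train([_intron()] * 4)
    donor, acceptor = splice_pwm_train([_intron()] * 8)
    assert donor.shape == (4, 9)
    assert acceptor.shape == (4, 15)
    assert np.allclose(donor.sum(axis=0), 1.0, atol=1e-9)
    assert np.allclose(acceptor.sum(axis=0), 1.0, atol=1e-9)
    # identical training junctions: near-point-mass columns, GT/AG consensus
    assert pwm_consensus(donor)[3:5] == "GT"
    assert pwm_consensus(acceptor)[12:14] == "AG"
    assert donor.to_numpy().max() == pytest.approx(9 / 12)


def test_gff3_phase_column(annotated, tmp_path):
    _, models = annotated
    path = tmp_path / "models.gff3"
    write_gff3(models, path)
    lines = path.read_text().splitlines()
    assert lines[0] == "##gff-version 3"
    by_mrna = {}
    for line in lines[1:]:
        cols = line.split("\t")
        if cols[2] == "CDS":
            by_mrna.setdefault(cols[8], []).append(cols)
    for cds_rows in by_mrna.values():
        coding = 0
        for cols in cds_rows:
            assert int(cols[7]) == (3 - coding % 3) % 3
            coding += int(cols[4]) - int(cols[3]) + 1


def test_status_table_and_intron_report_shapes(annotated):
    _, models = annotated
    table = models_to_status_table(models)
    assert len(table) == len(models)
    assert set(table.status) <= {"complete", "pseudogene", "edge", "fragment"}
    report = intron_report(models)
    assert len(report) == sum(len(m.introns) for m in models)
    if len(report):
        assert set(report.intron_phase) <= {0, 1, 2}
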