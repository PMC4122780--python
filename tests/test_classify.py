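"""Identity, family/subfamily assignment, near-identical groups, NJ, names."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from orfish.classify import (
    assign_families,
    canonical_name,
    find_near_identical,
    global_identity,
    identity_matrix,
    nj_tree,
    parse_name,
)

AAS = "ACDEFGHIKLMNPQRSTVWY"


def _matrix(ids, entries):
    m = pd.DataFrame(100.0, index=ids, columns=ids)
    for a, b, v in entries:
        m.at[a, b] = m.at[b, a] = v
    for a in ids:
        for b in ids:
            if a != b and m.at[a, b] == 100.0:
                m.at[a, b] = m.at[b, a] = 0.0
    for a in ids:
        m.at[a, a] = 100.0
    return m


def test_identity_examples():
    assert global_identity("MAYDRY", "MAYDRY") == 100.0
    assert global_identity("AAAA", "AAAT") == 75.0


@settings(derandomize=True, max_examples=25)
@given(
    a=st.text(alphabet=AAS, min_size=5, max_size=40),
    b=st.text(alphabet=AAS, min_size=5, max_size=40),
)
def test_identity_symmetric_and_bounded(a, b):
    ab = global_identity(a, b)
    assert ab == pytest.approx(global_identity(b, a), abs=1e-9)
    assert 0.0 <= ab <= 100.0


def test_identity_matrix_is_symmetric_with_unit_diagonal():
    rng = np.random.default_rng(0)
    prots = {
        f"g{i}": "".join(rng.choice(list(AAS), size=30)) for i in range(5)
    }
    m = identity_matrix(prots)
    assert np.allclose(m.to_numpy(), m.to_numpy().T, atol=1e-9)
    assert np.allclose(np.diag(m.to_numpy()), 100.0)


def test_family_threshold_semantics():
    m = _matrix(["a", "b"], [("a", "b", 65.0)])
    fams = assign_families(m)
    assert fams.family_of["a"] == fams.family_of["b"]
    assert fams.subfamily_of["a"] == fams.subfamily_of["b"]

    m2 = _matrix(["a", "b"], [("a", "b", 45.0)])
    fams2 = assign_families(m2)
    assert fams2.family_of["a"] == fams2.family_of["b"]
    assert fams2.subfamily_of["a"] != fams2.subfamily_of["b"]

    # single linkage chains 41/41/20 into one family
    m3 = _matrix(
        ["a", "b", "c"], [("a", "b", 41.0), ("b", "c", 41.0), ("a", "c", 20.0)]
    )
    fams3 = assign_families(m3)
    assert len(set(fams3.family_of.values())) == 1


def test_family_labels_invariant_under_permutation():
    rng = np.random.default_rng(1)
    ids = [f"g{i}" for i in range(8)]
    vals = rng.uniform(0, 100, size=(8, 8))
    vals = (vals + vals.T) / 2
    np.fill_diagonal(vals, 100.0)
    m = pd.DataFrame(vals, index=ids, columns=ids)
    ref = assign_families(m)
    perm = list(rng.permutation(ids))
    shuffled = m.loc[perm, perm]
    got = assign_families(shuffled)
    assert got.family_of == ref.family_of
    assert got.subfamily_of == ref.subfamily_of


def test_raising_subfamily_threshold_never_merges():
    rng = np.random.default_rng(2)
    ids = [f"g{i}" for i in range(7)]
    vals = rng.uniform(30, 100, size=(7, 7))
    vals = (vals + vals.T) / 2
    np.fill_diagonal(vals, 100.0)
    m = pd.DataFrame(vals, index=ids, columns=ids)
    low = assign_families(m, subfamily_threshold=55.0)
    high = assign_families(m, subfamily_threshold=70.0)
    # partition at the higher threshold refines the lower one
    for a in ids:
        for b in ids:
            same_high = (
                high.family_of[a] == high.family_of[b]
                and high.subfamily_of[a] == high.subfamily_of[b]
            )
            same_low = (
                low.family_of[a] == low.family_of[b]
                and low.subfamily_of[a] == low.subfamily_of[b]
            )
            if same_high:
                assert same_low


def test_near_identical_maximal_cliques():
    ids = ["a", "b", "c", "d", "e"]
    entries = [(x, y, 99.5) for x in "abcd" for y in "abcd" if x < y]
    m = _matrix(ids, entries)
    species = dict.fromkeys(ids, "Bri")
    groups = find_near_identical(m, species)
    assert len(groups) == 1
    assert groups[0].kind == "quadruplet"
    assert groups[0].members == ("a", "b", "c", "d")
    # strict threshold: 98.9 does not group
    m2 = _matrix(["a", "b"], [("a", "b", 98.9)])
    assert find_near_identical(m2, {"a": "x", "b": "y"}) == []


def test_planted_near_duplicates_detected(small_pipeline):
    groups = small_pipeline.near_groups
    truth = small_pipeline.repertoire.truth
    planted = truth[truth.near_group != "."]
    # every planted near-duplicate pair whose realized identity stayed at
    # or above the threshold must appear together in some group
    idents = small_pipeline.identity
    models = small_pipeline.models
    by_truth = {}
    for _, row in planted.iterrows():
        for m in models:
            if (
                m.contig_id == row.contig_id
                and m.exons[0][0] < int(row.exon_ends.split(",")[-1])
                and int(row.exon_starts.split(",")[0]) < m.exons[-1][1]
            ):
                by_truth.setdefault(row.near_group, []).append(m.gene_id)
    for grp_ids in by_truth.values():
        for i, a in enumerate(grp_ids):
            for b in grp_ids[i + 1 :]:
                if idents.at[a, b] >= 99.0:
                    assert any(
                        a in g.members and b in g.members for g in groups
                    )


def test_nj_three_taxa_closed_form():
    ids = ["a", "b", "c"]
    m = _matrix(
        ids, [("a", "b", 90.0), ("a", "c", 80.0), ("b", "c", 86.0)]
    )
    newick = nj_tree(m)
    import io

    from Bio import Phylo

    tree = Phylo.read(io.StringIO(newick), "newick")
    lengths = {t.name: t.branch_length for t in tree.get_terminals()}
    # three-point formulas: la = (dab + dac - dbc)/2 etc., on d = 1 - id/100
    dab, dac, dbc = 0.10, 0.20, 0.14
    assert lengths["a"] == pytest.approx((dab + dac - dbc) / 2, abs=1e-9)
    assert lengths["b"] == pytest.approx((dab + dbc - dac) / 2, abs=1e-9)
    assert lengths["c"] == pytest.approx((dac + dbc - dab) / 2, abs=1e-9)


def test_nj_recovers_additive_four_taxon_tree():
    ids = list("abcd")
    dist = np.array(
        [[0, 3, 8, 9], [3, 0, 9, 10], [8, 9, 0, 5], [9, 10, 5, 0]], float
    )
    m = pd.DataFrame(100.0 - dist, index=ids, columns=ids)
    newick = nj_tree(m)
    import io

    from Bio import Phylo

    tree = Phylo.read(io.StringIO(newick), "newick")
    assert {t.name for t in tree.get_terminals()} == set(ids)
    # path distances reproduce the additive matrix exactly (scaled by 1/100)
    for i, a in enumerate(ids):
        for b in ids[i + 1 :]:
            got = tree.distance(a, b)
            assert got == pytest.approx(dist[i][ids.index(b)] / 100, abs=1e-9)
    with pytest.raises(ValueError):
        nj_tree(m.iloc[:2, :2])


def test_canonical_names_and_roundtrip():
    assert canonical_name("Bri", "edge", "E", 41) == "BRIORe.E041"
    assert canonical_name("Til", "complete", "W", 238) == "TILOR.W238"
    assert parse_name("BRIORe.E041") == ("BRI", "edge", "E", 41)
    assert parse_name("TILOR.W238") == ("TIL", "complete", "W", 238)
    with pytest.raises(ValueError):
        canonical_name("Bri", "complete", "E", 1000)
    with pytest.raises(ValueError):
        parse_name("nonsense")
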