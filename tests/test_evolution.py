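"""Unit and oracle tests for the modified Nei-Gojobori dN/dS estimator."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from orfish.codons import (
    CODON_TO_AA,
    NUCLEOTIDES,
    SENSE_CODONS,
    is_stop,
    is_transition,
)
from orfish.evolution import (
    SaturationError,
    codon_site_counts,
    dnds_pair,
    family_dnds_summary,
    jukes_cantor,
    pairwise_differences,
)


def site_counts_oracle(codon: str, kappa: float) -> tuple[float, float]:
    """Brute-force 9-mutant scan, independent of the implementation."""
    s = 0.0
    for pos in range(3):
        syn_w = tot_w = 0.0
        for nt in NUCLEOTIDES:
            if nt == codon[pos]:
                continue
            mutant = codon[:pos] + nt + codon[pos + 1 :]
            if is_stop(mutant):
                continue
            w = kappa if is_transition(codon[pos], nt) else 1.0
            tot_w += w
            if CODON_TO_AA[mutant] == CODON_TO_AA[codon]:
                syn_w += w
        if tot_w:
            s += syn_w / tot_w
    return s, 3.0 - s


def pathway_oracle(a: str, b: str):
    """Exhaustive pathway enumeration with stop exclusion."""
    diff = [i for i in range(3) if a[i] != b[i]]
    results = []
    for order in itertools.permutations(diff):
        cur, syn, non, ok = a, 0, 0, True
        for pos in order:
            nxt = cur[:pos] + b[pos] + cur[pos + 1 :]
            if is_stop(nxt):
                ok = False
                break
            if CODON_TO_AA[nxt] == CODON_TO_AA[cur]:
                syn += 1
            else:
                non += 1
            cur = nxt
        if ok:
            results.append((syn, non))
    if not results:
        return None
    return (
        sum(r[0] for r in results) / len(results),
        sum(r[1] for r in results) / len(results),
    )


@pytest.mark.parametrize("kappa", [1.0, 2.0, 5.0])
def test_site_counts_match_brute_force_all_codons(kappa):
    for codon in SENSE_CODONS:
        s, n = codon_site_counts(codon, kappa)
        s_ref, n_ref = site_counts_oracle(codon, kappa)
        assert s == pytest.approx(s_ref, abs=1e-12)
        assert n == pytest.approx(n_ref, abs=1e-12)
        assert s + n == pytest.approx(3.0, abs=1e-9)


def test_site_counts_examples():
    # Phe TTT: only the third-position transition T->C is synonymous
    s, n = codon_site_counts("TTT", 1.0)
    assert s == pytest.approx(1 / 3)
    assert n == pytest.approx(8 / 3)
    # fourfold-degenerate third position contributes one full syn site
    for codon in ("GGA", "GGC", "GGG", "GGT"):
        s, _ = codon_site_counts(codon, 1.0)
        assert s >= 1.0 - 1e-9
    # kappa -> infinity: TTT's synonymous change is a transition
    s_inf, _ = codon_site_counts("TTT", 1e9)
    assert s_inf == pytest.approx(1.0, abs=1e-6)


def test_site_counts_rejects_stop_codons():
    with pytest.raises(ValueError):
        codon_site_counts("TAA", 1.0)


def test_pairwise_differences_match_enumeration_oracle():
    rng = np.random.default_rng(0)
    codons = list(SENSE_CODONS)
    for _ in range(1000):
        a, b = rng.choice(codons, size=2)
        ref = pathway_oracle(a, b)
        got = pairwise_differences(a, b)
        if ref is None:
            assert got.blocked
        else:
            assert not got.blocked
            assert got.sd == pytest.approx(ref[0])
            assert got.nd == pytest.approx(ref[1])
            k = sum(x != y for x, y in zip(a, b))
            assert got.sd + got.nd == pytest.approx(k)


def test_pairwise_differences_examples():
    assert pairwise_differences("TTT", "TTC").sd == 1.0  # Phe->Phe
    assert pairwise_differences("TTT", "TTC").nd == 0.0
    d = pairwise_differences("TTT", "CTC")  # both orderings: 1 syn + 1 non
    assert (d.sd, d.nd) == (1.0, 1.0)
    assert pairwise_differences("ATG", "ATG") == pairwise_differences(
        "ATG", "ATG"
    )
    assert pairwise_differences("AAA", "AAA").sd == 0.0


def test_jukes_cantor_values_and_domain():
    assert jukes_cantor(0.0) == 0.0
    assert jukes_cantor(3 / 16) == pytest.approx(-0.75 * math.log(0.75))
    with pytest.raises(SaturationError):
        jukes_cantor(0.75)
    with pytest.raises(ValueError):
        jukes_cantor(-0.01)


@settings(derandomize=True, max_examples=50)
@given(
    p=st.floats(min_value=1e-6, max_value=0.74),
    q=st.floats(min_value=1e-6, max_value=0.74),
)
def test_jukes_cantor_increasing_and_expanding(p, q):
    if p < q:
        assert jukes_cantor(p) < jukes_cantor(q)
    assert jukes_cantor(p) >= p


def test_dnds_identical_pair_is_undefined():
    cds = "ATGGCTGCTAAGGCTTTG" * 20
    r = dnds_pair(cds, cds)
    assert r.sentinel == "undefined"
    assert r.omega is None
    assert r.sd == 0 and r.nd == 0


def test_dnds_single_synonymous_change_gives_omega_zero():
    base = ["TTT"] * 100
    other = list(base)
    other[50] = "TTC"  # one synonymous difference
    r = dnds_pair("".join(base), "".join(other))
    assert r.nd == 0.0
    assert r.sd == 1.0
    assert r.omega == 0.0
    assert r.sentinel == "none"


def test_dnds_ds_zero_sentinel_displayed_as_gt10():
    base = ["TTT"] * 100
    other = list(base)
    other[50] = "GTT"  # one nonsynonymous difference, no synonymous ones
    r = dnds_pair("".join(base), "".join(other))
    assert r.sentinel == "ds_zero"
    assert r.omega_display == ">10"


def test_dnds_too_short_pair_raises():
    with pytest.raises(ValueError):
        dnds_pair("ATGGCT", "ATGGCA")


def test_dnds_site_count_invariant():
    rng = np.random.default_rng(3)
    codons = [c for c in SENSE_CODONS]
    a = "".join(rng.choice(codons, size=60))
    b = "".join(rng.choice(codons, size=60))
    try:
        r = dnds_pair(a, b)
    except ValueError:
        return  # saturated random pair: nothing to assert
    assert r.s_sites + r.n_sites == pytest.approx(3 * r.n_codons, abs=1e-6)


def test_regional_counts_sum_to_whole(small_repertoire):
    from orfish.features import predict_topology

    truth = small_repertoire.truth
    complete = truth[truth.status == "complete"]
    fam = complete.family_seed.value_counts().idxmax()
    rows = complete[complete.family_seed == fam].head(2)
    assert len(rows) == 2

    def cds_of(row):
        starts = [int(x) for x in row.exon_starts.split(",")]
        ends = [int(x) for x in row.exon_ends.split(",")]
        seq = small_repertoire.contigs[row.contig_id].seq
        cds = "".join(seq[a:b] for a, b in zip(starts, ends))
        if row.strand == "-":
            cds = cds.translate(str.maketrans("ACGT", "TGCA"))[::-1]
        return cds

    r1, r2 = rows.iloc[0], rows.iloc[1]
    topo = predict_topology(r1.protein)
    assert topo.resolved
    whole, regions = dnds_pair(
        cds_of(r1), cds_of(r2), topology=topo
    )
    assert sum(r.result.sd for r in regions) == pytest.approx(whole.sd)
    assert sum(r.result.nd for r in regions) == pytest.approx(whole.nd)
    assert sum(r.result.n_codons for r in regions) == whole.n_codons


def test_family_summary_degenerate_and_counts():
    cds = "ATGGCTAAGTTGGCTTCA" * 20
    genes = {f"g{i}": cds for i in range(4)}
    species = {f"g{i}": "Bri" for i in range(4)}
    s = family_dnds_summary("A", genes, species)
    assert s.n_pairs == 6  # 4*3/2
    assert s.n_included == 0
    assert s.n_undefined == 6
    assert s.mean is None
    with pytest.raises(ValueError):
        family_dnds_summary("B", dict(list(genes.items())[:3]), species)
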