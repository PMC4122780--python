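"""Pairwise dN/dS by the Nei-Gojobori method with Zhang's modification.

The estimator counts synonymous (S) and nonsynonymous (N) *sites* per codon
with transition/transversion weighting (Zhang et al.'s refinement of the
classical equal-weight count): each codon position contributes one site,
apportioned between S and N according to the kappa-weighted fraction of its
possible single-nucleotide changes that are synonymous.  Changes that would
create a stop codon are excluded and the remaining weights renormalised, so
every sense codon contributes exactly three sites.

Differences between two codons are counted by pathway averaging: for codons
differing at k positions, all k! orderings of the single changes are
enumerated, orderings passing through a stop codon are discarded, and the
synonymous/nonsynonymous step counts are averaged over the survivors.

Proportions pS = Sd/S and pN = Nd/N are corrected for multiple hits with the
Jukes-Cantor formula d = -(3/4)ln(1 - 4p/3), and omega = dN/dS.  Pairs with
dS = 0 but dN > 0 are reported with a ``ds_zero`` sentinel (conventionally
displayed as ">10"); identical pairs carry the ``undefined`` sentinel.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Mapping, Sequence

import numpy as np

from .codons import (
    CODON_TO_AA,
    STOP_CODONS,
    codons_of,
    is_stop,
    is_transition,
    single_mutants,
    translate_codon,
)

DISPLAY_DS_ZERO = ">10"


class SaturationError(ValueError):
    """Raised when a difference proportion exceeds the Jukes-Cantor domain."""


@lru_cache(maxsize=None)
def codon_site_counts(codon: str, kappa: float = 2.0) -> tuple[float, float]:
    """Synonymous/nonsynonymous site counts for one sense codon.

    Each of the three positions contributes exactly one site, split between
    S and N by the kappa-weighted share of its non-stop single-nucleotide
    changes that are synonymous.  ``kappa`` is the transition/transversion
    rate ratio; ``kappa=1`` recovers the classical Nei-Gojobori count.

    Returns ``(s_sites, n_sites)`` with ``s_sites + n_sites == 3``.
    """
    codon = codon.upper()
    if is_stop(codon):
        raise ValueError(f"stop codon {codon!r} has no site counts")
    if codon not in CODON_TO_AA:
        raise ValueError(f"not a sense codon: {codon!r}")
    if kappa <= 0:
        raise ValueError("kappa must be positive")
    aa = CODON_TO_AA[codon]
    s_total = 0.0
    for pos in range(3):
        syn_w = 0.0
        tot_w = 0.0
        for nt, mutant in single_mutants(codon, pos):
            if is_stop(mutant):
                continue
            w = kappa if is_transition(codon[pos], nt) else 1.0
            tot_w += w
            if CODON_TO_AA[mutant] == aa:
                syn_w += w
        if tot_w > 0:
            s_total += syn_w / tot_w
    return s_total, 3.0 - s_total


@dataclass(frozen=True)
class DifferenceCount:
    sd: float
    nd: float
    #: True when every mutational pathway crossed a stop codon and the
    #: per-position direct count was used instead.
    blocked: bool = False


@lru_cache(maxsize=None)
def pairwise_differences(codon_a: str, codon_b: str) -> DifferenceCount:
    """Synonymous/nonsynonymous difference counts between two sense codons.

    Averages over all orderings of the single-nucleotide changes separating
    the codons, excluding orderings that pass through a stop codon.  When
    every ordering is blocked the changes are classified one at a time
    against ``codon_a`` (direct-count fallback) and the result is flagged.
    """
    a, b = codon_a.upper(), codon_b.upper()
    for c in (a, b):
        if c in STOP_CODONS or c not in CODON_TO_AA:
            raise ValueError(f"not a sense codon: {c!r}")
    diff_pos = [i for i in range(3) if a[i] != b[i]]
    if not diff_pos:
        return DifferenceCount(0.0, 0.0)
    syn_counts: list[int] = []
    non_counts: list[int] = []
    for order in itertools.permutations(diff_pos):
        current = a
        syn = non = 0
        ok = True
        for pos in order:
            nxt = current[:pos] + b[pos] + current[pos + 1 :]
            if is_stop(nxt):
                ok = False
                break
            if CODON_TO_AA[nxt] == CODON_TO_AA[current]:
                syn += 1
            else:
                non += 1
            current = nxt
        if ok:
            syn_counts.append(syn)
            non_counts.append(non)
    if syn_counts:
        return DifferenceCount(
            float(np.mean(syn_counts)), float(np.mean(non_counts))
        )
    # all pathways blocked: classify each change in isolation
    syn = non = 0
    for pos in diff_pos:
        mutant = a[:pos] + b[pos] + a[pos + 1 :]
        if not is_stop(mutant) and CODON_TO_AA[mutant] == CODON_TO_AA[a]:
            syn += 1
        else:
            non += 1
    return DifferenceCount(float(syn), float(non), blocked=True)


def jukes_cantor(p: float) -> float:
    """Jukes-Cantor multiple-hit correction d = -(3/4) ln(1 - 4p/3)."""
    if p < 0:
        raise ValueError("negative difference proportion")
    if p >= 0.75:
        raise SaturationError(f"p = {p:.4f} is beyond the correctable range")
    if p == 0.0:
        return 0.0
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0)


@dataclass
class DnDsResult:
    """Whole-alignment dN/dS for one gene pair."""

    id_a: str
    id_b: str
    n_codons: int
    s_sites: float
    n_sites: float
    sd: float
    nd: float
    ps: float
    pn: float
    ds: float | None
    dn: float | None
    omega: float | None
    #: none | ds_zero | undefined | saturated
    sentinel: str = "none"

    @property
    def omega_display(self) -> str:
        if self.sentinel == "ds_zero":
            return DISPLAY_DS_ZERO
        if self.omega is None:
            return "NA"
        return f"{self.omega:.4f}"


@dataclass
class RegionDnDs:
    region: str
    result: DnDsResult


def _codon_alignment(
    cds_a: str, cds_b: str
) -> list[tuple[int, str, str]]:
    """Codon pairs compared between two CDSs, via protein global alignment.

    Returns ``(codon_index_in_a, codon_a, codon_b)`` for every alignment
    column where both proteins have a residue; codons opposite a gap are
    dropped from both site and difference counting.
    """
    from .classify import global_alignment  # local import: avoids a cycle

    ca = codons_of(cds_a.upper())
    cb = codons_of(cds_b.upper())
    # drop a terminal stop if present
    if ca and is_stop(ca[-1]):
        ca = ca[:-1]
    if cb and is_stop(cb[-1]):
        cb = cb[:-1]
    prot_a = "".join(translate_codon(c) for c in ca)
    prot_b = "".join(translate_codon(c) for c in cb)
    if "*" in prot_a or "*" in prot_b:
        raise ValueError("internal stop codon in CDS; not a coding pair")
    aln = global_alignment(prot_a, prot_b)
    pairs: list[tuple[int, str, str]] = []
    for (a0, a1), (b0, b1) in zip(*aln.aligned):
        for off in range(a1 - a0):
            pairs.append((a0 + off, ca[a0 + off], cb[b0 + off]))
    return pairs


def _counts_from_pairs(
    pairs: Sequence[tuple[str, str]], kappa: float
) -> tuple[float, float, float, float]:
    s_sites = n_sites = sd = nd = 0.0
    for codon_a, codon_b in pairs:
        sa, na = codon_site_counts(codon_a, kappa)
        sb, nb = codon_site_counts(codon_b, kappa)
        s_sites += 0.5 * (sa + sb)
        n_sites += 0.5 * (na + nb)
        diff = pairwise_differences(codon_a, codon_b)
        sd += diff.sd
        nd += diff.nd
    return s_sites, n_sites, sd, nd


def _finish(
    id_a: str,
    id_b: str,
    n_codons: int,
    s_sites: float,
    n_sites: float,
    sd: float,
    nd: float,
) -> DnDsResult:
    ps = sd / s_sites if s_sites > 0 else 0.0
    pn = nd / n_sites if n_sites > 0 else 0.0
    try:
        ds = jukes_cantor(ps)
        dn = jukes_cantor(pn)
    except SaturationError:
        return DnDsResult(
            id_a, id_b, n_codons, s_sites, n_sites, sd, nd, ps, pn,
            None, None, None, sentinel="saturated",
        )
    if ds == 0.0 and dn == 0.0:
        sentinel, omega = "undefined", None
    elif ds == 0.0:
        sentinel, omega = "ds_zero", None
    else:
        sentinel, omega = "none", dn / ds
    return DnDsResult(
        id_a, id_b, n_codons, s_sites, n_sites, sd, nd, ps, pn,
        ds, dn, omega, sentinel=sentinel,
    )


def dnds_pair(
    cds_a: str,
    cds_b: str,
    kappa: float = 2.0,
    id_a: str = "A",
    id_b: str = "B",
    topology=None,
    min_codons: int = 10,
) -> DnDsResult | tuple[DnDsResult, list[RegionDnDs]]:
    """Whole-protein dN/dS for a CDS pair; per-region when topology is given.

    ``topology`` is a :class:`~orfish.features.TopologyMap` for the protein
    of ``cds_a``; compared codons are then partitioned by the segment label
    of their position in protein A and a :class:`RegionDnDs` list is
    returned alongside the whole-protein result.
    """
    indexed = _codon_alignment(cds_a, cds_b)
    if len(indexed) < min_codons:
        raise ValueError(
            f"only {len(indexed)} comparable codons (< {min_codons})"
        )
    pairs = [(a, b) for _, a, b in indexed]
    result = _finish(id_a, id_b, len(pairs), *_counts_from_pairs(pairs, kappa))
    if topology is None:
        return result
    regions: list[RegionDnDs] = []
    for seg in topology.segments:
        seg_pairs = [
            (a, b) for i, a, b in indexed if seg.start <= i < seg.end
        ]
        if not seg_pairs:
            continue
        sub = _finish(
            id_a, id_b, len(seg_pairs), *_counts_from_pairs(seg_pairs, kappa)
        )
        regions.append(RegionDnDs(seg.label, sub))
    return result, regions


@dataclass
class FamilyDnDsSummary:
    """All-pairs dN/dS summary for one OR family (>= 4 genes)."""

    family: str
    n_genes: int
    n_pairs: int
    n_included: int
    n_ds_zero: int
    n_undefined: int
    n_saturated: int
    mean: float | None
    sd: float | None
    min: float | None
    max: float | None
    #: pairs with omega > 1 (ds_zero pairs, displayed ">10", are counted)
    n_above_one: int
    #: species -> (paralog mean, ortholog mean, ratio)
    paralog_ortholog: dict[str, tuple[float | None, float | None, float | None]] = field(
        default_factory=dict
    )
    pair_results: list[DnDsResult] = field(default_factory=list)


def family_dnds_summary(
    family: str,
    cds_by_gene: Mapping[str, str],
    species_by_gene: Mapping[str, str],
    kappa: float = 2.0,
) -> FamilyDnDsSummary:
    """All-pairs dN/dS within a family of four or more genes.

    Sentinel pairs (dS = 0, identical, saturated) are excluded from the
    mean/sd/min/max and tallied separately; ds_zero pairs count toward the
    omega > 1 tally.  Per-species paralog (within-species) and ortholog
    (that species vs all others) means are reported with their ratio.
    """
    genes = sorted(cds_by_gene)
    if len(genes) < 4:
        raise ValueError(
            f"family {family}: {len(genes)} genes (< 4), summary skipped"
        )
    results: list[DnDsResult] = []
    for i, ga in enumerate(genes):
        for gb in genes[i + 1 :]:
            results.append(
                dnds_pair(
                    cds_by_gene[ga], cds_by_gene[gb], kappa,
                    id_a=ga, id_b=gb,
                )
            )
    included = [r.omega for r in results if r.sentinel == "none"]
    n_ds_zero = sum(r.sentinel == "ds_zero" for r in results)
    n_undef = sum(r.sentinel == "undefined" for r in results)
    n_sat = sum(r.sentinel == "saturated" for r in results)
    above_one = sum(1 for w in included if w > 1.0) + n_ds_zero

    def _mean(vals):
        return float(np.mean(vals)) if vals else None

    paralog_ortholog = {}
    for sp in sorted(set(species_by_gene.values())):
        para = [
            r.omega
            for r in results
            if r.sentinel == "none"
            and species_by_gene[r.id_a] == sp
            and species_by_gene[r.id_b] == sp
        ]
        orth = [
            r.omega
            for r in results
            if r.sentinel == "none"
            and (species_by_gene[r.id_a] == sp) != (species_by_gene[r.id_b] == sp)
        ]
        pm, om = _mean(para), _mean(orth)
        ratio = pm / om if pm is not None and om else None
        paralog_ortholog[sp] = (pm, om, ratio)

    return FamilyDnDsSummary(
        family=family,
        n_genes=len(genes),
        n_pairs=len(results),
        n_included=len(included),
        n_ds_zero=n_ds_zero,
        n_undefined=n_undef,
        n_saturated=n_sat,
        mean=_mean(included),
        sd=float(np.std(included)) if included else None,
        min=float(np.min(included)) if included else None,
        max=float(np.max(included)) if included else None,
        n_above_one=above_one,
        paralog_ortholog=paralog_ortholog,
        pair_results=results,
    )
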