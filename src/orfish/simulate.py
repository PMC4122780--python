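"""Synthetic genome generator with ground truth for pipeline verification.

Real fish assemblies cannot serve as a test substrate because their OR
content is unknown; this module plants OR-like genes of every status class
the pipeline must recognise — complete single- and multi-exon genes,
frameshift and premature-stop pseudogenes, contig-edge truncations, internal
gene fragments — plus decoy non-OR GPCR genes, into random-background
contigs, and records every planted feature in a machine-readable truth
table.

OR templates are built on a fixed 7-TM architecture with the canonical
landmarks of fish ORs (an N-terminal N-X-S/T sequon, the MAYDRY/MAYERY
block at the TM3/IN2 boundary, one or three EC2 cysteines) so the feature
annotators have real signal; decoy templates are landmark-free proteins of
similar length and composition.  The positive bait set is the OR template
proteins and the negative bait set the decoy templates, mirroring the
literature-OR / non-OR-GPCR bait design of the survey this package
re-implements.

A small codon-pair simulator (:func:`simulate_codon_pair`) evolves a pair
of stop-free ORFs under a target dN/dS with transition/transversion bias,
for parameter-recovery testing of the estimator.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .codons import (
    CODON_TO_AA,
    NUCLEOTIDES,
    SENSE_CODONS,
    is_stop,
    is_transition,
    translate_codon,
)
from .mining import BaitSet, Contig


class ConfigurationError(ValueError):
    pass


DEFAULT_SPECIES = ("Bri", "Bur", "Nye", "Til", "Zeb")

#: 7-TM OR architecture: (segment label, length in residues).  Loops are kept
#: >= 13 residues so hydropathy smoothing separates adjacent helices; total
#: length 300 aa sits inside the plausible 250-400 aa range for a fish OR.
OR_ARCHITECTURE: tuple[tuple[str, int], ...] = (
    ("Nter", 22),
    ("TM1", 24),
    ("IN1", 14),
    ("TM2", 23),
    ("OUT1", 16),
    ("TM3", 24),
    ("IN2", 16),
    ("TM4", 22),
    ("OUT2", 18),
    ("TM5", 24),
    ("IN3", 14),
    ("TM6", 23),
    ("OUT3", 13),
    ("TM7", 23),
    ("Cter", 24),
)

_TM_POOL = "LIVFAM"  # strongly hydrophobic (Kyte-Doolittle > 1.8)
_LOOP_POOL = "DEKRNQSTGH"  # hydrophilic (Kyte-Doolittle < 0)


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic repertoire.

    The per-status counts are the planted gene inventory; the seed fully
    determines the output.  ``mutation_rate_per_site`` is the per-residue
    substitution probability applied to each gene relative to its family
    template (substitutions stay within the hydropathy class of the
    replaced residue so planted topology survives).
    """

    seed: int = 0
    n_contigs: int = 42
    contig_length_mean: int = 9000
    n_or_templates: int = 8
    complete_single_exon: int = 30
    complete_multi_exon: int = 8
    pseudogene_frameshift: int = 5
    pseudogene_stop: int = 5
    edge: int = 6
    fragment: int = 4
    decoy_gpcr: int = 6
    intron_length_range: tuple[int, int] = (80, 400)
    intron_phase_distribution: Mapping[int, float] = field(
        default_factory=lambda: {0: 0.75, 1: 0.05, 2: 0.20}
    )
    mutation_rate_per_site: float = 0.04
    omega_target: float = 0.4
    transition_transversion_ratio: float = 2.0
    species: tuple[str, ...] = DEFAULT_SPECIES
    near_identical_groups: int = 2
    near_identical_group_size: int = 3
    near_identical_divergence: float = 0.004

    def validate(self) -> None:
        counts = (
            self.n_contigs,
            self.n_or_templates,
            self.complete_single_exon,
            self.complete_multi_exon,
            self.pseudogene_frameshift,
            self.pseudogene_stop,
            self.edge,
            self.fragment,
            self.decoy_gpcr,
        )
        if any(c < 0 for c in counts):
            raise ConfigurationError("counts must be non-negative")
        total_p = sum(self.intron_phase_distribution.values())
        if abs(total_p - 1.0) > 1e-9:
            raise ConfigurationError(
                f"intron phase probabilities sum to {total_p}, expected 1"
            )
        if set(self.intron_phase_distribution) - {0, 1, 2}:
            raise ConfigurationError("intron phases must be in {0, 1, 2}")
        lo, hi = self.intron_length_range
        if not (10 <= lo <= hi):
            raise ConfigurationError("bad intron length range")
        if not 0 <= self.mutation_rate_per_site < 1:
            raise ConfigurationError("mutation rate must be in [0, 1)")
        if self.omega_target <= 0:
            raise ConfigurationError("omega_target must be positive")
        need = (
            self.near_identical_groups * self.near_identical_group_size
        )
        if need > self.complete_single_exon:
            raise ConfigurationError(
                "near-identical groups exceed the complete single-exon budget"
            )


TRUTH_COLUMNS = [
    "gene_id",
    "contig_id",
    "species",
    "strand",
    "status",
    "exon_starts",
    "exon_ends",
    "phases",
    "lesion",
    "family_seed",
    "near_group",
    "protein",
]


@dataclass
class SyntheticRepertoire:
    """Contigs, truth table and bait sets for one simulated genome."""

    contigs: dict[str, Contig]
    truth: pd.DataFrame
    baits: BaitSet
    config: SimulationConfig


# --- template construction -------------------------------------------------


def _segment_bounds() -> dict[str, tuple[int, int]]:
    bounds = {}
    pos = 0
    for label, length in OR_ARCHITECTURE:
        bounds[label] = (pos, pos + length)
        pos += length
    return bounds


SEGMENT_BOUNDS = _segment_bounds()
OR_LENGTH = sum(length for _, length in OR_ARCHITECTURE)


def _make_or_template(rng: np.random.Generator, subgroup: str) -> str:
    """One OR family template with planted landmarks.

    ``subgroup`` is ``threeC`` (classical MAYDRY, three EC2 cysteines) or
    ``oneC`` (MAYERY variant, single EC2 cysteine), the two subgroups seen
    in real fish repertoires.
    """
    residues: list[str] = []
    for label, length in OR_ARCHITECTURE:
        pool = _TM_POOL if label.startswith("TM") else _LOOP_POOL
        residues.extend(rng.choice(list(pool), size=length))
    # landmarks (0-based protein coordinates)
    residues[0] = "M"
    nter = SEGMENT_BOUNDS["Nter"]
    residues[3:6] = ["N", "A", "T"]  # N-terminal sequon N-X-T
    residues[10] = "C"  # conserved N-terminal cysteine
    out1 = SEGMENT_BOUNDS["OUT1"]
    residues[out1[0] + 6] = "C"  # EC1 cysteine
    in2 = SEGMENT_BOUNDS["IN2"]
    motif = "MAYDRY" if subgroup == "threeC" else "MAYERY"
    residues[in2[0] : in2[0] + 6] = list(motif)
    out2 = SEGMENT_BOUNDS["OUT2"]
    # clear any pool-sampled C from OUT2, then plant exactly one or three
    for i in range(*out2):
        if residues[i] == "C":
            residues[i] = "S"
    cys_pos = [out2[0] + 3] if subgroup == "oneC" else [
        out2[0] + 3,
        out2[0] + 9,
        out2[0] + 14,
    ]
    for i in cys_pos:
        residues[i] = "C"
    assert len(residues) == OR_LENGTH
    return "".join(residues)


_PROTECTED = set(range(3, 6)) | {0, 10}
_PROTECTED |= set(range(SEGMENT_BOUNDS["IN2"][0], SEGMENT_BOUNDS["IN2"][0] + 6))
_PROTECTED |= set(range(*SEGMENT_BOUNDS["OUT2"]))
_PROTECTED.add(SEGMENT_BOUNDS["OUT1"][0] + 6)


def _pool_of(position: int) -> str:
    for label, (a, b) in SEGMENT_BOUNDS.items():
        if a <= position < b:
            return _TM_POOL if label.startswith("TM") else _LOOP_POOL
    raise IndexError(position)


_AA_TO_CODONS: dict[str, list[str]] = {}
for _codon, _aa in CODON_TO_AA.items():
    _AA_TO_CODONS.setdefault(_aa, []).append(_codon)
for _v in _AA_TO_CODONS.values():
    _v.sort()

_STOPS = ("TAA", "TAG", "TGA")

#: flank guard inserted on the interior side(s) of every planted piece: it
#: carries a stop codon in all three frames of both strands (it is its own
#: reverse complement), so planted ORF boundaries are identifiable instead
#: of bleeding into flank sequence that happens to lack a nearby stop
_STOP_BARRIER = "TTAATTAATTAA"


def _reverse_translate(rng: np.random.Generator, protein: str) -> str:
    return "".join(
        _AA_TO_CODONS[aa][rng.integers(len(_AA_TO_CODONS[aa]))]
        for aa in protein
    )


def _derive_gene(
    rng: np.random.Generator,
    tpl_protein: str,
    tpl_cds: str,
    rate: float,
    syn_rate: float | None = None,
) -> tuple[str, str]:
    """One gene copy derived from a family template, protein and CDS.

    Amino-acid substitutions are applied at ``rate`` per residue (within
    the hydropathy class of the template residue; landmarks protected) and
    synonymous codon swaps at ``syn_rate`` (default equal to ``rate``).
    Deriving the CDS from a shared template CDS — rather than re-choosing
    codons freely — keeps synonymous divergence between family members in
    a realistic range, so pairwise dS is informative rather than
    saturated.
    """
    if syn_rate is None:
        syn_rate = rate
    prot_out: list[str] = []
    cds_out: list[str] = []
    for i, aa in enumerate(tpl_protein):
        codon = tpl_cds[3 * i : 3 * i + 3]
        if i not in _PROTECTED and rng.random() < rate:
            pool = [c for c in _pool_of(i) if c != aa]
            aa = str(rng.choice(pool))
            codon = _AA_TO_CODONS[aa][rng.integers(len(_AA_TO_CODONS[aa]))]
        elif rng.random() < syn_rate and len(_AA_TO_CODONS[aa]) > 1:
            alts = [c for c in _AA_TO_CODONS[aa] if c != codon]
            codon = alts[rng.integers(len(alts))]
        prot_out.append(aa)
        cds_out.append(codon)
    return "".join(prot_out), "".join(cds_out)


def _random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(NUCLEOTIDES), size=length))


def _make_decoy_template(rng: np.random.Generator) -> str:
    """A landmark-free GPCR-like decoy protein (distinct residue stream)."""
    pool = list("ACDEFGHIKLMNPQRSTVWY")
    return "M" + "".join(rng.choice(pool, size=OR_LENGTH - 1))


def _revcomp(seq: str) -> str:
    comp = str.maketrans("ACGT", "TGCA")
    return seq.translate(comp)[::-1]


# --- gene assembly ---------------------------------------------------------


@dataclass
class _PlantedGene:
    gene_id: str
    status: str
    piece: str  # the nucleotide piece inserted into the contig
    exon_local: list[tuple[int, int]]  # coding-orientation coords in piece
    phases: list[int]
    lesion: str  # "kind:cds_codon" or "."
    family_seed: str
    near_group: str
    protein: str
    at_boundary: str = ""  # "", "start" or "end" (coding orientation 5'/3')


def _plant_complete(
    rng, gene_id, template, family, rate, near_group="."
) -> _PlantedGene:
    protein, cds = _derive_gene(rng, *template, rate)
    cds = cds + str(_STOPS[rng.integers(3)])
    return _PlantedGene(
        gene_id,
        "complete",
        cds,
        [(0, len(cds))],
        [],
        ".",
        family,
        near_group,
        protein,
    )


def _plant_multi_exon(
    rng, gene_id, template, family, rate, config
) -> _PlantedGene:
    protein, cds = _derive_gene(rng, *template, rate)
    cds = cds + str(_STOPS[rng.integers(3)])
    n_codons = len(cds) // 3
    n_introns = int(rng.integers(1, 4))
    # intron insertion points, well separated and away from the termini
    codon_positions = sorted(
        rng.choice(np.arange(20, n_codons - 20), size=n_introns, replace=False)
    )
    while any(
        b - a < 30 for a, b in zip(codon_positions, codon_positions[1:])
    ):
        codon_positions = sorted(
            rng.choice(
                np.arange(20, n_codons - 20), size=n_introns, replace=False
            )
        )
    phases_avail = sorted(config.intron_phase_distribution)
    probs = [config.intron_phase_distribution[p] for p in phases_avail]
    phases = [int(rng.choice(phases_avail, p=probs)) for _ in range(n_introns)]
    lo, hi = config.intron_length_range
    piece = cds
    exon_breaks = []  # coding-nt offsets of intron insertion
    for cp, ph in zip(codon_positions, phases):
        exon_breaks.append(3 * int(cp) + ph)
    offset = 0
    exons: list[tuple[int, int]] = []
    prev = 0
    out = []
    for brk in exon_breaks:
        intron_len = int(rng.integers(lo, hi + 1))
        intron = "GT" + _random_dna(rng, intron_len - 4) + "AG"
        out.append(cds[prev:brk])
        exons.append((prev + offset, brk + offset))
        out.append(intron)
        offset += intron_len
        prev = brk
    out.append(cds[prev:])
    exons.append((prev + offset, len(cds) + offset))
    piece = "".join(out)
    return _PlantedGene(
        gene_id,
        "complete",
        piece,
        exons,
        phases,
        ".",
        family,
        ".",
        protein,
    )


def _plant_pseudogene(
    rng, gene_id, template, family, rate, kind: str
) -> _PlantedGene:
    protein, cds0 = _derive_gene(rng, *template, rate)
    cds = list(cds0 + str(_STOPS[rng.integers(3)]))
    n_codons = len(cds) // 3
    # lesion placed in codons [30, n-80): far from both termini, and early
    # enough that the residual ORF cannot pass the complete-length check
    lesion_codon = int(rng.integers(30, n_codons - 80))
    if kind == "frameshift":
        indel = int(rng.integers(1, 3))  # 1-2 bp
        pos = 3 * lesion_codon
        if rng.random() < 0.5:
            del cds[pos : pos + indel]
        else:
            for _ in range(indel):
                cds.insert(pos, str(rng.choice(list(NUCLEOTIDES))))
        lesion = f"frameshift:{lesion_codon}"
    else:
        # replace a sense codon by a stop (prefer a single-nt change)
        pos = 3 * lesion_codon
        for stop in _STOPS:
            if sum(a != b for a, b in zip(cds[pos : pos + 3], stop)) == 1:
                cds[pos : pos + 3] = list(stop)
                break
        else:
            cds[pos : pos + 3] = list("TAA")
        lesion = f"premature_stop:{lesion_codon}"
    piece = "".join(cds)
    return _PlantedGene(
        gene_id,
        "pseudogene",
        piece,
        [(0, len(piece))],
        [],
        lesion,
        family,
        ".",
        protein,
    )


def _plant_edge(
    rng, gene_id, template, family, rate
) -> _PlantedGene:
    protein, cds = _derive_gene(rng, *template, rate)
    cds = cds + str(_STOPS[rng.integers(3)])
    keep = rng.uniform(0.4, 0.7)
    n_keep = 3 * int(keep * (len(cds) // 3))
    if rng.random() < 0.5:
        piece, boundary = cds[:n_keep], "end"  # 3' end of the gene missing
    else:
        piece, boundary = cds[-n_keep:], "start"  # 5' end missing
    return _PlantedGene(
        gene_id,
        "edge",
        piece,
        [(0, len(piece))],
        [],
        ".",
        family,
        ".",
        protein,
        at_boundary=boundary,
    )


def _plant_fragment(
    rng, gene_id, template, family, rate
) -> _PlantedGene:
    protein, cds = _derive_gene(rng, *template, rate)
    n_codons = len(cds) // 3
    frac = rng.uniform(0.4, 0.6)
    n_keep = int(frac * n_codons)
    start = int(rng.integers(15, n_codons - n_keep - 15))
    piece = cds[3 * start : 3 * (start + n_keep)]
    return _PlantedGene(
        gene_id,
        "fragment",
        piece,
        [(0, len(piece))],
        [],
        ".",
        family,
        ".",
        protein,
    )


def _plant_decoy(
    rng, gene_id, template_protein, family, rate
) -> _PlantedGene:
    out = list(template_protein)
    pool = list("ACDEFGHIKLMNPQRSTVWY")
    for i in range(1, len(out)):
        if rng.random() < rate:
            out[i] = str(rng.choice(pool))
    protein = "".join(out)
    cds = _reverse_translate(rng, protein) + str(_STOPS[rng.integers(3)])
    return _PlantedGene(
        gene_id,
        "decoy",
        cds,
        [(0, len(cds))],
        [],
        ".",
        family,
        ".",
        protein,
    )


def generate_repertoire(config: SimulationConfig) -> SyntheticRepertoire:
    """Build contigs with planted genes of every status class, plus truth.

    Every requested gene is embedded in a contig on a random strand; edge
    genes are flush with a contig boundary, fragments and pseudogenes sit
    internally with intact flanks, multi-exon genes carry GT..AG introns
    with phases drawn from the configured distribution.  The truth table
    records forward-strand 0-based half-open exon coordinates, intron
    phases in coding order, lesion coordinates (CDS codon index) and the
    family seed of each gene.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    subgroups = ["threeC" if i % 2 == 0 else "oneC" for i in range(config.n_or_templates)]
    template_proteins = {
        f"fam{i:02d}": _make_or_template(rng, subgroups[i])
        for i in range(config.n_or_templates)
    }
    # one template CDS per family: genes inherit these codons, so family
    # members share realistic synonymous backgrounds
    templates = {
        fam: (prot, _reverse_translate(rng, prot))
        for fam, prot in template_proteins.items()
    }
    fam_ids = sorted(templates)
    # multi-exon genes cluster in dedicated seed families, as real spliced
    # ORs cluster in families of their own
    multi_fams = fam_ids[-2:] if len(fam_ids) >= 2 else fam_ids
    single_fams = fam_ids[: max(1, len(fam_ids) - 2)]
    decoy_templates = {
        f"gpcr{i:02d}": _make_decoy_template(rng) for i in range(3)
    }

    rate = config.mutation_rate_per_site
    genes: list[_PlantedGene] = []
    counter = 0

    def next_id() -> str:
        nonlocal counter
        counter += 1
        return f"g{counter:03d}"

    # near-identical groups first (low-divergence copies of one template)
    n_near = config.near_identical_groups * config.near_identical_group_size
    for grp in range(config.near_identical_groups):
        fam = single_fams[grp % len(single_fams)]
        base = _derive_gene(rng, *templates[fam], rate)
        for _ in range(config.near_identical_group_size):
            protein, cds0 = _derive_gene(
                rng, *base, config.near_identical_divergence
            )
            cds = cds0 + str(_STOPS[rng.integers(3)])
            genes.append(
                _PlantedGene(
                    next_id(), "complete", cds, [(0, len(cds))], [], ".",
                    fam, f"ni{grp:02d}", protein,
                )
            )
    for _ in range(config.complete_single_exon - n_near):
        fam = single_fams[int(rng.integers(len(single_fams)))]
        genes.append(
            _plant_complete(rng, next_id(), templates[fam], fam, rate)
        )
    for _ in range(config.complete_multi_exon):
        fam = multi_fams[int(rng.integers(len(multi_fams)))]
        genes.append(
            _plant_multi_exon(rng, next_id(), templates[fam], fam, rate, config)
        )
    for _ in range(config.pseudogene_frameshift):
        fam = single_fams[int(rng.integers(len(single_fams)))]
        genes.append(
            _plant_pseudogene(rng, next_id(), templates[fam], fam, rate, "frameshift")
        )
    for _ in range(config.pseudogene_stop):
        fam = single_fams[int(rng.integers(len(single_fams)))]
        genes.append(
            _plant_pseudogene(rng, next_id(), templates[fam], fam, rate, "premature_stop")
        )
    for _ in range(config.edge):
        fam = single_fams[int(rng.integers(len(single_fams)))]
        genes.append(_plant_edge(rng, next_id(), templates[fam], fam, rate))
    for _ in range(config.fragment):
        fam = single_fams[int(rng.integers(len(single_fams)))]
        genes.append(_plant_fragment(rng, next_id(), templates[fam], fam, rate))
    for _ in range(config.decoy_gpcr):
        gid = sorted(decoy_templates)[int(rng.integers(len(decoy_templates)))]
        genes.append(
            _plant_decoy(rng, next_id(), decoy_templates[gid], gid, rate)
        )

    # --- contig assembly ---------------------------------------------------
    edge_genes = [g for g in genes if g.status == "edge"]
    internal_genes = [g for g in genes if g.status != "edge"]
    n_internal_contigs = config.n_contigs - len(edge_genes)
    if n_internal_contigs < (len(internal_genes) + 1) // 2:
        raise ConfigurationError(
            "not enough contigs to host the requested genes at <= 2 per contig"
        )

    contigs: dict[str, Contig] = {}
    rows: list[dict] = []
    flank = 250

    def contig_length() -> int:
        return max(
            2000, int(rng.normal(config.contig_length_mean, config.contig_length_mean / 6))
        )

    def record(gene: _PlantedGene, contig_id: str, species: str,
               insert_pos: int, strand: str) -> None:
        lg = len(gene.piece)
        if strand == "+":
            exons = [(insert_pos + a, insert_pos + b) for a, b in gene.exon_local]
        else:
            exons = sorted(
                (insert_pos + lg - b, insert_pos + lg - a)
                for a, b in gene.exon_local
            )
        rows.append(
            {
                "gene_id": gene.gene_id,
                "contig_id": contig_id,
                "species": species,
                "strand": strand,
                "status": gene.status,
                "exon_starts": ",".join(str(a) for a, _ in exons),
                "exon_ends": ",".join(str(b) for _, b in exons),
                "phases": ",".join(str(p) for p in gene.phases) or ".",
                "lesion": gene.lesion,
                "family_seed": gene.family_seed,
                "near_group": gene.near_group,
                "protein": gene.protein,
            }
        )

    contig_idx = 0

    def new_contig_id() -> tuple[str, str]:
        nonlocal contig_idx
        species = config.species[contig_idx % len(config.species)]
        cid = f"contig{contig_idx:04d}"
        contig_idx += 1
        return cid, species

    # edge genes: one per contig, flush with a boundary
    for gene in edge_genes:
        cid, species = new_contig_id()
        length = contig_length()
        lg = len(gene.piece)
        if length < lg + flank:
            raise ConfigurationError(
                f"contig too short to host gene {gene.gene_id}"
            )
        strand = "+" if rng.random() < 0.5 else "-"
        piece = gene.piece if strand == "+" else _revcomp(gene.piece)
        # the missing gene end must coincide with a contig boundary
        missing_5p = gene.at_boundary == "start"
        at_fwd_start = missing_5p if strand == "+" else not missing_5p
        background = _random_dna(rng, length - lg - len(_STOP_BARRIER))
        if at_fwd_start:
            seq = piece + _STOP_BARRIER + background
            insert_pos = 0
        else:
            seq = background + _STOP_BARRIER + piece
            insert_pos = length - lg
        contigs[cid] = Contig(cid, seq, species)
        record(gene, cid, species, insert_pos, strand)

    # internal genes: up to two per contig with generous flanks
    pending = list(internal_genes)
    while pending:
        batch, pending = pending[:2], pending[2:]
        cid, species = new_contig_id()
        need = sum(len(g.piece) for g in batch) + flank * (len(batch) + 1)
        length = max(contig_length(), need)
        seq_parts: list[str] = []
        pos = 0
        gap = (length - sum(len(g.piece) for g in batch)) // (len(batch) + 1)
        for gene in batch:
            strand = "+" if rng.random() < 0.5 else "-"
            piece = gene.piece if strand == "+" else _revcomp(gene.piece)
            seq_parts.append(_random_dna(rng, gap - len(_STOP_BARRIER)))
            seq_parts.append(_STOP_BARRIER)
            pos += gap
            seq_parts.append(piece)
            record(gene, cid, species, pos, strand)
            pos += len(piece)
            seq_parts.append(_STOP_BARRIER)
            pos += len(_STOP_BARRIER)
        seq_parts.append(_random_dna(rng, length - pos))
        contigs[cid] = Contig(cid, "".join(seq_parts), species)

    # background-only contigs up to the configured count
    while contig_idx < config.n_contigs:
        cid, species = new_contig_id()
        contigs[cid] = Contig(cid, _random_dna(rng, contig_length()), species)

    truth = pd.DataFrame(rows, columns=TRUTH_COLUMNS)
    baits = BaitSet(
        positive={f"orbait_{k}": v for k, v in template_proteins.items()},
        negative={f"gpcrbait_{k}": v for k, v in decoy_templates.items()},
    )
    return SyntheticRepertoire(contigs, truth, baits, config)


# --- codon-pair simulation for dN/dS recovery ------------------------------


def random_orf(rng: np.random.Generator, n_codons: int) -> str:
    """A stop-free random ORF of the requested codon count."""
    return "".join(
        SENSE_CODONS[rng.integers(len(SENSE_CODONS))] for _ in range(n_codons)
    )


def _evolve(
    rng: np.random.Generator,
    seq: list[str],
    n_proposals: int,
    omega: float,
    kappa: float,
) -> None:
    """Apply proposal/acceptance substitution events to a codon list.

    Each event proposes a single-nucleotide change at a uniform site with
    transition probability weighted by kappa; proposals creating stop
    codons are rejected and resampled; synonymous proposals are always
    accepted, nonsynonymous ones with probability min(1, omega).
    """
    n_nt = 3 * len(seq)
    accept_non = min(1.0, omega)
    done = 0
    while done < n_proposals:
        site = int(rng.integers(n_nt))
        ci, pos = divmod(site, 3)
        codon = seq[ci]
        old = codon[pos]
        # kappa-weighted target choice
        choices = [nt for nt in NUCLEOTIDES if nt != old]
        weights = np.array(
            [kappa if is_transition(old, nt) else 1.0 for nt in choices]
        )
        nt = choices[int(rng.choice(3, p=weights / weights.sum()))]
        mutant = codon[:pos] + nt + codon[pos + 1 :]
        if is_stop(mutant):
            continue  # resample: stop codons are never introduced
        done += 1
        if translate_codon(mutant) == translate_codon(codon):
            seq[ci] = mutant
        elif rng.random() < accept_non:
            seq[ci] = mutant


def simulate_codon_pair(
    ancestral_length: int,
    omega: float,
    branch_divergence: float,
    kappa: float = 2.0,
    seed: int | np.random.Generator = 0,
) -> tuple[str, str]:
    """Evolve two stop-free ORFs from a common ancestor under a target omega.

    ``branch_divergence`` is the expected number of substitution proposals
    per nucleotide site separating the two sequences (before acceptance
    thinning of nonsynonymous proposals); half is applied to each lineage.
    """
    if ancestral_length < 30:
        raise ValueError("need >= 30 codons for stable estimation")
    if omega <= 0:
        raise ValueError("omega must be positive")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    ancestor = random_orf(rng, ancestral_length)
    n_nt = 3 * ancestral_length
    a = list(ancestor[i : i + 3] for i in range(0, n_nt, 3))
    b = list(a)
    if branch_divergence > 0:
        per_lineage = rng.poisson(branch_divergence * n_nt / 2.0, size=2)
        _evolve(rng, a, int(per_lineage[0]), omega, kappa)
        _evolve(rng, b, int(per_lineage[1]), omega, kappa)
    return "".join(a), "".join(b)


# --- I/O -------------------------------------------------------------------


def write_fasta(sequences: Mapping[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name in sequences:
            fh.write(f">{name}\n")
            seq = sequences[name]
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


def write_repertoire(rep: SyntheticRepertoire, outdir: str | Path) -> None:
    """Write contig FASTA, truth TSV and bait FASTAs to a directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_fasta(
        {c.id + f" species={c.species}": c.seq for c in rep.contigs.values()},
        outdir / "contigs.fasta",
    )
    rep.truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)
    write_fasta(dict(rep.baits.positive), outdir / "baits_positive.fasta")
    write_fasta(dict(rep.baits.negative), outdir / "baits_negative.fasta")


def config_from_mapping(data: Mapping) -> SimulationConfig:
    """Build a SimulationConfig from a parsed YAML/JSON mapping."""
    known = {f.name for f in fields(SimulationConfig)}
    unknown = set(data) - known
    if unknown:
        raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
    kwargs = dict(data)
    if "intron_phase_distribution" in kwargs:
        kwargs["intron_phase_distribution"] = {
            int(k): float(v)
            for k, v in kwargs["intron_phase_distribution"].items()
        }
    for tup_key in ("intron_length_range", "species"):
        if tup_key in kwargs:
            kwargs[tup_key] = tuple(kwargs[tup_key])
    cfg = SimulationConfig(**kwargs)
    cfg.validate()
    return cfg
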