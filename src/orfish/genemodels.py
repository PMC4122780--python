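"""Gene-model reconstruction and status classification at candidate loci.

Each mined locus is annotated by aligning its best bait protein back to the
padded locus window and asking, in order:

1. Is there a complete single-exon ORF (ATG..stop, plausible OR length)
   overlapping the seed?  -> ``complete``.
2. Can a spliced model be assembled — 1-3 GT..AG introns whose removal
   yields a complete stop-free ORF?  Candidate junctions are seeded by the
   block structure of the bait alignment (unaligned bait stretches mark
   introns), refined over nearby GT/AG dinucleotides under a reading-frame
   continuity constraint, and the solution maximising the bait alignment
   score wins.  -> ``complete`` with intron records.
3. Otherwise the locus is an incomplete copy: a premature stop codon or a
   frameshift inside the bait-covered region makes it a ``pseudogene``
   (with lesion coordinates); a copy truncated by a contig boundary is an
   ``edge``; an internal partial copy with intact flanks is a ``fragment``.

All coordinates are 0-based half-open on the forward strand; reverse-strand
genes carry forward coordinates plus a strand flag, with phases and CDS in
coding order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .mining import BaitSet, Contig, Locus, local_align

_COMP = str.maketrans("ACGT", "TGCA")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def _translate(seq: str) -> str:
    sub = seq[: len(seq) - len(seq) % 3]
    return str(Seq(sub).translate())


@dataclass
class AnnotationParams:
    """Tunable reconstruction thresholds (defaults in codons/bp/residues)."""

    min_aa: int = 250  # plausible complete OR length range
    max_aa: int = 400
    fragment_min: int = 60  # codons; smaller matches are dropped
    edge_margin: int = 10  # bp from a contig boundary to call an edge
    min_intron: int = 50
    max_intron: int = 5000
    max_introns: int = 3
    junction_slop: int = 12  # nt searched around a seeded junction
    min_block_aa: int = 15  # smallest exon seed considered


@dataclass
class IntronRecord:
    """One GT..AG intron of a spliced gene model."""

    start: int  # forward contig coordinates, 0-based half-open
    end: int
    phase: int  # (coding nt upstream) mod 3
    donor: str  # dinucleotide, coding orientation
    acceptor: str
    last_codon_context: str  # e.g. "CAA.CAG"
    codon_position: int  # 1-based interrupted/adjacent codon in the protein
    region: str | None = None  # topology segment label, filled later
    donor_window: str = ""  # 3 exonic + 6 intronic nt
    acceptor_window: str = ""  # 14 intronic + 1 exonic nt


@dataclass
class GeneModel:
    gene_id: str
    contig_id: str
    species: str
    strand: str
    exons: list[tuple[int, int]]  # forward coords, ascending
    status: str  # complete | pseudogene | edge | fragment
    cds: str  # coding-orientation nucleotides (concatenated exons)
    protein: str
    lesions: list[tuple[str, int]] = field(default_factory=list)
    introns: list[IntronRecord] = field(default_factory=list)
    bait_id: str = ""
    bait_score: float = 0.0
    name: str | None = None  # canonical repertoire name, assigned later

    @property
    def n_coding_exons(self) -> int:
        return len(self.exons)

    def validate(self) -> None:
        starts = [a for a, _ in self.exons]
        ends = [b for _, b in self.exons]
        if sorted(starts) != starts or any(
            a >= b for a, b in self.exons
        ) or any(b > s for b, s in zip(ends, starts[1:])):
            raise ValueError(f"{self.gene_id}: malformed exon list")
        if sum(b - a for a, b in self.exons) != len(self.cds):
            raise ValueError(f"{self.gene_id}: exon lengths != CDS length")
        if self.status == "complete":
            if not self.protein.startswith("M") or "*" in self.protein:
                raise ValueError(f"{self.gene_id}: invalid complete protein")
        if self.status == "pseudogene" and not self.lesions:
            raise ValueError(f"{self.gene_id}: pseudogene without lesion")


class _Workspace:
    """A locus window in coding orientation with coordinate mapping.

    ``extend`` widens the window beyond the mined locus padding — the
    spliced search needs room for introns far longer than the padding.
    """

    def __init__(
        self,
        locus: Locus,
        contig: Contig,
        extend: int = 0,
        clip: tuple[int, int] | None = None,
    ):
        self.locus = locus
        self.contig = contig
        lo, hi = clip if clip is not None else (0, len(contig.seq))
        self.ws = max(0, lo, locus.window_start - extend)
        self.we = min(len(contig.seq), hi, locus.window_end + extend)
        window = contig.seq[self.ws : self.we].upper()
        self.seq = window if locus.strand == "+" else _revcomp(window)
        self.frames = [_translate(self.seq[f:]) for f in range(3)]

    def to_forward(self, a: int, b: int) -> tuple[int, int]:
        """Map a work-coordinate interval to forward contig coordinates."""
        if self.locus.strand == "+":
            return self.ws + a, self.ws + b
        return self.we - b, self.we - a

    def forward_point(self, w: int) -> int:
        return self.ws + w if self.locus.strand == "+" else self.we - w

    @property
    def seed(self) -> tuple[int, int]:
        """The merged-hit interval of the locus, in work coordinates."""
        if self.locus.strand == "+":
            return self.locus.start - self.ws, self.locus.end - self.ws
        return self.we - self.locus.end, self.we - self.locus.start


def _find_orfs(seq: str, min_codons: int, max_codons: int | None = None):
    """(start, end, protein) of ATG..stop ORFs, end includes the stop codon.

    Start-codon choice when several in-frame ATGs precede the stop: the
    5'-most ATG that keeps the protein length within ``max_codons`` (the
    maximal-ORF convention, bounded by the plausible length range).
    """
    out = []
    for f in range(3):
        prot = _translate(seq[f:])
        stops = [i for i, c in enumerate(prot) if c == "*"] + [len(prot)]
        prev = -1
        for s in stops:
            if s < len(prot):  # a real stop codon terminates the ORF
                region = prot[prev + 1 : s]
                m = region.find("M")
                while m >= 0:
                    aa_start = prev + 1 + m
                    if max_codons is None or s - aa_start <= max_codons:
                        break
                    m = region.find("M", m + 1)
                if m >= 0 and s - (prev + 1 + m) >= min_codons:
                    aa_start = prev + 1 + m
                    out.append(
                        (
                            f + 3 * aa_start,
                            f + 3 * (s + 1),
                            prot[aa_start:s],
                        )
                    )
            prev = s
    return out


def reconstruct_single_exon(
    locus: Locus,
    contig: Contig,
    bait: str,
    params: AnnotationParams = AnnotationParams(),
) -> GeneModel | None:
    """Best complete single-exon model at the locus, or None.

    Returns a ``complete`` model for the maximal ATG..stop ORF of plausible
    OR length overlapping the seed hit; incomplete loci fall through to the
    spliced search and the pseudogene/edge/fragment classifier.
    """
    ws = _Workspace(locus, contig)
    model = _complete_single_exon(ws, bait, params)
    return model


def _complete_single_exon(
    ws: _Workspace, bait: str, params: AnnotationParams
) -> GeneModel | None:
    s0, s1 = ws.seed
    best = None
    for start, end, prot in _find_orfs(ws.seq, params.min_aa, params.max_aa):
        if not (params.min_aa <= len(prot) <= params.max_aa):
            continue
        if end <= s0 or start >= s1:  # must overlap the seed
            continue
        aln = local_align(prot, bait)
        t0, t1 = aln.target_interval
        # a genuine complete gene accounts for (almost) the whole bait; a
        # chance ORF reading through a partial copy does not
        if t0 > 30 or len(bait) - t1 > 30:
            continue
        if best is None or aln.score > best[0]:
            best = (aln.score, start, end, prot)
    if best is None:
        return None
    score, start, end, prot = best
    exon = ws.to_forward(start, end)
    cds = ws.seq[start:end]
    return GeneModel(
        gene_id="",
        contig_id=ws.contig.id,
        species=ws.contig.species,
        strand=ws.locus.strand,
        exons=[exon],
        status="complete",
        cds=cds,
        protein=prot,
        bait_score=score,
    )


# --- spliced reconstruction ------------------------------------------------


def _frame_anchors(bait: str, frame_prot: str, f: int, params: AnnotationParams):
    """High-confidence exon anchors for one frame, by masked re-alignment.

    An anchor is an ungapped aligned chunk of >= 10 bait residues with
    >= 50% identity: long enough, and clean enough, that it can only be a
    piece of a real exon.  The aligned target region is masked and the
    frame re-aligned so that several exons landing in the same frame are
    all recovered.  Anchors are (q0, q1, nt0, nt1, frame).
    """
    anchors = []
    work = list(frame_prot)
    for _ in range(params.max_introns + 1):
        aln = local_align(bait, "".join(work))
        if aln.score < 40:
            break
        for (q0, q1), (t0, t1) in aln.blocks:
            if q1 - q0 < 10:
                continue
            match = [
                bait[q0 + i] == frame_prot[t0 + i] for i in range(q1 - q0)
            ]
            if sum(match) < 0.5 * len(match):
                continue
            # trim low-identity edges: local alignment overruns exon ends
            # into intron junk, which would misplace the junction seeds
            s, e = 0, len(match)
            while e - s > 10 and sum(match[s : s + 5]) < 3:
                s += 1
            while e - s > 10 and sum(match[e - 5 : e]) < 3:
                e -= 1
            anchors.append(
                (q0 + s, q0 + e, f + 3 * (t0 + s), f + 3 * (t0 + e), f)
            )
        t0, t1 = aln.target_interval
        if t1 <= t0:
            break
        for i in range(t0, t1):
            work[i] = "X"
    return anchors


def _alignment_blocks(ws: _Workspace, bait: str, params: AnnotationParams):
    """Exon seed groups ((bait_iv, work_nt_iv)) in coding order.

    Anchors from all three frames are chained (increasing bait and genomic
    coordinates, maximal bait coverage) and collinear same-frame anchors
    are merged into one exon group; the gaps between groups are the
    candidate introns.
    """
    anchors = []
    for f, frame_prot in enumerate(ws.frames):
        if frame_prot:
            anchors.extend(_frame_anchors(bait, frame_prot, f, params))
    if not anchors:
        return []
    anchors.sort(key=lambda a: (a[0], a[2]))
    n = len(anchors)
    best_score = [float(a[1] - a[0]) for a in anchors]
    prev = [-1] * n
    # chain DP; local alignment can overrun an exon end by a few codons,
    # so modest query/genomic overlaps between anchors are tolerated.  A
    # mild genomic-gap penalty prefers compact gene structures over
    # equally-covering chains that jump to a distant family relative.
    for i in range(n):
        for j in range(i):
            q_overlap = anchors[j][1] - anchors[i][0]
            if q_overlap > 24 or anchors[i][2] < anchors[j][3] - 36:
                continue
            gain = (anchors[i][1] - anchors[i][0]) - max(0, q_overlap)
            nt_gap = max(0, anchors[i][2] - anchors[j][3])
            cand = best_score[j] + gain - nt_gap / 1000.0
            if cand > best_score[i]:
                best_score[i] = cand
                prev[i] = j
    end = int(np.argmax(best_score))
    chain = []
    while end != -1:
        chain.append(anchors[end])
        end = prev[end]
    chain.reverse()
    # merge collinear same-frame anchors into exon groups
    groups: list[list[int]] = []  # [q0, q1, nt0, nt1, frame]
    for q0, q1, nt0, nt1, f in chain:
        if groups:
            g = groups[-1]
            collinear = (
                g[4] == f
                and nt0 - 3 * q0 == g[2] - 3 * g[0]
                and 0 <= nt0 - g[3] < params.min_intron
            )
            if collinear:
                g[1], g[3] = max(g[1], q1), max(g[3], nt1)
                continue
        groups.append([q0, q1, nt0, nt1, f])
    # spurious short chance anchors must not masquerade as exons
    groups = [g for g in groups if g[1] - g[0] >= params.min_block_aa]
    return [((g[0], g[1]), (g[2], g[3]), g[4]) for g in groups]


def _junction_candidates(
    ws: _Workspace,
    up_block,
    down_block,
    params: AnnotationParams,
):
    """(donor, acceptor) work positions for the junction between two groups.

    The donor must start GT downstream of the upstream anchor (a little
    slack is allowed because local alignment can overrun an exon end into
    the intron), the acceptor must end AG upstream of the downstream
    anchor, the intron length must be plausible, and the reading frame
    must continue across the junction.  Candidates are ranked by how well
    the implied coding length between the anchors matches the number of
    unanchored bait residues.
    """
    (_, q1e), (_, e1), f1 = up_block[0], up_block[1], up_block[2]
    (q2s, _), (s2, _), f2 = down_block[0], down_block[1], down_block[2]
    q_gap = q2s - q1e  # unanchored bait residues; negative on overrun
    overlap = max(0, -q_gap)
    slack = 3 * params.junction_slop
    d_lo = max(1, e1 - 18 - 3 * overlap)
    d_hi = min(len(ws.seq) - 2, e1 + 3 * max(0, q_gap) + slack)
    a_lo = max(2, s2 - 3 * max(0, q_gap) - slack)
    a_hi = min(len(ws.seq), s2 + 18 + 3 * overlap)
    donors = [
        d for d in range(d_lo, d_hi + 1) if ws.seq[d : d + 2] == "GT"
    ]
    acceptors = [
        a for a in range(a_lo, a_hi + 1) if ws.seq[a - 2 : a] == "AG"
    ]
    pairs = []
    for d in donors:
        for a in acceptors:
            if not params.min_intron <= a - d <= params.max_intron:
                continue
            # reading-frame continuity across the junction
            if (d - f1) % 3 != (a - f2) % 3:
                continue
            mismatch = abs((d - e1) + (s2 - a) - 3 * q_gap)
            pairs.append((mismatch, d, a))
    pairs.sort()
    return [(d, a) for _, d, a in pairs[:20]]


def detect_spliced_model(
    locus: Locus,
    contig: Contig,
    bait: str,
    params: AnnotationParams = AnnotationParams(),
) -> GeneModel | None:
    """Assemble a complete multi-exon model with GT..AG introns, or None.

    Among junction combinations that yield a stop-free ATG..stop ORF of
    plausible length crossing every junction, the one maximising the bait
    alignment score of the predicted protein wins (ties: fewer introns,
    then junctions closest to the seeded exon boundaries).
    """
    ws = _Workspace(locus, contig)
    return _spliced(ws, bait, params)


def _spliced(
    ws: _Workspace, bait: str, params: AnnotationParams
) -> GeneModel | None:
    blocks = _alignment_blocks(ws, bait, params)
    if len(blocks) < 2 or len(blocks) > params.max_introns + 1:
        return None
    per_junction = []
    for up, down in zip(blocks, blocks[1:]):
        cands = _junction_candidates(ws, up, down, params)
        if not cands:
            return None
        per_junction.append(cands)
    best = None
    import itertools

    for combo in itertools.product(*per_junction):
        if any(a >= d2 for (_, a), (d2, _) in zip(combo, combo[1:])):
            continue
        model = _build_spliced(ws, bait, combo, blocks, params)
        if model is None:
            continue
        dist = sum(
            abs(d - up[1][1]) + abs(a - down[1][0])
            for (d, a), up, down in zip(combo, blocks, blocks[1:])
        )
        key = (model.bait_score, -len(combo), -dist)
        if best is None or key > best[0]:
            best = (key, model)
    return best[1] if best is not None else None


def _build_spliced(
    ws: _Workspace, bait: str, junctions, blocks, params: AnnotationParams
) -> GeneModel | None:
    # splice out the introns and look for a complete ORF crossing them all
    seq = ws.seq
    cuts = []
    prev = 0
    for d, a in junctions:
        cuts.append((prev, d))
        prev = a
    cuts.append((prev, len(seq)))
    spliced = "".join(seq[a:b] for a, b in cuts)
    # spliced-coordinate positions of each junction
    spliced_junctions = []
    acc = 0
    for a, b in cuts[:-1]:
        acc += b - a
        spliced_junctions.append(acc)
    best = None
    for start, end, prot in _find_orfs(spliced, params.min_aa, params.max_aa):
        if not (params.min_aa <= len(prot) <= params.max_aa):
            continue
        if not all(start < j < end for j in spliced_junctions):
            continue
        aln = local_align(prot, bait)
        # a mis-splice that excises coding sequence (e.g. "repairing" a
        # frameshift) shows up as a long internal deletion against the bait
        prev = None
        deleted = False
        for (qs, qe), (ts, te) in aln.blocks:
            if prev is not None and (ts - prev[1]) - (qs - prev[0]) >= 10:
                deleted = True
                break
            prev = (qe, te)
        if deleted:
            continue
        if best is None or aln.score > best[0]:
            best = (aln.score, start, end, prot)
    if best is None:
        return None
    score, start, end, prot = best

    def to_work(spliced_pos: int) -> int:
        off = spliced_pos
        for a, b in cuts:
            if off < b - a:
                return a + off
            off -= b - a
        return cuts[-1][1]

    exons_work = []
    w_start = to_work(start)
    for j, (d, a) in zip(spliced_junctions, junctions):
        exons_work.append((w_start, d))
        w_start = a
    exons_work.append((w_start, to_work(end - 1) + 1))
    cds = "".join(seq[a:b] for a, b in exons_work)

    introns = []
    upstream = 0
    for (e_a, e_b), (d, a) in zip(exons_work, junctions):
        upstream += e_b - e_a
        phase = upstream % 3
        codon = upstream // 3 if phase == 0 else upstream // 3 + 1
        if phase == 0:
            context = f"{cds[upstream - 3:upstream]}.{cds[upstream:upstream + 3]}"
        else:
            context = f"{cds[upstream - 3:upstream]}.{cds[upstream:upstream + 2]}"
        fa, fb = ws.to_forward(d, a)
        introns.append(
            IntronRecord(
                start=fa,
                end=fb,
                phase=phase,
                donor=seq[d : d + 2],
                acceptor=seq[a - 2 : a],
                last_codon_context=context,
                codon_position=codon,
                donor_window=seq[d - 3 : d + 6],
                acceptor_window=seq[a - 14 : a + 1],
            )
        )
    exons_fwd = sorted(ws.to_forward(a, b) for a, b in exons_work)
    return GeneModel(
        gene_id="",
        contig_id=ws.contig.id,
        species=ws.contig.species,
        strand=ws.locus.strand,
        exons=exons_fwd,
        status="complete",
        cds=cds,
        protein=prot,
        introns=introns,
        bait_score=score,
    )


# --- incomplete-copy classification ----------------------------------------


def classify_edge_or_fragment(
    missing_5p: bool,
    missing_3p: bool,
    gene_start_fwd: int,
    gene_end_fwd: int,
    strand: str,
    contig_len: int,
    edge_margin: int = 10,
) -> str:
    """``edge`` iff a missing gene end coincides with a contig boundary.

    ``gene_start_fwd``/``gene_end_fwd`` bound the recovered gene region in
    forward coordinates; the gene's 5' end maps to the interval start on
    '+' and to the interval end on '-'.
    """
    if strand == "+":
        p5, p3 = gene_start_fwd, gene_end_fwd
        at5 = p5 <= edge_margin
        at3 = p3 >= contig_len - edge_margin
    else:
        p5, p3 = gene_end_fwd, gene_start_fwd
        at5 = p5 >= contig_len - edge_margin
        at3 = p3 <= edge_margin
    if (missing_5p and at5) or (missing_3p and at3):
        return "edge"
    return "fragment"


def _frame_alignments(ws: _Workspace, bait: str):
    alns = []
    for f, frame in enumerate(ws.frames):
        if frame:
            alns.append((f, local_align(bait, frame)))
    alns.sort(key=lambda fa: -fa[1].score)
    return alns


def _lesion_signature(ws: _Workspace, bait: str, params: AnnotationParams):
    """Pseudogene evidence at the locus, from the bait frame alignments.

    Returns ``("premature_stop", codon, span)`` when the best single-frame
    alignment reads through a stop, ``("frameshift", codon, span)`` when a
    second frame covers the complementary part of the bait immediately
    adjacent in the genome (far too close for an intron), else None.
    ``span`` is the work-coordinate extent of the disabled copy and
    ``codon`` the 0-based lesion position in bait coordinates.
    """
    alns = _frame_alignments(ws, bait)
    if not alns:
        return None
    f1, a1 = alns[0]
    q0, q1 = a1.query_interval
    t0, t1 = a1.target_interval
    if q1 - q0 < params.min_block_aa:
        return None
    nt0, nt1 = f1 + 3 * t0, f1 + 3 * t1
    covered = ws.frames[f1][t0:t1]
    for k, c in enumerate(covered):
        # a credible premature stop is flanked by well-matching coding
        # sequence on BOTH sides; stops at alignment edges or inside
        # read-through junk are not lesion evidence
        if c != "*" or k < 8 or k > len(covered) - 9:
            continue
        left = covered[k - 8 : k]
        left_ref = bait[q0 + k - 8 : q0 + k]
        right = covered[k + 1 : k + 9]
        right_ref = bait[q0 + k + 1 : q0 + k + 9]
        left_id = sum(a == b for a, b in zip(left, left_ref))
        right_id = sum(a == b for a, b in zip(right, right_ref))
        if left_id >= 4 and right_id >= 4:
            return ("premature_stop", q0 + k, (nt0, nt1))
    for f2, a2 in alns[1:]:
        if f2 == f1 or a2.score < 80:
            continue
        p0, p1 = a2.query_interval
        u0, u1 = a2.target_interval
        if p1 - p0 < params.min_block_aa:
            continue
        m0, m1 = f2 + 3 * u0, f2 + 3 * u1
        bait_overlap = min(q1, p1) - max(q0, p0)
        if bait_overlap > 0.5 * min(q1 - q0, p1 - p0):
            continue
        if p0 + p1 > q0 + q1:  # second piece is C-terminal on the bait
            gap = m0 - nt1
            junction_codon = (q1 + p0) // 2
        else:
            gap = nt0 - m1
            junction_codon = (p1 + q0) // 2
        # both alignments overrun past the indel, so the genomic overlap
        # can reach three nt per overlapping bait residue
        if -(3 * max(0, bait_overlap) + 45) <= gap < params.min_intron - 10:
            span = (min(nt0, m0), max(nt1, m1))
            return ("frameshift", junction_codon, span)
    return None


def _classify_incomplete(
    ws: _Workspace, bait: str, params: AnnotationParams
) -> GeneModel | None:
    alns = _frame_alignments(ws, bait)
    if not alns:
        return None
    f1, a1 = alns[0]
    q0, q1 = a1.query_interval
    t0, t1 = a1.target_interval
    if q1 - q0 < params.fragment_min:
        return None  # below reporting threshold
    nt0, nt1 = f1 + 3 * t0, f1 + 3 * t1
    covered = ws.frames[f1][t0:t1]

    def base_model(status, lesions=(), span=None):
        lo, hi = span if span else (nt0, nt1)
        return GeneModel(
            gene_id="",
            contig_id=ws.contig.id,
            species=ws.contig.species,
            strand=ws.locus.strand,
            exons=[ws.to_forward(lo, hi)],
            status=status,
            cds=ws.seq[lo:hi],
            protein=covered,
            lesions=list(lesions),
            bait_score=a1.score,
        )

    lesion = _lesion_signature(ws, bait, params)
    if lesion is not None:
        kind, codon, span = lesion
        return base_model("pseudogene", [(kind, codon)], span)

    # truncated copy: edge if the missing end sits on a contig boundary
    missing_5p = q0 >= params.min_block_aa
    missing_3p = len(bait) - q1 >= params.min_block_aa
    fwd = ws.to_forward(nt0, nt1)
    status = classify_edge_or_fragment(
        missing_5p,
        missing_3p,
        fwd[0],
        fwd[1],
        ws.locus.strand,
        len(ws.contig.seq),
        params.edge_margin,
    )
    return base_model(status)


# --- driver ----------------------------------------------------------------


def _suspect_intron(protein: str, bait: str) -> bool:
    """True when a single-exon model may be reading through an intron.

    Either a long unaligned bait stretch (an exon missing from the model)
    or a long insertion in the model relative to the bait (an in-frame
    intron translated into the protein) warrants a spliced attempt.
    """
    aln = local_align(protein, bait)
    q0, q1 = aln.query_interval
    t0, t1 = aln.target_interval
    if (len(bait) - (t1 - t0)) >= 20:
        return True
    prev = None
    for (qs, qe), (ts, te) in aln.blocks:
        if prev is not None:
            gap_q = qs - prev[0]
            gap_t = ts - prev[1]
            if gap_q - gap_t >= 15:
                return True
        prev = (qe, te)
    return False


def annotate_locus(
    locus: Locus,
    contig: Contig,
    baits: BaitSet,
    params: AnnotationParams = AnnotationParams(),
    clip: tuple[int, int] | None = None,
) -> GeneModel | None:
    """Reconstruct and classify the gene model at one mined locus.

    ``clip`` bounds the annotation window (used to stop the spliced search
    at neighbouring candidate loci, which would otherwise donate exons of
    a different gene of the same family).
    """
    bait = baits.positive[locus.best_bait]
    ws = _Workspace(locus, contig, clip=clip)
    model = _complete_single_exon(ws, bait, params)
    # a complete-looking ORF can be a spurious sub-ORF of a disabled gene
    # (re-initiation after a premature stop, or the shifted frame after an
    # indel); lesion evidence from the bait alignment vetoes it
    lesion = _lesion_signature(ws, bait, params)
    if lesion is not None:
        model = None
    if model is None or _suspect_intron(model.protein, bait):
        # widen the window: introns can far exceed the locus padding
        ws_ext = _Workspace(locus, contig, extend=params.max_intron, clip=clip)
        spliced = _spliced(ws_ext, bait, params)
        if spliced is not None and (
            model is None or spliced.bait_score > model.bait_score
        ):
            model = spliced
    if model is None:
        model = _classify_incomplete(ws, bait, params)
    if model is not None:
        model.bait_id = locus.best_bait
        if model.status == "complete":
            model.validate()
    return model


def annotate(
    loci: Sequence[Locus],
    contigs: Mapping[str, Contig],
    baits: BaitSet,
    params: AnnotationParams = AnnotationParams(),
) -> list[GeneModel]:
    """Annotate all loci; gene ids are locus-ordered ``loc0001`` etc.

    A locus whose model leaves distant supporting hits unexplained (two
    tandem family members merged into one candidate) is split: the
    residual hits form a secondary locus that is annotated in turn.
    """
    from .mining import _make_locus

    models = []
    queue = [(locus, None) for locus in loci]
    counter = 0
    while queue:
        locus, forced_clip = queue.pop(0)
        contig = contigs[locus.contig_id]
        lo, hi = forced_clip if forced_clip else (0, len(contig.seq))
        for other in loci:
            if (
                other is locus
                or other.contig_id != locus.contig_id
                or other.strand != locus.strand
            ):
                continue
            if other.end <= locus.start:
                lo = max(lo, other.end)
            elif other.start >= locus.end:
                hi = min(hi, other.start)
        model = annotate_locus(locus, contig, baits, params, clip=(lo, hi))
        if model is None:
            continue
        counter += 1
        model.gene_id = f"loc{counter:04d}"
        models.append(model)
        if forced_clip is not None:
            continue  # one split per locus
        span0, span1 = model.exons[0][0], model.exons[-1][1]
        residual = [
            h
            for h in locus.hits
            if h.end <= span0 - 100 or h.start >= span1 + 100
        ]
        if residual:
            sub = _make_locus(
                locus.contig_id, locus.strand, residual, len(contig.seq), 300
            )
            sub_clip = (
                (span1, hi) if sub.start >= span1 else (lo, span0)
            )
            queue.append((sub, sub_clip))
    return models


# --- splice-site PWM -------------------------------------------------------

DONOR_WINDOW = (3, 6)  # exonic, intronic nt
ACCEPTOR_WINDOW = (14, 1)  # intronic, exonic nt


def splice_pwm_train(
    introns: Sequence[IntronRecord], pseudocount: float = 1.0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Position-frequency matrices for donor and acceptor junctions.

    Donor window: 3 exonic + 6 intronic nt; acceptor: 14 intronic + 1
    exonic.  Columns are normalised with the given pseudocount; needs at
    least five introns with full context windows.
    """
    usable = [
        it
        for it in introns
        if len(it.donor_window) == sum(DONOR_WINDOW)
        and len(it.acceptor_window) == sum(ACCEPTOR_WINDOW)
    ]
    if len(usable) < 5:
        raise ValueError(f"need >= 5 introns with context, got {len(usable)}")

    def pwm(windows: list[str]) -> pd.DataFrame:
        width = len(windows[0])
        counts = np.full((4, width), pseudocount)
        idx = {nt: i for i, nt in enumerate("ACGT")}
        for w in windows:
            for j, nt in enumerate(w):
                if nt in idx:
                    counts[idx[nt], j] += 1
        counts /= counts.sum(axis=0, keepdims=True)
        return pd.DataFrame(counts, index=list("ACGT"))

    donor = pwm([it.donor_window for it in usable])
    acceptor = pwm([it.acceptor_window for it in usable])
    return donor, acceptor


def pwm_consensus(pwm: pd.DataFrame) -> str:
    return "".join(pwm.index[pwm[c].to_numpy().argmax()] for c in pwm.columns)


# --- output ----------------------------------------------------------------


def models_to_status_table(models: Sequence[GeneModel]) -> pd.DataFrame:
    rows = []
    for m in models:
        rows.append(
            {
                "gene_id": m.gene_id,
                "name": m.name or ".",
                "contig_id": m.contig_id,
                "species": m.species,
                "strand": m.strand,
                "status": m.status,
                "n_exons": m.n_coding_exons,
                "start": m.exons[0][0],
                "end": m.exons[-1][1],
                "lesions": ";".join(f"{k}:{c}" for k, c in m.lesions) or ".",
                "protein_length": len(m.protein),
            }
        )
    return pd.DataFrame(rows)


def write_gff3(models: Sequence[GeneModel], path: str | Path) -> None:
    """gene/mRNA/CDS features with correct CDS phase in column 8."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for m in models:
            gid = m.name or m.gene_id
            start = m.exons[0][0] + 1
            end = m.exons[-1][1]
            fh.write(
                f"{m.contig_id}\torfish\tgene\t{start}\t{end}\t.\t{m.strand}"
                f"\t.\tID={gid};status={m.status}\n"
            )
            fh.write(
                f"{m.contig_id}\torfish\tmRNA\t{start}\t{end}\t.\t{m.strand}"
                f"\t.\tID={gid}.t1;Parent={gid}\n"
            )
            exons = m.exons if m.strand == "+" else list(reversed(m.exons))
            coding = 0
            for a, b in exons:
                phase = (3 - coding % 3) % 3
                fh.write(
                    f"{m.contig_id}\torfish\tCDS\t{a + 1}\t{b}\t.\t{m.strand}"
                    f"\t{phase}\tID={gid}.cds;Parent={gid}.t1\n"
                )
                coding += b - a


def intron_report(models: Sequence[GeneModel]) -> pd.DataFrame:
    """Per-intron table: context, phase, codon position, topology region."""
    rows = []
    for m in models:
        for it in m.introns:
            rows.append(
                {
                    "gene": m.name or m.gene_id,
                    "n_coding_exons": m.n_coding_exons,
                    "last_codon": it.last_codon_context,
                    "intron_phase": it.phase,
                    "codon_position": it.codon_position,
                    "intron_position": it.region or ".",
                    "intron_start": it.start,
                    "intron_end": it.end,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "gene",
            "n_coding_exons",
            "last_codon",
            "intron_phase",
            "codon_position",
            "intron_position",
            "intron_start",
            "intron_end",
        ],
    )
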