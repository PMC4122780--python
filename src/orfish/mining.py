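"""Bait-based OR locus mining by translated homology search.

Candidate OR loci are found by aligning a positive bait set (known OR
proteins) against all six reading frames of each contig with a
Smith-Waterman local aligner (BLOSUM62, affine gaps), attaching
Karlin-Altschul e-values E = K*m*n*exp(-lambda*S).  A locus is retained iff
it has at least one positive hit at or below the positive e-value cut-off
and no overlapping negative hit (non-OR GPCR bait) at or below the negative
cut-off — the two retention rules of the survey this pipeline reproduces
(both cut-offs default to 1e-50; the downstream protein re-check uses
1e-100).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

from Bio import Align
from Bio.Align import substitution_matrices
from Bio.Seq import Seq

# gapped BLOSUM62 Karlin-Altschul parameters (standard published values)
DEFAULT_LAMBDA = 0.267
DEFAULT_K = 0.041

DEFAULT_POSITIVE_CUTOFF = 1e-50
DEFAULT_NEGATIVE_CUTOFF = 1e-50
RECHECK_CUTOFF = 1e-100

LOCUS_PADDING = 300  # bp added on each side of a merged hit before annotation

_BLOSUM62 = substitution_matrices.load("BLOSUM62")


def make_local_aligner(open_gap: float = -11.0, extend_gap: float = -1.0):
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = _BLOSUM62
    aligner.open_gap_score = open_gap
    aligner.extend_gap_score = extend_gap
    return aligner


_LOCAL = make_local_aligner()


@dataclass(frozen=True)
class Contig:
    """A DNA contig with an identifier and a species tag."""

    id: str
    seq: str
    species: str = "UNK"

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class BaitSet:
    """Positive (OR) and negative (non-OR GPCR) bait proteins."""

    positive: Mapping[str, str]
    negative: Mapping[str, str]

    def __post_init__(self):
        overlap = set(self.positive) & set(self.negative)
        if overlap:
            raise ValueError(f"bait ids in both sets: {sorted(overlap)}")
        if not self.positive or not self.negative:
            raise ValueError("both bait sets must be non-empty")


@dataclass(frozen=True)
class EvalueParams:
    """Karlin-Altschul parameters and search-space sizes."""

    lambda_: float = DEFAULT_LAMBDA
    K: float = DEFAULT_K
    m: int = 1
    n: int = 1

    def __post_init__(self):
        if self.lambda_ <= 0 or self.K <= 0:
            raise ValueError("lambda and K must be positive")


def evalue(score: float, params: EvalueParams) -> float:
    """E = K * m * n * exp(-lambda * S)."""
    return params.K * params.m * params.n * math.exp(-params.lambda_ * score)


def bit_score(score: float, params: EvalueParams) -> float:
    return (params.lambda_ * score - math.log(params.K)) / math.log(2.0)


@dataclass(frozen=True)
class Hit:
    """One bait-vs-frame local alignment mapped back to contig coordinates."""

    contig_id: str
    strand: str  # '+' or '-'
    frame: int  # 0..5 (3..5 on the reverse complement)
    start: int  # forward-strand, 0-based half-open
    end: int
    bait_id: str
    bait_start: int  # aligned interval on the bait protein
    bait_end: int
    score: float
    bitscore: float
    e_value: float
    set_label: str  # positive | negative


def six_frame_translate(seq: str) -> list[str]:
    """Translate a DNA sequence in all six frames.

    Frames 0-2 read the forward strand at offsets 0/1/2; frames 3-5 read
    the reverse complement at offsets 0/1/2.  Stop codons are rendered as
    ``*``; codons containing N translate to ``X``.  Trailing partial codons
    are dropped.
    """
    seq = seq.upper()
    bad = set(seq) - set("ACGTN")
    if bad:
        raise ValueError(f"non-DNA characters in sequence: {sorted(bad)}")
    frames = []
    rc = str(Seq(seq).reverse_complement())
    for template in (seq, rc):
        for off in range(3):
            sub = template[off : off + 3 * ((len(template) - off) // 3)]
            frames.append(str(Seq(sub).translate()))
    return frames


def frame_interval_to_contig(
    frame: int, aa_start: int, aa_end: int, contig_len: int
) -> tuple[int, int, str]:
    """Map an amino-acid interval in frame 0-5 to forward contig coordinates."""
    off = frame % 3
    nt_start = off + 3 * aa_start
    nt_end = off + 3 * aa_end
    if frame < 3:
        return nt_start, nt_end, "+"
    return contig_len - nt_end, contig_len - nt_start, "-"


@dataclass
class LocalAlignment:
    score: float
    query_interval: tuple[int, int]
    target_interval: tuple[int, int]
    blocks: tuple[tuple[tuple[int, int], tuple[int, int]], ...]


def local_align(
    query: str, target: str, aligner=None
) -> LocalAlignment:
    """Optimal Smith-Waterman local alignment (BLOSUM62, affine gaps).

    Returns the aligner's first optimal alignment, which is deterministic
    for fixed inputs; ``blocks`` pairs ungapped (query, target) intervals.
    """
    if not query or not target:
        raise ValueError("empty sequence")
    aligner = aligner or _LOCAL
    aln = aligner.align(query, target)[0]
    q_blocks, t_blocks = aln.aligned
    if len(q_blocks) == 0:
        return LocalAlignment(aln.score, (0, 0), (0, 0), ())
    return LocalAlignment(
        score=aln.score,
        query_interval=(int(q_blocks[0][0]), int(q_blocks[-1][1])),
        target_interval=(int(t_blocks[0][0]), int(t_blocks[-1][1])),
        blocks=tuple(
            ((int(q0), int(q1)), (int(t0), int(t1)))
            for (q0, q1), (t0, t1) in zip(q_blocks, t_blocks)
        ),
    )


@dataclass
class Locus:
    """A candidate OR locus: merged same-strand positive hits, padded."""

    contig_id: str
    strand: str
    start: int  # merged hit bounds, forward coordinates
    end: int
    window_start: int  # padded annotation window, clamped to the contig
    window_end: int
    best_bait: str
    best_evalue: float
    hits: list[Hit] = field(default_factory=list)

    def overlaps(self, start: int, end: int) -> bool:
        return start < self.end and self.start < end


def _scan_contig(
    contig: Contig,
    baits: Iterable[tuple[str, str, str]],
    total_frame_len: int,
    max_evalue: float,
    lambda_: float,
    K: float,
    aligner,
) -> list[Hit]:
    frames = six_frame_translate(contig.seq)
    hits: list[Hit] = []
    for bait_id, bait_seq, label in baits:
        params = EvalueParams(lambda_, K, m=len(bait_seq), n=total_frame_len)
        for f, frame_seq in enumerate(frames):
            if not frame_seq:
                continue
            # a Smith-Waterman pass yields one alignment; mask it and
            # re-align so tandem copies and further exons in the same
            # frame are reported as separate hits
            work = frame_seq
            for _ in range(6):
                score = aligner.score(bait_seq, work)
                e = evalue(score, params)
                if e > max_evalue:
                    break
                aln = local_align(bait_seq, work, aligner)
                aa_start, aa_end = aln.target_interval
                if aa_end <= aa_start:
                    break
                start, end, strand = frame_interval_to_contig(
                    f, aa_start, aa_end, len(contig)
                )
                hits.append(
                    Hit(
                        contig_id=contig.id,
                        strand=strand,
                        frame=f,
                        start=start,
                        end=end,
                        bait_id=bait_id,
                        bait_start=aln.query_interval[0],
                        bait_end=aln.query_interval[1],
                        score=score,
                        bitscore=bit_score(score, params),
                        e_value=e,
                        set_label=label,
                    )
                )
                work = work[:aa_start] + "X" * (aa_end - aa_start) + work[aa_end:]
    return hits


def mine(
    contigs: Mapping[str, Contig],
    baits: BaitSet,
    positive_cutoff: float = DEFAULT_POSITIVE_CUTOFF,
    negative_cutoff: float = DEFAULT_NEGATIVE_CUTOFF,
    lambda_: float = DEFAULT_LAMBDA,
    K: float = DEFAULT_K,
    padding: int = LOCUS_PADDING,
    max_intron_gap: int = 5000,
) -> tuple[list[Locus], list[Hit]]:
    """Mine candidate OR loci from contigs under the two retention rules.

    Returns the retained loci and the full hit table (positive and
    negative hits at or below the respective cut-offs).  Overlapping
    positive hits on the same strand of a contig are merged into one
    locus.  Hits of the *same* bait whose bait intervals are essentially
    complementary also merge across genomic gaps up to ``max_intron_gap``:
    these are the exon-by-exon seeds of a spliced gene.  A locus overlapped
    by any qualifying negative hit is discarded.
    """
    if positive_cutoff <= 0 or negative_cutoff <= 0:
        raise ValueError("e-value cut-offs must be positive")
    aligner = _LOCAL
    total_frame_len = sum(
        len(f) for c in contigs.values() for f in six_frame_translate(c.seq)
    )
    bait_list = [(i, s, "positive") for i, s in baits.positive.items()] + [
        (i, s, "negative") for i, s in baits.negative.items()
    ]
    all_hits: list[Hit] = []
    for contig in contigs.values():
        all_hits.extend(
            _scan_contig(
                contig,
                bait_list,
                total_frame_len,
                max(positive_cutoff, negative_cutoff),
                lambda_,
                K,
                aligner,
            )
        )
    pos_hits = [
        h
        for h in all_hits
        if h.set_label == "positive" and h.e_value <= positive_cutoff
    ]
    neg_hits = [
        h
        for h in all_hits
        if h.set_label == "negative" and h.e_value <= negative_cutoff
    ]
    loci: list[Locus] = []
    for (contig_id, strand) in sorted(
        {(h.contig_id, h.strand) for h in pos_hits}
    ):
        group = sorted(
            (h for h in pos_hits if h.contig_id == contig_id and h.strand == strand),
            key=lambda h: h.start,
        )
        clen = len(contigs[contig_id])
        current: list[Hit] = []
        for h in group:
            if current and _should_merge(current, h, max_intron_gap):
                current.append(h)
            else:
                if current:
                    loci.append(_make_locus(contig_id, strand, current, clen, padding))
                current = [h]
        if current:
            loci.append(_make_locus(contig_id, strand, current, clen, padding))
    retained = [
        loc
        for loc in loci
        if not any(
            h.contig_id == loc.contig_id and loc.overlaps(h.start, h.end)
            for h in neg_hits
        )
    ]
    retained.sort(key=lambda l: (l.contig_id, l.start, l.strand))
    return retained, all_hits


def _should_merge(current: list[Hit], h: Hit, max_intron_gap: int) -> bool:
    cur_end = max(x.end for x in current)
    if h.start < cur_end:
        return True
    if h.start - cur_end > max_intron_gap:
        return False
    # spliced-gene bridge: the same bait, with the genomically downstream
    # hit continuing the bait where the upstream hit left off (in bait
    # orientation, i.e. reversed for minus-strand genes).  Tandem copies of
    # a family re-cover the bait from the start instead and stay separate.
    for x in current:
        if x.bait_id != h.bait_id:
            continue
        overlap = min(x.bait_end, h.bait_end) - max(x.bait_start, h.bait_start)
        smaller = min(x.bait_end - x.bait_start, h.bait_end - h.bait_start)
        if smaller <= 0 or overlap > 0.35 * smaller:
            continue
        continues = (
            h.bait_start >= x.bait_end - 40
            if h.strand == "+"
            else h.bait_end <= x.bait_start + 40
        )
        if continues:
            return True
    return False


def _make_locus(
    contig_id: str, strand: str, hits: list[Hit], contig_len: int, padding: int
) -> Locus:
    start = min(h.start for h in hits)
    end = max(h.end for h in hits)
    best = min(hits, key=lambda h: (h.e_value, -h.score, h.bait_id))
    return Locus(
        contig_id=contig_id,
        strand=strand,
        start=start,
        end=end,
        window_start=max(0, start - padding),
        window_end=min(contig_len, end + padding),
        best_bait=best.bait_id,
        best_evalue=best.e_value,
        hits=sorted(hits, key=lambda h: h.e_value),
    )
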