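"""GPCR feature annotation for OR proteins.

Topology is segmented from Kyte-Doolittle hydropathy: a sliding-window
average above threshold marks helix cores, each core is expanded to its
surrounding run of hydrophobic residues and clamped to plausible helix
length, and when exactly seven helices result the inter-helix regions are
labelled assuming an extracellular N-terminus (Nter, TM1, IN1, TM2, OUT1,
TM3, IN2, TM4, OUT2, TM5, IN3, TM6, OUT3, TM7, Cter).  On that frame the
annotators report N-glycosylation sequons (N-X-S/T, X != P), count the EC2
(OUT2) cysteines that split fish ORs into one-cysteine and three-cysteine
subgroups, and read the MAYDRY/MAYERY variant at the TM3/IN2 boundary.

Conserved motifs are extracted from a star multiple alignment by summed
per-column information content over ungapped windows — a deterministic
conservation-block analogue of de novo motif discovery.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .classify import global_alignment, identity_matrix

KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
    "X": 0.0, "*": 0.0,
}

SEGMENT_ORDER = (
    "Nter", "TM1", "IN1", "TM2", "OUT1", "TM3", "IN2",
    "TM4", "OUT2", "TM5", "IN3", "TM6", "OUT3", "TM7", "Cter",
)


@dataclass(frozen=True)
class Segment:
    label: str
    start: int
    end: int


@dataclass
class TopologyMap:
    """Tiling of a protein into Nter/TM/loop/Cter segments.

    ``helices`` holds the detected hydrophobic stretches even when their
    count differs from seven and the map is left unresolved.
    """

    length: int
    segments: list[Segment]
    resolved: bool
    helices: list[tuple[int, int]] = None  # type: ignore[assignment]

    def __post_init__(self):
        if self.resolved:
            pos = 0
            for seg in self.segments:
                if seg.start != pos or seg.end < seg.start:
                    raise ValueError("segments must tile the protein")
                pos = seg.end
            if pos != self.length:
                raise ValueError("segments must tile the protein")

    def segment(self, label: str) -> Segment:
        for seg in self.segments:
            if seg.label == label:
                return seg
        raise KeyError(label)

    def label_of(self, position: int) -> str:
        for seg in self.segments:
            if seg.start <= position < seg.end:
                return seg.label
        raise IndexError(position)

    @property
    def tm_count(self) -> int:
        return sum(1 for s in self.segments if s.label.startswith("TM"))


def hydropathy_profile(protein: str, window: int = 19) -> np.ndarray:
    """Sliding-window mean Kyte-Doolittle hydropathy, one value per residue.

    Windows are clipped at the termini (the mean runs over the available
    residues), so the profile has the same length as the protein.
    """
    values = np.array([KYTE_DOOLITTLE.get(c, 0.0) for c in protein])
    half = window // 2
    out = np.empty(len(values))
    for i in range(len(values)):
        lo, hi = max(0, i - half), min(len(values), i + half + 1)
        out[i] = values[lo:hi].mean()
    return out


def predict_topology(
    protein: str,
    window: int = 19,
    threshold: float = 1.5,
    tm_min: int = 17,
    tm_max: int = 30,
) -> TopologyMap:
    """Hydropathy-based 7-TM segmentation.

    Maximal runs of smoothed hydropathy above ``threshold`` seed helix
    cores; each core expands to the maximal flanking run of residues with
    positive raw hydropathy and is then clamped into [tm_min, tm_max].
    Anything other than exactly seven helices leaves the topology
    unresolved and per-domain analyses skip the protein.
    """
    if len(protein) < 200:
        raise ValueError("protein too short for topology prediction")
    smoothed = hydropathy_profile(protein, window)
    raw = np.array([KYTE_DOOLITTLE.get(c, 0.0) for c in protein])
    above = smoothed > threshold
    runs: list[tuple[int, int]] = []
    i = 0
    while i < len(above):
        if above[i]:
            j = i
            while j < len(above) and above[j]:
                j += 1
            runs.append((i, j))
            i = j
        else:
            i += 1
    helices: list[tuple[int, int]] = []
    for a, b in runs:
        lo, hi = a, b
        while lo > 0 and raw[lo - 1] > 0:
            lo -= 1
        while hi < len(raw) and raw[hi] > 0:
            hi += 1
        if helices and lo <= helices[-1][1]:
            helices[-1] = (helices[-1][0], max(hi, helices[-1][1]))
            continue
        helices.append((lo, hi))
    clamped: list[tuple[int, int]] = []
    for lo, hi in helices:
        length = hi - lo
        centre = (lo + hi) // 2
        if length > tm_max:
            lo = centre - tm_max // 2
            hi = lo + tm_max
        elif length < tm_min:
            grow = tm_min - length
            lo = max(0, lo - grow // 2)
            hi = min(len(protein), lo + tm_min)
            lo = max(0, hi - tm_min)
        if clamped and lo < clamped[-1][1]:
            lo = clamped[-1][1]
        if hi - lo >= tm_min:
            clamped.append((lo, hi))
    if len(clamped) != 7:
        return TopologyMap(len(protein), [], resolved=False, helices=clamped)
    loop_labels = ["IN1", "OUT1", "IN2", "OUT2", "IN3", "OUT3"]
    segments = [Segment("Nter", 0, clamped[0][0])]
    for k, (lo, hi) in enumerate(clamped):
        segments.append(Segment(f"TM{k + 1}", lo, hi))
        if k < 6:
            segments.append(Segment(loop_labels[k], hi, clamped[k + 1][0]))
    segments.append(Segment("Cter", clamped[6][1], len(protein)))
    return TopologyMap(len(protein), segments, resolved=True, helices=clamped)


# --- sequons ----------------------------------------------------------------


@dataclass(frozen=True)
class Sequon:
    position: int  # 1-based position of the N
    context: str  # the N-X-S/T tripeptide
    n_terminal: bool = False  # 5'-most sequon inside the Nter segment


def find_sequons(
    protein: str, topology: TopologyMap | None = None
) -> list[Sequon]:
    """All N-X-[S/T] sequons with X != P, 1-based, overlapping scan.

    When a resolved topology is supplied, the 5'-most sequon falling in the
    Nter segment is flagged: an N-proximal site is required for OR
    membrane trafficking and is present in all fish ORs described to date.
    """
    hits = []
    for i in range(len(protein) - 2):
        if (
            protein[i] == "N"
            and protein[i + 1] != "P"
            and protein[i + 2] in "ST"
        ):
            hits.append((i + 1, protein[i : i + 3]))
    flagged = None
    if topology is not None and topology.resolved:
        nter = topology.segment("Nter")
        for pos, _ in hits:
            if nter.start < pos <= nter.end:
                flagged = pos
                break
    return [
        Sequon(pos, ctx, n_terminal=(pos == flagged)) for pos, ctx in hits
    ]


# --- cysteine subgroups -----------------------------------------------------


@dataclass(frozen=True)
class SubgroupCall:
    gene_id: str
    ec2_cysteine_count: int
    subgroup: str  # oneC | threeC | other
    maydry_block: str
    maydry_variant: str  # D | E | other


_MAYDRY = "MAYDRY"

_BLOSUM = None


def _blosum():
    global _BLOSUM
    if _BLOSUM is None:
        from Bio.Align import substitution_matrices

        _BLOSUM = substitution_matrices.load("BLOSUM62")
    return _BLOSUM


def cysteine_subgroup(
    gene_id: str, protein: str, topology: TopologyMap
) -> SubgroupCall | None:
    """EC2 cysteine count and MAYDRY variant for one protein.

    Counts cysteines in the OUT2 (EC2) segment and reads position 4 of the
    six-residue block best matching the MAYDRY consensus around the
    TM3/IN2 boundary; D is the classical motif, E the variant associated
    with the single-cysteine subgroup.  Returns None when the topology is
    unresolved.
    """
    if not topology.resolved:
        return None
    out2 = topology.segment("OUT2")
    cys = protein[out2.start : out2.end].count("C")
    subgroup = {1: "oneC", 3: "threeC"}.get(cys, "other")
    tm3 = topology.segment("TM3")
    in2 = topology.segment("IN2")
    lo = max(0, tm3.end - 8)
    hi = min(len(protein) - 6, in2.end)
    matrix = _blosum()
    best_pos, best_score = lo, -math.inf
    for i in range(lo, hi + 1):
        block = protein[i : i + 6]
        if len(block) < 6:
            break
        score = sum(matrix[a][b] for a, b in zip(_MAYDRY, block))
        if score > best_score:
            best_pos, best_score = i, score
    block = protein[best_pos : best_pos + 6]
    variant = block[3] if block[3] in "DE" else "other"
    return SubgroupCall(gene_id, cys, subgroup, block, variant)


# --- star MSA and conserved motifs ------------------------------------------


def star_msa(proteins: Mapping[str, str]) -> pd.DataFrame:
    """Star multiple alignment projected onto the medoid sequence.

    The medoid (highest mean pairwise identity) anchors the alignment;
    every other sequence is globally aligned to it and its residues are
    placed at the medoid positions they align to (insertions relative to
    the medoid are dropped).  Adequate for conserved-block extraction.

    Returns a DataFrame of single characters, rows = sequence ids,
    columns = medoid positions; '-' marks gaps.
    """
    if len(proteins) < 2:
        raise ValueError("need >= 2 sequences")
    ids = sorted(proteins)
    matrix = identity_matrix(proteins)
    mean_identity = matrix.mean(axis=1)
    medoid = mean_identity.idxmax()
    width = len(proteins[medoid])
    rows = {}
    for gid in ids:
        if gid == medoid:
            rows[gid] = list(proteins[medoid])
            continue
        aln = global_alignment(proteins[medoid], proteins[gid])
        row = ["-"] * width
        for (m0, m1), (o0, o1) in zip(*aln.aligned):
            for k in range(m1 - m0):
                row[m0 + k] = proteins[gid][o0 + k]
        rows[gid] = row
    return pd.DataFrame.from_dict(rows, orient="index")


_AA20 = "ACDEFGHIKLMNPQRSTVWY"


def column_information(column: Sequence[str]) -> float:
    """Information content (bits) of one MSA column, gaps ignored,
    with the small-sample correction e_n = 19 / (2 ln2 n)."""
    residues = [c for c in column if c in _AA20]
    n = len(residues)
    if n == 0:
        return 0.0
    _, counts = np.unique(residues, return_counts=True)
    freqs = counts / n
    entropy = -(freqs * np.log2(freqs)).sum()
    correction = (len(_AA20) - 1) / (2 * math.log(2) * n)
    return max(0.0, math.log2(len(_AA20)) - entropy - correction)


@dataclass
class MotifReport:
    start: int  # column interval in the MSA
    width: int
    score: float  # summed column information (bits)
    pfm: pd.DataFrame  # 20 x width, columns normalised
    information: list[float]
    consensus: str
    location: str | None = None  # majority topology segment label


def extract_conserved_motifs(
    msa: pd.DataFrame,
    k: int = 4,
    width_range: tuple[int, int] = (6, 15),
    max_gap_fraction: float = 0.2,
    topologies: Mapping[str, TopologyMap] | None = None,
) -> list[MotifReport]:
    """Top-k non-overlapping conservation blocks of an alignment.

    Every window of width 6-15 whose columns all have <= 20% gaps is
    scored by summed corrected information content; windows are taken
    greedily by score (deterministic, score then leftmost).  When resolved
    topologies cover at least half the members, each motif gets the
    majority-vote segment label of its central column.
    """
    if msa.shape[0] < 10:
        raise ValueError("need an alignment of >= 10 sequences")
    lo, hi = width_range
    if msa.shape[1] < lo:
        raise ValueError("alignment shorter than the minimum motif width")
    n_cols = msa.shape[1]
    cols = [msa.iloc[:, j].tolist() for j in range(n_cols)]
    gap_ok = [
        sum(1 for c in col if c not in _AA20) <= max_gap_fraction * len(col)
        for col in cols
    ]
    info = [column_information(col) for col in cols]
    candidates = []
    for width in range(lo, min(hi, n_cols) + 1):
        for start in range(n_cols - width + 1):
            if not all(gap_ok[start : start + width]):
                continue
            score = sum(info[start : start + width])
            candidates.append((score, start, width))
    candidates.sort(key=lambda c: (-c[0], c[1], c[2]))
    chosen: list[tuple[float, int, int]] = []
    for score, start, width in candidates:
        if len(chosen) == k:
            break
        if any(
            start < s + w and s < start + width for _, s, w in chosen
        ):
            continue
        chosen.append((score, start, width))
    chosen.sort(key=lambda c: -c[0])
    reports = []
    for score, start, width in chosen:
        counts = np.zeros((len(_AA20), width))
        for j in range(width):
            for c in cols[start + j]:
                if c in _AA20:
                    counts[_AA20.index(c), j] += 1
        sums = counts.sum(axis=0)
        sums[sums == 0] = 1.0
        pfm = pd.DataFrame(counts / sums, index=list(_AA20))
        consensus = "".join(
            _AA20[pfm[j].to_numpy().argmax()] for j in range(width)
        )
        location = None
        if topologies:
            location = _majority_location(
                msa, start + width // 2, topologies
            )
        reports.append(
            MotifReport(
                start=start,
                width=width,
                score=score,
                pfm=pfm,
                information=info[start : start + width],
                consensus=consensus,
                location=location,
            )
        )
    return reports


def _majority_location(
    msa: pd.DataFrame, column: int, topologies: Mapping[str, TopologyMap]
) -> str | None:
    votes: dict[str, int] = {}
    resolved = 0
    for gid in msa.index:
        topo = topologies.get(gid)
        if topo is None or not topo.resolved:
            continue
        resolved += 1
        # ungapped position of this sequence at the MSA column
        row = msa.loc[gid].tolist()
        if row[column] == "-":
            continue
        pos = sum(1 for c in row[:column] if c != "-")
        if pos < topo.length:
            label = topo.label_of(pos)
            votes[label] = votes.get(label, 0) + 1
    if resolved < 0.5 * msa.shape[0] or not votes:
        return None
    return max(sorted(votes), key=lambda lab: votes[lab])


def write_meme_minimal(
    motifs: Sequence[MotifReport], path, background: float = 0.05
) -> None:
    """Write motif PFMs in MEME minimal text format."""
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= " + _AA20 + "\n\n")
        fh.write(
            "Background letter frequencies\n"
            + " ".join(f"{c} {background:.5f}" for c in _AA20)
            + "\n\n"
        )
        for i, m in enumerate(motifs, start=1):
            fh.write(f"MOTIF motif_{i} {m.consensus}\n")
            fh.write(
                f"letter-probability matrix: alength= {len(_AA20)} "
                f"w= {m.width} nsites= 0 E= 0\n"
            )
            for j in range(m.width):
                fh.write(
                    " ".join(f"{m.pfm.iloc[a, j]:.6f}" for a in range(len(_AA20)))
                    + "\n"
                )
            fh.write("\n")
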