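"""Repertoire classification: identities, families, names, NJ tree.

OR repertoires are conventionally partitioned by pairwise amino-acid
identity: genes connected at >= 40% identity form a family, and within a
family the >= 60% components form subfamilies (Glusman-style nomenclature).
Identity is computed from a global (Needleman-Wunsch) alignment under
BLOSUM62 with affine gaps; the denominator is the number of alignment
columns with at least one residue, so truncations are penalised.

Near-identical ortholog/paralog groups are maximal cliques in the >= 99%
identity graph, reported with their species composition.  The descriptive
tree is neighbour joining on d = 1 - identity/100 (scikit-bio), with
negative branch lengths clamped to zero.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices

_BLOSUM62 = substitution_matrices.load("BLOSUM62")


def _make_global_aligner(open_gap: float = -11.0, extend_gap: float = -1.0):
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = _BLOSUM62
    aligner.open_gap_score = open_gap
    aligner.extend_gap_score = extend_gap
    return aligner


_GLOBAL = _make_global_aligner()


def global_alignment(a: str, b: str):
    """Best global alignment of two protein sequences (deterministic pick)."""
    if not a or not b:
        raise ValueError("empty sequence")
    return _GLOBAL.align(a, b)[0]


def global_identity(a: str, b: str) -> float:
    """Percent identity from the global alignment, in [0, 100].

    Denominator: alignment columns with at least one residue (a gap against
    a residue counts as a mismatch; gap-gap columns cannot occur in a
    pairwise alignment).
    """
    aln = global_alignment(a, b)
    matches = 0
    aligned_cols = 0
    for (a0, a1), (b0, b1) in zip(*aln.aligned):
        aligned_cols += a1 - a0
        for i in range(a1 - a0):
            if a[a0 + i] == b[b0 + i]:
                matches += 1
    total_cols = aln.length  # includes gap columns
    if total_cols == 0:
        return 0.0
    return 100.0 * matches / total_cols


def identity_matrix(proteins: Mapping[str, str]) -> pd.DataFrame:
    """Symmetric pairwise percent-identity matrix (diagonal 100)."""
    ids = sorted(proteins)
    mat = np.full((len(ids), len(ids)), 100.0)
    for i, j in itertools.combinations(range(len(ids)), 2):
        pid = global_identity(proteins[ids[i]], proteins[ids[j]])
        mat[i, j] = mat[j, i] = pid
    return pd.DataFrame(mat, index=ids, columns=ids)


def _components(matrix: pd.DataFrame, ids: Sequence[str], threshold: float):
    """Single-linkage connected components at >= threshold identity."""
    idx = {g: k for k, g in enumerate(ids)}
    parent = list(range(len(ids)))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for a, b in itertools.combinations(ids, 2):
        if matrix.at[a, b] >= threshold:
            ra, rb = find(idx[a]), find(idx[b])
            if ra != rb:
                parent[ra] = rb
    groups: dict[int, list[str]] = {}
    for g in ids:
        groups.setdefault(find(idx[g]), []).append(g)
    comps = [sorted(v) for v in groups.values()]
    # canonical order: decreasing size, ties by smallest member id
    comps.sort(key=lambda c: (-len(c), c[0]))
    return comps


def _family_letters():
    """A, B, ..., Z, AA, AB, ... — family labels in canonical order."""
    n = 1
    while True:
        for combo in itertools.product(
            "ABCDEFGHIJKLMNOPQRSTUVWXYZ", repeat=n
        ):
            yield "".join(combo)
        n += 1


@dataclass
class FamilyAssignment:
    """Family/subfamily membership for a repertoire."""

    family_of: dict[str, str]
    subfamily_of: dict[str, int]
    families: dict[str, list[str]] = field(default_factory=dict)

    def members(self, family: str) -> list[str]:
        return self.families[family]


def assign_families(
    matrix: pd.DataFrame,
    family_threshold: float = 40.0,
    subfamily_threshold: float = 60.0,
    linkage: str = "single",
) -> FamilyAssignment:
    """Families (>= 40%) and subfamilies (>= 60%) from the identity matrix.

    Families are single-linkage connected components at the family
    threshold, labelled A, B, ... in decreasing size (ties by lexicographic
    smallest member).  Subfamilies are components at the subfamily
    threshold within each family, numbered from 1 by decreasing size.
    Complete linkage is available for sensitivity checks.
    """
    if linkage not in {"single", "complete"}:
        raise ValueError(f"unknown linkage {linkage!r}")
    ids = sorted(matrix.index)
    if linkage == "single":
        fam_comps = _components(matrix, ids, family_threshold)
    else:
        fam_comps = _complete_linkage(matrix, ids, family_threshold)
    family_of: dict[str, str] = {}
    subfamily_of: dict[str, int] = {}
    families: dict[str, list[str]] = {}
    for label, comp in zip(_family_letters(), fam_comps):
        families[label] = comp
        for g in comp:
            family_of[g] = label
        if linkage == "single":
            sub_comps = _components(matrix, comp, subfamily_threshold)
        else:
            sub_comps = _complete_linkage(matrix, comp, subfamily_threshold)
        for k, sub in enumerate(sub_comps, start=1):
            for g in sub:
                subfamily_of[g] = k
    return FamilyAssignment(family_of, subfamily_of, families)


def _complete_linkage(matrix, ids, threshold):
    """Agglomerative complete linkage cut at >= threshold identity."""
    clusters = [[g] for g in sorted(ids)]
    merged = True
    while merged and len(clusters) > 1:
        merged = False
        best = None
        for i, j in itertools.combinations(range(len(clusters)), 2):
            worst = min(
                matrix.at[a, b]
                for a in clusters[i]
                for b in clusters[j]
            )
            if worst >= threshold and (best is None or worst > best[0]):
                best = (worst, i, j)
        if best is not None:
            _, i, j = best
            clusters[i] = sorted(clusters[i] + clusters[j])
            del clusters[j]
            merged = True
    clusters.sort(key=lambda c: (-len(c), c[0]))
    return clusters


@dataclass(frozen=True)
class NearIdenticalGroup:
    members: tuple[str, ...]
    species: tuple[str, ...]
    size: int
    kind: str  # pair | triplet | quadruplet | larger


_KINDS = {2: "pair", 3: "triplet", 4: "quadruplet"}


def find_near_identical(
    matrix: pd.DataFrame,
    species_of: Mapping[str, str],
    threshold: float = 99.0,
) -> list[NearIdenticalGroup]:
    """Maximal cliques of genes all pairwise >= threshold percent identical.

    Cross-species groups flag putative orthologs retained since speciation;
    within-species groups flag recent paralog duplications.
    """
    if not 0 < threshold <= 100:
        raise ValueError("threshold must be in (0, 100]")
    import networkx as nx

    g = nx.Graph()
    ids = sorted(matrix.index)
    g.add_nodes_from(ids)
    for a, b in itertools.combinations(ids, 2):
        if matrix.at[a, b] >= threshold:
            g.add_edge(a, b)
    groups = []
    for clique in nx.find_cliques(g):
        if len(clique) < 2:
            continue
        members = tuple(sorted(clique))
        groups.append(
            NearIdenticalGroup(
                members=members,
                species=tuple(species_of[m] for m in members),
                size=len(members),
                kind=_KINDS.get(len(members), "larger"),
            )
        )
    groups.sort(key=lambda grp: (-grp.size, grp.members))
    return groups


def nj_tree(matrix: pd.DataFrame) -> str:
    """Neighbour-joining Newick tree from d = 1 - identity/100.

    Descriptive only (no support values); negative branch lengths are
    clamped to zero.
    """
    if len(matrix) < 3:
        raise ValueError("need at least 3 taxa for a tree")
    from skbio import DistanceMatrix
    from skbio.tree import nj

    ids = list(matrix.index)
    dist = 1.0 - matrix.loc[ids, ids].to_numpy() / 100.0
    np.fill_diagonal(dist, 0.0)
    dist = (dist + dist.T) / 2.0
    tree = nj(DistanceMatrix(dist, ids), neg_as_zero=True)
    return tree.write_newick() if hasattr(tree, "write_newick") else str(tree)


# --- gene naming -----------------------------------------------------------

_STATUS_LETTER = {"complete": "", "pseudogene": "p", "edge": "e", "fragment": "f"}
_LETTER_STATUS = {"": "complete", "p": "pseudogene", "e": "edge", "f": "fragment"}

_NAME_RE = re.compile(r"^([A-Z]{3})OR([pef]?)\.([A-Z]+)(\d{3})$")


def canonical_name(
    species_symbol: str, status: str, family: str, serial: int
) -> str:
    """Canonical repertoire gene name, e.g. ``BRIORe.E041``.

    Species symbol (three letters, upper-cased) + "OR" + status letter
    (p pseudogene / e edge / f fragment; complete genes carry none) + "." +
    family letter(s) + zero-padded three-digit serial.
    """
    if status not in _STATUS_LETTER:
        raise ValueError(f"unknown status {status!r}")
    if not (1 <= serial <= 999):
        raise ValueError(f"serial {serial} out of range 1..999")
    sym = species_symbol[:3].upper()
    if len(sym) != 3 or not sym.isalpha():
        raise ValueError(f"bad species symbol {species_symbol!r}")
    if not family.isalpha():
        raise ValueError(f"bad family label {family!r}")
    return f"{sym}OR{_STATUS_LETTER[status]}.{family.upper()}{serial:03d}"


def parse_name(name: str) -> tuple[str, str, str, int]:
    """Inverse of :func:`canonical_name` -> (species, status, family, serial)."""
    m = _NAME_RE.match(name)
    if not m:
        raise ValueError(f"unparseable gene name {name!r}")
    sym, letter, family, serial = m.groups()
    return sym, _LETTER_STATUS[letter], family, int(serial)
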