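"""Reference summary tables from the five-cichlid OR repertoire survey.

These are transcriptions of the printed per-species gene counts, pseudogene
lesion counts and intron tables of the survey whose analysis this package
re-implements (species: *O. niloticus* Til, *H. burtoni* Bur, *M. zebra*
Zeb, *N. brichardi* Bri, *P. nyererei* Nye).  They serve two purposes:
fixing the report layouts the pipeline emits, and arithmetic
reconciliation — the totals, ratios and tallies the survey quotes in its
text must be recomputable from its own tables.
"""

from __future__ import annotations

import pandas as pd

SPECIES = ["Til", "Bur", "Zeb", "Bri", "Nye"]

#: complete-gene counts by coding-exon class (per-species survey table)
GENE_COUNTS = pd.DataFrame(
    {
        "Til": {"one_exon": 146, "multi_exon": 12},
        "Bur": {"one_exon": 78, "multi_exon": 12},
        "Zeb": {"one_exon": 94, "multi_exon": 8},
        "Bri": {"one_exon": 62, "multi_exon": 7},
        "Nye": {"one_exon": 81, "multi_exon": 7},
    }
)[SPECIES]

#: pseudogene lesion counts per species
PSEUDOGENE_LESIONS = pd.DataFrame(
    {
        "Til": {"frameshift": 4, "in_frame_stop": 3},
        "Zeb": {"frameshift": 8, "in_frame_stop": 5},
        "Nye": {"frameshift": 9, "in_frame_stop": 3},
        "Bri": {"frameshift": 6, "in_frame_stop": 7},
        "Bur": {"frameshift": 6, "in_frame_stop": 3},
    }
)[["Til", "Zeb", "Nye", "Bri", "Bur"]]

#: intron table of the survey: one row per intron of each spliced OR gene.
#: columns: gene, n_coding_exons, last codon context, phase, 1-based codon
#: position, topology region.
_INTRON_ROWS = [
    # -- genes with 2 coding exons (one intron) --
    ("NyeORs.A033", 2, "GTC.AG", 2, 159, "TM4"),
    ("NyeORs.W129", 2, "CAA.CAG", 0, 50, "IN1"),
    ("NyeORs.W131", 2, "AAC.AAG", 0, 50, "IN1"),
    ("NyeORs.W130", 2, "CAC.CAG", 0, 50, "IN1/TM2"),
    ("NyeORs.W132", 2, "CAC.CAG", 0, 52, "IN1"),
    ("BriORs.W112", 2, "CAA.CAG", 0, 50, "IN1"),
    ("BriORs.W113", 2, "CAA.CAG", 0, 50, "IN1"),
    ("BriORs.W114", 2, "AAC.AA", 2, 41, "TM1"),
    ("BriORs.W115", 2, "CAG.CAG", 0, 52, "IN1"),
    ("BriORs.W116", 2, "TAT.CAG", 0, 49, "IN1"),
    ("ZebORs.K090", 2, "AAG.TAT", 0, 24, "Nter"),
    ("ZebORs.W140", 2, "CAA.CAG", 0, 50, "IN1"),
    ("ZebORs.W141", 2, "AAA.CA", 2, 43, "IN1"),
    ("ZebORs.W142", 2, "AAA.CAC", 0, 51, "IN1"),
    ("ZebORs.W139", 2, "AGT.ATC", 0, 52, "IN1"),
    ("BurORs.W131", 2, "CAA.CAG", 0, 50, "IN1"),
    ("BurORs.W148", 2, "TAT.CAG", 0, 49, "IN1"),
    ("BurORs.W132", 2, "CAC.CAG", 0, 50, "IN1"),
    ("BurORs.W133", 2, "CAC.CAG", 0, 52, "IN1"),
    ("BurORs.W134", 2, "AAC.AAG", 0, 50, "IN1"),
    ("BurORs.W135", 2, "AAA.CA", 2, 43, "IN1"),
    ("BurORs.V144", 2, "CGA.CAC", 0, 59, "IN1"),
    ("BurORs.AB153", 2, "AAC.AGT", 0, 77, "IN1"),
    ("TilORs.K143", 2, "AAG.TAT", 0, 24, "Nter"),
    ("TilORs.W238", 2, "CAC.CAG", 0, 50, "IN1"),
    ("TilORs.W239", 2, "AAC.CGG", 0, 50, "IN1"),
    ("TilORs.W240", 2, "CAC.CAG", 0, 50, "IN1"),
    ("TilORs.W241", 2, "CAC.CAG", 0, 50, "IN1"),
    ("TilORs.W243", 2, "AAA.CAC", 0, 51, "IN1"),
    ("TilORs.AB275", 2, "TAT.GTG", 0, 72, "TM1"),
    ("TilORs.V262", 2, "CGA.CAC", 0, 59, "IN1"),
    # -- genes with 3 coding exons (two introns) --
    ("NyeORs.I079", 3, "GAG.AGG", 0, 121, "IN2"),
    ("NyeORs.I079", 3, "ACA.ATC", 0, 232, "OUT3"),
    ("NyeORs.U128", 3, "TAT.CA", 2, 15, "Nter"),
    ("NyeORs.U128", 3, "CAC.CAG", 0, 54, "IN1"),
    ("BriORs.U109", 3, "TAT.CAG", 0, 16, "Nter"),
    ("BriORs.U109", 3, "CAG.GAT", 0, 56, "OUT1"),
    ("ZebORs.U137", 3, "TAT.CAG", 0, 16, "Nter"),
    ("ZebORs.U137", 3, "CAC.CAG", 0, 54, "IN1"),
    ("ZebORs.I082", 3, "GAC.AG", 2, 125, "IN2"),
    ("ZebORs.I082", 3, "GAC.ATC", 0, 200, "OUT2-TM5"),
    ("BurORs.I076", 3, "GAC.AG", 2, 125, "IN2"),
    ("BurORs.I076", 3, "ATC.TAT", 0, 201, "OUT2"),
    ("BurORs.U130", 3, "TAT.CA", 2, 15, "Nter"),
    ("BurORs.U130", 3, "CAC.CAG", 0, 54, "IN1"),
    ("TilORs.I128", 3, "GAC.AG", 2, 120, "IN2"),
    ("TilORs.I128", 3, "AAC.AT", 2, 194, "OUT2-TM5"),
    ("TilORs.I129", 3, "GAC.AG", 2, 125, "IN2"),
    ("TilORs.I129", 3, "ATC.TAT", 0, 201, "OUT2-TM5"),
    ("TilORs.I130", 3, "GAC.AG", 2, 120, "IN2"),
    ("TilORs.I130", 3, "ATC.TAT", 0, 196, "OUT2-TM5"),
    ("TilORs.U236", 3, "TAT.CA", 2, 15, "Nter"),
    ("TilORs.U236", 3, "CAC.CAG", 0, 54, "IN1"),
    # -- genes with 4 coding exons (three introns) --
    ("BriORs.V122", 4, "CAC.AG", 2, 80, "IN1"),
    ("BriORs.V122", 4, "CTT.CTG", 0, 127, "OUT1"),
    ("BriORs.V122", 4, "GTG.CAG", 0, 269, "TM6"),
    ("ZebORs.V149", 4, "CAC.AG", 2, 62, "IN1"),
    ("ZebORs.V149", 4, "CTT.CTG", 0, 109, "OUT1"),
    ("ZebORs.V149", 4, "GTG.CAG", 0, 251, "TM6"),
    ("BurORs.T129", 4, "CCC.AG", 2, 48, "IN1"),
    ("BurORs.T129", 4, "AAC.AAG", 0, 96, "OUT1"),
    ("BurORs.T129", 4, "GTC.CAG", 0, 184, "TM5"),
]

INTRON_TABLE = pd.DataFrame(
    _INTRON_ROWS,
    columns=[
        "gene",
        "n_coding_exons",
        "last_codon",
        "intron_phase",
        "codon_position",
        "intron_position",
    ],
)


# --- arithmetic reconciliation ---------------------------------------------


def total_complete_genes() -> int:
    """Sum of per-species complete-gene counts (all coding-exon classes)."""
    return int(GENE_COUNTS.sum().sum())


def total_multi_exon_genes() -> int:
    return int(GENE_COUNTS.loc["multi_exon"].sum())


def multi_exon_percent() -> int:
    """Share of complete genes with >1 coding exon, nearest integer."""
    return round(100 * total_multi_exon_genes() / total_complete_genes())


def total_frameshift_pseudogenes() -> int:
    return int(PSEUDOGENE_LESIONS.loc["frameshift"].sum())


def total_pseudogene_lesions() -> int:
    return int(PSEUDOGENE_LESIONS.sum().sum())


def single_intron_entries() -> pd.DataFrame:
    return INTRON_TABLE[INTRON_TABLE.n_coding_exons == 2]


def n_single_intron_genes() -> int:
    return int(single_intron_entries().gene.nunique())


def n_single_intron_phase0() -> int:
    sub = single_intron_entries()
    return int((sub.intron_phase == 0).sum())


def n_three_exon_genes() -> int:
    sub = INTRON_TABLE[INTRON_TABLE.n_coding_exons == 3]
    return int(sub.gene.nunique())
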