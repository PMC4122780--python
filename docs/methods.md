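# Methods

This note documents the models and algorithms in `orfish`, the defaults
and why they were chosen, what the synthetic data do and do not emulate,
and the package's known limitations.

## 1. Mining by translated homology

Each contig is translated in all six frames (stops rendered `*`, N-codons
`X`) and every bait protein is aligned to every frame with Smith–Waterman
(BLOSUM62, gap open −11, extend −1, via Biopython's `PairwiseAligner`).
Because one optimal local alignment per bait×frame would hide tandem gene
copies and the further exons of spliced genes, the aligned target region
is masked and re-aligned (up to six rounds) until the score drops below
the reporting threshold — a stand-in for the multiple-HSP output of a
translated BLAST search.

Scores get Karlin–Altschul e-values `E = K·m·n·exp(−λS)` with the
standard gapped-BLOSUM62 parameters λ = 0.267, K = 0.041, `m` the bait
length and `n` the total translated search space. Retention follows two
rules: a locus needs at least one positive-bait hit at `E ≤ 1e-50`, and
no negative-bait (non-OR GPCR) hit overlapping it at the same cut-off.
The negative rule is evaluated per locus by coordinate overlap on either
strand. A later protein-level re-check against the positive set applies
the stricter `1e-100` to complete models; incomplete copies (pseudogene,
edge, fragment) are re-checked at `1e-50` because at this search-space
size a sub-200-residue protein cannot mathematically reach the `1e-100`
score, yet such copies belong in the inventory.

Overlapping positive hits on a strand merge into one candidate locus.
Hits of the *same* bait also merge across genomic gaps up to 5 kb when
the downstream hit continues the bait where the upstream hit stopped
(reversed on the minus strand, ≤ 40-residue slack, ≤ 35% bait-interval
overlap): these are the exon-by-exon seeds of one spliced gene. Tandem
copies of a family re-cover the bait from the start and stay separate.
Merged loci are padded by 300 bp for annotation.

## 2. Gene-model reconstruction

Annotation works on the locus window in coding orientation and asks, in
order:

1. **Complete single-exon ORF.** All ATG..stop ORFs overlapping the seed
   are enumerated; where several in-frame ATGs precede a stop, the
   5'-most one keeping the protein within the plausible range (250–400
   aa by default; fish ORs run ~300–330 aa) is used. The winning ORF
   must account for essentially the whole bait (≤ 30 unaligned bait
   residues at either end) — a chance ORF reading through a partial copy
   does not.
2. **Lesion evidence veto.** A complete-looking ORF can be a spurious
   sub-ORF of a disabled gene (re-initiation at an internal ATG after a
   premature stop; the shifted frame after an indel). Before accepting,
   the bait frame-alignments are scanned for (a) a stop codon flanked on
   both sides by well-matching coding sequence, or (b) two frames
   covering complementary parts of the bait immediately adjacent in the
   genome — far too close for an intron. Either vetoes the single-exon
   model.
3. **Spliced model.** Exon anchors are collected per frame (masked
   re-alignment; ungapped chunks of ≥ 10 residues at ≥ 50% identity,
   edge-trimmed to their high-identity core), chained by dynamic
   programming (increasing bait and genomic coordinates, modest overlap
   tolerance, a mild genomic-gap penalty that prefers compact structures
   over equally-covering jumps to a distant family relative), and
   grouped into exons where collinear. Junctions between groups are
   refined over nearby GT/AG dinucleotides under intron-length bounds
   (50–5000 bp) and a reading-frame continuity constraint
   `(d − f1) ≡ (a − f2) (mod 3)`; candidates are ranked by how well the
   implied coding length matches the unanchored bait residues. Each
   junction combination is validated by splicing the window and
   requiring a stop-free ATG..stop ORF of plausible length crossing
   every junction; solutions that excise ≥ 10 consecutive bait residues
   (a mis-splice "repairing" a frameshift) are rejected; the highest
   bait-alignment score wins, ties broken by fewer introns and junction
   proximity to the anchor seeds. The spliced search widens the window
   up to the maximal intron length but clips at neighbouring same-strand
   loci, which would otherwise donate exons of a different gene of the
   same family. When both a single-exon and a spliced model validate,
   the better bait score decides — an in-frame intron without stops can
   otherwise masquerade as coding sequence.
4. **Incomplete copies.** Remaining loci are pseudogenes when lesion
   evidence exists (lesion kind and CDS codon recorded), `edge` when the
   missing gene end lies within 10 bp of a contig boundary, else
   `fragment`; matches under 60 codons are dropped.

If a locus's model leaves supporting hits more than 100 bp outside the
model span unexplained (two tandem family members merged into one
candidate), the residual hits form a secondary locus annotated in turn.

Per intron the model records phase (coding nucleotides upstream mod 3),
the 1-based interrupted/adjacent codon, donor/acceptor dinucleotides, and
the junction context string (`last codon . next codon` for phase 0; last
three coding nucleotides, dot, the two continuation nucleotides for
phases 1/2). A donor/acceptor position-frequency matrix can be trained
from ≥ 5 recovered introns (windows: 3 exonic + 6 intronic, and 14
intronic + 1 exonic; pseudocount 1).

Non-canonical splice sites (GC–AG, AT–AC) are rejected; canonical GT–AG
describes the observed fish OR junction motifs and keeps the search
space small.

## 3. Protein features

**Topology.** Kyte–Doolittle hydropathy is averaged in a 19-residue
window (clipped at the termini); maximal runs above 1.5 seed helix
cores, each core expands to its surrounding run of positive raw
hydropathy and is clamped into 17–30 residues. Exactly seven helices
resolve the map; the regions are then labelled assuming an extracellular
N-terminus (`Nter, TM1, IN1, TM2, OUT1, TM3, IN2, TM4, OUT2, TM5, IN3,
TM6, OUT3, TM7, Cter`). Any other helix count leaves the protein
unresolved and per-domain analyses skip it. Window, threshold and length
bounds are configurable; the defaults are ordinary textbook values, not
fitted quantities.

**Sequons.** Every N-X-[S/T] with X ≠ P is reported (overlapping scan,
1-based). With a resolved topology the 5'-most sequon inside the Nter
segment is flagged: an N-proximal site is required for OR surface
expression and is present in fish ORs generally. Neural-network scoring
of glycosylation potential is out of scope; the pattern with the
standard proline exclusion stands in for it.

**Cysteine subgroups.** Cysteines are counted in OUT2 (= EC2); one or
three cysteines define the `oneC`/`threeC` subgroups observed in fish
repertoires. The six-residue block best matching the MAYDRY consensus
(BLOSUM62 sum) is read around the TM3/IN2 boundary; position 4 gives the
D (classical) / E (variant) call — the E variant co-occurs with the
single-cysteine subgroup.

**Motifs.** A star multiple alignment is projected onto the medoid
sequence (highest mean pairwise identity; insertions relative to the
medoid are dropped — adequate for conserved blocks, not a general MSA).
Ungapped windows of width 6–15 with ≤ 20% gaps per column are scored by
summed column information content with the small-sample correction
`e_n = 19/(2·ln2·n)`, and the top k non-overlapping windows are reported
as position-frequency matrices with consensus and, when topologies cover
at least half the members, a majority-vote location label. Note the
planted MAYDRY block straddles the predicted TM3/IN2 boundary, so its
location label can legitimately vote either side; the source literature
itself places the motif inconsistently (internal loop 1 vs 2).

## 4. Classification

Percent identity comes from a global Needleman–Wunsch alignment
(BLOSUM62, 11/1); the denominator is all alignment columns with at least
one residue, so a gap against a residue counts as a mismatch and
truncations are penalised. Families are single-linkage components at
≥ 40% identity, labelled `A, B, …` by decreasing size (ties by smallest
member id); subfamilies are components at ≥ 60% within each family,
numbered from 1 by decreasing size. Complete linkage is available for
sensitivity checks. "Similarity" thresholds in OR nomenclature are
interpreted as identity throughout.

Near-identical groups are maximal cliques in the ≥ 99%-identity graph
(via `networkx`), reported with species composition so cross-species
(ortholog-like) and within-species (paralog-like) groups are
distinguishable; sizes 2/3/4 are labelled pair/triplet/quadruplet.

The descriptive tree is neighbour joining (scikit-bio) on
`d = 1 − identity/100` with negative branch lengths clamped to zero; no
bootstrap support is computed.

Canonical names follow the field's scheme: three-letter species symbol +
`OR` + status letter (`p` pseudogene, `e` edge, `f` fragment; none for
complete) + `.` + family letter(s) + three-digit serial, e.g.
`BRIORe.E041`; names parse back to their components.

## 5. dN/dS (Nei–Gojobori, Zhang-modified)

Site counting: each codon position contributes one site, split between
synonymous and nonsynonymous by the κ-weighted share of its single-
nucleotide changes that preserve the amino acid; changes creating stop
codons are excluded and the weights renormalised, so every sense codon
contributes exactly three sites (`S + N = 3L` is asserted in tests).
κ defaults to 2.0 and is user-configurable; κ = 1 recovers the classical
equal-weight count.

Differences: for codons differing at k positions all k! orderings of the
single changes are enumerated; orderings through stop codons are
discarded and counts averaged over survivors (`Sd + Nd = k` whenever one
survives). If every ordering is blocked, changes are classified one at a
time against the first codon and the pair is flagged.

Codon pairs to compare come from back-translating the protein global
alignment; codons opposite a gap are dropped from both site and
difference counts. Site counts are averaged over the two sequences.
`pS = Sd/S` and `pN = Nd/N` are Jukes–Cantor corrected; `p ≥ 3/4` flags
the pair saturated. ω = dN/dS; dS = 0 with dN > 0 carries the `ds_zero`
sentinel (displayed ">10" by convention), identical pairs `undefined`.

Family summaries cover families with ≥ 4 complete genes (smaller ones
are skipped with a log notice): all-pairs mean ± population sd, min,
max, a tally of pairs with ω > 1 (ds_zero pairs count toward it but are
excluded from the moments), and per-species paralog (within-species) vs
ortholog (cross-species) means with their ratio. Per-region results
restrict the compared codons to each topology segment of the first
protein; regional Sd/Nd sum exactly to the whole-protein values when the
topology is resolved.

## 6. The synthetic genome

The generator defines the verifiable study conditions. Defaults: 42
contigs of mean length 9 kb (sd ≈ 1.5 kb) across five species tags
(Bri, Bur, Nye, Til, Zeb); 8 OR template families; 30 complete
single-exon genes (including two near-identical triplets at 0.4%
divergence), 8 multi-exon genes with 1–3 GT..AG introns of 80–400 bp and
phases drawn from {0: 0.75, 1: 0.05, 2: 0.20}, 5 frameshift and 5
premature-stop pseudogenes, 6 contig-edge truncations, 4 internal
fragments, and 6 decoy GPCR genes — 64 planted genes. One seed fully
determines the output.

Templates are built on a fixed 15-segment 7-TM architecture (300 aa)
with the canonical landmarks planted: N-terminal N-X-T sequon and
cysteine, EC1 cysteine, MAYDRY (three EC2 cysteines) or MAYERY (one) at
the TM3/IN2 boundary. TMs sample from strongly hydrophobic residues and
loops from hydrophilic ones, so hydropathy segmentation has real signal.
Genes derive from their family template by per-residue substitution
(default 4%, within hydropathy class, landmarks protected) plus
synonymous codon swaps at the same rate against a single family template
CDS — deriving codons from a shared template keeps within-family dS
informative (family means land around 0.3–0.45 on defaults, the range
reported for fish OR families) instead of saturating. The multi-exon
genes cluster in two dedicated template families, as real spliced ORs
cluster in families of their own. Phase-1 introns are allowed (the
printed fish tallies show phases 0 and 2 only, but nothing forbids 1).

Lesions sit in codons [30, L−80]: at least 30 codons from either
terminus as an unambiguous-call guarantee, and early enough that the
residual ORF cannot reach the 250-codon complete threshold — an
identifiability choice, since a late premature stop is genuinely
indistinguishable from a short complete gene without expression data.
Every planted piece is flanked by a 12-nt guard that encodes a stop in
all three frames of both strands, making planted ORF boundaries
identifiable; real genomes provide the same property statistically (a
random in-frame stop every ~20 codons) rather than deterministically.

The positive bait set is the eight template proteins, the negative set
three landmark-free decoy templates — desk-scale counterparts of a
literature OR set and a non-OR GPCR set.

What the generator does **not** emulate: repeat structure and segmental
duplications, assembly gaps beyond simple truncation, sequencing error,
GC heterogeneity, codon-usage bias, indel divergence between family
members, and non-canonical splice sites. Passing the recovery tests
therefore demonstrates the pipeline's logic is correct under clean
conditions; it does not bound performance on real draft assemblies,
where bait divergence and assembly artefacts dominate.

The codon-pair simulator for ω recovery proposes substitutions at
uniform nucleotide sites with transition weight κ, rejects and resamples
proposals creating stops, accepts synonymous proposals always and
nonsynonymous ones with probability min(1, ω). `branch_divergence` is
the expected number of proposals per site separating the pair (half per
lineage, Poisson-distributed). At 500 codons, divergence 0.25 and 50
replicates, the estimator recovers ω = 1.0 within ±0.05 and ω = 0.3
within ±0.03 of the mean.

## 7. Problem sizes and numerical choices

The shipped test suite and the acceptance script run the full pipeline
on the default 64-gene genome (about a minute on one CPU) and a smaller
14-gene genome for unit-level checks; oracle comparisons cover all 61
sense codons and 1000 random codon pairs. These sizes were chosen so a
single desk run exercises every status class and code path several times
over.

Deterministic tie-breaks throughout: the aligner's first optimal
alignment; family labels canonicalised by size then lexicographic
smallest member; spliced solutions by score, then fewer introns, then
junction proximity to the anchor seeds (a trained splice PWM cannot
break ties at detection time, since no intron set exists yet — the
GT/AG constraint carries the same information as a default PWM).
All randomness flows through one seed via `numpy.random.default_rng`.

## 8. Known limitations

* Mining has no heuristic seeding; cost is (contigs × frames × baits)
  full Smith–Waterman passes. Fine at tens of contigs and baits;
  genome-scale inputs would need a word-hit prefilter.
* The spliced search assumes exons are visible as bait-alignment anchors
  (≥ 10 residues at ≥ 50% identity). Micro-exons or exons more divergent
  than that are not recovered, and at most three introns are considered.
* Edge classification depends on the 10-bp boundary margin; an edge gene
  whose terminal residues are heavily mutated can present its first
  anchor further inside the contig and be called a fragment.
* Percent identity from pairwise global alignment can differ from
  MSA-derived identity on distant pairs; family composition near the 40%
  threshold may shift accordingly.
* The star MSA distorts columns where members carry insertions relative
  to the medoid; it is adequate for conserved-block extraction only.
* ds_zero (">10") pairs are excluded from family means; a family of very
  recent duplicates can thus report a mean over few pairs.
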