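"""End-to-end pipeline: simulate -> mine -> annotate -> features ->
classify -> dN/dS -> report.

``run_pipeline`` drives every stage on a synthetic genome (the verifiable
substrate) or on user-supplied contig/bait FASTAs, writes each stage's
artifacts, and assembles the survey-style summary tables: per-species
status counts, pseudogene lesion breakdown, family x species matrix,
near-identical group tallies, the intron table and the multi-exon family
distribution.  When ground truth is available the result also carries
recovery metrics (complete-gene sensitivity, decoy rejection, status
confusion, exact intron-boundary recovery).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from . import classify as _classify
from . import evolution as _evolution
from . import features as _features
from . import genemodels as _genemodels
from . import mining as _mining
from .genemodels import AnnotationParams, GeneModel
from .mining import BaitSet, Contig
from .simulate import SimulationConfig, SyntheticRepertoire, generate_repertoire

log = logging.getLogger("orfish")


@dataclass
class PipelineConfig:
    """Thresholds and paths for one pipeline run."""

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    positive_cutoff: float = _mining.DEFAULT_POSITIVE_CUTOFF
    negative_cutoff: float = _mining.DEFAULT_NEGATIVE_CUTOFF
    recheck_cutoff: float = _mining.RECHECK_CUTOFF
    family_threshold: float = 40.0
    subfamily_threshold: float = 60.0
    near_identical_threshold: float = 99.0
    kappa: float = 2.0
    min_family_size_dnds: int = 4
    annotation: AnnotationParams = field(default_factory=AnnotationParams)
    outdir: Path | None = None


@dataclass
class RecoveryMetrics:
    """Truth-table comparison for a synthetic run."""

    n_truth_genes: int
    n_models: int
    complete_sensitivity: float
    decoy_rejection: float
    status_accuracy: float
    intron_exact_recovery: float
    confusion: pd.DataFrame


@dataclass
class PipelineResult:
    config: PipelineConfig
    repertoire: SyntheticRepertoire | None
    loci: list
    models: list[GeneModel]
    identity: pd.DataFrame | None
    families: _classify.FamilyAssignment | None
    near_groups: list
    newick: str | None
    dnds_summaries: list
    region_dnds: pd.DataFrame | None
    tables: dict[str, pd.DataFrame]
    metrics: RecoveryMetrics | None


def _recheck_models(
    models: list[GeneModel],
    baits: BaitSet,
    cutoff: float,
    incomplete_cutoff: float = _mining.DEFAULT_POSITIVE_CUTOFF,
) -> list[GeneModel]:
    """Protein-level re-check of candidates against the positive bait set.

    Stand-in for the survey's second-pass database check: a complete
    candidate protein must re-align to at least one positive bait at the
    stricter cut-off (default 1e-100).  Incomplete copies (pseudogene,
    edge, fragment) are by construction too short to ever reach that
    score, so they are re-checked at the mining cut-off instead and kept
    with their status label.
    """
    total = sum(len(s) for s in baits.positive.values())
    kept = []
    for m in models:
        prot = m.protein.replace("*", "X")
        if not prot:
            continue
        threshold = cutoff if m.status == "complete" else incomplete_cutoff
        ok = False
        for bait in baits.positive.values():
            aln = _mining.local_align(prot, bait)
            params = _mining.EvalueParams(m=len(prot), n=total)
            if _mining.evalue(aln.score, params) <= threshold:
                ok = True
                break
        if ok:
            kept.append(m)
        else:
            log.info("recheck dropped %s (no positive match)", m.gene_id)
    return kept


def _assign_names(
    models: Sequence[GeneModel], families: _classify.FamilyAssignment
) -> None:
    serial: dict[str, int] = {}
    for m in sorted(models, key=lambda x: x.gene_id):
        fam = families.family_of.get(m.gene_id, "Z")
        key = m.species
        serial[key] = serial.get(key, 0) + 1
        m.name = _classify.canonical_name(
            m.species, m.status, fam, serial[key]
        )


def _label_intron_regions(model: GeneModel, topology) -> None:
    if topology is None or not topology.resolved:
        return
    for it in model.introns:
        pos = min(max(it.codon_position - 1, 0), topology.length - 1)
        it.region = topology.label_of(pos)


def evaluate_against_truth(
    models: Sequence[GeneModel], truth: pd.DataFrame
) -> RecoveryMetrics:
    """Match models to planted genes by location and compare status."""

    def exons_of(row):
        starts = [int(x) for x in str(row.exon_starts).split(",")]
        ends = [int(x) for x in str(row.exon_ends).split(",")]
        return list(zip(starts, ends))

    matches: dict[str, GeneModel] = {}
    for _, row in truth.iterrows():
        span = (exons_of(row)[0][0], exons_of(row)[-1][1])
        for m in models:
            if m.contig_id != row.contig_id:
                continue
            mspan = (m.exons[0][0], m.exons[-1][1])
            if mspan[0] < span[1] and span[0] < mspan[1]:
                prev = matches.get(row.gene_id)
                if prev is None or m.bait_score > prev.bait_score:
                    matches[row.gene_id] = m

    non_decoy = truth[truth.status != "decoy"]
    decoy = truth[truth.status == "decoy"]
    n_decoy_hit = sum(1 for gid in decoy.gene_id if gid in matches)
    decoy_rejection = (
        1.0 - n_decoy_hit / len(decoy) if len(decoy) else 1.0
    )
    statuses = ["complete", "pseudogene", "edge", "fragment"]
    confusion = pd.DataFrame(
        0, index=statuses, columns=statuses + ["missed"]
    )
    for _, row in non_decoy.iterrows():
        m = matches.get(row.gene_id)
        if m is None:
            confusion.loc[row.status, "missed"] += 1
        else:
            confusion.loc[row.status, m.status] += 1
    complete_rows = non_decoy[non_decoy.status == "complete"]
    n_complete_found = sum(
        1
        for gid in complete_rows.gene_id
        if gid in matches and matches[gid].status == "complete"
    )
    sensitivity = (
        n_complete_found / len(complete_rows) if len(complete_rows) else 1.0
    )
    diagonal = sum(confusion.loc[s, s] for s in statuses)
    status_accuracy = diagonal / len(non_decoy) if len(non_decoy) else 1.0

    multi = non_decoy[
        (non_decoy.status == "complete")
        & non_decoy.exon_starts.astype(str).str.contains(",")
    ]
    n_exact = 0
    for _, row in multi.iterrows():
        m = matches.get(row.gene_id)
        if m is None or m.status != "complete":
            continue
        truth_exons = exons_of(row)
        truth_introns = [
            (a_end, b_start)
            for (_, a_end), (b_start, _) in zip(truth_exons, truth_exons[1:])
        ]
        model_introns = sorted((it.start, it.end) for it in m.introns)
        if model_introns == truth_introns:
            n_exact += 1
    intron_recovery = n_exact / len(multi) if len(multi) else 1.0

    return RecoveryMetrics(
        n_truth_genes=len(truth),
        n_models=len(models),
        complete_sensitivity=sensitivity,
        decoy_rejection=decoy_rejection,
        status_accuracy=status_accuracy,
        intron_exact_recovery=intron_recovery,
        confusion=confusion,
    )


def build_report_tables(
    models: Sequence[GeneModel],
    families: _classify.FamilyAssignment | None,
    near_groups: Sequence,
    species: Sequence[str],
) -> dict[str, pd.DataFrame]:
    """Survey-style summary tables from the annotated repertoire."""
    species = list(species)
    # per-species status / exon-number counts
    rows = {
        "one_exon_complete": [0] * len(species),
        "multi_exon_complete": [0] * len(species),
        "pseudogene": [0] * len(species),
        "edge": [0] * len(species),
        "fragment": [0] * len(species),
    }
    sp_idx = {s: i for i, s in enumerate(species)}
    for m in models:
        i = sp_idx.setdefault(m.species, len(species) - 1)
        if m.status == "complete":
            key = (
                "multi_exon_complete"
                if m.n_coding_exons > 1
                else "one_exon_complete"
            )
        else:
            key = m.status
        rows[key][i] += 1
    status_table = pd.DataFrame(rows, index=species).T

    # pseudogene lesion breakdown (all-zero rows kept by construction)
    lesion_rows = {
        "frameshift": [0] * len(species),
        "in_frame_stop": [0] * len(species),
    }
    for m in models:
        if m.status != "pseudogene":
            continue
        for kind, _ in m.lesions:
            key = "frameshift" if kind == "frameshift" else "in_frame_stop"
            lesion_rows[key][sp_idx[m.species]] += 1
    lesion_table = pd.DataFrame(lesion_rows, index=species).T

    # family x species matrix of complete genes
    fam_table = pd.DataFrame()
    if families is not None:
        counts: dict[str, dict[str, int]] = {}
        for m in models:
            fam = families.family_of.get(m.gene_id)
            if fam is None or m.status != "complete":
                continue
            counts.setdefault(fam, {s: 0 for s in species})
            counts[fam][m.species] += 1
        fam_table = pd.DataFrame(counts).T.fillna(0).astype(int)
        if not fam_table.empty:
            fam_table = fam_table.sort_index()

    # near-identical group tallies by size and species combination
    ni_rows = []
    for grp in near_groups:
        ni_rows.append(
            {
                "size": grp.size,
                "kind": grp.kind,
                "species": "/".join(sorted(set(grp.species))),
                "members": ",".join(grp.members),
            }
        )
    ni_table = pd.DataFrame(
        ni_rows, columns=["size", "kind", "species", "members"]
    )

    intron_table = _genemodels.intron_report(models)

    # multi-exon distribution among families
    multi_rows = []
    if families is not None:
        for fam, members in families.families.items():
            fam_models = [
                m for m in models if m.gene_id in members and m.status == "complete"
            ]
            n_multi = sum(1 for m in fam_models if m.n_coding_exons > 1)
            if not fam_models:
                continue
            multi_rows.append(
                {
                    "family": fam,
                    "n_genes": len(fam_models),
                    "n_multi_exon": n_multi,
                    "exon_numbers": "/".join(
                        sorted(
                            {
                                str(m.n_coding_exons)
                                for m in fam_models
                                if m.n_coding_exons > 1
                            }
                        )
                    )
                    or ".",
                }
            )
    multi_table = pd.DataFrame(
        multi_rows, columns=["family", "n_genes", "n_multi_exon", "exon_numbers"]
    )

    n_complete = sum(1 for m in models if m.status == "complete")
    n_multi = sum(
        1 for m in models if m.status == "complete" and m.n_coding_exons > 1
    )
    summary = pd.DataFrame(
        [
            {
                "n_complete": n_complete,
                "n_multi_exon_complete": n_multi,
                "multi_exon_percent": round(100 * n_multi / n_complete)
                if n_complete
                else 0,
            }
        ]
    )
    return {
        "status_counts": status_table,
        "pseudogene_lesions": lesion_table,
        "family_by_species": fam_table,
        "near_identical": ni_table,
        "introns": intron_table,
        "multi_exon_families": multi_table,
        "summary": summary,
    }


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute every stage on a synthetic genome and assemble the report."""
    log.info("simulate: seed=%d", config.simulation.seed)
    rep = generate_repertoire(config.simulation)
    return run_pipeline_on(
        rep.contigs, rep.baits, config, repertoire=rep
    )


def run_pipeline_on(
    contigs: Mapping[str, Contig],
    baits: BaitSet,
    config: PipelineConfig,
    repertoire: SyntheticRepertoire | None = None,
) -> PipelineResult:
    log.info("mine: %d contigs, %d+%d baits", len(contigs),
             len(baits.positive), len(baits.negative))
    loci, hits = _mining.mine(
        contigs,
        baits,
        positive_cutoff=config.positive_cutoff,
        negative_cutoff=config.negative_cutoff,
    )
    log.info("mine: %d candidate loci retained", len(loci))
    models = _genemodels.annotate(loci, contigs, baits, config.annotation)
    models = _recheck_models(models, baits, config.recheck_cutoff)
    log.info("annotate: %d gene models", len(models))

    # features on complete models
    topologies = {}
    subgroups = []
    sequon_rows = []
    for m in models:
        if m.status != "complete":
            continue
        topo = _features.predict_topology(m.protein)
        topologies[m.gene_id] = topo
        _label_intron_regions(m, topo)
        call = _features.cysteine_subgroup(m.gene_id, m.protein, topo)
        if call is not None:
            subgroups.append(call)
        for s in _features.find_sequons(m.protein, topo):
            sequon_rows.append(
                {
                    "gene_id": m.gene_id,
                    "position": s.position,
                    "context": s.context,
                    "n_terminal": s.n_terminal,
                }
            )

    # classification over all model proteins
    identity = families = None
    near_groups: list = []
    newick = None
    proteins = {
        m.gene_id: m.protein.replace("*", "X") for m in models if m.protein
    }
    if len(proteins) >= 2:
        identity = _classify.identity_matrix(proteins)
        families = _classify.assign_families(
            identity,
            config.family_threshold,
            config.subfamily_threshold,
        )
        _assign_names(models, families)
        complete_ids = [
            m.gene_id for m in models if m.status == "complete"
        ]
        if len(complete_ids) >= 2:
            species_of = {
                m.gene_id: m.species for m in models
            }
            near_groups = _classify.find_near_identical(
                identity.loc[complete_ids, complete_ids],
                species_of,
                config.near_identical_threshold,
            )
        if len(complete_ids) >= 3:
            newick = _classify.nj_tree(
                identity.loc[complete_ids, complete_ids]
            )

    # dN/dS for families with enough complete genes
    dnds_summaries = []
    region_rows = []
    if families is not None:
        for fam, members in families.families.items():
            cds = {
                m.gene_id: m.cds
                for m in models
                if m.gene_id in members and m.status == "complete"
            }
            if len(cds) < config.min_family_size_dnds:
                log.info("dnds: family %s skipped (%d genes)", fam, len(cds))
                continue
            species_by = {
                m.gene_id: m.species for m in models if m.gene_id in cds
            }
            dnds_summaries.append(
                _evolution.family_dnds_summary(
                    fam, cds, species_by, config.kappa
                )
            )
        # per-region dN/dS on the largest summarised family
        if dnds_summaries:
            biggest = max(dnds_summaries, key=lambda s: s.n_genes)
            members = families.families[biggest.family]
            fam_models = [
                m
                for m in models
                if m.gene_id in members
                and m.status == "complete"
                and topologies.get(m.gene_id)
                and topologies[m.gene_id].resolved
            ]
            for i, ma in enumerate(fam_models):
                for mb in fam_models[i + 1 :]:
                    try:
                        _, regions = _evolution.dnds_pair(
                            ma.cds,
                            mb.cds,
                            config.kappa,
                            id_a=ma.gene_id,
                            id_b=mb.gene_id,
                            topology=topologies[ma.gene_id],
                        )
                    except ValueError:
                        continue
                    for reg in regions:
                        r = reg.result
                        if r.omega is not None:
                            region_rows.append(
                                {
                                    "family": biggest.family,
                                    "region": reg.region,
                                    "pair": f"{ma.gene_id}-{mb.gene_id}",
                                    "omega": r.omega,
                                }
                            )
    region_dnds = (
        pd.DataFrame(region_rows) if region_rows else None
    )

    species = (
        list(repertoire.config.species)
        if repertoire is not None
        else sorted({m.species for m in models})
    )
    tables = build_report_tables(models, families, near_groups, species)
    tables["sequons"] = pd.DataFrame(
        sequon_rows, columns=["gene_id", "position", "context", "n_terminal"]
    )
    tables["subgroups"] = pd.DataFrame(
        [
            {
                "gene_id": c.gene_id,
                "ec2_cysteines": c.ec2_cysteine_count,
                "subgroup": c.subgroup,
                "maydry_block": c.maydry_block,
                "maydry_variant": c.maydry_variant,
            }
            for c in subgroups
        ],
        columns=[
            "gene_id",
            "ec2_cysteines",
            "subgroup",
            "maydry_block",
            "maydry_variant",
        ],
    )

    metrics = None
    if repertoire is not None:
        metrics = evaluate_against_truth(models, repertoire.truth)
        log.info(
            "truth: sensitivity=%.3f decoy_rejection=%.3f status=%.3f introns=%.3f",
            metrics.complete_sensitivity,
            metrics.decoy_rejection,
            metrics.status_accuracy,
            metrics.intron_exact_recovery,
        )

    result = PipelineResult(
        config=config,
        repertoire=repertoire,
        loci=loci,
        models=models,
        identity=identity,
        families=families,
        near_groups=near_groups,
        newick=newick,
        dnds_summaries=dnds_summaries,
        region_dnds=region_dnds,
        tables=tables,
        metrics=metrics,
    )
    if config.outdir is not None:
        emit_report(result, config.outdir)
    return result


def emit_report(result: PipelineResult, outdir: str | Path) -> None:
    """Write all per-stage artifacts and summary tables as text files."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    from .simulate import write_fasta, write_repertoire

    if result.repertoire is not None:
        write_repertoire(result.repertoire, outdir / "genome")
    if result.models:
        _genemodels.write_gff3(result.models, outdir / "models.gff3")
        write_fasta(
            {m.name or m.gene_id: m.protein for m in result.models},
            outdir / "proteins.fasta",
        )
        write_fasta(
            {m.name or m.gene_id: m.cds for m in result.models},
            outdir / "cds.fasta",
        )
        _genemodels.models_to_status_table(result.models).to_csv(
            outdir / "status.tsv", sep="\t", index=False
        )
    if result.identity is not None:
        result.identity.to_csv(outdir / "identity.tsv", sep="\t")
    if result.newick is not None:
        (outdir / "tree.nwk").write_text(result.newick)
    for name, table in result.tables.items():
        table.to_csv(outdir / f"{name}.tsv", sep="\t")
    if result.dnds_summaries:
        pd.DataFrame(
            [
                {
                    "family": s.family,
                    "n_genes": s.n_genes,
                    "n_pairs": s.n_pairs,
                    "mean_omega": s.mean,
                    "sd_omega": s.sd,
                    "min_omega": s.min,
                    "max_omega": s.max,
                    "n_above_one": s.n_above_one,
                    "n_ds_zero": s.n_ds_zero,
                }
                for s in result.dnds_summaries
            ]
        ).to_csv(outdir / "dnds_families.tsv", sep="\t", index=False)
    if result.region_dnds is not None:
        result.region_dnds.to_csv(
            outdir / "dnds_regions.tsv", sep="\t", index=False
        )
    if result.metrics is not None:
        result.metrics.confusion.to_csv(outdir / "confusion.tsv", sep="\t")
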