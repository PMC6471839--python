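"""End-to-end orchestration: simulate -> infer -> metacluster -> profile
-> compare -> pathways, with all reports written as TSV/JSON."""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from . import compare as cmp
from . import inference, io, metacluster as mcl, pathways as pw
from . import profile as prof
from . import simulate as sim
from .models import ProteinDatabase, PSM

log = logging.getLogger("metaproteo")

ENTERO_GENERA = ("Klebsiella", "Escherichia", "Citrobacter")


def simulate_inputs(spec: sim.CommunitySpec, taxonomy, outdir) -> dict:
    """Run the generator and write database, PSM, 16S and pathway files."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    proteomes = sim.synthesize_proteomes(
        taxonomy, spec.proteins_per_strain, spec.homolog_family_count,
        spec.gene_annotation_rate, spec.seed,
        n_host_proteins=spec.n_host_proteins,
        host_family_count=spec.host_family_count)
    psms, truth = sim.sample_psms(spec, proteomes, taxonomy)
    reads = sim.sample_16s(truth, read_depth=20000,
                           noise_sd_16s=spec.noise_sd_16s, seed=spec.seed)
    pathway_table = sim.make_pathway_table(proteomes, seed=spec.seed)

    io.write_database(proteomes, outdir / "database.fasta")
    for subj, rows in psms.items():
        io.write_psms(rows, outdir / f"psms_{subj}.tsv")
    io.write_psms([p for rows in psms.values() for p in rows],
                  outdir / "psms_all.tsv")
    io.write_16s(reads, outdir / "reads_16s.tsv")
    io.write_pathway_table(pathway_table, outdir / "pathways.tsv")
    io.write_truth(truth, outdir / "truth.json")
    io.spec_to_yaml(spec, outdir / "config.yaml")
    return {"proteomes": proteomes, "psms": psms, "truth": truth,
            "reads_16s": reads, "pathway_table": pathway_table}


@dataclasses.dataclass
class PipelineResult:
    database: ProteinDatabase
    retained: list[PSM]
    fdr: "inference.FdrResult"
    groups: list
    metaclusters: list
    metacluster_counts: pd.DataFrame
    accounting: pd.DataFrame
    strain_profile: prof.RankProfile
    genus_profile: prof.RankProfile
    strain_tiers: pd.DataFrame
    cross_method: Optional["cmp.CorrelationResult"]
    pairwise: Optional[pd.DataFrame]
    pathway_contrasts: Optional[pd.DataFrame]
    bundle: io.ResultsBundle


def run_analysis(database: ProteinDatabase, psms: Sequence[PSM],
                 reads_16s: Optional[pd.DataFrame] = None,
                 pathway_table: Optional[pd.DataFrame] = None,
                 target_fdr: float = 0.016,
                 treated: Sequence[str] = ("R",),
                 merge_entero: bool = True) -> PipelineResult:
    """Run every analysis stage downstream of the PSM tables."""
    retained, fdr_result = inference.fdr_filter(psms, database, target_fdr)
    groups = inference.infer_protein_groups(retained, database)
    inference.assign_spectral_counts(groups, retained)
    plev = inference.protein_level_fdr(groups, psms, database,
                                       fdr_result.score_threshold)

    clusters = mcl.build_metaclusters(groups, database)
    counts = mcl.count_metacluster_spectra(clusters, retained)
    accounting = mcl.annotation_summary(clusters, counts)

    strain_profile = prof.build_rank_profile(retained, database, "strain")
    genus_profile = prof.build_rank_profile(retained, database, "genus")
    tiers = prof.strain_detection_tiers(strain_profile)

    cross = None
    heat = None
    if reads_16s is not None:
        genus_counts = genus_profile.matrix.copy()
        s16 = reads_16s.copy()
        if merge_entero:
            genus_counts = cmp.merge_family(genus_counts,
                                            "Enterobacteriaceae",
                                            ENTERO_GENERA)
            s16 = cmp.merge_family(s16, "Enterobacteriaceae", ENTERO_GENERA)
        cross = cmp.cross_method_correlation(genus_counts, s16)
        heat, _ = cmp.heatmap_matrix(genus_counts,
                                     top_k=min(13, len(genus_counts)))

    pairwise = None
    if counts.shape[1] >= 2:
        pairwise = cmp.all_pairwise_correlations(counts)

    contrasts_df = None
    if pathway_table is not None and len(pathway_table):
        untreated = [s for s in counts.columns if s not in set(treated)]
        if untreated and all(t in counts.columns for t in treated):
            dedup = pw.deduplicate_at_genus(clusters, retained, database)
            members = pw.map_to_pathways(clusters, pathway_table)
            gene_of = {m.metacluster_id: ",".join(sorted(m.gene_names))
                       for m in clusters}
            contrasts = pw.contrast_groups(members, dedup, treated,
                                           untreated, gene_of=gene_of)
            contrasts_df = pw.contrasts_to_frame(contrasts)

    corr_rows = []
    if cross is not None:
        corr_rows.append(("proteomics_vs_16S", "-", cross.spearman_rho,
                          cross.pearson_r, cross.r_squared, cross.n))
    corr_df = pd.DataFrame(corr_rows, columns=[
        "comparison", "pair", "spearman_rho", "pearson_r", "r_squared",
        "n"]) if corr_rows else None

    group_table = pd.DataFrame(
        [(g.group_id, ";".join(g.member_accessions), len(g.peptide_set),
          int(g.is_host), sum(g.spectral_counts.values()))
         for g in groups],
        columns=["group_id", "members", "n_peptides", "is_host",
                 "total_spectra"])
    mc_table = pd.DataFrame(
        [(m.metacluster_id, ";".join(m.group_ids),
          ",".join(sorted(m.gene_names)),
          ",".join(sorted(m.uniref50_ids)), int(m.has_useful_annotation),
          int(m.is_host), len(m.peptide_set))
         for m in clusters],
        columns=["metacluster_id", "groups", "gene_names", "uniref50_ids",
                 "has_useful_annotation", "is_host", "n_peptides"])

    bundle = io.ResultsBundle(
        accounting=accounting,
        strain_tiers=tiers,
        rank_profiles={"strain": strain_profile.matrix,
                       "genus": genus_profile.matrix},
        metacluster_counts=counts,
        metacluster_table=mc_table,
        group_table=group_table,
        correlations=corr_df if corr_df is not None else pairwise,
        heatmap=heat,
        pathway_contrasts=contrasts_df,
        fdr=fdr_result,
        protein_level_fdr=plev)
    if pairwise is not None and corr_df is not None:
        bundle.correlations = pd.concat(
            [corr_df,
             pairwise.rename(columns={"subject_a": "comparison",
                                      "subject_b": "pair"})],
            ignore_index=True)
    return PipelineResult(
        database=database, retained=retained, fdr=fdr_result,
        groups=groups, metaclusters=clusters, metacluster_counts=counts,
        accounting=accounting, strain_profile=strain_profile,
        genus_profile=genus_profile, strain_tiers=tiers,
        cross_method=cross, pairwise=pairwise,
        pathway_contrasts=contrasts_df, bundle=bundle)


def run_all(spec: sim.CommunitySpec, taxonomy, outdir,
            target_fdr: float = 0.016,
            treated: Sequence[str] = ("R",)) -> PipelineResult:
    """Simulate inputs, re-read them from disk, and run the full analysis.

    Reading back the written files exercises the reader/writer round trip
    on every run.
    """
    outdir = Path(outdir)
    inputs = simulate_inputs(spec, taxonomy, outdir / "inputs")
    database = io.read_database(outdir / "inputs" / "database.fasta",
                                max_missed_cleavages=spec.max_missed_cleavages,
                                min_peptide_len=spec.min_peptide_len,
                                max_peptide_len=spec.max_peptide_len)
    psms = io.read_psms(outdir / "inputs" / "psms_all.tsv", database)
    reads = io.read_16s(outdir / "inputs" / "reads_16s.tsv")
    pathway_table = io.read_pathway_table(outdir / "inputs" / "pathways.tsv")

    treated = [t for t in treated if t in spec.subjects] or None
    result = run_analysis(database, psms, reads, pathway_table,
                          target_fdr=target_fdr,
                          treated=treated or ("R",))
    result.bundle.manifest.update({
        "config_hash": io.config_hash(spec),
        "seed": spec.seed,
        "n_psms_input": len(psms),
        "n_psms_retained": len(result.retained),
    })
    io.write_reports(result.bundle, outdir / "reports")
    return result
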