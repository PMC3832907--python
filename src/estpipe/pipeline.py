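"""End-to-end orchestration of the post-assembly pipeline.

``run_all`` executes the stages in order — simulate (or ingest) → assembly
stats → condensation → homology → variants → enrichment → array evaluation —
writing each stage's TSV/FASTA/VCF outputs plus ``summary.json`` with the
headline counts and ``manifest.json`` recording the configuration, seed and a
sha256 checksum per output file.  Every random draw funnels through the one
seed in the configuration, so re-running with the same manifest reproduces
byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import array_eval, condense, enrich, homology, seq_core, similarity, variants
from .synthetic_data import ArrayConfig, GroundTruth, SimConfig, gen_annotations, \
    gen_signals, gen_transcriptome, write_ground_truth

logger = logging.getLogger(__name__)

STAGES = ("simulate", "stats", "condense", "homology", "variants", "enrich", "array")


@dataclass
class PipelineConfig:
    outdir: str = "estpipe_run"
    seed: int = 0
    input_dir: str | None = None      # ingest mode: models.fasta + unigenes.fasta + contigs.fasta
    simulate: bool = True
    stages: tuple[str, ...] = STAGES
    # thresholds (defaults are the pipeline's standard operating points)
    cluster_identity: float = 99.0
    cluster_coverage: float = 99.0
    evalue_orient: float = 1e-3
    evalue_map: float = 1e-10
    evalue_strict: float = 1e-50
    min_qcov: float = 90.0
    de_min_abs_log2fc: float = 1.0
    de_max_fdr: float = 0.05
    pss_n_target: int = 100
    sim: SimConfig = field(default_factory=SimConfig)

    def __post_init__(self) -> None:
        self.sim.seed = self.seed


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_all(config: PipelineConfig) -> Path:
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {}
    written: list[Path] = []

    def emit(name: str) -> Path:
        p = out / name
        written.append(p)
        return p

    # --- simulate / ingest -------------------------------------------------
    if config.simulate and "simulate" in config.stages:
        models, unigenes_b, contigs, truth = gen_transcriptome(config.sim)
        seq_core.write_fasta(models, emit("models.fasta"))
        seq_core.write_fasta(unigenes_b, emit("unigenes.fasta"))
        seq_core.write_fasta([c.record for c in contigs], emit("contigs.fasta"))
        write_ground_truth(truth, emit("ground_truth.json"))
    elif config.input_dir:
        d = Path(config.input_dir)
        for req in ("models.fasta", "unigenes.fasta", "contigs.fasta"):
            if not (d / req).exists():
                raise FileNotFoundError(f"ingest stage: missing input {req!r} in {d}")
        models = seq_core.read_fasta(d / "models.fasta", library="external")
        unigenes_b = seq_core.read_fasta(d / "unigenes.fasta")
        contigs = [seq_core.Contig(r) for r in seq_core.read_fasta(d / "contigs.fasta")]
        truth = GroundTruth()
    else:
        raise FileNotFoundError("no input directory and synthetic mode disabled")

    # --- assembly statistics ----------------------------------------------
    if "stats" in config.stages:
        stats = seq_core.assembly_stats(contigs)
        summary["assembly"] = dataclasses.asdict(stats)
        seq_core.stats_report(contigs, emit("contig_stats.tsv"))

    # --- condensation ------------------------------------------------------
    if "condense" in config.stages:
        unigenes = condense.condense_assembly(
            contigs, min_identity=config.cluster_identity,
            min_coverage=config.cluster_coverage)
        summary["condense"] = condense.condensation_summary(contigs, unigenes)
        seq_core.write_fasta(
            [seq_core.SeqRecord(u.id, u.consensus) for u in unigenes],
            emit("condensed_unigenes.fasta"))
        condense.write_membership(unigenes, emit("cluster_membership.tsv"))

    # --- homology ----------------------------------------------------------
    hits = similarity.search_local(unigenes_b, models, prefilter_kmer=15)
    if "homology" in config.stages:
        cm = homology.crossmap([u.id for u in unigenes_b], hits,
                               config.evalue_map, direction="unigenes_vs_models")
        hits_cov = homology.coverage_vs_subject(hits, {m.id: len(m) for m in models})
        fl = homology.classify_full_length(hits_cov, config.evalue_map, config.min_qcov)
        comps, dup = homology.classify_relationships(
            hits_cov, config.evalue_map, config.min_qcov)
        summary["homology"] = {
            "n_query": cm.n_query, "n_matched": cm.n_matched, "n_unique": cm.n_unique,
            "full_length_pct": round(homology.full_length_fraction(fl), 1),
            "n_components": len(comps),
            "duplicated_member_count": len(dup),
            "duplicated_component_count": homology.duplicated_component_count(comps),
        }
        homology.write_crossmap([cm], emit("crossmap.tsv"))
        homology.write_components(comps, emit("homology_components.tsv"))
        pd.DataFrame([c.__dict__ for c in fl]).to_csv(
            emit("full_length.tsv"), sep="\t", index=False)

    # --- variants ----------------------------------------------------------
    if "variants" in config.stages:
        calls, ambiguous = variants.call_snps(models, unigenes_b, hits, config.evalue_map)
        table = variants.snp_frequency_table(calls)
        summary["variants"] = {
            "n_non_ambiguous": len(calls), "n_ambiguous": len(ambiguous),
            "n_genes_with_snp": table.total_genes,
        }
        variants.write_vcf(calls, emit("snps.vcf"))
        variants.write_vcf(ambiguous, emit("snps_ambiguous.vcf"))
        variants.write_frequency_table(table, emit("snp_frequency.tsv"))

    # --- enrichment --------------------------------------------------------
    if "enrich" in config.stages:
        gene_ids = [m.id for m in models]
        selected = gene_ids[: max(2, len(gene_ids) // 5)]
        gene_bins, planted = gen_annotations(config.sim, gene_ids, selected)
        ann = enrich.BinAnnotation(gene_bins)
        ann.write_tsv(emit("bin_annotations.tsv"))
        results = enrich.fisher_enrichment(selected, gene_ids, ann, min_bin_size=2)
        enrich.write_enrichment(results, emit("enrichment.tsv"))
        top = results[0] if results else None
        summary["enrich"] = {
            "planted_bin": planted, "n_bins_tested": len(results),
            "top_bin": top.bin_code if top else None,
            "top_p_bonferroni": top.p_bonferroni if top else None,
        }

    # --- array evaluation --------------------------------------------------
    if "array" in config.stages:
        uni_seqs = {u.id: u.seq for u in unigenes_b if len(u.seq) >= array_eval.PROBE_LEN}
        kidx = array_eval.build_kmer_index(uni_seqs)
        candidates = []
        for uid, seq in uni_seqs.items():
            candidates.extend(array_eval.design_probes(
                uid, seq, target_count=config.sim.array.n_probes_per_gene,
                kmer_index=kidx))
        array_eval.write_probes(candidates, emit("probe_candidates.tsv"))
        probe_genes = [(c.probe_id, c.unigene_id) for c in candidates]
        mat_same, meta, de_truth = gen_signals(config.sim, probe_genes, cross_species=False)
        mat_cross, _, _ = gen_signals(config.sim, probe_genes, cross_species=True)
        mat_same.to_csv(emit("signals_same_species.tsv"), sep="\t")
        mat_cross.to_csv(emit("signals_cross_species.tsv"), sep="\t")
        meta.to_csv(emit("sample_metadata.tsv"), sep="\t")
        primary = mat_same.median(axis=1).to_dict()
        secondary = mat_cross.median(axis=1).to_dict()
        selected_probes, split = array_eval.pss_select(
            candidates, primary, secondary, n_target=min(config.pss_n_target, len(candidates)))
        p2g = dict(probe_genes)
        de_same = array_eval.differential_expression(mat_same, meta, p2g)
        de_cross = array_eval.differential_expression(mat_cross, meta, p2g)
        array_eval.write_de_results(de_same, emit("de_same_species.tsv"))
        array_eval.write_de_results(de_cross, emit("de_cross_species.tsv"))
        overlap = array_eval.cross_species_overlap(de_same, de_cross)
        fit_same, _ = array_eval.classify_signal_modes(mat_same.to_numpy().ravel())
        fit_cross, _ = array_eval.classify_signal_modes(mat_cross.to_numpy().ravel())
        summary["array"] = {
            "n_probe_candidates": len(candidates),
            "n_selected": len(selected_probes), "pss_split": split,
            "planted_de_genes": len(de_truth.de_genes),
            "de_same_significant": sum(r.significant for r in de_same),
            "de_cross_significant": sum(r.significant for r in de_cross),
            "overlap": {"both": overlap.both, "same_only": overlap.same_only,
                        "cross_only": overlap.cross_only},
            "w_low_same": round(fit_same.w_low, 4),
            "w_low_cross": round(fit_cross.w_low, 4),
            "same_effectively_unimodal": fit_same.effectively_unimodal,
            "cross_effectively_unimodal": fit_cross.effectively_unimodal,
        }

    # --- summary + manifest ------------------------------------------------
    with open(emit("summary.json"), "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True, default=str)
    manifest = {
        "config": {k: v for k, v in dataclasses.asdict(config).items() if k != "sim"},
        "sim": dataclasses.asdict(config.sim),
        "seed": config.seed,
        "thresholds": {
            "evalue_strict": config.evalue_strict, "evalue_map": config.evalue_map,
            "evalue_orient": config.evalue_orient,
            "cluster_identity": config.cluster_identity,
            "cluster_coverage": config.cluster_coverage,
            "min_qcov": config.min_qcov,
            "de_min_abs_log2fc": config.de_min_abs_log2fc,
            "de_max_fdr": config.de_max_fdr,
        },
        "checksums": {p.name: _sha256(p) for p in sorted(written)},
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True, default=str)
    logger.info("pipeline complete: %s", out)
    return out
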