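"""End-to-end pipeline: reference -> counts -> DCS -> peaks -> profiles -> integration.

Driven by a single YAML/JSON config; writes a fixed artifact layout plus a
manifest with per-file checksums so reruns can be verified byte-for-byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import io as dio
from .dcs import dcs_analysis, ma_table, tmm_factors
from .genome import FusedGenome, Gene, library_key
from .integrate import cluster_summary, correlate_lfc, join_lfc, tf_candidates
from .peaks import assign_peaks_to_genes, call_peaks, concordance, quantify_peaks, write_peaks_bed
from .profiles import meta_profile
from .quantify import BinGrid, bin_counts, coverage_track, feature_counts
from .simulate import SimulationConfig, simulate_reads, simulate_reference

log = logging.getLogger("dualchip.pipeline")


@dataclass
class PipelineConfig:
    """Inputs, parameters, and output layout for one pipeline run."""

    out_dir: str
    # either a simulation block ...
    simulate: dict | None = None
    # ... or file inputs
    contig_table: str | None = None
    host_fasta: str | None = None
    symbiont_fasta: str | None = None
    annotation: str | None = None
    reads_bed: list[str] = field(default_factory=list)
    reads_sam: list[str] = field(default_factory=list)
    expression_lfc: str | None = None
    # parameters
    bin_sizes: tuple[int, ...] = (50_000, 2_000)
    promoter_upstream: int = 1000
    promoter_downstream: int = 500
    fragment_length: int = 0      # 0: reads are already fragment-sized
    count_mode: str = "gene_body"
    fdr_cutoff: float = 0.01
    peak_window: int = 200
    peak_step: int = 50
    peak_p_cut: float = 1e-5
    peak_merge_gap: int = 100
    profile_flank: int = 1500
    profile_bin: int = 25
    min_mapq: int = 0
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | os.PathLike) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        try:
            return cls(**raw)
        except TypeError as exc:
            raise ValueError(f"invalid pipeline config: {exc}") from exc


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage and return the output manifest.

    Stage order: reference, quantify, dcs (per target), peaks + concordance,
    profiles, integrate (skipped with a notice when no expression table is
    given).  Deterministic given identical inputs and seed.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: list[dict] = []

    def record(stage: str, path: Path) -> None:
        manifest.append({"file": str(path.relative_to(out)), "stage": stage,
                         "sha256": _sha256(path)})

    # ---- stage: reference -------------------------------------------------
    stage = "reference"
    try:
        if config.simulate is not None:
            sim = SimulationConfig.from_dict({**config.simulate, "seed": config.seed})
            genome, genes, truth = simulate_reference(sim)
            reads = simulate_reads(sim, genome, truth)
            dio.write_bed_reads(out / "reads.bed", reads)
            truth.to_tsv(out / "truth.tsv")
            record(stage, out / "reads.bed")
            record(stage, out / "truth.tsv")
        else:
            if config.contig_table:
                genome = dio.read_contig_table(config.contig_table)
            else:
                from .genome import build_fused_genome
                host = dio.read_fasta_contigs(config.host_fasta, "host")
                sym = dio.read_fasta_contigs(config.symbiont_fasta, "symbiont")
                genome = build_fused_genome(host, sym)
            genes = dio.read_gff3_genes(config.annotation)
            parts = [dio.read_bed_reads(p) for p in config.reads_bed]
            parts += [dio.read_sam_reads(p, min_mapq=config.min_mapq)
                      for p in config.reads_sam]
            if not parts:
                raise ValueError("no read input (reads_bed / reads_sam)")
            reads = pd.concat(parts, ignore_index=True)
            truth = None
        genome.contig_table().to_csv(out / "contigs.tsv", sep="\t", index=False)
        dio.write_gff3_genes(out / "genes.gff3", genes)
        record(stage, out / "contigs.tsv")
        record(stage, out / "genes.gff3")
        log.info("stage=%s n_contigs=%d n_genes=%d n_reads=%d",
                 stage, len(genome.contigs), len(genes), len(reads))
    except Exception as exc:
        raise StageError(stage, exc) from exc

    lib_meta = pd.DataFrame(
        {k: dict(zip(("condition", "target", "replicate"), k.split(":")))
         for k in sorted(reads["library"].unique())}).T
    targets = [t for t in lib_meta["target"].unique() if t != "background"]

    # ---- stage: quantify --------------------------------------------------
    stage = "quantify"
    try:
        from .genome import extend_reads
        if config.fragment_length:
            reads = extend_reads(reads, genome, config.fragment_length)
        for bs in config.bin_sizes:
            grid = BinGrid(bs, genome)
            bm = bin_counts(reads, grid, genome)
            bm.to_tsv(out / f"bin_counts_{bs}.tsv")
            record(stage, out / f"bin_counts_{bs}.tsv")
        for lib in lib_meta.index:
            track = coverage_track(reads, lib, config.bin_sizes[0], genome)
            path = out / f"coverage_{lib.replace(':', '_')}.bedgraph"
            path.write_text("")
            for contig, values in track.items():
                dio.write_bedgraph(path, contig, config.bin_sizes[0], values,
                                   genome.length(contig))
            record(stage, path)
        matrix = feature_counts(reads, genes, genome, mode=config.count_mode,
                                promoter_upstream=config.promoter_upstream,
                                promoter_downstream=config.promoter_downstream)
        matrix.to_tsv(out / "gene_counts.tsv")
        record(stage, out / "gene_counts.tsv")
        log.info("stage=%s features=%d libraries=%d", stage, *matrix.counts.shape)
    except Exception as exc:
        raise StageError(stage, exc) from exc

    # ---- stage: dcs (per antibody target) ---------------------------------
    stage = "dcs"
    dcs_results = {}
    try:
        for target in targets:
            res = dcs_analysis(matrix, target=target, fdr_cutoff=config.fdr_cutoff)
            res.to_tsv(out / f"dcs_{target}.tsv")
            record(stage, out / f"dcs_{target}.tsv")
            sub = matrix.select_target(target, conditions=("mono", "cocult"))
            expressed = sub.counts.sum(axis=1) > 0
            from .quantify import CountMatrix
            core = CountMatrix(sub.counts.loc[expressed], sub.effective_sizes,
                               sub.feature_lengths, sub.libraries)
            ma = ma_table(core, tmm_factors(core))
            ma.rename_axis("feature").to_csv(out / f"ma_{target}.tsv", sep="\t")
            record(stage, out / f"ma_{target}.tsv")
            dcs_results[target] = res
            log.info("stage=%s target=%s higher=%d lower=%d", stage, target,
                     len(res.higher), len(res.lower))
    except Exception as exc:
        raise StageError(stage, exc) from exc

    # ---- stage: peaks + concordance ---------------------------------------
    stage = "peaks"
    try:
        conc = {}
        for target in targets:
            t_libs = lib_meta.index[lib_meta["target"] == target]
            t_reads = reads.loc[reads["library"].isin(t_libs)]
            pooled = t_reads.assign(library=library_key("pooled", target, 0))
            pks = call_peaks(pooled, library_key("pooled", target, 0), genome,
                             window=config.peak_window, step=config.peak_step,
                             p_cut=config.peak_p_cut, merge_gap=config.peak_merge_gap)
            pk_matrix = quantify_peaks(pks, t_reads, genome)
            write_peaks_bed(out / f"peaks_{target}.bed", pks)
            record(stage, out / f"peaks_{target}.bed")
            if len(pks) >= 2:
                pk_res = dcs_analysis(pk_matrix, target=target,
                                      fdr_cutoff=config.fdr_cutoff)
                sig = [p for p in pks if p.id in set(pk_res.differential)]
                gene_map, _ = assign_peaks_to_genes(
                    sig, genes, genome,
                    promoter_upstream=config.promoter_upstream,
                    promoter_downstream=config.promoter_downstream)
                rep = concordance(set(dcs_results[target].differential),
                                  set(gene_map))
                conc[target] = rep.to_dict()
        (out / "concordance.json").write_text(json.dumps(conc, indent=2))
        record(stage, out / "concordance.json")
    except Exception as exc:
        raise StageError(stage, exc) from exc

    # ---- stage: profiles ---------------------------------------------------
    stage = "profiles"
    try:
        for lib in lib_meta.index:
            for anchor in ("TSS", "TTS"):
                prof = meta_profile(reads, lib, genes, genome, anchor=anchor,
                                    flank=config.profile_flank,
                                    bin_size=config.profile_bin)
                path = out / f"profile_{anchor}_{lib.replace(':', '_')}.tsv"
                prof.to_frame().to_csv(path, sep="\t", index=False)
                record(stage, path)
    except Exception as exc:
        raise StageError(stage, exc) from exc

    # ---- stage: integrate (optional) ---------------------------------------
    stage = "integrate"
    try:
        if config.expression_lfc:
            expr = pd.read_csv(config.expression_lfc, sep="\t", index_col=0) \
                     .iloc[:, 0].astype(float)
            summary = {}
            target = targets[0]
            join = join_lfc(dcs_results[target], expr)
            join.table.rename_axis("gene").to_csv(out / "lfc_join.tsv", sep="\t")
            record(stage, out / "lfc_join.tsv")
            for subset in ("all", "differential"):
                try:
                    r, n = correlate_lfc(join, subset)
                    summary[f"r_{subset}"] = {"r": r, "n": n}
                except ValueError as e:
                    summary[f"r_{subset}"] = {"error": str(e)}
            tf = {g.id: g.is_tf for g in genes}
            cand = tf_candidates(dcs_results[target], tf)
            cand.candidates.rename_axis("gene").to_csv(out / "tf_candidates.tsv", sep="\t")
            record(stage, out / "tf_candidates.tsv")
            summary["tf_candidates"] = {"n_differential": cand.n_differential,
                                        "n_candidates": len(cand.candidates),
                                        "n_higher": cand.n_higher,
                                        "n_lower": cand.n_lower}
            clusters = {g.id: g.cluster_id for g in genes if g.cluster_id}
            if clusters:
                cs = cluster_summary(dcs_results[target], clusters)
                cs.to_csv(out / "cluster_summary.tsv", sep="\t")
                record(stage, out / "cluster_summary.tsv")
            (out / "integration.json").write_text(json.dumps(summary, indent=2))
            record(stage, out / "integration.json")
        else:
            log.info("stage=%s skipped: no expression table configured", stage)
    except Exception as exc:
        raise StageError(stage, exc) from exc

    man = {"outputs": manifest}
    (out / "manifest.json").write_text(json.dumps(man, indent=2, sort_keys=True))
    return man
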