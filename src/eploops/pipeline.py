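"""End-to-end orchestration: stage ordering, config handling, manifest.

The pipeline reproduces the full integration analysis: significant-loop
filtering, motif scanning of anchors, anchor classification, ROSE-style
enhancer calling, chromatin-state clustering at motif centers, the
enhancer-promoter gene table with DE integration, subtype specificity,
signature scoring (module score + preranked GSEA), and replicate SCC.
Each stage reads only files and the outputs of earlier stages, so
stage-wise and run-all execution agree; the manifest hashes every output.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd
import yaml

from . import chromstate, enhancers, loops, motifs, regulome, signatures, tracks
from .errors import ConfigError, DegenerateDataError, InputFormatError
from .genome import GenomicInterval, read_fasta, read_gtf
from .simulate import SimConfig, simulate

logger = logging.getLogger("eploops")


@dataclass
class PipelineConfig:
    """All pipeline inputs and thresholds, with validated domains."""

    outdir: str = "eploops_out"
    seed: int = 0
    simulate: bool = False

    # inputs (ignored when simulate=True; then filled from the generator)
    genome_fa: Optional[str] = None
    gtf: Optional[str] = None
    loops_bedpe: Optional[str] = None
    tf_peaks: Optional[str] = None
    k27ac_peaks: Optional[str] = None
    tracks_dir: Optional[str] = None
    external_enhancers: Optional[str] = None
    de_table: Optional[str] = None
    tf_list: Optional[str] = None
    subtype_expr: Optional[str] = None
    subtype_labels: Optional[str] = None
    cell_expr: Optional[str] = None
    gene_sets: Optional[str] = None
    matrix_rep1: Optional[str] = None
    matrix_rep2: Optional[str] = None
    motif_meme: Optional[str] = None  # default: built-in HLF-like consensus PWM

    # thresholds (printed defaults of the analysis)
    bin_size: int = 5000
    loop_q: float = 0.01
    d_min: int = 50_000
    d_max: int = 3_000_000
    promoter_halfwidth: int = 10_000
    de_alpha: float = 0.05
    stitch_gap: int = 12_500
    tss_exclusion: int = 0
    top_fraction: float = 0.75
    k_clusters: int = 3
    fold: float = 3.0
    motif_threshold: float = 0.8
    span: int = 2000
    bin_width: int = 50
    scc_h: int = 3
    scc_lb: int = 0
    scc_ub: int = 3_000_000
    n_bins_module: int = 24
    n_ctrl: int = 100
    n_perm: int = 1000
    target_subtype: str = "TCF3HLF"
    active_track: str = "H3K27ac"
    tf_track: str = "TCF3HLF"
    atac_track: str = "ATAC"
    module_set: Optional[str] = None  # default: first set in the GMT
    scc_resolution: int = 100_000

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**data)
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ConfigError(f"{path}: config must be a mapping")
        return cls.from_dict(data)

    def validate(self) -> None:
        checks = [
            (0 < self.loop_q <= 1, "loop_q must be in (0, 1]"),
            (0 < self.de_alpha <= 1, "de_alpha must be in (0, 1]"),
            (0 <= self.d_min <= self.d_max, "need 0 <= d_min <= d_max"),
            (self.promoter_halfwidth > 0, "promoter_halfwidth must be positive"),
            (self.stitch_gap >= 0, "stitch_gap must be >= 0"),
            (0 < self.top_fraction <= 1, "top_fraction must be in (0, 1]"),
            (self.k_clusters >= 1, "k_clusters must be >= 1"),
            (self.fold > 0, "fold must be positive"),
            (0 < self.motif_threshold <= 1, "motif_threshold must be in (0, 1]"),
            (self.scc_h >= 0, "scc_h must be >= 0"),
            (0 <= self.scc_lb <= self.scc_ub, "need 0 <= scc_lb <= scc_ub"),
            (self.span > 0 and self.bin_width > 0, "span/bin_width must be positive"),
            (2 * self.span % self.bin_width == 0, "2*span must divide by bin_width"),
        ]
        for ok, msg in checks:
            if not ok:
                raise ConfigError(msg)

    def require(self, *names: str) -> None:
        for name in names:
            value = getattr(self, name)
            if value is None:
                raise ConfigError(f"config key {name!r} is required for this stage")
            if not Path(value).exists():
                raise InputFormatError(f"{name}: path {value} does not exist")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def default_pwm() -> motifs.PWM:
    """The shipped HLF-like PWM: a synthetic sharp PAR-bZIP consensus.

    This is a stand-in motif built from the TTACGTAA consensus, not a
    database PFM; swap in a MEME/JASPAR motif via the config for real data.
    """
    return motifs.PWM.from_consensus("HLF_like", "TTACGTAA")


def run_all(config: PipelineConfig) -> dict:
    """Execute every stage; returns the manifest dict (also written out)."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    summary: Dict[str, object] = {}

    if config.simulate:
        simdir = outdir / "sim"
        logger.info("stage simulate -> %s", simdir)
        sim_cfg = SimConfig(seed=config.seed)
        simulate(sim_cfg, simdir)
        config = dataclasses.replace(
            config,
            genome_fa=str(simdir / "genome.fa"),
            gtf=str(simdir / "genes.gtf"),
            loops_bedpe=str(simdir / "loops.bedpe"),
            tf_peaks=str(simdir / "tf_peaks.narrowPeak"),
            k27ac_peaks=str(simdir / "k27ac_peaks.broadPeak"),
            tracks_dir=str(simdir / "tracks"),
            external_enhancers=str(simdir / "external_enhancers.bed"),
            de_table=str(simdir / "de_table.tsv"),
            tf_list=str(simdir / "tf_list.txt"),
            subtype_expr=str(simdir / "subtype_expr.tsv"),
            subtype_labels=str(simdir / "subtype_labels.tsv"),
            cell_expr=str(simdir / "cell_expr.tsv"),
            gene_sets=str(simdir / "gene_sets.gmt"),
            matrix_rep1=str(simdir / "matrix_rep1.txt"),
            matrix_rep2=str(simdir / "matrix_rep2.txt"),
        )

    config.require(
        "genome_fa", "gtf", "loops_bedpe", "tf_peaks", "de_table"
    )

    # ---- stage: load core inputs
    genome = read_fasta(config.genome_fa)
    genes = read_gtf(config.gtf, chrom_names=genome.keys())
    all_loops = loops.read_bedpe(config.loops_bedpe, bin_size=config.bin_size)
    logger.info("loaded %d genes, %d loops", len(genes), len(all_loops))
    kept = loops.filter_loops(
        all_loops, q_max=config.loop_q, d_min=config.d_min, d_max=config.d_max
    )
    logger.info("significant loops after filter: %d", len(kept))
    anchors, _anchor_loops = loops.anchors_union(kept)
    summary["n_loops_input"] = len(all_loops)
    summary["n_loops_significant"] = len(kept)
    summary["n_anchors"] = len(anchors)

    # ---- stage: motif scan
    pwm = (
        motifs.read_meme_motif(config.motif_meme)
        if config.motif_meme
        else default_pwm()
    )
    flags_hits = motifs.flag_motif_regions(
        anchors, genome, pwm, threshold=config.motif_threshold
    )
    motif_flags = {k: has for k, (has, _) in flags_hits.items()}
    summary["n_motif_anchors"] = sum(motif_flags.values())
    summary["motif_anchor_fraction"] = (
        sum(motif_flags.values()) / len(anchors) if anchors else 0.0
    )
    hits_flat = [h for _, (_, hs) in sorted(flags_hits.items()) for h in hs]
    motifs.write_hits_bed(hits_flat, outdir / "motif_hits.bed")

    # ---- stage: anchor classification
    tf_peaks = enhancers.read_peaks(config.tf_peaks)
    anchor_classes = regulome.classify_anchors(
        anchors,
        genes,
        motif_flags,
        tf_peaks,
        promoter_halfwidth=config.promoter_halfwidth,
    )
    klass_counts = {
        k: sum(1 for a in anchor_classes if a.klass == k)
        for k in regulome.ANCHOR_CLASSES
    }
    summary["anchor_class_counts"] = klass_counts
    logger.info("anchor classes: %s", klass_counts)
    with open(outdir / "anchor_classes.tsv", "w") as fh:
        fh.write("chrom\tstart\tend\tklass\tis_promoter\thas_motif\thas_tf_peak\tgenes\n")
        for ac in anchor_classes:
            fh.write(
                f"{ac.anchor.chrom}\t{ac.anchor.start}\t{ac.anchor.end}\t{ac.klass}\t"
                f"{int(ac.is_promoter)}\t{int(ac.has_motif)}\t{int(ac.has_tf_peak)}\t"
                f"{','.join(ac.promoter_genes)}\n"
            )

    # ---- stage: enhancer calling
    rose_regions: List[enhancers.StitchedEnhancer] = []
    enhancer_classes: Dict[tuple, str] = {}
    track_set: Dict[str, tracks.BedGraphTrack] = {}
    if config.tracks_dir:
        for p in sorted(Path(config.tracks_dir).glob("*.bedGraph")):
            track_set[p.stem] = tracks.read_bedgraph(p)
    if config.k27ac_peaks and config.active_track in track_set:
        peaks = enhancers.read_peaks(config.k27ac_peaks)
        stitched = enhancers.stitch_peaks(
            peaks,
            stitch_gap=config.stitch_gap,
            tss_exclusion=config.tss_exclusion,
            genes=genes,
        )
        ranked = enhancers.score_and_rank(stitched, track_set[config.active_track])
        ranked = enhancers.call_super_enhancers(ranked)
        rose_regions = ranked
        enhancers.write_rose_table(ranked, outdir / "rose_table.tsv")
        summary["n_stitched_enhancers"] = len(ranked)
        summary["n_super_enhancers"] = sum(r.is_super for r in ranked)
        external = (
            enhancers.read_bed(config.external_enhancers)
            if config.external_enhancers
            else None
        )
        ihlf_anchors = [a.anchor for a in anchor_classes if a.klass == "I_HLF"]
        enhancer_classes = enhancers.annotate_enhancer_class(
            ihlf_anchors, rose_regions, external
        )

    # ---- stage: chromatin-state clustering at motif centers
    cluster_by_anchor: Dict[tuple, int] = {}
    assignment = None
    matrix = None
    if track_set:
        centers = []
        center_anchor = []
        for ac in anchor_classes:
            if ac.klass != "I_HLF":
                continue
            has, hs = flags_hits[ac.anchor.key()]
            if not has:
                continue
            best = max(hs, key=lambda h: (h.rel_score, -h.interval.start))
            centers.append(best.interval)
            center_anchor.append(ac.anchor.key())
        if len(centers) >= config.k_clusters:
            matrix = chromstate.build_signal_matrix(
                centers, track_set, span=config.span, bin_width=config.bin_width
            )
            top = chromstate.select_top_enriched(
                matrix, track=config.tf_track, top_fraction=config.top_fraction
            ) if config.tf_track in track_set else matrix
            assignment = chromstate.cluster_regions(
                top,
                k=config.k_clusters,
                seed=config.seed,
                active_track=config.active_track,
            )
            center_by_key = {
                c.key(): ak for c, ak in zip(centers, center_anchor)
            }
            for region, label in zip(top.regions, assignment.labels):
                cluster_by_anchor[center_by_key[region.key()]] = int(label)
            chromstate.write_cluster_bed(top, assignment, outdir / "clusters.bed")
            chromstate.write_matrix_tsv(top, outdir / "signal_matrix.tsv")
            try:
                stats_df = chromstate.density_stats(top, assignment)
                stats_df.to_csv(outdir / "density_stats.tsv", sep="\t", index=False)
            except DegenerateDataError as exc:
                logger.warning("density stats skipped: %s", exc)
            if (
                config.atac_track in track_set
                and config.tf_track in track_set
            ):
                corr = chromstate.cluster_signal_correlation(
                    top, assignment, track_a=config.atac_track, track_b=config.tf_track
                )
                corr.to_csv(outdir / "cluster_correlation.tsv", sep="\t", index=False)
            summary["cluster_sizes"] = {
                int(c): int((assignment.labels == c).sum())
                for c in sorted(set(assignment.labels))
            }
        else:
            logger.warning("too few motif-centered regions for clustering")

    # ---- stage: E-P pairing and the gene table
    pairs = regulome.build_ep_pairs(kept, anchor_classes)
    summary["n_ep_pairs"] = len(pairs)
    if pairs:
        summary["both_anchor_motif_fraction"] = regulome.both_anchor_motif_fraction(
            pairs
        )
    regulome.write_pairs_bedpe(pairs, outdir / "ep_pairs.bedpe")

    de = regulome.read_de_table(config.de_table)
    tf_set = regulome.read_gene_list(config.tf_list) if config.tf_list else set()

    specific: List[str] = []
    if config.subtype_expr and config.subtype_labels:
        expr = regulome.read_expression_tsv(config.subtype_expr)
        labels = regulome.read_label_tsv(config.subtype_labels)
        specific = regulome.subtype_specific_genes(
            expr, labels, config.target_subtype, fold=config.fold
        )
        with open(outdir / "subtype_specific.txt", "w") as fh:
            fh.write("\n".join(specific) + ("\n" if specific else ""))
        summary["n_subtype_specific_genes"] = len(specific)

    table = regulome.ep_gene_table(
        pairs,
        de,
        enhancer_classes=enhancer_classes,
        cluster_by_anchor=cluster_by_anchor,
        tf_list=tf_set,
        subtype_specific=set(specific),
        alpha=config.de_alpha,
    )
    regulome.write_ep_table(table, outdir / "ep_gene_table.tsv")
    sig = regulome.ep_genes(table)
    summary["n_candidate_genes"] = len(table)
    summary["n_ep_genes"] = len(sig)
    summary["n_ep_genes_up"] = sum(r.de_direction == "up" for r in sig)
    summary["n_ep_genes_down"] = sum(r.de_direction == "down" for r in sig)
    breakdown = regulome.cluster_direction_breakdown(table)
    if not breakdown.empty:
        breakdown.to_csv(outdir / "cluster_direction.tsv", sep="\t", index=False)
        summary["cluster_fraction_down"] = {
            int(r.cluster): float(r.fraction_down) for r in breakdown.itertuples()
        }
    tfs = regulome.tf_subset(table)
    summary["n_tf_ep_genes_down"] = len(tfs["down_tfs"])
    summary["n_tf_ep_genes_up"] = len(tfs["up_tfs"])
    with open(outdir / "tf_ep_genes.json", "w") as fh:
        json.dump(tfs, fh, indent=1, sort_keys=True)

    # ---- stage: signatures
    if config.cell_expr and config.gene_sets:
        cell_expr = regulome.read_expression_tsv(config.cell_expr)
        sets = signatures.read_gmt(config.gene_sets)
        set_name = config.module_set or next(iter(sets))
        if set_name not in sets:
            raise ConfigError(f"module_set {set_name!r} not present in gene sets")
        ms = signatures.module_score(
            cell_expr,
            sets[set_name],
            n_bins=config.n_bins_module,
            n_ctrl=config.n_ctrl,
            seed=config.seed,
        )
        ms.scores.rename("module_score").to_csv(
            outdir / "module_scores.tsv", sep="\t"
        )
        summary["module_score_mean"] = float(ms.scores.mean())
    if config.gene_sets:
        de_df = pd.read_csv(config.de_table, sep="\t")
        ranking = signatures.ranking_from_de(de_df)
        sets = signatures.read_gmt(config.gene_sets)
        gsea = signatures.preranked_gsea(
            ranking, sets, n_perm=config.n_perm, seed=config.seed
        )
        signatures.write_gsea_results(gsea, outdir / "gsea_results.tsv")
        summary["n_gsea_sets"] = len(gsea)

    # ---- stage: replicate SCC
    if config.matrix_rep1 and config.matrix_rep2:
        chrom = sorted(genome)[0]
        n_bins = len(genome[chrom]) // config.scc_resolution
        m1 = loops.read_triplet_matrix(
            config.matrix_rep1, chrom, config.scc_resolution, n_bins
        )
        m2 = loops.read_triplet_matrix(
            config.matrix_rep2, chrom, config.scc_resolution, n_bins
        )
        summary["scc_replicates"] = loops.scc(
            m1, m2, h=config.scc_h, lb=config.scc_lb, ub=config.scc_ub
        )

    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)

    manifest = {"outputs": {}}
    for p in sorted(outdir.rglob("*")):
        if p.is_file() and p.name != "manifest.json":
            manifest["outputs"][str(p.relative_to(outdir))] = _sha256(p)
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    logger.info("wrote %d outputs to %s", len(manifest["outputs"]), outdir)
    return manifest
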