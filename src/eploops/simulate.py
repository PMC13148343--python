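"""Seeded synthetic-data generator with planted ground truth.

Emits every input the pipeline consumes — a toy genome with gene models,
loops with planted distal-anchor/promoter structure over a
distance-decaying background, motif instances at planted anchors, TF and
H3K27ac peaks, chromatin-signal tracks realizing three archetypes
(active, primed, repressed-but-accessible), a knockout DE table, a
subtype-labeled expression matrix with planted specific genes, a
cell-level expression matrix with a planted shifted module, and replicate
contact matrices — together with a ground-truth record so every stage of
the analysis has an exact oracle.

Layout strategy: each chromosome is tiled at 50 kb; genes occupy a random
subset of tiles (one gene per tile, body away from tile edges), so that
promoter windows of distinct genes never share a 5-kb anchor bin and free
tiles always exist for distal anchors.  Background loops draw q above the
significance threshold (easy mode), so the planted/background split is
exact under the default loop filter; ``hard_mode`` overlaps the two q
distributions for sensitivity studies.

Randomness: one RNG stream per (seed, stage), so adding a stage never
perturbs the output of earlier stages.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Sequence, Tuple

import numpy as np

from .errors import ConfigError
from .genome import GeneModel, GenomicInterval, write_fasta, write_gtf
from .chromstate import SignalMatrix
from .loops import ContactMatrix, write_triplet_matrix

TILE = 50_000

TRACK_NAMES = ["TCF3HLF", "H3K27ac", "H3K4me1", "H3K4me3", "H3K27me3", "ATAC"]

# Peak amplitudes of the three chromatin archetypes (rows: archetype 1..3).
# 1: active enhancer-like (high acetylation + accessibility);
# 2: primed (K4me1-high, K27ac-low); 3: repressed-but-accessible
# (K27me3-high with elevated accessibility and TF occupancy).
ARCHETYPE_AMPLITUDES = {
    1: {"TCF3HLF": 8.0, "H3K27ac": 10.0, "H3K4me1": 8.0, "H3K4me3": 3.0, "H3K27me3": 0.5, "ATAC": 8.0},
    2: {"TCF3HLF": 5.0, "H3K27ac": 2.0, "H3K4me1": 9.0, "H3K4me3": 1.0, "H3K27me3": 1.0, "ATAC": 3.0},
    3: {"TCF3HLF": 6.0, "H3K27ac": 0.5, "H3K4me1": 0.5, "H3K4me3": 0.5, "H3K27me3": 8.0, "ATAC": 5.0},
}

_STAGES = {
    "genome": 1,
    "genes": 2,
    "loops": 3,
    "tracks": 4,
    "enhancers": 5,
    "de": 6,
    "subtype": 7,
    "cells": 8,
    "sets": 9,
    "contacts": 10,
    "gmt": 11,
}

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class SimConfig:
    """Study conditions for the synthetic regulome."""

    seed: int = 0
    n_chroms: int = 3
    chrom_len: int = 5_000_000
    n_genes: int = 200
    bin_size: int = 5000
    n_loops: int = 2000
    n_planted_ep_genes: int = 30
    frac_both_anchor_motif: float = 0.01
    archetype_fractions: Tuple[float, float, float] = (0.5, 0.3, 0.2)
    de_alpha: float = 0.05
    n_subtypes: int = 24
    n_samples_per_subtype: int = 8
    n_specific_genes: int = 22
    n_cells: int = 500
    n_expr_genes: int = 1000
    noise_sd: float = 0.1
    module_size: int = 30
    module_delta: float = 1.0
    motif_consensus: str = "TTACGTAA"  # PAR-bZIP (HLF-like) consensus
    n_decoy_tf_peaks: int = 30
    n_typical_enhancer_domains: int = 25
    n_super_enhancer_domains: int = 5
    hard_mode: bool = False

    def validate(self) -> None:
        if self.n_chroms < 1 or self.chrom_len < 10 * TILE:
            raise ConfigError("need >=1 chromosome of >=500 kb")
        if self.chrom_len % self.bin_size:
            raise ConfigError("chrom_len must be a multiple of bin_size")
        n_tiles = self.chrom_len // TILE
        genes_per_chrom = math.ceil(self.n_genes / self.n_chroms)
        planted_per_chrom = math.ceil((self.n_planted_ep_genes + 2) / self.n_chroms)
        if genes_per_chrom + planted_per_chrom + 2 > n_tiles:
            raise ConfigError(
                "infeasible layout: too many genes + planted anchors per chromosome"
            )
        if self.n_planted_ep_genes > self.n_genes:
            raise ConfigError("more planted E-P genes than genes")
        if self.n_planted_ep_genes < 1:
            raise ConfigError("need at least one planted E-P gene")
        if not 0 <= self.frac_both_anchor_motif <= 1:
            raise ConfigError("frac_both_anchor_motif must be in [0, 1]")
        if abs(sum(self.archetype_fractions) - 1.0) > 1e-9:
            raise ConfigError("archetype_fractions must sum to 1")
        if self.n_specific_genes > self.n_expr_genes:
            raise ConfigError("more specific genes than expression genes")
        if self.module_size > self.n_expr_genes:
            raise ConfigError("module larger than expression gene universe")
        if self.n_loops < self.n_planted_ep_genes + 2:
            raise ConfigError("n_loops too small for the planted structure")
        if len(self.motif_consensus) < 4 or any(
            c not in "ACGT" for c in self.motif_consensus.upper()
        ):
            raise ConfigError("motif_consensus must be an ACGT word of length >= 4")


@dataclass
class GroundTruth:
    """Planted facts, serialized next to the generated files."""

    motif_positions: List[Tuple[str, int]] = field(default_factory=list)
    planted_genes: List[dict] = field(default_factory=list)
    top_gene: str = ""
    anchor_archetypes: Dict[str, int] = field(default_factory=dict)
    de_directions: Dict[str, str] = field(default_factory=dict)
    specific_genes: List[str] = field(default_factory=list)
    module_genes: List[str] = field(default_factory=list)
    shifted_cells: List[str] = field(default_factory=list)
    module_delta: float = 0.0
    super_enhancers: List[Tuple[str, int, int]] = field(default_factory=list)
    both_anchor_motif_genes: List[str] = field(default_factory=list)
    n_planted_loops: int = 0
    tf_genes: List[str] = field(default_factory=list)
    target_subtype: str = "TCF3HLF"

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True)

    @classmethod
    def load(cls, path) -> "GroundTruth":
        with open(path) as fh:
            data = json.load(fh)
        gt = cls(**data)
        gt.motif_positions = [tuple(x) for x in gt.motif_positions]
        gt.super_enhancers = [tuple(x) for x in gt.super_enhancers]
        return gt


def _rng(config: SimConfig, stage: str) -> np.random.Generator:
    return np.random.default_rng([config.seed % (2**31), _STAGES[stage]])


def _anchor_name(chrom: str, start: int, end: int) -> str:
    return f"{chrom}:{start}-{end}"


# ---------------------------------------------------------------------------
# Genome / genes


def _scrub_motif(seqs: Dict[str, np.ndarray], consensus: str) -> None:
    """Mutate chance occurrences of the consensus (either strand) away.

    The genome is random, so the planted word must not occur by chance or
    planted-fraction statistics would drift.  Each occurrence has its
    middle base rotated A->C->G->T->A; rescan until clean.
    """
    patterns = [consensus, _revcomp(consensus)]
    pat_arrays = [np.frombuffer(p.encode(), dtype=np.uint8) for p in patterns]
    L = len(consensus)
    for _ in range(50):
        dirty = False
        for arr in seqs.values():
            windows = np.lib.stride_tricks.sliding_window_view(arr, L)
            for pat in pat_arrays:
                hits = np.nonzero((windows == pat).all(axis=1))[0]
                for pos in hits:
                    base = arr[pos + L // 2]
                    idx = int(np.nonzero(_BASES == base)[0][0])
                    arr[pos + L // 2] = _BASES[(idx + 1) % 4]
                    dirty = True
        if not dirty:
            return
    raise RuntimeError("motif scrubbing did not converge")


def _revcomp(s: str) -> str:
    return s.translate(str.maketrans("ACGT", "TGCA"))[::-1]


def _make_genome(config: SimConfig) -> Dict[str, np.ndarray]:
    rng = _rng(config, "genome")
    seqs = {}
    for c in range(1, config.n_chroms + 1):
        seqs[f"chr{c}"] = _BASES[rng.integers(0, 4, size=config.chrom_len)].copy()
    _scrub_motif(seqs, config.motif_consensus.upper())
    return seqs


def _make_genes(config: SimConfig) -> Tuple[List[GeneModel], Dict[str, set]]:
    """Place one gene per selected 50-kb tile; return genes + gene tiles."""
    rng = _rng(config, "genes")
    chroms = [f"chr{c}" for c in range(1, config.n_chroms + 1)]
    n_tiles = config.chrom_len // TILE
    per_chrom = [config.n_genes // config.n_chroms] * config.n_chroms
    for i in range(config.n_genes % config.n_chroms):
        per_chrom[i] += 1
    genes: List[GeneModel] = []
    gene_tiles: Dict[str, set] = {c: set() for c in chroms}
    gi = 0
    for chrom, n_here in zip(chroms, per_chrom):
        tiles = rng.choice(n_tiles, size=n_here, replace=False)
        for tile in sorted(tiles):
            gene_tiles[chrom].add(int(tile))
            t0 = int(tile) * TILE
            strand = "+" if rng.random() < 0.5 else "-"
            gstart = t0 + 12_000
            span = 8_000 + int(rng.integers(0, 12_000))
            gend = gstart + span
            e1 = 500 + int(rng.integers(0, 1500))
            e2 = 500 + int(rng.integers(0, 1500))
            exons = [
                GenomicInterval(chrom, gstart, gstart + e1, strand),
                GenomicInterval(chrom, gend - e2, gend, strand),
            ]
            gi += 1
            genes.append(
                GeneModel(
                    gene_id=f"G{gi:04d}",
                    symbol=f"G{gi:04d}",
                    chrom=chrom,
                    strand=strand,
                    exons=exons,
                )
            )
    return genes, gene_tiles


# ---------------------------------------------------------------------------
# Loops and planted E-P structure


def _plant_structure(
    config: SimConfig,
    genes: List[GeneModel],
    gene_tiles: Dict[str, set],
    seqs: Dict[str, np.ndarray],
):
    """Choose planted genes, distal anchors and loops; plant motifs."""
    rng = _rng(config, "loops")
    bin_size = config.bin_size
    n_tiles = config.chrom_len // TILE
    consensus = config.motif_consensus.upper()
    L = len(consensus)
    pat = np.frombuffer(consensus.encode(), dtype=np.uint8)

    tss_by_chrom: Dict[str, np.ndarray] = {}
    for g in genes:
        tss_by_chrom.setdefault(g.chrom, []).append(g.tss)  # type: ignore[arg-type]
    tss_by_chrom = {c: np.sort(np.array(v)) for c, v in tss_by_chrom.items()}

    def far_from_tss(chrom: str, start: int, margin: int = 16_000) -> bool:
        tss = tss_by_chrom.get(chrom)
        if tss is None or tss.size == 0:
            return True
        return not ((tss > start - margin) & (tss < start + bin_size + margin)).any()

    free_bins: Dict[str, List[int]] = {}
    for chrom in tss_by_chrom:
        bins = []
        for tile in range(n_tiles):
            if tile in gene_tiles[chrom]:
                continue
            for b in range(tile * TILE, (tile + 1) * TILE, bin_size):
                if far_from_tss(chrom, b):
                    bins.append(b)
        free_bins[chrom] = bins

    planted_idx = rng.choice(len(genes), size=config.n_planted_ep_genes, replace=False)
    planted_genes = [genes[i] for i in sorted(planted_idx)]
    top_gene = planted_genes[int(rng.integers(0, len(planted_genes)))]

    used_bins: Dict[str, set] = {c: set() for c in free_bins}
    motif_positions: List[Tuple[str, int]] = []
    loops_rows = []  # (chrom, b1, chrom, b2, count, q)
    planted_records: List[dict] = []
    archetype_choices = [1, 2, 3]

    def pick_i_anchor(chrom: str, p_bin: int) -> int:
        candidates = [
            b
            for b in free_bins[chrom]
            if b not in used_bins[chrom]
            and 60_000 <= abs(b - p_bin) <= 1_500_000
        ]
        if not candidates:
            raise ConfigError(
                f"infeasible layout: no free distal bin near {chrom}:{p_bin}"
            )
        return int(candidates[int(rng.integers(0, len(candidates)))])

    def plant_motif(chrom: str, bin_start: int) -> int:
        center = bin_start + bin_size // 2
        pos = center - L // 2
        seqs[chrom][pos: pos + L] = pat
        motif_positions.append((chrom, pos))
        return center

    anchor_archetypes: Dict[str, int] = {}
    for g in planted_genes:
        p_bin = (g.tss // bin_size) * bin_size
        n_anchors = 3 if g is top_gene else 1
        anchors = []
        for j in range(n_anchors):
            i_bin = pick_i_anchor(g.chrom, p_bin)
            used_bins[g.chrom].add(i_bin)
            plant_motif(g.chrom, i_bin)
            arch = int(
                rng.choice(archetype_choices, p=list(config.archetype_fractions))
            )
            anchor_archetypes[_anchor_name(g.chrom, i_bin, i_bin + bin_size)] = arch
            if g is top_gene:
                count = 1 + int(rng.poisson(60))
                q = (j + 1) * 1e-7
            else:
                count = 1 + int(rng.poisson(15))
                q = 10.0 ** rng.uniform(-6, -3)
            lo, hi = min(p_bin, i_bin), max(p_bin, i_bin)
            loops_rows.append((g.chrom, lo, g.chrom, hi, count, q))
            anchors.append({"start": i_bin, "count": count, "q": q, "archetype": arch})
        planted_records.append(
            {
                "gene_id": g.gene_id,
                "chrom": g.chrom,
                "tss": g.tss,
                "p_bin": p_bin,
                "i_anchors": anchors,
                "sumCC": sum(a["count"] for a in anchors),
                "best_q": min(a["q"] for a in anchors),
            }
        )

    # both-anchor-motif pairs: plant the consensus into the promoter anchor
    # of a few non-top planted genes
    n_pairs = len(loops_rows)
    if config.frac_both_anchor_motif > 0:
        n_both = max(1, int(round(config.frac_both_anchor_motif * n_pairs)))
    else:
        n_both = 0
    both_candidates = [r for r in planted_records if r["gene_id"] != top_gene.gene_id]
    both_genes = [
        both_candidates[i]["gene_id"]
        for i in rng.choice(len(both_candidates), size=min(n_both, len(both_candidates)), replace=False)
    ]
    for rec in planted_records:
        if rec["gene_id"] in both_genes:
            plant_motif(rec["chrom"], rec["p_bin"])

    # background loops: q above threshold (easy mode), distance-decaying counts
    n_bg = config.n_loops - n_pairs
    chroms = list(tss_by_chrom)
    max_bin = config.chrom_len - bin_size
    for _ in range(n_bg):
        chrom = chroms[int(rng.integers(0, len(chroms)))]
        while True:
            b1 = int(rng.integers(0, max_bin // bin_size)) * bin_size
            d = int(rng.integers(50_000 // bin_size, 3_000_000 // bin_size + 1)) * bin_size
            b2 = b1 + d
            if b2 <= max_bin:
                break
        q = rng.uniform(0.003 if config.hard_mode else 0.0101, 1.0)
        lam = 15.0 * (100_000.0 / d)
        count = 1 + int(rng.poisson(lam))
        loops_rows.append((chrom, b1, chrom, b2, count, q))

    return (
        planted_genes,
        top_gene,
        planted_records,
        both_genes,
        loops_rows,
        motif_positions,
        anchor_archetypes,
        free_bins,
        used_bins,
    )


# ---------------------------------------------------------------------------
# Signal profiles


def _profile(n_bins: int, amplitude: float, rng: np.random.Generator, noise_sd: float) -> np.ndarray:
    x = (np.arange(n_bins) - (n_bins - 1) / 2) / (n_bins / 6.0)
    shape = np.exp(-0.5 * x**2)
    return np.clip(amplitude * shape + rng.normal(0, noise_sd, n_bins), 0, None)


def archetype_signal_matrix(
    n_regions: int,
    noise_sd: float = 0.1,
    seed: int = 0,
    fractions: Sequence[float] = (0.5, 0.3, 0.2),
    span: int = 2000,
    bin_width: int = 50,
) -> Tuple[SignalMatrix, np.ndarray]:
    """Directly construct a motif-centered signal matrix with known labels.

    A file-free shortcut through the same archetype model the full
    generator writes to bedGraph, for clustering tests at chosen n and
    noise.  Returns the matrix and the planted archetype label (1..3) per
    region.
    """
    rng = np.random.default_rng(seed)
    n_bins = 2 * span // bin_width
    labels = rng.choice([1, 2, 3], size=n_regions, p=list(fractions))
    values = {t: np.zeros((n_regions, n_bins)) for t in TRACK_NAMES}
    regions = []
    for i in range(n_regions):
        regions.append(
            GenomicInterval("chrS", 10_000 + i * 10_000, 10_000 + i * 10_000 + 8)
        )
        for t in TRACK_NAMES:
            values[t][i] = _profile(
                n_bins, ARCHETYPE_AMPLITUDES[int(labels[i])][t], rng, noise_sd
            )
    matrix = SignalMatrix(
        regions=regions,
        tracks=list(TRACK_NAMES),
        values=values,
        bin_width=bin_width,
        span=span,
        track_totals={t: float(values[t].sum() * bin_width) or 1.0 for t in TRACK_NAMES},
    )
    return matrix, labels


# ---------------------------------------------------------------------------
# Main entry


def simulate(config: SimConfig, outdir) -> GroundTruth:
    """Generate the full synthetic input tree; returns the ground truth.

    Output files (all plain text): genome.fa, genes.gtf, loops.bedpe,
    tf_peaks.narrowPeak, k27ac_peaks.broadPeak, external_enhancers.bed,
    tracks/<name>.bedGraph, de_table.tsv, subtype_expr.tsv,
    subtype_labels.tsv, cell_expr.tsv, cell_labels.tsv, gene_sets.gmt,
    tf_list.txt, matrix_rep1.txt, matrix_rep2.txt, ground_truth.json.
    """
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "tracks").mkdir(exist_ok=True)
    gt = GroundTruth()

    seqs = _make_genome(config)
    genes, gene_tiles = _make_genes(config)
    (
        planted_genes,
        top_gene,
        planted_records,
        both_genes,
        loops_rows,
        motif_positions,
        anchor_archetypes,
        free_bins,
        used_bins,
    ) = _plant_structure(config, genes, gene_tiles, seqs)

    gt.motif_positions = sorted(motif_positions)
    gt.planted_genes = planted_records
    gt.top_gene = top_gene.gene_id
    gt.anchor_archetypes = anchor_archetypes
    gt.both_anchor_motif_genes = sorted(both_genes)
    gt.n_planted_loops = sum(len(r["i_anchors"]) for r in planted_records)

    write_fasta({c: arr.tobytes().decode() for c, arr in seqs.items()}, outdir / "genome.fa")
    write_gtf(genes, outdir / "genes.gtf")

    with open(outdir / "loops.bedpe", "w") as fh:
        for chrom1, b1, chrom2, b2, count, q in loops_rows:
            fh.write(
                f"{chrom1}\t{b1}\t{b1 + config.bin_size}\t{chrom2}\t{b2}\t"
                f"{b2 + config.bin_size}\t{count}\t{q:.6g}\n"
            )

    _write_peaks_and_tracks(
        config, outdir, gt, planted_records, anchor_archetypes, free_bins, used_bins, gene_tiles
    )
    _write_de_table(config, outdir, gt, genes, planted_records, anchor_archetypes, top_gene)
    _write_expression(config, outdir, gt, genes)
    _write_contact_matrices(config, outdir)

    gt.save(outdir / "ground_truth.json")
    return gt


def _write_peaks_and_tracks(
    config: SimConfig,
    outdir: Path,
    gt: GroundTruth,
    planted_records: List[dict],
    anchor_archetypes: Dict[str, int],
    free_bins: Dict[str, List[int]],
    used_bins: Dict[str, set],
    gene_tiles: Dict[str, set],
) -> None:
    rng = _rng(config, "tracks")
    erng = _rng(config, "enhancers")
    bin_size = config.bin_size
    n_bins = bin_size // 50

    # TF peaks: one per planted distal anchor + uniform decoys
    tf_rows = []
    anchor_list = []
    for rec in planted_records:
        for a in rec["i_anchors"]:
            anchor_list.append((rec["chrom"], a["start"]))
    for chrom, start in sorted(set(anchor_list)):
        center = start + bin_size // 2
        tf_rows.append((chrom, center - 250, center + 250))
    chroms = sorted(free_bins)
    for _ in range(config.n_decoy_tf_peaks):
        chrom = chroms[int(rng.integers(0, len(chroms)))]
        pos = int(rng.integers(0, config.chrom_len - 500))
        tf_rows.append((chrom, pos, pos + 500))
    with open(outdir / "tf_peaks.narrowPeak", "w") as fh:
        for i, (chrom, s, e) in enumerate(sorted(tf_rows)):
            fh.write(
                f"{chrom}\t{s}\t{e}\tpeak{i}\t0\t.\t1.0\t-1\t-1\t{(e - s) // 2}\n"
            )

    # archetype signal profiles over each planted anchor bin (50-bp bins)
    track_rows: Dict[str, List[tuple]] = {t: [] for t in TRACK_NAMES}
    k27_peaks: List[Tuple[str, int, int]] = []
    for name in sorted(anchor_archetypes):
        chrom, rest = name.split(":")
        start = int(rest.split("-")[0])
        arch = anchor_archetypes[name]
        for t in TRACK_NAMES:
            prof = _profile(n_bins, ARCHETYPE_AMPLITUDES[arch][t], rng, config.noise_sd)
            for j, v in enumerate(prof):
                if v > 0:
                    track_rows[t].append(
                        (chrom, start + j * 50, start + (j + 1) * 50, float(v))
                    )
        if arch in (1, 2):
            center = start + bin_size // 2
            k27_peaks.append((chrom, center - 1000, center + 1000))

    # H3K27ac enhancer domains in tiles free of planted anchors
    n_tiles = config.chrom_len // TILE
    anchor_tiles = {
        (c, b // TILE) for c in used_bins for b in used_bins[c]
    }
    domain_tiles: List[Tuple[str, int]] = []
    attempts = 0
    need = config.n_typical_enhancer_domains + config.n_super_enhancer_domains
    taken = set(anchor_tiles)
    while len(domain_tiles) < need and attempts < 50 * need:
        attempts += 1
        chrom = chroms[int(erng.integers(0, len(chroms)))]
        tile = int(erng.integers(0, n_tiles))
        if (chrom, tile) in taken:
            continue
        taken.add((chrom, tile))
        domain_tiles.append((chrom, tile))
    if len(domain_tiles) < need:
        raise ConfigError("infeasible layout: not enough tiles for enhancer domains")

    super_regions: List[Tuple[str, int, int]] = []
    for k, (chrom, tile) in enumerate(domain_tiles):
        is_super = k < config.n_super_enhancer_domains
        t0 = tile * TILE + 1000
        n_peaks = 2 + int(erng.integers(0, 3))
        area = (
            erng.uniform(5e6, 1e7) if is_super else erng.uniform(1e4, 1e5)
        )
        peak_area = area / n_peaks
        pos = t0
        dom_start = pos
        for _ in range(n_peaks):
            plen = 1000 + int(erng.integers(0, 1000))
            value = peak_area / plen
            k27_peaks.append((chrom, pos, pos + plen))
            track_rows["H3K27ac"].append((chrom, pos, pos + plen, float(value)))
            pos += plen + 3000 + int(erng.integers(0, 5000))
        dom_end = k27_peaks[-1][2]
        if is_super:
            super_regions.append((chrom, dom_start, dom_end))
    gt.super_enhancers = sorted(super_regions)

    with open(outdir / "k27ac_peaks.broadPeak", "w") as fh:
        for i, (chrom, s, e) in enumerate(sorted(k27_peaks)):
            fh.write(f"{chrom}\t{s}\t{e}\tk27peak{i}\t0\t.\t1.0\t-1\t-1\n")

    for t in TRACK_NAMES:
        rows = sorted(track_rows[t])
        with open(outdir / "tracks" / f"{t}.bedGraph", "w") as fh:
            for chrom, s, e, v in rows:
                fh.write(f"{chrom}\t{s}\t{e}\t{v:.6g}\n")

    # external (FANTOM-like) enhancer BED: archetype-2 anchors + random decoys
    ext_rows = []
    for name, arch in sorted(anchor_archetypes.items()):
        if arch == 2:
            chrom, rest = name.split(":")
            s, e = (int(x) for x in rest.split("-"))
            ext_rows.append((chrom, s, e))
    for _ in range(20):
        chrom = chroms[int(erng.integers(0, len(chroms)))]
        pos = int(erng.integers(0, config.chrom_len - 2000))
        ext_rows.append((chrom, pos, pos + 2000))
    with open(outdir / "external_enhancers.bed", "w") as fh:
        for chrom, s, e in sorted(ext_rows):
            fh.write(f"{chrom}\t{s}\t{e}\n")


def _write_de_table(
    config: SimConfig,
    outdir: Path,
    gt: GroundTruth,
    genes: List[GeneModel],
    planted_records: List[dict],
    anchor_archetypes: Dict[str, int],
    top_gene: GeneModel,
) -> None:
    rng = _rng(config, "de")
    directions: Dict[str, str] = {}
    rows = []
    planted_ids = {r["gene_id"] for r in planted_records}
    arch_of_gene = {
        r["gene_id"]: r["i_anchors"][0]["archetype"] for r in planted_records
    }
    for g in genes:
        gid = g.gene_id
        if gid in planted_ids:
            adj_p = 10.0 ** rng.uniform(-8, math.log10(0.01))
            arch = arch_of_gene[gid]
            if gid == top_gene.gene_id:
                direction = "down"
            elif arch == 1:
                direction = "down" if rng.random() < 0.7 else "up"
            else:
                direction = "down" if rng.random() < 0.5 else "up"
            mag = rng.uniform(0.5, 3.0)
            log2fc = -mag if direction == "down" else mag
            directions[gid] = direction
        else:
            adj_p = rng.uniform(0.06, 1.0)
            log2fc = rng.normal(0, 0.3)
        rows.append((gid, log2fc, adj_p))
    with open(outdir / "de_table.tsv", "w") as fh:
        fh.write("gene_id\tlog2fc\tadj_p\n")
        for gid, fc, p in rows:
            fh.write(f"{gid}\t{fc:.4f}\t{p:.6g}\n")
    gt.de_directions = directions

    # TF list: a subset of planted genes plus null genes
    srng = _rng(config, "sets")
    planted_sorted = sorted(planted_ids)
    n_tf_planted = min(12, len(planted_sorted))
    tf_planted = [
        planted_sorted[i]
        for i in srng.choice(len(planted_sorted), size=n_tf_planted, replace=False)
    ]
    null_ids = sorted(set(g.gene_id for g in genes) - planted_ids)
    tf_null = [
        null_ids[i] for i in srng.choice(len(null_ids), size=min(20, len(null_ids)), replace=False)
    ]
    tf_genes = sorted(set(tf_planted) | set(tf_null))
    with open(outdir / "tf_list.txt", "w") as fh:
        for gid in tf_genes:
            fh.write(gid + "\n")
    gt.tf_genes = tf_genes


def _write_expression(
    config: SimConfig, outdir: Path, gt: GroundTruth, genes: List[GeneModel]
) -> None:
    # gene universe: genome genes first, then synthetic fillers
    universe = [g.gene_id for g in genes][: config.n_expr_genes]
    fill = config.n_expr_genes - len(universe)
    universe += [f"X{i:04d}" for i in range(1, fill + 1)]

    # --- subtype matrix with planted specific genes
    rng = _rng(config, "subtype")
    planted_ids = [r["gene_id"] for r in gt.planted_genes]
    down_first = sorted(
        planted_ids, key=lambda g: (gt.de_directions.get(g) != "down", g)
    )
    specific = down_first[: config.n_specific_genes]
    if len(specific) < config.n_specific_genes:
        extras = [u for u in universe if u not in specific]
        specific += extras[: config.n_specific_genes - len(specific)]
    specific_set = set(specific)

    subtypes = [gt.target_subtype] + [
        f"SUBTYPE{i:02d}" for i in range(1, config.n_subtypes)
    ]
    samples = []
    labels = []
    for st in subtypes:
        for j in range(config.n_samples_per_subtype):
            samples.append(f"{st}_s{j}")
            labels.append(st)
    mu = rng.normal(1.0, 0.5, size=len(universe))
    expr = rng.lognormal(mean=mu[:, None], sigma=0.6, size=(len(universe), len(samples)))
    label_arr = np.array(labels)
    target_cols = label_arr == gt.target_subtype
    other_masks = [
        label_arr == st for st in subtypes if st != gt.target_subtype
    ]
    for gi, gid in enumerate(universe):
        max_other = max(np.median(expr[gi, m]) for m in other_masks)
        t_med = np.median(expr[gi, target_cols])
        if gid in specific_set:
            factor = 3.5 * max_other / t_med if t_med > 0 else 1.0
            expr[gi, target_cols] *= max(1.0, factor)
        elif t_med > 2.0 * max_other:
            expr[gi, target_cols] *= 2.0 * max_other / t_med
    with open(outdir / "subtype_expr.tsv", "w") as fh:
        fh.write("gene_id\t" + "\t".join(samples) + "\n")
        for gi, gid in enumerate(universe):
            fh.write(gid + "\t" + "\t".join(f"{v:.4f}" for v in expr[gi]) + "\n")
    with open(outdir / "subtype_labels.tsv", "w") as fh:
        fh.write("sample\tsubtype\n")
        for s, lab in zip(samples, labels):
            fh.write(f"{s}\t{lab}\n")
    gt.specific_genes = sorted(specific)

    # --- cell matrix with a planted shifted module; module genes sit in the
    # mid-range of baseline expression so bin-matched controls exist
    crng = _rng(config, "cells")
    cells = [f"cell{i:04d}" for i in range(config.n_cells)]
    n_shift = config.n_cells // 2
    mu_g = crng.uniform(0, 2, size=len(universe))
    mid = np.nonzero(mu_g <= 1.3)[0]
    module = sorted(
        universe[i]
        for i in crng.choice(mid, size=min(config.module_size, mid.size), replace=False)
    )
    cexpr = crng.normal(mu_g[:, None], 1.0, size=(len(universe), len(cells)))
    mod_idx = [universe.index(g) for g in module]
    cexpr[np.ix_(mod_idx, range(n_shift))] += config.module_delta
    with open(outdir / "cell_expr.tsv", "w") as fh:
        fh.write("gene_id\t" + "\t".join(cells) + "\n")
        for gi, gid in enumerate(universe):
            fh.write(gid + "\t" + "\t".join(f"{v:.4f}" for v in cexpr[gi]) + "\n")
    with open(outdir / "cell_labels.tsv", "w") as fh:
        fh.write("cell\tgroup\n")
        for i, c in enumerate(cells):
            fh.write(f"{c}\t{'shifted' if i < n_shift else 'baseline'}\n")
    gt.module_genes = module
    gt.shifted_cells = cells[:n_shift]
    gt.module_delta = config.module_delta

    # --- gene sets (GMT): planted module, planted DE directions, random sets
    srng = _rng(config, "gmt")
    sets = {"PLANTED_MODULE": module}
    down = sorted(g for g, d in gt.de_directions.items() if d == "down")
    up = sorted(g for g, d in gt.de_directions.items() if d == "up")
    if len(down) >= 3:
        sets["PLANTED_DOWN"] = down
    if len(up) >= 3:
        sets["PLANTED_UP"] = up
    de_universe = [g.gene_id for g in genes]
    for k in range(1, 6):
        members = sorted(
            de_universe[i]
            for i in srng.choice(len(de_universe), size=min(30, len(de_universe)), replace=False)
        )
        sets[f"RANDOM_SET_{k}"] = members
    with open(outdir / "gene_sets.gmt", "w") as fh:
        for name, members in sets.items():
            fh.write("\t".join([name, "na", *members]) + "\n")


def _write_contact_matrices(config: SimConfig, outdir: Path) -> None:
    rng = _rng(config, "contacts")
    resolution = 100_000
    n = config.chrom_len // resolution
    ij = np.abs(np.subtract.outer(np.arange(n), np.arange(n)))
    base = 80.0 / (1.0 + ij)
    for rep in (1, 2):
        noisy = rng.poisson(base).astype(float)
        sym = np.triu(noisy) + np.triu(noisy, 1).T
        cm = ContactMatrix(chrom="chr1", resolution=resolution, matrix=sym)
        write_triplet_matrix(cm, outdir / f"matrix_rep{rep}.txt")
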