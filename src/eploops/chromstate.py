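"""Motif-centered signal matrices, 3-state clustering and density statistics.

Regions (typically fusion-TF-bound sites centered on their DNA motif) are
summarized as per-bin mean signal for a set of tracks (TF occupancy,
histone marks, accessibility), clustered with k-means into chromatin
states, and compared with RPKM-style density statistics (Welch t-tests
with Benjamini-Hochberg correction) and per-cluster signal correlations.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans
from statsmodels.stats.multitest import multipletests

from .errors import DegenerateDataError
from .genome import GenomicInterval
from .tracks import BedGraphTrack

DEFAULT_SPAN = 2000
DEFAULT_BIN_WIDTH = 50
DEFAULT_TOP_FRACTION = 0.75
DEFAULT_K = 3


@dataclass
class SignalMatrix:
    """Per-region, per-bin signal values around region centers.

    ``values[track]`` is an (n_regions x n_bins) array; row order is shared
    across tracks.  ``track_totals`` stores each track's genome-wide signal
    area, needed for RPKM-style density normalization.
    """

    regions: List[GenomicInterval]
    tracks: List[str]
    values: Dict[str, np.ndarray]
    bin_width: int
    span: int
    track_totals: Dict[str, float] = field(default_factory=dict)
    edge_flags: List[bool] = field(default_factory=list)

    def __post_init__(self) -> None:
        n = len(self.regions)
        for t in self.tracks:
            v = self.values[t]
            if v.shape[0] != n:
                raise ValueError(f"track {t}: row count != region count")
            if (v < 0).any():
                raise ValueError(f"track {t}: negative signal values")
        if not self.edge_flags:
            self.edge_flags = [False] * n

    @property
    def n_regions(self) -> int:
        return len(self.regions)

    @property
    def n_bins(self) -> int:
        return self.values[self.tracks[0]].shape[1]

    def row_sums(self, track: str) -> np.ndarray:
        return self.values[track].sum(axis=1)

    def subset(self, idx: np.ndarray) -> "SignalMatrix":
        return SignalMatrix(
            regions=[self.regions[i] for i in idx],
            tracks=list(self.tracks),
            values={t: self.values[t][idx] for t in self.tracks},
            bin_width=self.bin_width,
            span=self.span,
            track_totals=dict(self.track_totals),
            edge_flags=[self.edge_flags[i] for i in idx],
        )


@dataclass
class ClusterAssignment:
    """1-based cluster labels per region, ordered by activity.

    Cluster 1 has the highest mean signal on the designated active mark
    (H3K27ac by convention), descending thereafter.
    """

    labels: np.ndarray  # 1-based, aligned to SignalMatrix.regions
    cluster_means: pd.DataFrame  # index: cluster, columns: tracks
    active_track: str

    @property
    def k(self) -> int:
        return int(self.cluster_means.shape[0])


def build_signal_matrix(
    centers: Sequence[GenomicInterval],
    tracks: Mapping[str, BedGraphTrack],
    span: int = DEFAULT_SPAN,
    bin_width: int = DEFAULT_BIN_WIDTH,
) -> SignalMatrix:
    """Per-bin mean signal in a +/- span window around each region midpoint.

    Bins run 5'->3': rows for minus-strand regions are flipped.  Windows
    running off a chromosome edge are zero-padded and flagged.
    """
    if 2 * span % bin_width != 0:
        raise ValueError("window width 2*span must be divisible by bin_width")
    n_bins = 2 * span // bin_width
    names = list(tracks)
    values = {t: np.zeros((len(centers), n_bins)) for t in names}
    edge_flags = []
    for i, region in enumerate(centers):
        c = region.midpoint
        start, end = c - span, c + span
        edge_flags.append(start < 0)
        for t in names:
            row = tracks[t].binned_mean(region.chrom, start, end, n_bins)
            if region.strand == "-":
                row = row[::-1]
            values[t][i] = row
    return SignalMatrix(
        regions=list(centers),
        tracks=names,
        values=values,
        bin_width=bin_width,
        span=span,
        track_totals={t: tracks[t].total for t in names},
        edge_flags=edge_flags,
    )


def select_top_enriched(
    matrix: SignalMatrix,
    track: str = "TCF3HLF",
    top_fraction: float = DEFAULT_TOP_FRACTION,
) -> SignalMatrix:
    """Keep the top fraction of regions by row-sum of the named track.

    The kept count is floor(n * top_fraction) (at least 1); ties are
    resolved by genomic coordinate so the subset is deterministic.
    """
    if track not in matrix.tracks:
        raise DegenerateDataError(f"track {track!r} absent from signal matrix")
    n_keep = max(1, int(matrix.n_regions * top_fraction))
    sums = matrix.row_sums(track)
    coord_rank = np.array(
        sorted(
            range(matrix.n_regions),
            key=lambda i: (
                matrix.regions[i].chrom,
                matrix.regions[i].start,
                matrix.regions[i].end,
            ),
        )
    )
    # order: descending sum, ties by coordinate order
    pos_of = np.empty(matrix.n_regions, dtype=int)
    pos_of[coord_rank] = np.arange(matrix.n_regions)
    order = sorted(range(matrix.n_regions), key=lambda i: (-sums[i], pos_of[i]))
    keep = np.array(sorted(order[:n_keep]))
    return matrix.subset(keep)


def cluster_regions(
    matrix: SignalMatrix,
    k: int = DEFAULT_K,
    seed: int = 0,
    active_track: str = "H3K27ac",
) -> ClusterAssignment:
    """k-means on concatenated standardized track profiles.

    Each track's matrix is z-scored globally (across all its entries) so a
    deep track cannot dominate the Euclidean metric.  10 restarts, best
    inertia.  Clusters are relabeled 1..k by descending mean signal of
    ``active_track`` so cluster identity is stable across seeds.
    """
    if matrix.n_regions < k:
        raise DegenerateDataError(
            f"cannot form {k} clusters from {matrix.n_regions} regions"
        )
    blocks = []
    for t in matrix.tracks:
        v = matrix.values[t]
        sd = v.std()
        blocks.append((v - v.mean()) / sd if sd > 0 else np.zeros_like(v))
    X = np.hstack(blocks)
    km = KMeans(n_clusters=k, n_init=10, random_state=seed)
    raw = km.fit_predict(X)

    ref = active_track if active_track in matrix.tracks else matrix.tracks[0]
    ref_sums = matrix.row_sums(ref)
    order = sorted(range(k), key=lambda c: -ref_sums[raw == c].mean())
    relabel = {old: new + 1 for new, old in enumerate(order)}
    labels = np.array([relabel[c] for c in raw])

    means = pd.DataFrame(
        {
            t: [matrix.row_sums(t)[labels == c].mean() for c in range(1, k + 1)]
            for t in matrix.tracks
        },
        index=pd.Index(range(1, k + 1), name="cluster"),
    )
    return ClusterAssignment(labels=labels, cluster_means=means, active_track=ref)


def region_densities(matrix: SignalMatrix, track: str) -> np.ndarray:
    """RPKM-style per-region density: row_sum / (span_kb * track_total/1e6)."""
    span_kb = 2 * matrix.span / 1000.0
    total = matrix.track_totals.get(track, 0.0)
    if total <= 0:
        raise DegenerateDataError(f"track {track!r} has zero total signal")
    return matrix.row_sums(track) / (span_kb * total / 1e6)


def density_stats(matrix: SignalMatrix, assignment: ClusterAssignment) -> pd.DataFrame:
    """Per-cluster densities and BH-adjusted Welch t-tests per cluster pair.

    Returns one row per (track, cluster_a, cluster_b) with mean densities,
    the two-tailed Welch p-value and its BH q across the whole table.
    Degenerate clusters (n < 2) are skipped with a note.
    """
    labels = assignment.labels
    clusters = sorted(set(labels))
    rows = []
    for t in matrix.tracks:
        dens = region_densities(matrix, t)
        for a, b in itertools.combinations(clusters, 2):
            xa, xb = dens[labels == a], dens[labels == b]
            if xa.size < 2 or xb.size < 2:
                warnings.warn(
                    f"cluster pair ({a},{b}) on {t}: fewer than 2 regions; skipped"
                )
                continue
            _, p = stats.ttest_ind(xa, xb, equal_var=False)
            rows.append(
                {
                    "track": t,
                    "cluster_a": a,
                    "cluster_b": b,
                    "mean_a": float(xa.mean()),
                    "mean_b": float(xb.mean()),
                    "p_value": float(p),
                }
            )
    if not rows:
        raise DegenerateDataError("no cluster pair with >= 2 regions per side")
    df = pd.DataFrame(rows)
    df["q_value"] = benjamini_hochberg(df["p_value"].to_numpy())
    return df


def benjamini_hochberg(p_values: np.ndarray) -> np.ndarray:
    """Step-up BH adjusted p-values (monotone, capped at 1)."""
    _, q, _, _ = multipletests(p_values, method="fdr_bh")
    return q


def cluster_signal_correlation(
    matrix: SignalMatrix,
    assignment: ClusterAssignment,
    track_a: str = "ATAC",
    track_b: str = "TCF3HLF",
) -> pd.DataFrame:
    """Pearson r of per-region row-sums of two tracks within each cluster.

    Clusters with fewer than 3 regions are skipped (r undefined).
    """
    for t in (track_a, track_b):
        if t not in matrix.tracks:
            raise DegenerateDataError(f"track {t!r} absent from signal matrix")
    xa = matrix.row_sums(track_a)
    xb = matrix.row_sums(track_b)
    rows = []
    for c in sorted(set(assignment.labels)):
        mask = assignment.labels == c
        if mask.sum() < 3:
            warnings.warn(f"cluster {c}: n < 3, correlation skipped")
            continue
        if xa[mask].std() == 0 or xb[mask].std() == 0:
            warnings.warn(f"cluster {c}: constant signal, correlation skipped")
            continue
        r, p = stats.pearsonr(xa[mask], xb[mask])
        rows.append({"cluster": c, "n": int(mask.sum()), "pearson_r": float(r), "p_value": float(p)})
    return pd.DataFrame(rows)


def write_matrix_tsv(matrix: SignalMatrix, path) -> None:
    frames = []
    for t in matrix.tracks:
        df = pd.DataFrame(
            matrix.values[t],
            columns=[f"{t}_bin{j}" for j in range(matrix.n_bins)],
        )
        frames.append(df)
    meta = pd.DataFrame(
        {
            "chrom": [r.chrom for r in matrix.regions],
            "start": [r.start for r in matrix.regions],
            "end": [r.end for r in matrix.regions],
            "strand": [r.strand for r in matrix.regions],
        }
    )
    pd.concat([meta] + frames, axis=1).to_csv(path, sep="\t", index=False)


def write_cluster_bed(
    matrix: SignalMatrix, assignment: ClusterAssignment, path
) -> None:
    with open(path, "w") as fh:
        for region, label in zip(matrix.regions, assignment.labels):
            fh.write(
                f"{region.chrom}\t{region.start}\t{region.end}\tcluster{label}\t0\t"
                f"{region.strand}\n"
            )
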