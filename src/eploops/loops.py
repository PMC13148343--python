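"""Significant HiChIP interaction I/O, filtering, anchors and replicate SCC.

Loops arrive as 7-8 column BEDPE (chr1, s1, e1, chr2, s2, e2, count[, q])
on a fixed bin grid, the output contract of spline-background loop callers
run at a single resolution (5 kb by default).  Replicate agreement is the
stratum-adjusted correlation coefficient (SCC): a distance-stratified,
variance-weighted Pearson correlation between smoothed contact matrices.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple

import numpy as np
from scipy.ndimage import uniform_filter

from .errors import DegenerateDataError, InputFormatError
from .genome import GenomicInterval

DEFAULT_BIN_SIZE = 5000
DEFAULT_Q_MAX = 0.01
DEFAULT_D_MIN = 50_000
DEFAULT_D_MAX = 3_000_000


@dataclass(frozen=True)
class Loop:
    """One significant interaction between two fixed-width anchor bins."""

    anchor1: GenomicInterval
    anchor2: GenomicInterval
    contact_count: int
    q_value: float = 0.0

    def __post_init__(self) -> None:
        if self.contact_count <= 0:
            raise ValueError("contact_count must be positive")
        if not (0.0 <= self.q_value <= 1.0):
            raise ValueError("q_value must be in [0, 1]")

    @property
    def intra(self) -> bool:
        return self.anchor1.chrom == self.anchor2.chrom

    @property
    def distance(self) -> int:
        """Anchor-start separation; only meaningful for intra loops."""
        if not self.intra:
            raise ValueError("distance undefined for inter-chromosomal loop")
        return self.anchor2.start - self.anchor1.start


def _canonical(a1: GenomicInterval, a2: GenomicInterval) -> Tuple[GenomicInterval, GenomicInterval]:
    if (a1.chrom, a1.start) <= (a2.chrom, a2.start):
        return a1, a2
    return a2, a1


def make_loop(
    a1: GenomicInterval, a2: GenomicInterval, count: int, q: float = 0.0
) -> Loop:
    """Canonicalized Loop constructor: anchor1 always precedes anchor2."""
    a1, a2 = _canonical(a1, a2)
    return Loop(anchor1=a1, anchor2=a2, contact_count=count, q_value=q)


def read_bedpe(path, bin_size: int = DEFAULT_BIN_SIZE) -> List[Loop]:
    """Read a 7-8 column BEDPE of significant loops.

    Anchors are normalized so anchor1 precedes anchor2; a missing q column
    means the file is pre-filtered and q is set to 0.  An anchor whose
    width differs from ``bin_size`` is a hard error naming the row.
    """
    loops: List[Loop] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 7:
                raise InputFormatError(
                    f"{path}:{lineno}: expected >=7 BEDPE columns, got {len(fields)}"
                )
            c1, s1, e1, c2, s2, e2, count = fields[:7]
            q = float(fields[7]) if len(fields) >= 8 else 0.0
            a1 = GenomicInterval(c1, int(s1), int(e1))
            a2 = GenomicInterval(c2, int(s2), int(e2))
            for a in (a1, a2):
                if a.length != bin_size:
                    raise InputFormatError(
                        f"{path}:{lineno}: anchor width {a.length} != bin size "
                        f"{bin_size}"
                    )
            loops.append(make_loop(a1, a2, int(count), q))
    return loops


def write_bedpe(loops: Sequence[Loop], path) -> None:
    with open(path, "w") as fh:
        for lp in loops:
            a1, a2 = lp.anchor1, lp.anchor2
            fh.write(
                f"{a1.chrom}\t{a1.start}\t{a1.end}\t{a2.chrom}\t{a2.start}\t"
                f"{a2.end}\t{lp.contact_count}\t{lp.q_value:.6g}\n"
            )


def filter_loops(
    loops: Sequence[Loop],
    q_max: float = DEFAULT_Q_MAX,
    d_min: int = DEFAULT_D_MIN,
    d_max: int = DEFAULT_D_MAX,
    keep_inter: bool = False,
) -> List[Loop]:
    """Keep intra loops with q <= q_max and d_min <= distance <= d_max.

    Inter-chromosomal loops are dropped unless ``keep_inter`` (they then
    bypass the distance filter but still face the q filter).
    """
    kept = []
    for lp in loops:
        if lp.q_value > q_max:
            continue
        if lp.intra:
            if d_min <= lp.distance <= d_max:
                kept.append(lp)
        elif keep_inter:
            kept.append(lp)
    return kept


def anchors_union(
    loops: Sequence[Loop],
) -> Tuple[List[GenomicInterval], Dict[Tuple[str, int, int], List[int]]]:
    """Unique anchor bins, sorted, each tagged with touching loop indices."""
    index: Dict[Tuple[str, int, int], List[int]] = {}
    anchors: Dict[Tuple[str, int, int], GenomicInterval] = {}
    for i, lp in enumerate(loops):
        for a in (lp.anchor1, lp.anchor2):
            key = a.key()
            anchors.setdefault(key, GenomicInterval(a.chrom, a.start, a.end))
            index.setdefault(key, []).append(i)
    ordered = sorted(anchors.values(), key=lambda a: (a.chrom, a.start, a.end))
    return ordered, index


# ---------------------------------------------------------------------------
# Contact matrices and SCC


@dataclass
class ContactMatrix:
    """Dense symmetric per-chromosome contact matrix at fixed resolution."""

    chrom: str
    resolution: int
    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        n, m = self.matrix.shape
        if n != m:
            raise ValueError("contact matrix must be square")
        if (self.matrix < 0).any():
            raise ValueError("contact matrix must be non-negative")
        if not np.allclose(self.matrix, self.matrix.T):
            raise ValueError("contact matrix must be symmetric")

    @property
    def n_bins(self) -> int:
        return self.matrix.shape[0]


def read_triplet_matrix(path, chrom: str, resolution: int, n_bins: int) -> ContactMatrix:
    """Read a ``bin_i bin_j count`` triplet text file (symmetrized)."""
    m = np.zeros((n_bins, n_bins))
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 3:
                raise InputFormatError(f"{path}:{lineno}: expected 3 columns")
            i, j, c = int(parts[0]), int(parts[1]), float(parts[2])
            m[i, j] = c
            m[j, i] = c
    return ContactMatrix(chrom=chrom, resolution=resolution, matrix=m)


def write_triplet_matrix(cm: ContactMatrix, path) -> None:
    with open(path, "w") as fh:
        n = cm.n_bins
        for i in range(n):
            for j in range(i, n):
                if cm.matrix[i, j] != 0:
                    fh.write(f"{i}\t{j}\t{cm.matrix[i, j]:.6g}\n")


def _truncated_mean_filter(m: np.ndarray, h: int) -> np.ndarray:
    """(2h+1)^2 mean filter averaging only in-bounds entries (no padding)."""
    if h == 0:
        return m.astype(float)
    size = 2 * h + 1
    num = uniform_filter(m.astype(float), size=size, mode="constant", cval=0.0)
    den = uniform_filter(np.ones_like(m, dtype=float), size=size, mode="constant", cval=0.0)
    return num / den


def scc(
    m1: ContactMatrix,
    m2: ContactMatrix,
    h: int = 3,
    lb: int = 0,
    ub: int = 3_000_000,
) -> float:
    """Stratum-adjusted correlation coefficient between two replicates.

    Both matrices are mean-filtered with a (2h+1) x (2h+1) window
    (edge-truncated).  For each diagonal stratum k whose genomic offset
    ``k * resolution`` lies in [lb, ub], the Pearson correlation rho_k is
    computed over paired entries, and strata are combined with weights
    N_k * sigma1k * sigma2k.  Strata with zero variance in either matrix
    are skipped.
    """
    if m1.chrom != m2.chrom:
        raise ValueError("SCC requires matrices on the same chromosome")
    if m1.resolution != m2.resolution:
        raise ValueError("SCC requires matching resolutions")
    if m1.n_bins != m2.n_bins:
        raise ValueError("SCC requires matching dimensions")
    s1 = _truncated_mean_filter(m1.matrix, h)
    s2 = _truncated_mean_filter(m2.matrix, h)
    n = m1.n_bins
    num = 0.0
    den = 0.0
    any_valid = False
    for k in range(n):
        if not (lb <= k * m1.resolution <= ub):
            continue
        x = np.diagonal(s1, offset=k)
        y = np.diagonal(s2, offset=k)
        if x.size < 2:
            continue
        sx = x.std(ddof=1)
        sy = y.std(ddof=1)
        if sx == 0 or sy == 0:
            continue
        if np.array_equal(x, y):
            rho = 1.0  # exact self-correlation, immune to rounding
        else:
            rho = float(np.clip(np.corrcoef(x, y)[0, 1], -1.0, 1.0))
        w = x.size * sx * sy
        num += w * rho
        den += w
        any_valid = True
    if not any_valid:
        raise DegenerateDataError("degenerate matrices: no stratum with variance")
    return num / den
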