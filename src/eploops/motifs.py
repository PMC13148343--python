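"""Position-weight-matrix scanning of peak/anchor sequences.

Scores are log2 odds of the position probability model against a background
distribution.  Hits are reported when the score reaches a fraction
(``rel_score``) of the best attainable score — a deterministic,
background-free thresholding that makes hit sets reproducible bit-for-bit
without a p-value calibration step.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .errors import DegenerateDataError, InputFormatError
from .genome import GenomicInterval

ALPHABET = "ACGT"
_CODE = {c: i for i, c in enumerate(ALPHABET)}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

DEFAULT_REL_SCORE = 0.8


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class PWM:
    """A position count matrix with scoring machinery.

    ``counts`` is L x 4 over ACGT.  Column probabilities use a pseudocount
    added per cell, so p_ij = (c_ij + pc) / (sum_j c_ij + 4 pc); log-odds
    are taken against ``background`` (uniform by default).
    """

    name: str
    counts: np.ndarray
    pseudocount: float = 0.1
    background: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2 or self.counts.shape[1] != 4:
            raise ValueError("counts must be an L x 4 matrix")
        if self.counts.shape[0] < 4:
            raise ValueError("motif length must be >= 4")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")
        if self.pseudocount <= 0:
            raise ValueError("pseudocount must be positive")
        if self.background is None:
            self.background = np.full(4, 0.25)
        self.background = np.asarray(self.background, dtype=float)
        if not np.isclose(self.background.sum(), 1.0):
            raise ValueError("background must sum to 1")

    @property
    def length(self) -> int:
        return self.counts.shape[0]

    @property
    def log_odds(self) -> np.ndarray:
        probs = (self.counts + self.pseudocount) / (
            self.counts.sum(axis=1, keepdims=True) + 4 * self.pseudocount
        )
        return np.log2(probs / self.background)

    @property
    def max_score(self) -> float:
        return float(self.log_odds.max(axis=1).sum())

    @property
    def consensus(self) -> str:
        return "".join(ALPHABET[i] for i in self.counts.argmax(axis=1))

    def reverse_complement(self) -> "PWM":
        return PWM(
            name=self.name,
            counts=self.counts[::-1, ::-1].copy(),
            pseudocount=self.pseudocount,
            background=self.background[::-1].copy(),
        )

    @classmethod
    def from_consensus(
        cls, name: str, consensus: str, weight: float = 100.0, off: float = 1.0
    ) -> "PWM":
        """Build a sharp PWM whose maximal-scoring word is ``consensus``."""
        consensus = consensus.upper()
        if any(c not in _CODE for c in consensus):
            raise ValueError("consensus must be over ACGT")
        counts = np.full((len(consensus), 4), off)
        for i, c in enumerate(consensus):
            counts[i, _CODE[c]] = weight
        return cls(name=name, counts=counts)


@dataclass(frozen=True)
class MotifHit:
    interval: GenomicInterval
    strand: str
    score: float
    rel_score: float


def _encode(seq: str) -> np.ndarray:
    """Map ACGT -> 0..3, anything else -> 4 (treated as N)."""
    table = np.full(256, 4, dtype=np.int8)
    for c, i in _CODE.items():
        table[ord(c)] = i
    return table[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def scan_sequence(
    seq: str,
    pwm: PWM,
    threshold: float = DEFAULT_REL_SCORE,
    chrom: str = "seq",
    offset: int = 0,
) -> List[MotifHit]:
    """Scan both strands of ``seq``; windows containing N are skipped.

    Hits are positions where score / max_score >= ``threshold``, sorted by
    position (then + before -).  ``offset`` shifts reported coordinates so
    sub-sequences report genomic positions.
    """
    L = pwm.length
    n = len(seq)
    if n < L:
        return []
    codes = _encode(seq.upper())
    windows = np.lib.stride_tricks.sliding_window_view(codes, L)
    valid = (windows < 4).all(axis=1)

    lom_fwd = np.vstack([pwm.log_odds, np.zeros((1, 4))])  # row 4 unused (N-masked)
    lom_rev = np.vstack([pwm.reverse_complement().log_odds, np.zeros((1, 4))])
    idx = np.arange(L)
    safe = np.where(windows < 4, windows, 0)
    scores_fwd = lom_fwd[idx, safe].sum(axis=1)
    scores_rev = lom_rev[idx, safe].sum(axis=1)

    max_score = pwm.max_score
    if max_score <= 0:
        raise DegenerateDataError(
            f"PWM {pwm.name!r} has non-positive maximal score; cannot form rel_score"
        )
    hits: List[MotifHit] = []
    for pos in np.nonzero(valid)[0]:
        for strand, score in (("+", scores_fwd[pos]), ("-", scores_rev[pos])):
            rel = score / max_score
            if rel >= threshold:
                hits.append(
                    MotifHit(
                        interval=GenomicInterval(
                            chrom, offset + int(pos), offset + int(pos) + L, strand
                        ),
                        strand=strand,
                        score=float(score),
                        rel_score=float(rel),
                    )
                )
    return hits


def flag_motif_regions(
    regions: Sequence[GenomicInterval],
    genome: Mapping[str, str],
    pwm: PWM,
    threshold: float = DEFAULT_REL_SCORE,
) -> Dict[Tuple[str, int, int], Tuple[bool, List[MotifHit]]]:
    """Per-region motif presence plus the hit list for motif-centering.

    Regions extending past a chromosome end are clipped with a warning.
    Keys are location tuples ``(chrom, start, end)``.
    """
    out: Dict[Tuple[str, int, int], Tuple[bool, List[MotifHit]]] = {}
    for region in regions:
        if region.chrom not in genome:
            raise InputFormatError(f"region chromosome {region.chrom!r} not in genome")
        chrom_len = len(genome[region.chrom])
        start, end = region.start, region.end
        if end > chrom_len:
            warnings.warn(
                f"region {region.chrom}:{start}-{end} clipped to chromosome end "
                f"({chrom_len})"
            )
            end = chrom_len
        if start >= end:
            out[region.key()] = (False, [])
            continue
        seq = genome[region.chrom][start:end]
        hits = scan_sequence(seq, pwm, threshold, chrom=region.chrom, offset=start)
        out[region.key()] = (len(hits) > 0, hits)
    return out


def motif_enrichment(
    fg: Sequence[GenomicInterval],
    bg: Sequence[GenomicInterval],
    genome: Mapping[str, str],
    pwm: PWM,
    threshold: float = DEFAULT_REL_SCORE,
) -> dict:
    """One-sided Fisher's exact test for motif enrichment in fg vs bg.

    Returns the odds ratio (Haldane 0.5 correction when any cell is zero)
    and the one-sided (greater) p-value.
    """
    from scipy.stats import fisher_exact

    if not fg or not bg:
        raise DegenerateDataError("motif_enrichment requires non-empty fg and bg")
    fg_flags = flag_motif_regions(fg, genome, pwm, threshold)
    bg_flags = flag_motif_regions(bg, genome, pwm, threshold)
    a = sum(1 for has, _ in fg_flags.values() if has)
    b = len(fg_flags) - a
    c = sum(1 for has, _ in bg_flags.values() if has)
    d = len(bg_flags) - c
    _, p = fisher_exact([[a, b], [c, d]], alternative="greater")
    if min(a, b, c, d) == 0:
        odds = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
    else:
        odds = (a * d) / (b * c)
    return {
        "odds_ratio": float(odds),
        "p_value": float(p),
        "table": ((a, b), (c, d)),
    }


# ---------------------------------------------------------------------------
# Motif file formats


def read_meme_motif(path) -> PWM:
    """Read the first motif of a MEME minimal-format file.

    Probability rows are rescaled by nsites (default 20) into counts.
    """
    name = None
    rows: List[List[float]] = []
    nsites = 20.0
    background = None
    with open(path) as fh:
        lines = fh.readlines()
    i = 0
    in_matrix = False
    expected = None
    while i < len(lines):
        line = lines[i].strip()
        if line.startswith("Background letter frequencies"):
            freq_line = lines[i + 1].split()
            background = np.array([float(freq_line[j]) for j in (1, 3, 5, 7)])
            i += 2
            continue
        if line.startswith("MOTIF"):
            if name is not None:
                break  # only the first motif
            name = line.split()[1]
        elif line.startswith("letter-probability matrix"):
            in_matrix = True
            # key=value parse of "w= 8 nsites= 20 E= 0"
            toks = line.split()
            for j, t in enumerate(toks):
                if t.rstrip("=") == "nsites" and j + 1 < len(toks):
                    nsites = float(toks[j + 1])
                if t.rstrip("=") == "w" and j + 1 < len(toks):
                    expected = int(toks[j + 1])
        elif in_matrix and line:
            vals = line.split()
            if len(vals) == 4:
                rows.append([float(v) for v in vals])
            else:
                in_matrix = False
        i += 1
    if name is None or not rows:
        raise InputFormatError(f"no MEME motif found in {path}")
    if expected is not None and len(rows) != expected:
        raise InputFormatError(
            f"MEME motif {name!r}: expected {expected} rows, found {len(rows)}"
        )
    counts = np.array(rows) * nsites
    return PWM(name=name, counts=counts, background=background)


def read_jaspar_pfm(path) -> PWM:
    """Read a JASPAR PFM text motif (4 rows, A/C/G/T, optional brackets)."""
    name = "motif"
    rows: Dict[str, List[float]] = {}
    order: List[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                name = line[1:].split()[0]
                continue
            letter = None
            rest = line
            if line[0] in ALPHABET and (len(line) == 1 or not line[1].isdigit()):
                letter = line[0]
                rest = line[1:]
            rest = rest.replace("[", " ").replace("]", " ")
            vals = [float(v) for v in rest.split()]
            if letter is None:
                letter = ALPHABET[len(order)]
            rows[letter] = vals
            order.append(letter)
    if set(rows) != set(ALPHABET):
        raise InputFormatError(f"JASPAR PFM in {path} must have A, C, G and T rows")
    counts = np.column_stack([rows[c] for c in ALPHABET])
    return PWM(name=name, counts=counts)


def write_hits_bed(hits: Sequence[MotifHit], path) -> None:
    """BED6 with score = rel_score x 1000 (clipped at 0)."""
    with open(path, "w") as fh:
        for h in hits:
            score = max(0, int(round(h.rel_score * 1000)))
            fh.write(
                f"{h.interval.chrom}\t{h.interval.start}\t{h.interval.end}\t"
                f"motif\t{score}\t{h.strand}\n"
            )
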