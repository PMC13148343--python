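"""ROSE-style stitched-enhancer and super-enhancer calling.

H3K27ac peaks are gap-merged into stitched domains, scored by
(background-subtracted) signal area, ranked, and split into typical (TE)
and super (SE) enhancers at the hockey-stick cutoff: with ranks and
signals rescaled to the unit square, the cutoff is the signal at the
point where the slope of the ascending curve first reaches 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .errors import DegenerateDataError, InputFormatError
from .genome import GeneModel, GenomicInterval
from .tracks import BedGraphTrack

DEFAULT_STITCH_GAP = 12_500


@dataclass
class StitchedEnhancer:
    interval: GenomicInterval
    member_peaks: List[GenomicInterval] = field(default_factory=list)
    signal: float = 0.0
    rank: Optional[int] = None
    is_super: bool = False

    @property
    def n_peaks(self) -> int:
        return len(self.member_peaks)


def read_peaks(path) -> List[GenomicInterval]:
    """Read narrowPeak/broadPeak/BED peaks (first three columns used)."""
    peaks = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise InputFormatError(f"{path}:{lineno}: expected >=3 BED columns")
            peaks.append(GenomicInterval(parts[0], int(parts[1]), int(parts[2])))
    return peaks


def read_bed(path) -> List[GenomicInterval]:
    return read_peaks(path)


def stitch_peaks(
    peaks: Sequence[GenomicInterval],
    stitch_gap: int = DEFAULT_STITCH_GAP,
    tss_exclusion: int = 0,
    genes: Optional[Sequence[GeneModel]] = None,
) -> List[StitchedEnhancer]:
    """Transitively merge peaks whose gap is <= ``stitch_gap``.

    With ``tss_exclusion > 0``, peaks fully inside +/- tss_exclusion of any
    TSS are withheld from stitching and returned as singleton regions.
    """
    excluded: List[GenomicInterval] = []
    stitchable: List[GenomicInterval] = []
    if tss_exclusion > 0 and genes:
        tss_by_chrom: Dict[str, np.ndarray] = {}
        for g in genes:
            tss_by_chrom.setdefault(g.chrom, []).append(g.tss)  # type: ignore[arg-type]
        tss_by_chrom = {c: np.sort(v) for c, v in tss_by_chrom.items()}
        for p in peaks:
            tss = tss_by_chrom.get(p.chrom)
            inside = False
            if tss is not None and tss.size:
                j = np.searchsorted(tss, p.midpoint)
                for t in tss[max(0, j - 1): j + 1]:
                    if t - tss_exclusion <= p.start and p.end <= t + tss_exclusion + 1:
                        inside = True
                        break
            (excluded if inside else stitchable).append(p)
    else:
        stitchable = list(peaks)

    out: List[StitchedEnhancer] = []
    by_chrom: Dict[str, List[GenomicInterval]] = {}
    for p in stitchable:
        by_chrom.setdefault(p.chrom, []).append(p)
    for chrom in sorted(by_chrom):
        group: List[GenomicInterval] = []
        for p in sorted(by_chrom[chrom], key=lambda x: (x.start, x.end)):
            if group and p.start - max(q.end for q in group) <= stitch_gap:
                group.append(p)
            else:
                if group:
                    out.append(_make_stitched(group))
                group = [p]
        if group:
            out.append(_make_stitched(group))
    for p in excluded:
        out.append(_make_stitched([p]))
    out.sort(key=lambda s: (s.interval.chrom, s.interval.start, s.interval.end))
    return out


def _make_stitched(group: List[GenomicInterval]) -> StitchedEnhancer:
    return StitchedEnhancer(
        interval=GenomicInterval(
            group[0].chrom, min(p.start for p in group), max(p.end for p in group)
        ),
        member_peaks=list(group),
    )


def score_and_rank(
    stitched: Sequence[StitchedEnhancer],
    signal: BedGraphTrack,
    control: Optional[BedGraphTrack] = None,
) -> List[StitchedEnhancer]:
    """Score each region by signal area minus control area, floored at 0.

    Rank 1 is the highest signal; ties broken by wider interval, then
    lower coordinate.  Regions on chromosomes missing from the track get
    signal 0 with a warning.
    """
    scored = []
    missing = set()
    for s in stitched:
        iv = s.interval
        if iv.chrom not in signal.chroms:
            missing.add(iv.chrom)
            value = 0.0
        else:
            value = signal.area(iv.chrom, iv.start, iv.end)
            if control is not None:
                value -= control.area(iv.chrom, iv.start, iv.end)
        scored.append(
            StitchedEnhancer(
                interval=iv, member_peaks=list(s.member_peaks), signal=max(0.0, value)
            )
        )
    for chrom in sorted(missing):
        warnings.warn(f"signal track has no data for {chrom}; regions scored 0")
    scored.sort(
        key=lambda s: (
            -s.signal,
            -s.interval.length,
            s.interval.chrom,
            s.interval.start,
        )
    )
    for i, s in enumerate(scored, start=1):
        s.rank = i
    return scored


def hockey_stick_cutoff(signals: np.ndarray) -> Tuple[float, int]:
    """Signal cutoff at the first unit-slope point of the scaled rank curve.

    ``signals`` may be in any order; internally sorted ascending, then rank
    and signal are rescaled to [0, 1] and the cutoff is the (raw) signal at
    the first point whose forward-difference slope reaches 1, scanning from
    the low-signal end.  Returns (cutoff_value, cutoff_index_ascending).
    """
    ys = np.sort(np.asarray(signals, dtype=float))
    n = ys.size
    if n < 3:
        raise DegenerateDataError("need >= 3 regions to locate a cutoff")
    if ys[-1] == ys[0]:
        raise DegenerateDataError("all signals equal: no hockey-stick cutoff")
    x = np.arange(n) / (n - 1)
    y = (ys - ys[0]) / (ys[-1] - ys[0])
    slopes = np.diff(y) / np.diff(x)
    above = np.nonzero(slopes >= 1.0)[0]
    if above.size == 0:
        raise DegenerateDataError("curve slope never reaches 1: no cutoff")
    idx = int(above[0])
    return float(ys[idx]), idx


def call_super_enhancers(ranked: Sequence[StitchedEnhancer]) -> List[StitchedEnhancer]:
    """Flag regions above the hockey-stick cutoff as super-enhancers.

    Requires >= 3 regions with positive signal.  A degenerate profile
    (all-equal signals, or an elbow at the very first point) produces a
    warning; the all-equal case yields no super-enhancers.
    """
    positive = [s for s in ranked if s.signal > 0]
    if len(positive) < 3:
        raise DegenerateDataError("need >= 3 positive-signal regions")
    signals = np.array([s.signal for s in ranked], dtype=float)
    try:
        cutoff, idx = hockey_stick_cutoff(signals)
    except DegenerateDataError as exc:
        warnings.warn(f"degenerate signal profile: {exc}; no super-enhancers called")
        for s in ranked:
            s.is_super = False
        return list(ranked)
    if idx == 0:
        warnings.warn(
            "signal profile has no flat segment (elbow at first point); "
            "super-enhancer set may be degenerate"
        )
    for s in ranked:
        s.is_super = s.signal > cutoff
    return list(ranked)


ENHANCER_CLASSES = ("SE", "TE", "external_only", "none")


def annotate_enhancer_class(
    regions: Sequence[GenomicInterval],
    rose: Sequence[StitchedEnhancer],
    external_bed: Optional[Sequence[GenomicInterval]] = None,
) -> Dict[Tuple[str, int, int], str]:
    """Classify regions by any-overlap with SE > TE > external precedence."""
    out: Dict[Tuple[str, int, int], str] = {}
    ses = [s.interval for s in rose if s.is_super]
    tes = [s.interval for s in rose if not s.is_super]
    ext = list(external_bed) if external_bed else []
    for r in regions:
        if any(r.overlaps(iv) for iv in ses):
            klass = "SE"
        elif any(r.overlaps(iv) for iv in tes):
            klass = "TE"
        elif any(r.overlaps(iv) for iv in ext):
            klass = "external_only"
        else:
            klass = "none"
        out[r.key()] = klass
    return out


def write_rose_table(ranked: Sequence[StitchedEnhancer], path) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tstart\tend\tn_peaks\tsignal\trank\tisSuper\n")
        for s in ranked:
            fh.write(
                f"{s.interval.chrom}\t{s.interval.start}\t{s.interval.end}\t"
                f"{s.n_peaks}\t{s.signal:.6g}\t{s.rank}\t{int(s.is_super)}\n"
            )
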