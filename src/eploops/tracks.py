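"""bedGraph signal tracks with fast area and binned-mean queries.

Tracks are stored per chromosome as sorted, non-overlapping interval
arrays with a prefix-sum of signal area, so that the integral of the
track over any window is an O(log n) lookup.  Positions not covered by
any bedGraph interval have value 0.
"""

from __future__ import annotations

from typing import Dict, Tuple

import numpy as np

from .errors import InputFormatError


class BedGraphTrack:
    """Piecewise-constant non-negative signal over a genome."""

    def __init__(self, data: Dict[str, Tuple[np.ndarray, np.ndarray, np.ndarray]]):
        # data: chrom -> (starts, ends, values), sorted, non-overlapping
        self._data = {}
        self._cum = {}
        total = 0.0
        for chrom, (starts, ends, vals) in data.items():
            starts = np.asarray(starts, dtype=np.int64)
            ends = np.asarray(ends, dtype=np.int64)
            vals = np.asarray(vals, dtype=float)
            order = np.argsort(starts, kind="stable")
            starts, ends, vals = starts[order], ends[order], vals[order]
            if (ends[:-1] > starts[1:]).any():
                raise InputFormatError(
                    f"bedGraph intervals overlap on {chrom}; tracks must be flat"
                )
            if (vals < 0).any():
                raise InputFormatError(f"negative bedGraph value on {chrom}")
            areas = vals * (ends - starts)
            cum = np.concatenate([[0.0], np.cumsum(areas)])
            self._data[chrom] = (starts, ends, vals)
            self._cum[chrom] = cum
            total += float(areas.sum())
        self.total = total

    @property
    def chroms(self):
        return list(self._data)

    def _cum_at(self, chrom: str, pos: np.ndarray) -> np.ndarray:
        """Cumulative area of the track over [0, pos)."""
        starts, ends, vals = self._data[chrom]
        cum = self._cum[chrom]
        pos = np.asarray(pos, dtype=np.int64)
        idx = np.searchsorted(starts, pos, side="right") - 1
        out = np.zeros(pos.shape, dtype=float)
        inside = idx >= 0
        ii = idx[inside]
        overlap = np.clip(pos[inside] - starts[ii], 0, ends[ii] - starts[ii])
        out[inside] = cum[ii] + vals[ii] * overlap
        return out

    def area(self, chrom: str, start: int, end: int) -> float:
        """Integral of the signal over [start, end)."""
        if chrom not in self._data:
            return 0.0
        lo, hi = self._cum_at(chrom, np.array([start, end]))
        return float(hi - lo)

    def binned_mean(self, chrom: str, start: int, end: int, n_bins: int) -> np.ndarray:
        """Mean signal value in each of n_bins equal-width bins of [start, end).

        Portions outside the chromosome coverage count as 0; windows with
        ``start < 0`` are handled by zero-padding the missing prefix.
        """
        if chrom not in self._data:
            return np.zeros(n_bins)
        edges = np.linspace(start, end, n_bins + 1)
        edges_clipped = np.clip(edges, 0, None).astype(np.int64)
        cum = self._cum_at(chrom, edges_clipped)
        widths = np.diff(edges)
        return np.diff(cum) / widths


def read_bedgraph(path) -> BedGraphTrack:
    """Read a 4-column bedGraph into a :class:`BedGraphTrack`."""
    per_chrom: Dict[str, list] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise InputFormatError(f"{path}:{lineno}: expected 4 bedGraph columns")
            chrom, s, e, v = parts[0], int(parts[1]), int(parts[2]), float(parts[3])
            if e <= s:
                raise InputFormatError(f"{path}:{lineno}: end <= start")
            per_chrom.setdefault(chrom, []).append((s, e, v))
    data = {}
    for chrom, rows in per_chrom.items():
        rows.sort()
        starts, ends, vals = zip(*rows)
        data[chrom] = (np.array(starts), np.array(ends), np.array(vals))
    return BedGraphTrack(data)


def write_bedgraph(track_rows, path) -> None:
    """Write rows of (chrom, start, end, value), sorted, as bedGraph."""
    rows = sorted(track_rows)
    with open(path, "w") as fh:
        for chrom, s, e, v in rows:
            fh.write(f"{chrom}\t{s}\t{e}\t{v:.6g}\n")
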