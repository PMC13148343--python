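import numpy as np
import pytest

from eploops.enhancers import (
    StitchedEnhancer,
    annotate_enhancer_class,
    call_super_enhancers,
    hockey_stick_cutoff,
    score_and_rank,
    stitch_peaks,
)
from eploops.errors import DegenerateDataError
from eploops.genome import GenomicInterval
from eploops.tracks import BedGraphTrack


def _peak(chrom, start, end):
    return GenomicInterval(chrom, start, end)


def _constant_track(chrom, start, end, value):
    return BedGraphTrack(
        {chrom: (np.array([start]), np.array([end]), np.array([value]))}
    )


class TestStitching:
    def test_gap_below_threshold_merges(self):
        peaks = [_peak("chr1", 1000, 2000), _peak("chr1", 12_000, 13_000)]
        out = stitch_peaks(peaks)
        assert len(out) == 1
        assert (out[0].interval.start, out[0].interval.end) == (1000, 13_000)

    def test_gap_above_threshold_splits(self):
        peaks = [_peak("chr1", 1000, 2000), _peak("chr1", 15_100, 16_000)]
        assert len(stitch_peaks(peaks)) == 2

    def test_matches_union_find_oracle(self):
        import networkx as nx

        rng = np.random.default_rng(13)
        peaks = []
        for _ in range(200):
            start = int(rng.integers(0, 2_000_000))
            peaks.append(_peak("chr1", start, start + int(rng.integers(200, 2000))))
        peaks.sort(key=lambda p: p.start)
        out = stitch_peaks(peaks)
        g = nx.Graph()
        g.add_nodes_from(range(len(peaks)))
        for i in range(len(peaks)):
            for j in range(i + 1, len(peaks)):
                if peaks[j].start - peaks[i].end <= 12_500:
                    g.add_edge(i, j)
        components = list(nx.connected_components(g))
        spans = sorted(
            (min(peaks[i].start for i in c), max(peaks[i].end for i in c))
            for c in components
        )
        got = sorted((s.interval.start, s.interval.end) for s in out)
        assert got == spans

    def test_idempotent(self):
        rng = np.random.default_rng(14)
        peaks = sorted(
            (
                _peak("chr1", int(s), int(s) + 500)
                for s in rng.integers(0, 500_000, size=50)
            ),
            key=lambda p: p.start,
        )
        once = stitch_peaks(peaks)
        twice = stitch_peaks([s.interval for s in once])
        assert [(s.interval.start, s.interval.end) for s in once] == [
            (s.interval.start, s.interval.end) for s in twice
        ]


class TestScoring:
    def test_constant_track_area(self):
        stitched = [StitchedEnhancer(_peak("chr1", 100, 600))]
        track = _constant_track("chr1", 0, 10_000, 2.0)
        out = score_and_rank(stitched, track)
        assert out[0].signal == pytest.approx(2.0 * 500)

    def test_control_equal_signal_floors_to_zero(self):
        stitched = [StitchedEnhancer(_peak("chr1", 100, 600))]
        track = _constant_track("chr1", 0, 10_000, 2.0)
        out = score_and_rank(stitched, track, control=track)
        assert out[0].signal == 0.0

    def test_missing_chrom_warns_and_scores_zero(self):
        stitched = [StitchedEnhancer(_peak("chr9", 100, 600))]
        track = _constant_track("chr1", 0, 1000, 1.0)
        with pytest.warns(UserWarning):
            out = score_and_rank(stitched, track)
        assert out[0].signal == 0.0

    def test_ranking_matches_sort_oracle(self):
        rng = np.random.default_rng(15)
        starts = np.sort(rng.choice(np.arange(0, 10**6, 5000), 100, replace=False))
        stitched = [
            StitchedEnhancer(_peak("chr1", int(s), int(s) + int(rng.integers(500, 3000))))
            for s in starts
        ]
        values = rng.uniform(0.5, 5.0, size=100)
        track = BedGraphTrack(
            {
                "chr1": (
                    np.array([s.interval.start for s in stitched]),
                    np.array([s.interval.end for s in stitched]),
                    values,
                )
            }
        )
        out = score_and_rank(stitched, track)
        expected = sorted(
            (
                -(values[i] * stitched[i].interval.length),
                -stitched[i].interval.length,
                stitched[i].interval.start,
            )
            for i in range(100)
        )
        got = [(-s.signal, -s.interval.length, s.interval.start) for s in out]
        assert [g[2] for g in got] == [e[2] for e in expected]
        assert [s.rank for s in out] == list(range(1, 101))


def _hockey_regions(rng):
    lows = rng.uniform(1, 10, size=95)
    highs = rng.uniform(500, 1000, size=5)
    regions = []
    for i, sig in enumerate(np.concatenate([lows, highs])):
        r = StitchedEnhancer(_peak("chr1", 10_000 * (i + 1), 10_000 * (i + 1) + 1000))
        r.signal = float(sig)
        regions.append(r)
    regions.sort(key=lambda s: -s.signal)
    for i, r in enumerate(regions, 1):
        r.rank = i
    return regions, set(highs.round(9).tolist())


def diagonal_distance_elbow(signals):
    """Geometric oracle: index (ascending) maximizing distance below the diagonal."""
    ys = np.sort(np.asarray(signals, float))
    n = ys.size
    x = np.arange(n) / (n - 1)
    y = (ys - ys[0]) / (ys[-1] - ys[0])
    return int(np.argmax(x - y))


class TestSuperEnhancers:
    def test_hockey_stick_fixture_selects_planted_five(self):
        rng = np.random.default_rng(16)
        regions, high_set = _hockey_regions(rng)
        out = call_super_enhancers(regions)
        supers = [r for r in out if r.is_super]
        assert len(supers) == 5
        assert {round(r.signal, 9) for r in supers} == high_set

    def test_cutoff_agrees_with_diagonal_oracle(self):
        rng = np.random.default_rng(17)
        regions, _ = _hockey_regions(rng)
        signals = [r.signal for r in regions]
        _, idx = hockey_stick_cutoff(np.array(signals))
        assert abs(idx - diagonal_distance_elbow(signals)) <= 1

    def test_scale_invariance(self):
        rng = np.random.default_rng(18)
        regions, _ = _hockey_regions(rng)
        base = {r.interval.start for r in call_super_enhancers(regions) if r.is_super}
        for r in regions:
            r.signal *= 2.0
        doubled = {
            r.interval.start for r in call_super_enhancers(regions) if r.is_super
        }
        assert base == doubled

    def test_all_equal_signals_warns_no_super(self):
        regions = []
        for i in range(10):
            r = StitchedEnhancer(_peak("chr1", 1000 * (i + 1), 1000 * (i + 1) + 500))
            r.signal = 5.0
            r.rank = i + 1
            regions.append(r)
        with pytest.warns(UserWarning):
            out = call_super_enhancers(regions)
        assert not any(r.is_super for r in out)

    def test_linear_profile_flagged_degenerate(self):
        regions = []
        for i in range(20):
            r = StitchedEnhancer(_peak("chr1", 1000 * (i + 1), 1000 * (i + 1) + 500))
            r.signal = float(i + 1)
            r.rank = 20 - i
            regions.append(r)
        with pytest.warns(UserWarning):
            call_super_enhancers(regions)

    def test_se_te_partition(self):
        rng = np.random.default_rng(19)
        regions, _ = _hockey_regions(rng)
        out = call_super_enhancers(regions)
        n_se = sum(r.is_super for r in out)
        n_te = sum(not r.is_super for r in out)
        assert n_se + n_te == len(out)

    def test_too_few_positive_regions_is_error(self):
        regions = [StitchedEnhancer(_peak("chr1", 1000, 1500))]
        with pytest.raises(DegenerateDataError):
            call_super_enhancers(regions)


class TestEnhancerClass:
    def _rose(self):
        se = StitchedEnhancer(_peak("chr1", 10_000, 20_000))
        se.is_super = True
        te = StitchedEnhancer(_peak("chr1", 50_000, 55_000))
        return [se, te]

    def test_precedence_and_membership(self):
        rose = self._rose()
        external = [_peak("chr1", 80_000, 82_000)]
        regions = [
            _peak("chr1", 12_000, 13_000),  # inside SE
            _peak("chr1", 50_500, 51_000),  # inside TE
            _peak("chr1", 80_500, 81_000),  # external only
            _peak("chr1", 200_000, 201_000),  # nothing
        ]
        classes = annotate_enhancer_class(regions, rose, external)
        assert [classes[r.key()] for r in regions] == [
            "SE",
            "TE",
            "external_only",
            "none",
        ]

    def test_counts_match_overlap_oracle(self):
        rng = np.random.default_rng(20)
        rose = self._rose()
        external = [_peak("chr1", 80_000, 82_000)]
        regions = [
            _peak("chr1", int(s), int(s) + 800)
            for s in rng.integers(0, 250_000, size=300)
        ]
        classes = annotate_enhancer_class(regions, rose, external)

        def oracle(r):
            def hit(iv):
                return r.start < iv.end and iv.start < r.end

            if hit(rose[0].interval):
                return "SE"
            if hit(rose[1].interval):
                return "TE"
            if hit(external[0]):
                return "external_only"
            return "none"

        assert [classes[r.key()] for r in regions] == [oracle(r) for r in regions]
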