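import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from eploops.chromstate import (
    ClusterAssignment,
    SignalMatrix,
    benjamini_hochberg,
    build_signal_matrix,
    cluster_regions,
    cluster_signal_correlation,
    density_stats,
    select_top_enriched,
)
from eploops.errors import DegenerateDataError
from eploops.genome import GenomicInterval
from eploops.simulate import archetype_signal_matrix
from eploops.tracks import BedGraphTrack


def _track(chrom, rows):
    starts, ends, vals = zip(*rows)
    return BedGraphTrack(
        {chrom: (np.array(starts), np.array(ends), np.array(vals, dtype=float))}
    )


def _center(chrom, pos):
    return GenomicInterval(chrom, pos - 4, pos + 4)


class TestBuildMatrix:
    def test_constant_track_gives_constant_bins(self):
        track = _track("chr1", [(0, 100_000, 3.0)])
        m = build_signal_matrix([_center("chr1", 50_000)], {"t": track})
        assert np.allclose(m.values["t"], 3.0)

    def test_delta_peak_maximal_at_center(self):
        track = _track("chr1", [(49_975, 50_025, 10.0)])
        m = build_signal_matrix([_center("chr1", 50_000)], {"t": track})
        row = m.values["t"][0]
        assert row.argmax() in (len(row) // 2 - 1, len(row) // 2)
        assert row.sum() == pytest.approx(10.0 * 50 / 50)

    def test_matches_per_base_oracle(self):
        rng = np.random.default_rng(31)
        rows = []
        pos = 0
        dense = np.zeros(200_000)
        while pos < 190_000:
            length = int(rng.integers(100, 800))
            value = float(rng.uniform(0, 5))
            rows.append((pos, pos + length, value))
            dense[pos: pos + length] = value
            pos += length + int(rng.integers(0, 300))
        track = _track("chr1", rows)
        centers = [
            _center("chr1", int(p)) for p in rng.integers(3000, 190_000, size=20)
        ]
        m = build_signal_matrix(centers, {"t": track}, span=2000, bin_width=50)
        for i, c in enumerate(centers):
            start = c.midpoint - 2000
            expected = dense[start: start + 4000].reshape(-1, 50).mean(axis=1)
            assert np.allclose(m.values["t"][i], expected)

    def test_minus_strand_row_is_flipped(self):
        track = _track("chr1", [(48_000, 50_000, 1.0)])
        plus = GenomicInterval("chr1", 49_996, 50_004, "+")
        minus = GenomicInterval("chr1", 49_996, 50_004, "-")
        m = build_signal_matrix([plus, minus], {"t": track})
        assert np.allclose(m.values["t"][1], m.values["t"][0][::-1])

    def test_edge_region_padded_and_flagged(self):
        track = _track("chr1", [(0, 10_000, 1.0)])
        m = build_signal_matrix([_center("chr1", 500)], {"t": track})
        assert m.edge_flags == [True]
        assert m.values["t"][0][0] == 0.0  # window part before position 0


class TestTopSelection:
    def _matrix(self, sums):
        n = len(sums)
        regions = [_center("chr1", 10_000 * (i + 1)) for i in range(n)]
        values = {"TCF3HLF": np.tile(np.asarray(sums, float)[:, None], (1, 80)) / 80}
        return SignalMatrix(regions, ["TCF3HLF"], values, 50, 2000, {"TCF3HLF": 1.0})

    def test_count_arithmetic(self):
        m = self._matrix(list(range(100)))
        top = select_top_enriched(m, top_fraction=0.75)
        assert top.n_regions == 75
        assert min(r.row_sums("TCF3HLF").min() for r in [top]) >= 25 - 1e-9

    def test_all_equal_rows_keep_first_by_coordinate(self):
        m = self._matrix([1.0] * 100)
        top = select_top_enriched(m, top_fraction=0.75)
        starts = [r.start for r in top.regions]
        assert starts == sorted(starts)
        assert top.regions[0].start == m.regions[0].start
        assert top.n_regions == 75

    def test_kept_set_matches_sort_oracle(self):
        rng = np.random.default_rng(32)
        sums = rng.uniform(0, 10, size=40).tolist()
        m = self._matrix(sums)
        top = select_top_enriched(m, top_fraction=0.5)
        expected = {
            m.regions[i].start
            for i in np.argsort(-np.asarray(sums), kind="stable")[:20]
        }
        assert {r.start for r in top.regions} == expected

    def test_missing_track_is_error(self):
        m = self._matrix([1.0, 2.0, 3.0])
        with pytest.raises(DegenerateDataError):
            select_top_enriched(m, track="nope")


class TestClustering:
    def test_recovers_planted_archetypes(self):
        matrix, labels = archetype_signal_matrix(150, noise_sd=0.1, seed=0)
        assignment = cluster_regions(matrix, k=3, seed=0)
        assert adjusted_rand_score(labels, assignment.labels) >= 0.9

    def test_relabeling_puts_high_k27ac_first(self):
        matrix, labels = archetype_signal_matrix(150, noise_sd=0.1, seed=1)
        assignment = cluster_regions(matrix, k=3, seed=0)
        means = assignment.cluster_means["H3K27ac"]
        assert means.loc[1] == means.max()
        assert list(means.index) == [1, 2, 3]

    def test_duplicated_regions_get_identical_labels(self):
        matrix, _ = archetype_signal_matrix(30, noise_sd=0.05, seed=2)
        doubled = SignalMatrix(
            regions=matrix.regions + matrix.regions,
            tracks=matrix.tracks,
            values={t: np.vstack([matrix.values[t]] * 2) for t in matrix.tracks},
            bin_width=matrix.bin_width,
            span=matrix.span,
            track_totals=matrix.track_totals,
        )
        assignment = cluster_regions(doubled, k=3, seed=0)
        n = matrix.n_regions
        assert np.array_equal(assignment.labels[:n], assignment.labels[n:])

    def test_k1_puts_everything_in_cluster_one(self):
        matrix, _ = archetype_signal_matrix(10, seed=3)
        assignment = cluster_regions(matrix, k=1, seed=0)
        assert set(assignment.labels) == {1}

    def test_k_larger_than_n_is_error(self):
        matrix, _ = archetype_signal_matrix(2, seed=4)
        with pytest.raises(DegenerateDataError):
            cluster_regions(matrix, k=3, seed=0)

    def test_cluster_sizes_sum_to_region_count(self):
        matrix, _ = archetype_signal_matrix(80, seed=5)
        assignment = cluster_regions(matrix, k=3, seed=0)
        assert assignment.labels.size == matrix.n_regions


def _two_cluster_matrix(values_a, values_b, n_bins=40):
    n = len(values_a) + len(values_b)
    regions = [_center("chr1", 10_000 * (i + 1)) for i in range(n)]
    rows = np.array(
        [[v / n_bins] * n_bins for v in list(values_a) + list(values_b)], dtype=float
    )
    matrix = SignalMatrix(
        regions, ["t"], {"t": rows}, 100, 2000, {"t": float(rows.sum() * 100)}
    )
    labels = np.array([1] * len(values_a) + [2] * len(values_b))
    import pandas as pd

    assignment = ClusterAssignment(
        labels=labels,
        cluster_means=pd.DataFrame({"t": [np.mean(values_a), np.mean(values_b)]},
                                   index=pd.Index([1, 2], name="cluster")),
        active_track="t",
    )
    return matrix, assignment


class TestDensityStats:
    def test_identical_clusters_are_null(self):
        vals = [1.0, 2.0, 3.0, 4.0]
        matrix, assignment = _two_cluster_matrix(vals, vals)
        df = density_stats(matrix, assignment)
        assert df["p_value"].iloc[0] == pytest.approx(1.0)
        assert df["q_value"].iloc[0] == pytest.approx(1.0)

    def test_planted_shift_is_significant(self):
        rng = np.random.default_rng(41)
        a = rng.normal(10, 1, size=30)
        b = rng.normal(50, 5, size=30)
        matrix, assignment = _two_cluster_matrix(a, b)
        df = density_stats(matrix, assignment)
        assert df["q_value"].iloc[0] < 0.05

    def test_density_invariant_to_track_scaling(self):
        from eploops.chromstate import region_densities

        vals = [1.0, 2.0, 5.0]
        matrix, _ = _two_cluster_matrix(vals, vals)
        base = region_densities(matrix, "t")
        scaled = SignalMatrix(
            matrix.regions,
            ["t"],
            {"t": matrix.values["t"] * 7.0},
            matrix.bin_width,
            matrix.span,
            {"t": matrix.track_totals["t"] * 7.0},
        )
        assert np.allclose(region_densities(scaled, "t"), base)

    def test_bh_matches_hand_computed_step_up(self):
        p = np.array([0.001, 0.01, 0.02, 0.8])
        q = benjamini_hochberg(p)
        assert np.allclose(q, [0.004, 0.02, 0.0266667, 0.8], atol=1e-6)


class TestCorrelation:
    def _matrix_two_tracks(self, a, b):
        n = len(a)
        regions = [_center("chr1", 10_000 * (i + 1)) for i in range(n)]
        values = {
            "ATAC": np.asarray(a, float)[:, None] * np.ones((1, 10)) / 10,
            "TCF3HLF": np.asarray(b, float)[:, None] * np.ones((1, 10)) / 10,
        }
        return SignalMatrix(
            regions, ["ATAC", "TCF3HLF"], values, 400, 2000,
            {"ATAC": 1.0, "TCF3HLF": 1.0},
        )

    def _assignment(self, n):
        import pandas as pd

        return ClusterAssignment(
            labels=np.ones(n, dtype=int),
            cluster_means=pd.DataFrame({"ATAC": [0.0], "TCF3HLF": [0.0]},
                                       index=pd.Index([1], name="cluster")),
            active_track="TCF3HLF",
        )

    def test_proportional_tracks_give_r_one(self):
        a = [1.0, 2.0, 3.0, 4.0]
        m = self._matrix_two_tracks(a, [2 * x for x in a])
        df = cluster_signal_correlation(m, self._assignment(4))
        assert df["pearson_r"].iloc[0] == pytest.approx(1.0)

    def test_antiproportional_tracks_give_r_minus_one(self):
        a = [1.0, 2.0, 3.0, 4.0]
        m = self._matrix_two_tracks(a, [10 - x for x in a])
        df = cluster_signal_correlation(m, self._assignment(4))
        assert df["pearson_r"].iloc[0] == pytest.approx(-1.0)

    def test_matches_naive_formula(self):
        rng = np.random.default_rng(51)
        a = rng.uniform(0, 5, size=50)
        b = rng.uniform(0, 5, size=50)
        m = self._matrix_two_tracks(a, b)
        df = cluster_signal_correlation(m, self._assignment(50))
        r = ((a - a.mean()) * (b - b.mean())).sum() / np.sqrt(
            ((a - a.mean()) ** 2).sum() * ((b - b.mean()) ** 2).sum()
        )
        assert df["pearson_r"].iloc[0] == pytest.approx(r, rel=1e-9)

    def test_tiny_cluster_skipped(self):
        m = self._matrix_two_tracks([1.0, 2.0], [3.0, 1.0])
        with pytest.warns(UserWarning):
            df = cluster_signal_correlation(m, self._assignment(2))
        assert df.empty
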