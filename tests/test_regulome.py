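import numpy as np
import pandas as pd
import pytest

from eploops.errors import DegenerateDataError
from eploops.genome import GeneModel, GenomicInterval
from eploops.loops import make_loop
from eploops.regulome import (
    DERecord,
    both_anchor_motif_fraction,
    build_ep_pairs,
    classify_anchors,
    cluster_direction_breakdown,
    ep_gene_table,
    ep_genes,
    subtype_specific_genes,
    tf_subset,
)

BIN = 5000


def _anchor(start, chrom="chr1"):
    return GenomicInterval(chrom, start, start + BIN)


def _gene(gene_id, tss, chrom="chr1", strand="+"):
    if strand == "+":
        exons = [GenomicInterval(chrom, tss, tss + 2000, strand)]
    else:
        exons = [GenomicInterval(chrom, tss - 1999, tss + 1, strand)]
    return GeneModel(gene_id, gene_id, chrom, strand, exons)


class TestClassifyAnchors:
    def test_promoter_precedence_over_motif(self):
        gene = _gene("g1", 102_000)
        anchor = _anchor(100_000)  # overlaps TSS window
        [ac] = classify_anchors(
            [anchor], [gene], {anchor.key(): True}, [anchor]
        )
        assert ac.klass == "P" and ac.has_motif and ac.is_promoter
        assert ac.promoter_genes == ["g1"]

    def test_distal_motif_peak_anchor_is_ihlf(self):
        gene = _gene("g1", 102_000)
        anchor = _anchor(160_000)  # 50+ kb away
        [ac] = classify_anchors([anchor], [gene], {anchor.key(): True}, [anchor])
        assert ac.klass == "I_HLF"

    def test_peak_without_motif_is_iplain_else_other(self):
        anchor = _anchor(500_000)
        [ac] = classify_anchors([anchor], [], {}, [anchor])
        assert ac.klass == "I_plain"
        [ac] = classify_anchors([anchor], [], {}, [])
        assert ac.klass == "other"

    def test_counts_match_per_anchor_oracle(self):
        rng = np.random.default_rng(61)
        genes = [_gene(f"g{i}", 50_000 + 100_000 * i) for i in range(10)]
        anchors = [_anchor(int(b) * BIN) for b in rng.integers(0, 250, size=120)]
        anchors = list({a.key(): a for a in anchors}.values())
        motif_flags = {a.key(): bool(rng.random() < 0.4) for a in anchors}
        tf_peaks = [a for a in anchors if rng.random() < 0.5]
        out = classify_anchors(anchors, genes, motif_flags, tf_peaks)
        peak_keys = {p.key() for p in tf_peaks}
        for ac in out:
            a = ac.anchor
            is_promoter = any(
                g.tss - 10_000 < a.end and a.start <= g.tss + 10_000 for g in genes
            )
            has_motif = motif_flags[a.key()]
            has_peak = a.key() in peak_keys
            if is_promoter:
                expected = "P"
            elif has_motif and has_peak:
                expected = "I_HLF"
            elif has_peak:
                expected = "I_plain"
            else:
                expected = "other"
            assert ac.klass == expected


def _classified_world(rng, n_genes=20, n_anchors=120):
    """Random anchors with random classes over a gene panel."""
    genes = [_gene(f"g{i}", 50_000 + 120_000 * i) for i in range(n_genes)]
    anchors = [_anchor(int(b) * BIN) for b in rng.integers(0, 800, size=n_anchors)]
    anchors = list({a.key(): a for a in anchors}.values())
    motif_flags = {a.key(): bool(rng.random() < 0.5) for a in anchors}
    tf_peaks = [a for a in anchors if rng.random() < 0.7]
    classes = classify_anchors(anchors, genes, motif_flags, tf_peaks)
    return genes, anchors, classes


class TestPairs:
    def test_p_ihlf_loop_yields_one_pair(self):
        gene = _gene("g1", 102_000)
        p_anchor = _anchor(100_000)
        i_anchor = _anchor(200_000)
        classes = classify_anchors(
            [p_anchor, i_anchor],
            [gene],
            {i_anchor.key(): True},
            [i_anchor],
        )
        loop = make_loop(p_anchor, i_anchor, 7, 0.001)
        pairs = build_ep_pairs([loop], classes)
        assert len(pairs) == 1
        assert pairs[0].genes == ["g1"]
        assert not pairs[0].both_anchors_motif

    def test_homotypic_loop_yields_no_pair(self):
        i1, i2 = _anchor(200_000), _anchor(300_000)
        classes = classify_anchors(
            [i1, i2], [], {i1.key(): True, i2.key(): True}, [i1, i2]
        )
        loop = make_loop(i1, i2, 7, 0.001)
        assert build_ep_pairs([loop], classes) == []

    def test_pair_count_matches_enumeration_oracle(self):
        rng = np.random.default_rng(62)
        genes, anchors, classes = _classified_world(rng)
        by_key = {c.anchor.key(): c for c in classes}
        loops = []
        for _ in range(1000):
            a, b = rng.choice(len(anchors), size=2, replace=False)
            loops.append(
                make_loop(anchors[a], anchors[b], int(rng.integers(1, 30)),
                          float(rng.random() * 0.01))
            )
        pairs = build_ep_pairs(loops, classes)
        expected = sum(
            1
            for lp in loops
            if {by_key[lp.anchor1.key()].klass, by_key[lp.anchor2.key()].klass}
            == {"P", "I_HLF"}
        )
        assert len(pairs) == expected


class TestFraction:
    def test_extremes_and_planted(self):
        gene = _gene("g1", 102_000)
        p_anchor = _anchor(100_000)
        pairs = []
        for j in range(500):
            i_anchor = _anchor(400_000 + j * BIN)
            classes = classify_anchors(
                [p_anchor, i_anchor],
                [gene],
                {i_anchor.key(): True, p_anchor.key(): j < 5},
                [i_anchor],
            )
            pairs += build_ep_pairs(
                [make_loop(p_anchor, i_anchor, 3, 0.001)], classes
            )
        assert both_anchor_motif_fraction(pairs) == pytest.approx(5 / 500)
        assert both_anchor_motif_fraction(pairs[5:]) == 0.0
        assert both_anchor_motif_fraction(pairs[:5]) == 1.0

    def test_empty_is_error(self):
        with pytest.raises(DegenerateDataError):
            both_anchor_motif_fraction([])


def _pairs_for_gene(gene_id, counts_qs, tss=102_000, chrom="chr1"):
    gene = _gene(gene_id, tss, chrom=chrom)
    p_anchor = _anchor((tss // BIN) * BIN, chrom=chrom)
    pairs = []
    for j, (count, q) in enumerate(counts_qs):
        i_anchor = _anchor(tss + 100_000 + j * 3 * BIN, chrom=chrom)
        classes = classify_anchors(
            [p_anchor, i_anchor], [gene], {i_anchor.key(): True}, [i_anchor]
        )
        pairs += build_ep_pairs([make_loop(p_anchor, i_anchor, count, q)], classes)
    return pairs


class TestGeneTable:
    def test_sumcc_arithmetic(self):
        pairs = _pairs_for_gene("g1", [(4, 0.002), (7, 0.001), (9, 0.005)])
        [rec] = ep_gene_table(pairs, [])
        assert rec.sumCC == 20 and rec.n_pairs == 3
        assert rec.best_q == 0.001
        assert rec.de_direction == "absent"

    def test_nonsignificant_de_is_ns_and_excluded(self):
        pairs = _pairs_for_gene("g1", [(4, 0.002)])
        [rec] = ep_gene_table(pairs, [DERecord("g1", 1.5, 0.2)])
        assert rec.de_direction == "ns"
        assert ep_genes([rec]) == []

    def test_sumcc_matches_bruteforce_double_loop(self):
        rng = np.random.default_rng(63)
        genes, anchors, classes = _classified_world(rng)
        loops = []
        for _ in range(1000):
            a, b = rng.choice(len(anchors), size=2, replace=False)
            loops.append(
                make_loop(anchors[a], anchors[b], int(rng.integers(1, 30)),
                          float(rng.random() * 0.01))
            )
        pairs = build_ep_pairs(loops, classes)
        table = ep_gene_table(pairs, [])
        # brute force: for every gene, sum counts of pairs listing it
        expected = {}
        for pair in pairs:
            for gid in pair.genes:
                cur = expected.setdefault(gid, [0, 0, 1.0])
                cur[0] += pair.loop.contact_count
                cur[1] += 1
                cur[2] = min(cur[2], pair.loop.q_value)
        assert {r.gene_id: [r.sumCC, r.n_pairs, r.best_q] for r in table} == expected
        assert sum(r.n_pairs for r in table) >= len(pairs)

    def test_table_sorted_and_permutation_invariant(self):
        rng = np.random.default_rng(64)
        genes, anchors, classes = _classified_world(rng)
        loops = []
        for _ in range(300):
            a, b = rng.choice(len(anchors), size=2, replace=False)
            loops.append(
                make_loop(anchors[a], anchors[b], int(rng.integers(1, 30)),
                          float(rng.random() * 0.01))
            )
        pairs = build_ep_pairs(loops, classes)
        t1 = ep_gene_table(pairs, [])
        t2 = ep_gene_table(list(reversed(pairs)), [])
        assert t1 == t2
        keys = [(r.best_q, -r.sumCC, r.gene_id) for r in t1]
        assert keys == sorted(keys)

    def test_tightening_alpha_never_creates_significance(self):
        pairs = _pairs_for_gene("g1", [(4, 0.002)])
        de = [DERecord("g1", 1.5, 0.03)]
        loose = ep_gene_table(pairs, de, alpha=0.05)[0].de_direction
        tight = ep_gene_table(pairs, de, alpha=0.01)[0].de_direction
        assert loose == "up" and tight == "ns"


class TestBreakdownAndTfs:
    def _table(self):
        records = []
        pairs = _pairs_for_gene("gA", [(4, 0.001)])
        for gid, direction, cluster, is_tf in [
            ("gA", "up", 1, True),
            ("gB", "up", 1, False),
            ("gC", "down", 1, True),
            ("gD", "down", 1, False),
            ("gE", "down", 2, True),
            ("gF", "ns", 2, False),
        ]:
            adj_p = 0.001 if direction in ("up", "down") else 0.5
            fc = 1.0 if direction == "up" else -1.0
            rec = ep_gene_table(pairs, [DERecord("gA", fc, adj_p)])[0]
            rec.gene_id = gid
            rec.chromatin_cluster = cluster
            rec.is_tf = is_tf
            rec.de_direction = direction if direction != "ns" else "ns"
            records.append(rec)
        return records

    def test_breakdown_counts(self):
        df = cluster_direction_breakdown(self._table())
        row1 = df[df.cluster == 1].iloc[0]
        assert (row1.n_up, row1.n_down) == (2, 2)
        assert row1.fraction_down == 0.5
        row2 = df[df.cluster == 2].iloc[0]
        assert (row2.n_up, row2.n_down) == (0, 1)

    def test_tf_partition(self):
        out = tf_subset(self._table())
        assert out["down_tfs"] == ["gC", "gE"]
        assert out["up_tfs"] == ["gA"]

    def test_planted_breakdown_recovered(self):
        rng = np.random.default_rng(65)
        records = []
        pairs = _pairs_for_gene("gX", [(4, 0.001)])
        n_down = 0
        for i in range(200):
            rec = ep_gene_table(pairs, [DERecord("gX", -1.0, 0.001)])[0]
            rec.gene_id = f"g{i}"
            rec.chromatin_cluster = 1
            down = rng.random() < 0.7
            rec.de_direction = "down" if down else "up"
            n_down += down
            records.append(rec)
        df = cluster_direction_breakdown(records)
        assert df.fraction_down.iloc[0] == pytest.approx(n_down / 200)
        assert abs(df.fraction_down.iloc[0] - 0.7) < 0.1


class TestSubtypeSpecificity:
    def _expr(self, rows, subtypes):
        samples = []
        labels = {}
        for st in subtypes:
            for j in range(2):
                name = f"{st}_{j}"
                samples.append(name)
                labels[name] = st
        data = {
            s: [rows[g][labels[s]] for g in rows] for s in samples
        }
        return pd.DataFrame(data, index=list(rows)), labels

    def test_strict_rule_pass_and_fail(self):
        rows = {
            "gPass": {"T": 10.0, "A": 3.0, "B": 2.0, "C": 1.0},
            "gFail": {"T": 10.0, "A": 4.0, "B": 1.0, "C": 1.0},
        }
        expr, labels = self._expr(rows, ["T", "A", "B", "C"])
        out = subtype_specific_genes(expr, labels, "T", fold=3.0)
        assert out == ["gPass"]

    def test_pooled_option_differs(self):
        rows = {"g": {"T": 10.0, "A": 4.0, "B": 1.0, "C": 1.0}}
        expr, labels = self._expr(rows, ["T", "A", "B", "C"])
        assert subtype_specific_genes(expr, labels, "T") == []
        assert subtype_specific_genes(expr, labels, "T", pooled=True) == ["g"]

    def test_planted_set_recovered_exactly(self, sim_dir, ground_truth):
        from eploops.regulome import read_expression_tsv, read_label_tsv

        expr = read_expression_tsv(sim_dir / "subtype_expr.tsv")
        labels = read_label_tsv(sim_dir / "subtype_labels.tsv")
        out = subtype_specific_genes(expr, labels, ground_truth.target_subtype)
        assert out == sorted(ground_truth.specific_genes)

    def test_single_subtype_is_error(self):
        rows = {"g": {"T": 1.0}}
        expr, labels = self._expr(rows, ["T"])
        with pytest.raises(DegenerateDataError):
            subtype_specific_genes(expr, labels, "T")
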