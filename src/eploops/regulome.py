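"""The enhancer-promoter regulome: anchor classification, pair building,
contact aggregation and differential-expression integration.

Loop anchors are classified as promoter (P: overlapping a TSS +/- 10 kb
window), motif-bearing TF-bound intergenic/intragenic (I_HLF), TF-bound
without motif (I_plain), or other.  Loops joining one I_HLF anchor to one
P anchor nominate candidate target genes; per-gene evidence is aggregated
as sumCC (the sum of contact counts over all of a gene's significant
I_HLF-P interactions), the best loop q-value, the knockout DE direction,
the modal chromatin state of the gene's distal anchors and their enhancer
class.  A gene is an "E-P gene" when it is significantly differentially
expressed on fusion-TF knockout.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from .errors import DegenerateDataError, InputFormatError
from .genome import GeneModel, GenomicInterval
from .loops import Loop

DEFAULT_PROMOTER_HALFWIDTH = 10_000
DEFAULT_DE_ALPHA = 0.05

ANCHOR_CLASSES = ("P", "I_HLF", "I_plain", "other")
_ENH_PRECEDENCE = {"SE": 0, "TE": 1, "external_only": 2, "none": 3}


@dataclass
class AnchorClass:
    anchor: GenomicInterval
    is_promoter: bool
    has_motif: bool
    has_tf_peak: bool
    klass: str
    promoter_genes: List[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.klass not in ANCHOR_CLASSES:
            raise ValueError(f"unknown anchor class {self.klass!r}")


@dataclass
class EPPair:
    loop: Loop
    i_anchor: GenomicInterval
    p_anchor: GenomicInterval
    genes: List[str]
    both_anchors_motif: bool


@dataclass
class DERecord:
    gene_id: str
    log2fc: float
    adj_p: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.adj_p <= 1.0):
            raise ValueError(f"{self.gene_id}: adj_p must be in [0, 1]")


@dataclass
class EPGeneRecord:
    gene_id: str
    n_pairs: int
    sumCC: int
    best_q: float
    enhancer_class: str = "none"
    chromatin_cluster: Optional[int] = None
    de_log2fc: Optional[float] = None
    de_adj_p: Optional[float] = None
    de_direction: str = "absent"  # up | down | ns | absent
    is_tf: bool = False
    subtype_specific: bool = False


# ---------------------------------------------------------------------------
# Anchor classification


def classify_anchors(
    anchors: Sequence[GenomicInterval],
    genes: Sequence[GeneModel],
    motif_flags: Mapping[Tuple[str, int, int], bool],
    tf_peaks: Sequence[GenomicInterval],
    promoter_halfwidth: int = DEFAULT_PROMOTER_HALFWIDTH,
) -> List[AnchorClass]:
    """Classify each anchor bin as P, I_HLF, I_plain or other.

    Promoter status (any overlap of the anchor with TSS +/- halfwidth)
    takes precedence: a promoter-overlapping anchor is P even when it
    carries a motif, though its motif flag is retained for the
    both-anchor-motif statistic.
    """
    tss_by_chrom: Dict[str, List[Tuple[int, str]]] = {}
    for g in genes:
        tss_by_chrom.setdefault(g.chrom, []).append((g.tss, g.gene_id))
    for c in tss_by_chrom:
        tss_by_chrom[c].sort()

    peaks_by_chrom: Dict[str, List[GenomicInterval]] = {}
    for p in tf_peaks:
        peaks_by_chrom.setdefault(p.chrom, []).append(p)
    for c in peaks_by_chrom:
        peaks_by_chrom[c].sort(key=lambda iv: iv.start)

    out: List[AnchorClass] = []
    for anchor in anchors:
        # promoter test: anchor [s,e) overlaps [tss-hw, tss+hw] inclusive
        promoter_genes: List[str] = []
        for tss, gid in tss_by_chrom.get(anchor.chrom, []):
            if tss - promoter_halfwidth < anchor.end and anchor.start <= tss + promoter_halfwidth:
                promoter_genes.append(gid)
        is_promoter = bool(promoter_genes)
        has_motif = bool(motif_flags.get(anchor.key(), False))
        has_tf_peak = any(
            anchor.overlaps(p) for p in peaks_by_chrom.get(anchor.chrom, [])
        )
        if is_promoter:
            klass = "P"
        elif has_motif and has_tf_peak:
            klass = "I_HLF"
        elif has_tf_peak:
            klass = "I_plain"
        else:
            klass = "other"
        out.append(
            AnchorClass(
                anchor=anchor,
                is_promoter=is_promoter,
                has_motif=has_motif,
                has_tf_peak=has_tf_peak,
                klass=klass,
                promoter_genes=sorted(promoter_genes),
            )
        )
    return out


def build_ep_pairs(
    loops: Sequence[Loop], anchor_classes: Sequence[AnchorClass]
) -> List[EPPair]:
    """One EPPair per loop joining exactly one I_HLF and one P anchor."""
    by_key: Dict[Tuple[str, int, int], AnchorClass] = {
        ac.anchor.key(): ac for ac in anchor_classes
    }
    pairs: List[EPPair] = []
    for lp in loops:
        ac1 = by_key.get(lp.anchor1.key())
        ac2 = by_key.get(lp.anchor2.key())
        if ac1 is None or ac2 is None:
            continue
        if {ac1.klass, ac2.klass} != {"P", "I_HLF"}:
            continue
        p_ac, i_ac = (ac1, ac2) if ac1.klass == "P" else (ac2, ac1)
        pairs.append(
            EPPair(
                loop=lp,
                i_anchor=i_ac.anchor,
                p_anchor=p_ac.anchor,
                genes=list(p_ac.promoter_genes),
                both_anchors_motif=p_ac.has_motif and i_ac.has_motif,
            )
        )
    return pairs


def both_anchor_motif_fraction(pairs: Sequence[EPPair]) -> float:
    if not pairs:
        raise DegenerateDataError("no I_HLF-P pairs: fraction undefined")
    return sum(p.both_anchors_motif for p in pairs) / len(pairs)


# ---------------------------------------------------------------------------
# Gene table


def de_direction(rec: Optional[DERecord], alpha: float) -> str:
    if rec is None:
        return "absent"
    if rec.adj_p < alpha:
        return "up" if rec.log2fc > 0 else "down"
    return "ns"


def ep_gene_table(
    pairs: Sequence[EPPair],
    de: Sequence[DERecord],
    enhancer_classes: Optional[Mapping[Tuple[str, int, int], str]] = None,
    cluster_by_anchor: Optional[Mapping[Tuple[str, int, int], int]] = None,
    tf_list: Optional[Set[str]] = None,
    subtype_specific: Optional[Set[str]] = None,
    alpha: float = DEFAULT_DE_ALPHA,
) -> List[EPGeneRecord]:
    """Aggregate I_HLF-P pairs into one record per candidate target gene.

    sumCC = sum of contact counts over the gene's pairs; best_q = min q.
    The enhancer class is the highest-precedence class among the gene's
    distal (I_HLF) anchors; the chromatin cluster is the modal cluster of
    those anchors (ties to the lowest cluster number).  The table is
    sorted by ascending best_q, then descending sumCC, then gene_id, so
    the output is byte-stable under input permutation.
    """
    de_by_gene = {r.gene_id: r for r in de}
    tf_list = tf_list or set()
    subtype_specific = subtype_specific or set()
    enhancer_classes = enhancer_classes or {}
    cluster_by_anchor = cluster_by_anchor or {}

    per_gene: Dict[str, List[EPPair]] = {}
    for pair in pairs:
        for gid in pair.genes:
            per_gene.setdefault(gid, []).append(pair)

    records: List[EPGeneRecord] = []
    for gid, gene_pairs in per_gene.items():
        sum_cc = sum(p.loop.contact_count for p in gene_pairs)
        best_q = min(p.loop.q_value for p in gene_pairs)
        klasses = [
            enhancer_classes.get(p.i_anchor.key(), "none") for p in gene_pairs
        ]
        enh = min(klasses, key=lambda k: _ENH_PRECEDENCE.get(k, 99))
        clusters = [
            cluster_by_anchor[p.i_anchor.key()]
            for p in gene_pairs
            if p.i_anchor.key() in cluster_by_anchor
        ]
        if clusters:
            counts = Counter(clusters)
            top = max(counts.values())
            cluster = min(c for c, n in counts.items() if n == top)
        else:
            cluster = None
        rec = de_by_gene.get(gid)
        records.append(
            EPGeneRecord(
                gene_id=gid,
                n_pairs=len(gene_pairs),
                sumCC=sum_cc,
                best_q=best_q,
                enhancer_class=enh,
                chromatin_cluster=cluster,
                de_log2fc=rec.log2fc if rec else None,
                de_adj_p=rec.adj_p if rec else None,
                de_direction=de_direction(rec, alpha),
                is_tf=gid in tf_list,
                subtype_specific=gid in subtype_specific,
            )
        )
    records.sort(key=lambda r: (r.best_q, -r.sumCC, r.gene_id))
    return records


def ep_genes(records: Sequence[EPGeneRecord]) -> List[EPGeneRecord]:
    """The significantly regulated subset ('E-P genes')."""
    return [r for r in records if r.de_direction in ("up", "down")]


def cluster_direction_breakdown(records: Sequence[EPGeneRecord]) -> pd.DataFrame:
    """Per chromatin cluster: up/down counts and fraction down.

    Restricted to genes with a significant DE direction and an assigned
    cluster; empty clusters are simply absent from the output.
    """
    rows = []
    sig = [
        r
        for r in records
        if r.de_direction in ("up", "down") and r.chromatin_cluster is not None
    ]
    for cluster in sorted({r.chromatin_cluster for r in sig}):
        sub = [r for r in sig if r.chromatin_cluster == cluster]
        n_up = sum(r.de_direction == "up" for r in sub)
        n_down = sum(r.de_direction == "down" for r in sub)
        rows.append(
            {
                "cluster": cluster,
                "n_up": n_up,
                "n_down": n_down,
                "fraction_down": n_down / (n_up + n_down),
            }
        )
    return pd.DataFrame(rows)


def tf_subset(records: Sequence[EPGeneRecord]) -> Dict[str, List[str]]:
    """Transcription-factor E-P genes split by knockout DE direction."""
    down = [r for r in records if r.is_tf and r.de_direction == "down"]
    up = [r for r in records if r.is_tf and r.de_direction == "up"]
    down.sort(key=lambda r: (r.best_q, r.gene_id))
    up.sort(key=lambda r: (r.best_q, r.gene_id))
    return {"down_tfs": [r.gene_id for r in down], "up_tfs": [r.gene_id for r in up]}


# ---------------------------------------------------------------------------
# Subtype specificity


def subtype_specific_genes(
    expr: pd.DataFrame,
    labels: Mapping[str, str],
    target_subtype: str,
    fold: float = 3.0,
    pooled: bool = False,
) -> List[str]:
    """Genes with >= fold higher median expression in the target subtype.

    ``expr`` is genes x samples.  Strict rule (default): the target median
    must be >= fold x the median of EVERY other subtype.  With
    ``pooled=True`` the comparison is against the pooled median of all
    non-target samples.  Subtypes with zero samples are dropped with a
    warning; the target median must additionally be positive.
    """
    sample_groups: Dict[str, List[str]] = {}
    for sample in expr.columns:
        if sample not in labels:
            raise InputFormatError(f"sample {sample!r} has no subtype label")
        sample_groups.setdefault(labels[sample], []).append(sample)
    if target_subtype not in sample_groups:
        raise DegenerateDataError(f"target subtype {target_subtype!r} has no samples")
    if len(sample_groups) < 2:
        raise DegenerateDataError("need at least 2 subtypes")
    for subtype in [s for s, cols in sample_groups.items() if not cols]:
        warnings.warn(f"subtype {subtype!r} has no samples; excluded")
        del sample_groups[subtype]

    target_med = expr[sample_groups[target_subtype]].median(axis=1)
    if pooled:
        other_cols = [
            c
            for s, cols in sample_groups.items()
            if s != target_subtype
            for c in cols
        ]
        other_med = expr[other_cols].median(axis=1)
        passes = (target_med > 0) & (target_med >= fold * other_med)
    else:
        passes = target_med > 0
        for subtype, cols in sample_groups.items():
            if subtype == target_subtype:
                continue
            passes &= target_med >= fold * expr[cols].median(axis=1)
    return sorted(expr.index[passes])


# ---------------------------------------------------------------------------
# I/O


def read_de_table(path) -> List[DERecord]:
    """TSV with columns gene_id (or gene), log2fc, adj_p."""
    df = pd.read_csv(path, sep="\t")
    cols = {c.lower(): c for c in df.columns}
    gene_col = cols.get("gene_id") or cols.get("gene")
    if gene_col is None or "log2fc" not in cols or "adj_p" not in cols:
        raise InputFormatError(
            f"{path}: need columns gene_id (or gene), log2fc, adj_p"
        )
    return [
        DERecord(str(r[gene_col]), float(r[cols["log2fc"]]), float(r[cols["adj_p"]]))
        for _, r in df.iterrows()
    ]


def read_gene_list(path) -> Set[str]:
    with open(path) as fh:
        return {line.strip() for line in fh if line.strip()}


def read_expression_tsv(path) -> pd.DataFrame:
    """Genes x samples TSV with gene ids in the first column."""
    return pd.read_csv(path, sep="\t", index_col=0)


def read_label_tsv(path) -> Dict[str, str]:
    """Two-column TSV (sample, subtype), optional header."""
    out: Dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise InputFormatError(f"{path}:{lineno}: expected 2 columns")
            if lineno == 1 and parts[0].lower() in ("sample", "cell"):
                continue
            out[parts[0]] = parts[1]
    return out


def write_ep_table(records: Sequence[EPGeneRecord], path) -> None:
    rows = []
    for r in records:
        rows.append(
            {
                "gene_id": r.gene_id,
                "n_pairs": r.n_pairs,
                "sumCC": r.sumCC,
                "best_q": r.best_q,
                "enhancer_class": r.enhancer_class,
                "chromatin_cluster": r.chromatin_cluster
                if r.chromatin_cluster is not None
                else "NA",
                "de_log2fc": r.de_log2fc if r.de_log2fc is not None else "NA",
                "de_adj_p": r.de_adj_p if r.de_adj_p is not None else "NA",
                "de_direction": r.de_direction,
                "is_tf": int(r.is_tf),
                "subtype_specific": int(r.subtype_specific),
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_pairs_bedpe(pairs: Sequence[EPPair], path) -> None:
    """Annotated pairs: BEDPE plus gene list and both-anchor-motif flag."""
    with open(path, "w") as fh:
        for p in pairs:
            a1, a2 = p.loop.anchor1, p.loop.anchor2
            fh.write(
                f"{a1.chrom}\t{a1.start}\t{a1.end}\t{a2.chrom}\t{a2.start}\t"
                f"{a2.end}\t{p.loop.contact_count}\t{p.loop.q_value:.6g}\t"
                f"{','.join(p.genes)}\t{int(p.both_anchors_motif)}\n"
            )
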