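"""Genomic coordinate arithmetic, sequence access and gene-model handling.

All internal coordinates are 0-based half-open (``[start, end)``), matching
BED/BEDPE/bedGraph conventions.  GTF's 1-based inclusive coordinates are
converted at the I/O boundary and nowhere else, so downstream modules can
mix intervals from any source without off-by-one drift.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import InputFormatError

PROMOTER_UP_DEFAULT = 1000
PROMOTER_DOWN_DEFAULT = 100

ANNOTATION_CATEGORIES = ("promoter", "utr5", "utr3", "exon", "intron", "intergenic")


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open genomic interval.

    ``strand`` is ``+``, ``-`` or ``.`` (unstranded).  Strand does not
    participate in ordering or equality of anchor/peak coordinates; two
    intervals with the same span on opposite strands are distinct objects
    but sort adjacently.
    """

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def key(self) -> tuple:
        """Location-only key (strand ignored), used for anchor identity."""
        return (self.chrom, self.start, self.end)


@dataclass
class GeneModel:
    """A single-transcript gene model: one TSS per gene.

    The TSS is the start of the first exon on the + strand and ``end - 1``
    of the last exon on the - strand (0-based).
    """

    gene_id: str
    symbol: str
    chrom: str
    strand: str
    exons: list  # of GenomicInterval, sorted, non-overlapping
    utr5: list = field(default_factory=list)
    utr3: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValueError(f"gene {self.gene_id} has no exons")
        self.exons = sorted(self.exons, key=lambda iv: iv.start)
        for a, b in zip(self.exons, self.exons[1:]):
            if a.end > b.start:
                raise ValueError(f"gene {self.gene_id} has overlapping exons")
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be + or -")

    @property
    def tss(self) -> int:
        if self.strand == "+":
            return self.exons[0].start
        return self.exons[-1].end - 1

    @property
    def start(self) -> int:
        return self.exons[0].start

    @property
    def end(self) -> int:
        return self.exons[-1].end

    def span(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end, self.strand)


@dataclass
class FeatureAnnotation:
    """Category assigned to an interval plus its nearest-TSS context."""

    category: str
    gene_id: Optional[str] = None
    distance_to_tss: Optional[int] = None

    def __post_init__(self) -> None:
        if self.category not in ANNOTATION_CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path) -> dict:
    """Read a FASTA file into ``{chrom: uppercase sequence}``.

    Chromosome names are the header token up to the first whitespace.
    Duplicate names and empty records are hard errors.
    """
    genome: dict = {}
    with open(path) as fh:
        for record in SeqIO.parse(fh, "fasta"):
            name = record.id
            if name in genome:
                raise InputFormatError(f"duplicate chromosome name {name!r} in {path}")
            seq = str(record.seq).upper()
            if not seq:
                raise InputFormatError(f"empty record {name!r} in {path}")
            genome[name] = seq
    if not genome:
        raise InputFormatError(f"no FASTA records in {path}")
    return genome


def write_fasta(genome: Mapping[str, str], path, width: int = 80) -> None:
    records = [
        SeqRecord(Seq(seq), id=chrom, description="") for chrom, seq in genome.items()
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


# ---------------------------------------------------------------------------
# GTF


def _parse_gtf_attributes(raw: str) -> dict:
    attrs = {}
    for chunk in raw.strip().split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        if " " not in chunk:
            continue
        key, value = chunk.split(" ", 1)
        attrs[key] = value.strip().strip('"')
    return attrs


def read_gtf(path, chrom_names: Optional[Iterable[str]] = None) -> list:
    """Parse a GTF into :class:`GeneModel` objects.

    GTF's 1-based inclusive coordinates become 0-based half-open here.
    Exons on chromosomes outside ``chrom_names`` (when given) are dropped
    with a warning; a feature without ``gene_id`` is a hard error.
    """
    known = set(chrom_names) if chrom_names is not None else None
    per_gene: dict = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                raise InputFormatError(f"{path}:{lineno}: expected 9 GTF columns")
            chrom, _source, feature, start1, end1, _score, strand, _frame, attr_raw = (
                fields[:9]
            )
            attrs = _parse_gtf_attributes(attr_raw)
            if "gene_id" not in attrs:
                raise InputFormatError(f"{path}:{lineno}: missing gene_id attribute")
            if feature not in ("gene", "exon", "five_prime_utr", "three_prime_utr", "UTR"):
                continue
            if known is not None and chrom not in known:
                warnings.warn(
                    f"{path}:{lineno}: feature on unknown chromosome {chrom!r} dropped"
                )
                continue
            start = int(start1) - 1  # to 0-based half-open
            end = int(end1)
            gid = attrs["gene_id"]
            rec = per_gene.setdefault(
                gid,
                {
                    "symbol": attrs.get("gene_name", gid),
                    "chrom": chrom,
                    "strand": strand,
                    "exons": [],
                    "utr5": [],
                    "utr3": [],
                    "gene_span": None,
                },
            )
            iv = GenomicInterval(chrom, start, end, strand if strand in "+-" else ".")
            if feature == "gene":
                rec["gene_span"] = iv
            elif feature == "exon":
                rec["exons"].append(iv)
            elif feature == "five_prime_utr":
                rec["utr5"].append(iv)
            elif feature == "three_prime_utr":
                rec["utr3"].append(iv)

    genes = []
    for gid, rec in per_gene.items():
        exons = rec["exons"]
        if not exons:
            if rec["gene_span"] is None:
                warnings.warn(f"gene {gid} has no exon or gene feature; dropped")
                continue
            exons = [rec["gene_span"]]
        genes.append(
            GeneModel(
                gene_id=gid,
                symbol=rec["symbol"],
                chrom=rec["chrom"],
                strand=rec["strand"],
                exons=exons,
                utr5=rec["utr5"],
                utr3=rec["utr3"],
            )
        )
    genes.sort(key=lambda g: (g.chrom, g.start, g.gene_id))
    return genes


def write_gtf(genes: Sequence[GeneModel], path) -> None:
    """Write gene models as GTF (gene + exon + UTR features)."""
    with open(path, "w") as fh:
        for g in genes:
            attr = f'gene_id "{g.gene_id}"; gene_name "{g.symbol}";'

            def row(feature: str, iv: GenomicInterval) -> str:
                return (
                    f"{g.chrom}\teploops\t{feature}\t{iv.start + 1}\t{iv.end}\t.\t"
                    f"{g.strand}\t.\t{attr}\n"
                )

            fh.write(row("gene", g.span()))
            for ex in g.exons:
                fh.write(row("exon", ex))
            for iv in g.utr5:
                fh.write(row("five_prime_utr", iv))
            for iv in g.utr3:
                fh.write(row("three_prime_utr", iv))


# ---------------------------------------------------------------------------
# Annotation


def _promoter_window(gene: GeneModel, up: int, down: int) -> tuple:
    """Promoter window [lo, hi] (inclusive bp) oriented by gene strand."""
    if gene.strand == "+":
        return gene.tss - up, gene.tss + down
    return gene.tss - down, gene.tss + up


def _signed_tss_distance(pos: int, gene: GeneModel) -> int:
    """Signed distance from pos to TSS; negative = upstream on gene strand."""
    if gene.strand == "+":
        return pos - gene.tss
    return gene.tss - pos


def annotate_interval(
    iv: GenomicInterval,
    genes: Sequence[GeneModel],
    promoter_up: int = PROMOTER_UP_DEFAULT,
    promoter_down: int = PROMOTER_DOWN_DEFAULT,
) -> FeatureAnnotation:
    """Assign a single genomic category to an interval by its midpoint.

    Precedence: promoter > utr5 > utr3 > exon > intron > intergenic.
    Among genes tied at the winning category, the nearest TSS wins; an
    exact distance tie goes to the lexicographically smaller gene_id.
    """
    mid = iv.midpoint
    best: Optional[tuple] = None  # (precedence_rank, |dist|, gene_id, gene)
    for gene in genes:
        if gene.chrom != iv.chrom:
            continue
        lo, hi = _promoter_window(gene, promoter_up, promoter_down)
        category = None
        if lo <= mid <= hi:
            category = "promoter"
        elif any(u.start <= mid < u.end for u in gene.utr5):
            category = "utr5"
        elif any(u.start <= mid < u.end for u in gene.utr3):
            category = "utr3"
        elif any(e.start <= mid < e.end for e in gene.exons):
            category = "exon"
        elif gene.start <= mid < gene.end:
            category = "intron"
        if category is None:
            continue
        rank = ANNOTATION_CATEGORIES.index(category)
        cand = (rank, abs(mid - gene.tss), gene.gene_id, gene, category)
        if best is None or cand[:3] < best[:3]:
            best = cand
    if best is None:
        return FeatureAnnotation("intergenic")
    _, _, _, gene, category = best
    return FeatureAnnotation(
        category=category,
        gene_id=gene.gene_id,
        distance_to_tss=_signed_tss_distance(mid, gene),
    )


def annotate_intervals(
    intervals: Sequence[GenomicInterval],
    genes: Sequence[GeneModel],
    promoter_up: int = PROMOTER_UP_DEFAULT,
    promoter_down: int = PROMOTER_DOWN_DEFAULT,
) -> list:
    return [annotate_interval(iv, genes, promoter_up, promoter_down) for iv in intervals]


def category_counts(annotations: Iterable[FeatureAnnotation]) -> dict:
    counts = {c: 0 for c in ANNOTATION_CATEGORIES}
    for ann in annotations:
        counts[ann.category] += 1
    return counts


def write_annotated_bed(
    intervals: Sequence[GenomicInterval],
    annotations: Sequence[FeatureAnnotation],
    path,
) -> None:
    """BED6 dump: name = category, score = distance_to_tss (0 if undefined)."""
    with open(path, "w") as fh:
        for iv, ann in zip(intervals, annotations):
            dist = ann.distance_to_tss if ann.distance_to_tss is not None else 0
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{ann.category}\t{dist}\t{iv.strand}\n"
            )
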