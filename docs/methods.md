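# Methods

`eploops` reconstructs the regulatory map of a DNA-binding oncoprotein —
prototypically a fusion transcription factor such as TCF3::HLF in
t(17;19) acute lymphoblastic leukemia — from protein-directed chromosome
conformation data (HiChIP). The input is a set of significant chromatin
loops between fixed-width genomic bins; the output is a ranked table of
candidate direct target genes with chromatin-state, enhancer and
expression annotations. This note records the models, the parameters
that matter, and the choices made where the design was genuinely open.

## Coordinates and inputs

All internal coordinates are 0-based half-open. BED/BEDPE/bedGraph are
read natively; GTF (1-based inclusive) is converted at the boundary.
Loops arrive as 7–8 column BEDPE (`chr1 s1 e1 chr2 s2 e2 count [q]`) on
a fixed bin grid (default 5 kb, the resolution of the loop caller).
A missing q column means the file is pre-filtered and q is taken as 0.

## Loop filtering and anchors

Significant loops are intra-chromosomal contacts with q ≤ `loop_q`
(default 0.01) and anchor separation within [`d_min`, `d_max`] (defaults
50 kb and 3 Mb, the calling range of the upstream tool).
Inter-chromosomal loops survive I/O but are excluded from pairing. The
anchor universe is the set of unique anchor bins of the filtered loops.

## Motif scanning

Anchors are scanned with a position weight matrix on both strands.
Column probabilities use a per-cell pseudocount (default 0.1); scores
are log2 odds against a uniform background. A window is a hit when its
score reaches `motif_threshold` × the best attainable score (default
0.8). This relative-score rule is deterministic and background-free;
it trades FIMO-style p-value calibration for bit-for-bit
reproducibility. Windows containing N are skipped. The shipped default
motif is a synthetic sharp PWM built from the PAR-bZIP (HLF-like)
consensus TTACGTAA — a stand-in, not a database PFM; supply a
MEME-minimal or JASPAR motif for real data. Motif enrichment between
two region sets is a one-sided Fisher's exact test on the 2×2
presence table, with a Haldane 0.5 correction of the odds ratio when a
cell is empty.

## Anchor classification and E-P pairs

An anchor is a promoter anchor (P) when it overlaps any TSS ± 10 kb
window (`promoter_halfwidth`); one TSS per gene (no alternative
transcripts). A non-promoter anchor that carries both a motif hit and a
TF 1D peak is a motif-bearing distal anchor (I_HLF); with a peak but no
motif it is I_plain; otherwise "other". Promoter status takes
precedence: a promoter-overlapping anchor with a motif is still P,
though its motif flag feeds the heterotypic statistic below. Note the
±10 kb pairing window is deliberately distinct from the −1000/+100 bp
promoter window used for genomic feature annotation (HOMER-like
defaults; the annotation window is configurable because the exact value
used upstream is not fixed by convention).

Each filtered loop joining exactly one P and one I_HLF anchor becomes
an enhancer–promoter pair; the pair inherits every gene whose TSS
window overlaps the P anchor. The fraction of pairs whose two anchors
both carry the motif measures how heterotypic the interaction map is.

Per-gene aggregation: `sumCC` is the sum of contact counts over the
gene's pairs (cumulative contact frequency), `best_q` the minimum loop
q. The table sorts by ascending best_q, then descending sumCC, then
gene id — significance primary, contact magnitude secondary — and the
stable sort makes the output byte-identical under input permutation.
Genes significantly differentially expressed on TF knockout
(adjusted p < `de_alpha`, default 0.05) are the E-P genes; direction is
the sign of log2FC. A gene's chromatin cluster is the modal cluster of
its distal anchors (ties to the lowest cluster number — the
least-surprising aggregate; the multi-anchor rule is not dictated by
the method). Its enhancer class is the highest-precedence class
(SE > TE > external_only > none) among those anchors.

## ROSE-style enhancer calling

H3K27ac peaks are stitched when gaps are ≤ 12,500 bp (published ROSE
default; TSS exclusion defaults to 0). Stitched regions are scored by
the signal-track area minus an optional control area, floored at 0 —
area under a bedGraph rather than read counts keeps the module
alignment-free. The super-enhancer cutoff is the hockey-stick point:
with ranks and signals rescaled to the unit square (ascending), the
cutoff is the signal at the first point whose forward-difference slope
reaches 1; regions above it are super-enhancers. A geometric
max-distance-to-diagonal elbow is kept in the tests as an independent
cross-check; the two agree within one rank on well-formed profiles. An
all-equal profile has no elbow (warning, no SE); a perfectly linear
profile triggers a degeneracy warning.

## Chromatin-state clustering

Motif-centered windows (± 2 kb, 50-bp bins — conventional
signal-matrix defaults; the exact values used upstream are not printed,
both configurable) are summarized per track as per-bin mean bedGraph
value, strand-flipped for minus-strand motifs. Regions are ranked by
the TF-occupancy track row-sum and the top 75 % kept. k-means (k = 3,
10 restarts, fixed seed) runs on the concatenated per-track profiles,
each track z-scored globally so a deep track cannot dominate the
Euclidean metric. Clusters are relabeled 1..k by descending mean of
the active mark (H3K27ac), making cluster identity stable across seeds
when the states are separated. Densities are RPKM-like
(row-sum / (window kb × track-total/10⁶)), compared per cluster pair
with Welch t-tests and Benjamini–Hochberg correction across the whole
family; this density is invariant to rescaling a track. Per-cluster
association between accessibility and TF occupancy is a Pearson
correlation of row-sums (clusters with n < 3 skipped).

## Replicate reproducibility (SCC)

The stratum-adjusted correlation coefficient between two contact
matrices at matching resolution: both matrices are mean-filtered with a
(2h+1)² window (h = 3 by default; the filter truncates at matrix edges
rather than padding — stated explicitly because implementations
differ), then for each diagonal stratum with genomic offset in [lb, ub]
(defaults 0 and 3 Mb) the Pearson correlation is combined with weights
N_k·σ1k·σ2k. Zero-variance strata are skipped; identical matrices give
exactly 1. One caution for calibration studies: the mean filter
correlates neighbouring entries within and across strata, which widens
the null spread of the statistic on independent noise without biasing
it; null calibration checks therefore run at h = 0.

## Subtype specificity

A gene is subtype-specific when its median expression in the target
subtype is ≥ `fold` (default 3) times the median of **every** other
subtype (strict per-subtype rule) and positive. "Three-fold higher than
all other subtypes" also admits a pooled reading; the pooled-median
comparison is available via `pooled=True` and is strictly more
permissive. The strict rule is the default because it matches the
plain-language claim for each competing subtype.

## Signature scoring

**Module score** (the Seurat AddModuleScore construction with its
canonical defaults): genes are placed into 24 equal-frequency bins of
mean expression; for each module gene, 100 control genes are drawn with
replacement from its bin; the score per cell is the mean module
expression minus the mean of the pooled controls. The score is
invariant to adding a constant to the matrix and is exactly zero on a
constant matrix. Limitation: a module lying at the extreme top of the
expression distribution has no expression-matched controls — control
pools then contain the module itself and the score compresses toward
zero; the synthetic planted module is therefore drawn from the
mid-range of baseline expression.

**Preranked GSEA**: genes ordered by a signed metric (for this
pipeline's DE input: −log10(adjusted p) × sign(log2FC), capped — the
upstream choice of metric is not fixed, so it is configurable). ES is
the signed maximum deviation of the weighted running sum (hit weights
|metric|^p with p = 1, miss decrement 1/(N−m)); the implementation
matches Bioconductor fgsea's statistic on a frozen fixture. The null is
a gene-set permutation (random same-size sets; phenotype permutation is
unavailable for a preranked list), NES = ES divided by the mean |null
ES| of matching sign (falling back to the full null magnitude when no null
shares the sign, so sign(NES) = sign(ES)), p = (1 + #{as-or-more
extreme same-sign nulls}) / (1 + #same-sign nulls), BH across sets.
Plain permutation is used rather than fgsea's adaptive multilevel
algorithm; at the set counts handled here the resolution is adequate.
One documented reading: the source figure legend for the knockout
module ("adj. P value > 0.05") is taken as a typo for "< 0.05".

## Synthetic data and what passing tests show

The generator writes every input the pipeline reads, with planted
ground truth serialized alongside. Study conditions: 3 chromosomes × 5
Mb, 200 genes, 5-kb bins, 2000 loops, 30 planted target genes (one
designated top gene with three high-count, lowest-q loops), archetype
mix 0.5/0.3/0.2, 24 subtypes with 22 planted specific genes, a
500-cell × 1000-gene matrix with a δ = 1 module shift in half the
cells. Genes occupy disjoint 50-kb tiles so promoter windows of
distinct genes never share an anchor bin; distal anchors are placed in
gene-free tiles at 60 kb–1.5 Mb from their promoter. The random genome
is scrubbed of chance motif-consensus occurrences before planting, so
motif-fraction statistics are exact. Planted loops draw q from
10⁻⁶–10⁻³ and Poisson(15) counts (Poisson(60) for the top gene);
background loops draw q above the significance threshold (easy mode)
with distance-decaying counts (mean ∝ 1/d), so the planted/background
split is exact under the default filter; `hard_mode` overlaps the q
distributions for sensitivity studies. Chromatin tracks realize three
archetypes — active (high H3K27ac/H3K4me1/accessibility), primed
(H3K4me1-high, H3K27ac-low), repressed-but-accessible (H3K27me3-high
with elevated accessibility and TF occupancy) — as Gaussian peak
profiles with additive noise (σ = 0.1). Knockout DE directions are
planted with a 70 % down bias in active-archetype genes. Randomness is
one RNG stream per (seed, stage), so adding a stage never perturbs
earlier outputs and equal seeds give byte-identical trees.

What the synthetic data does **not** emulate: read-level noise,
peak-calling uncertainty, correlated loop anchors, copy-number effects,
overdispersed expression counts, doublets or batch structure. Passing
the planted-truth tests shows the integration logic is correct given
correct upstream calls; it does not validate the upstream callers.

## Numerical choices

- Ties: top-fraction selection and ranking break ties by genomic
  coordinate; gene-table ties by gene id; annotation ties by nearest
  TSS then lexicographic gene id; cluster ties by lowest label.
- Kept count for "top 75 %" is floor(n × fraction), minimum 1.
- Self-correlation strata in SCC short-circuit to exactly 1 to avoid
  rounding below 1.0.
- Degenerate inputs raise typed errors (config / input-format /
  degenerate-data), mapped to CLI exit codes 2/3/4.

## Problem sizes

Default pipeline runs use the generator's study conditions above
(~15 Mb genome, 2000 loops); oracle-equivalence tests use 100 × 10-kb
sequences, 1000-loop fixtures and 100–150-region clustering problems —
sizes at which the brute-force oracles are exact and fast.

## Known limitations

One TSS per gene; no CpG/TTS annotation subcategories; hockey-stick
cutoff assumes a convex ranked profile; the permutation GSEA p-value
resolution is 1/(n_perm+1); the module score inherits AddModuleScore's
bias for modules at the top of the expression range; SCC assumes dense
matrices at desk scale.
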