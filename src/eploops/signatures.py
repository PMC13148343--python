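"""Gene-signature scoring: bin-matched module scores and preranked GSEA.

The module score compares the mean expression of a gene set against
expression-matched control genes drawn from equal-frequency bins of mean
expression (the Seurat AddModuleScore construction: 24 bins, 100 controls
per gene, by default).  Preranked GSEA uses the weighted Kolmogorov-
Smirnov running-sum statistic with a gene-set permutation null, NES
normalization by the mean same-sign null magnitude, and BH correction
across sets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .errors import DegenerateDataError, InputFormatError

DEFAULT_N_BINS = 24
DEFAULT_N_CTRL = 100
DEFAULT_N_PERM = 1000


@dataclass
class ModuleScoreResult:
    scores: pd.Series  # index: cells
    module: List[str]
    n_bins: int
    n_ctrl: int
    seed: int


@dataclass
class GseaResult:
    name: str
    es: float
    nes: float
    p_perm: float
    adj_p: float = float("nan")
    size: int = 0
    leading_edge: List[str] = field(default_factory=list)


def module_score(
    expr: pd.DataFrame,
    module: Sequence[str],
    n_bins: int = DEFAULT_N_BINS,
    n_ctrl: int = DEFAULT_N_CTRL,
    seed: int = 0,
) -> ModuleScoreResult:
    """Bin-matched module score per cell.

    ``expr`` is genes x cells on a log-like scale.  Genes are placed into
    ``n_bins`` equal-frequency bins of mean expression across cells; for
    each module gene, ``n_ctrl`` control genes are sampled with
    replacement from its bin, and

        score(cell) = mean(module expr) - mean(pooled control expr).

    Module genes missing from the matrix are dropped with a warning.
    """
    module_present = [g for g in module if g in expr.index]
    missing = set(module) - set(module_present)
    if missing:
        warnings.warn(f"{len(missing)} module genes absent from matrix; dropped")
    if not module_present:
        raise DegenerateDataError("no module genes present in the matrix")
    genes = expr.index.to_numpy()
    n_genes = genes.size
    n_bins = min(n_bins, n_genes)

    means = expr.mean(axis=1).to_numpy()
    # equal-frequency bins: stable order by (mean, name) then split by rank
    order = np.lexsort((genes.astype(str), means))
    bin_of = np.empty(n_genes, dtype=int)
    bin_of[order] = (np.arange(n_genes) * n_bins) // n_genes
    bins: Dict[int, np.ndarray] = {
        b: np.nonzero(bin_of == b)[0] for b in range(n_bins)
    }
    gene_pos = {g: i for i, g in enumerate(genes)}

    rng = np.random.default_rng(seed)
    control_idx: List[int] = []
    for g in module_present:
        b = bin_of[gene_pos[g]]
        pool = bins[b]
        control_idx.extend(rng.choice(pool, size=n_ctrl, replace=True))
    values = expr.to_numpy()
    module_mean = values[[gene_pos[g] for g in module_present]].mean(axis=0)
    control_mean = values[control_idx].mean(axis=0)
    return ModuleScoreResult(
        scores=pd.Series(module_mean - control_mean, index=expr.columns),
        module=list(module_present),
        n_bins=n_bins,
        n_ctrl=n_ctrl,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Preranked GSEA


def _enrichment_score(
    abs_weights: np.ndarray,
    hit_positions: np.ndarray,
    n_genes: int,
    return_peak: bool = False,
):
    """Signed-maximum running-sum deviation for one gene set.

    ``hit_positions`` are sorted 0-based ranks of set members in the
    descending-metric ordering; ``abs_weights`` are |metric|^p at those
    ranks.  Evaluates the running sum only at hit boundaries, where its
    extrema occur.
    """
    m = hit_positions.size
    miss_dec = 1.0 / (n_genes - m)
    total_w = abs_weights.sum()
    if total_w == 0:
        hit_inc = np.full(m, 1.0 / m)
    else:
        hit_inc = abs_weights / total_w
    cum_hits = np.cumsum(hit_inc)
    misses_before = hit_positions - np.arange(m)
    after = cum_hits - misses_before * miss_dec
    before = np.concatenate([[0.0], cum_hits[:-1]]) - misses_before * miss_dec
    candidates = np.concatenate([after, before])
    idx = int(np.argmax(np.abs(candidates)))
    es = float(candidates[idx])
    if not return_peak:
        return es
    if es >= 0:
        peak_hit = int(np.argmax(after))
        leading = np.arange(0, peak_hit + 1)
    else:
        trough = int(np.argmin(before))
        leading = np.arange(trough, m)
    return es, leading


def preranked_gsea(
    ranking: pd.Series,
    gene_sets: Mapping[str, Sequence[str]],
    weight_p: float = 1.0,
    n_perm: int = DEFAULT_N_PERM,
    seed: int = 0,
    min_size: int = 3,
) -> List[GseaResult]:
    """Preranked GSEA with a gene-set permutation null.

    ``ranking`` maps gene -> real metric (no duplicate genes).  Genes are
    ordered by descending metric (ties broken by name for determinism).
    For each set, ES is the signed maximum deviation of the running sum
    with hit increments |metric|^p (normalized) and miss decrements
    1/(N - m).  The null is ``n_perm`` random same-size gene sets;
    NES = ES / mean(|null ES| of matching sign) and
    p = (1 + #{same-sign null as-or-more extreme}) / (1 + #same-sign null).
    BH correction is applied across the reported sets.
    """
    if ranking.index.duplicated().any():
        raise InputFormatError("ranking contains duplicate genes")
    order = np.lexsort((ranking.index.to_numpy().astype(str), -ranking.to_numpy()))
    genes_sorted = ranking.index.to_numpy()[order]
    metric_sorted = ranking.to_numpy()[order]
    n_genes = genes_sorted.size
    rank_of = {g: i for i, g in enumerate(genes_sorted)}
    abs_metric_p = np.abs(metric_sorted) ** weight_p

    rng = np.random.default_rng(seed)
    results: List[GseaResult] = []
    null_cache: Dict[int, np.ndarray] = {}
    for name in gene_sets:
        members = [g for g in set(gene_sets[name]) if g in rank_of]
        m = len(members)
        if m < min_size:
            warnings.warn(f"gene set {name!r}: {m} genes in ranking; skipped")
            continue
        if m >= n_genes:
            warnings.warn(f"gene set {name!r} covers the whole ranking; skipped")
            continue
        pos = np.sort(np.array([rank_of[g] for g in members]))
        es, leading = _enrichment_score(
            abs_metric_p[pos], pos, n_genes, return_peak=True
        )
        if m not in null_cache:
            null = np.empty(n_perm)
            for i in range(n_perm):
                rpos = np.sort(rng.choice(n_genes, size=m, replace=False))
                null[i] = _enrichment_score(abs_metric_p[rpos], rpos, n_genes)
            null_cache[m] = null
        null = null_cache[m]
        same_sign = null[null >= 0] if es >= 0 else null[null < 0]
        # fall back to the full null magnitude when no null ES shares the
        # sign, so sign(NES) always matches sign(ES)
        denom = (
            np.abs(same_sign).mean() if same_sign.size else np.abs(null).mean()
        )
        if denom == 0:
            nes = 0.0
            p_perm = 1.0
        else:
            nes = es / denom
            p_perm = (1 + int((np.abs(same_sign) >= abs(es)).sum())) / (
                1 + same_sign.size
            )
        results.append(
            GseaResult(
                name=name,
                es=es,
                nes=float(nes),
                p_perm=float(p_perm),
                size=m,
                leading_edge=[genes_sorted[pos[i]] for i in leading],
            )
        )
    if results:
        _, adj, _, _ = multipletests([r.p_perm for r in results], method="fdr_bh")
        for r, q in zip(results, adj):
            r.adj_p = float(q)
    return results


def ranking_from_de(de_table: pd.DataFrame, cap: float = 300.0) -> pd.Series:
    """Signed significance metric: -log10(adj_p) * sign(log2fc), capped."""
    p = de_table["adj_p"].clip(lower=10.0 ** (-cap))
    metric = -np.log10(p) * np.sign(de_table["log2fc"])
    gene_col = "gene_id" if "gene_id" in de_table.columns else "gene"
    return pd.Series(metric.to_numpy(), index=de_table[gene_col].astype(str))


# ---------------------------------------------------------------------------
# I/O


def read_gmt(path) -> Dict[str, List[str]]:
    sets: Dict[str, List[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise InputFormatError(
                    f"{path}:{lineno}: GMT rows need name, description, >=1 gene"
                )
            sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


def write_gmt(sets: Mapping[str, Sequence[str]], path) -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, "na", *genes]) + "\n")


def write_gsea_results(results: Sequence[GseaResult], path) -> None:
    rows = [
        {
            "set": r.name,
            "es": r.es,
            "nes": r.nes,
            "p_perm": r.p_perm,
            "adj_p": r.adj_p,
            "size": r.size,
            "leading_edge": ",".join(r.leading_edge),
        }
        for r in results
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
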