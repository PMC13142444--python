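"""Post-scoring analytics.

Variant accessibility vs cell-score correlation over quantile bins, variant
classification by fine-mapping PIP and correlation sign, nearest-gene
assignment, regulon enrichment by one-sided Fisher's exact test, and export
of fine-mapping prior annotations.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact, pearsonr
from scipy.stats.contingency import odds_ratio
from statsmodels.stats.multitest import multipletests

from .io_formats import GenomicRegion, VariantRecord, write_annotation
from .ldsc import EnrichmentTable

logger = logging.getLogger(__name__)

__all__ = [
    "VariantScoreCorrelation",
    "Regulon",
    "variant_score_correlation",
    "classify_variants",
    "nearest_gene",
    "regulon_enrichment",
    "export_finemapping_priors",
]


@dataclass
class VariantScoreCorrelation:
    """Per-variant CPM-vs-score correlation across quantile bins."""

    variant_id: str
    cpm: np.ndarray            # per-bin CPM (NaN where the bin library is 0)
    bin_scores: np.ndarray     # per-bin mean cell score
    pearson_r: float
    n_bins_passing: int
    retained: bool


@dataclass(frozen=True)
class Regulon:
    """A transcription factor with its co-regulated target-gene set."""

    tf: str
    targets: frozenset

    def __post_init__(self):
        if not self.targets:
            raise ValueError(f"regulon {self.tf}: empty target set")


# ---------------------------------------------------------------------------
# variant accessibility vs score
# ---------------------------------------------------------------------------

def variant_score_correlation(
    counts,
    cell_scores: np.ndarray,
    cell_subset: np.ndarray,
    variants: Sequence[VariantRecord],
    window_bp: int = 500,
    n_bins: int = 5,
    cpm_min: float = 5.0,
    min_bins: int = 2,
    bin_summary: str = "mean",
) -> list[VariantScoreCorrelation]:
    """Correlate per-variant accessibility (CPM) with cell scores over bins.

    Cells in ``cell_subset`` are split into ``n_bins`` equal-count quantile
    bins by score (ties broken by barcode order).  Per variant, a bin's
    accessibility is the reads of regions overlapping the symmetric window
    [pos - window_bp/2, pos + window_bp/2) summed over the bin's cells, and
    CPM = accessibility / bin library size x 1e6 where the library size is
    all reads of the bin's cells.  Variants need CPM >= ``cpm_min`` in at
    least ``min_bins`` bins to be retained.
    """
    from .io_formats import CellRegionMatrix

    if isinstance(counts, CellRegionMatrix):
        X = counts.counts
        regions = counts.regions
    else:
        raise TypeError("counts must be a CellRegionMatrix")
    cell_subset = np.asarray(cell_subset)
    if cell_subset.dtype == bool:
        cell_subset = np.flatnonzero(cell_subset)
    scores = np.asarray(cell_scores, dtype=float)[cell_subset]
    n_sub = cell_subset.size
    if n_sub < n_bins:
        raise ValueError(f"{n_sub} cells fewer than {n_bins} bins")

    order = np.argsort(scores, kind="stable")  # stable: barcode-order ties
    bin_edges = np.linspace(0, n_sub, n_bins + 1).astype(int)
    bins = [cell_subset[order[bin_edges[b]:bin_edges[b + 1]]] for b in range(n_bins)]

    summary = np.mean if bin_summary == "mean" else np.median
    all_scores = np.asarray(cell_scores, dtype=float)
    bin_scores = np.array([summary(all_scores[b]) for b in bins])
    lib = np.array([X[b].sum() for b in bins], dtype=float)

    # region overlap per variant: regions sorted by start within chromosome
    chroms = np.array([r.chrom for r in regions])
    starts = np.array([r.start for r in regions])
    ends = np.array([r.end for r in regions])
    half = window_bp // 2

    # per-bin region read totals (n_bins x J)
    bin_region = np.vstack(
        [np.asarray(X[b].sum(axis=0)).ravel() for b in bins]
    )

    out = []
    for v in variants:
        wlo, whi = v.pos - 1 - half, v.pos - 1 + half  # 0-based window
        sel = (chroms == v.chrom) & (starts < whi) & (ends > wlo)
        if sel.any():
            acc = bin_region[:, sel].sum(axis=1)
        else:
            acc = np.zeros(n_bins)
        with np.errstate(invalid="ignore", divide="ignore"):
            cpm = np.where(lib > 0, acc / lib * 1e6, np.nan)
        valid = np.isfinite(cpm)
        n_pass = int((cpm[valid] >= cpm_min).sum())
        retained = n_pass >= min_bins
        r = np.nan
        if retained and valid.sum() >= 2 and np.nanstd(cpm[valid]) > 0 \
                and np.std(bin_scores[valid]) > 0:
            r = float(pearsonr(cpm[valid], bin_scores[valid])[0])
        out.append(
            VariantScoreCorrelation(
                variant_id=v.id, cpm=cpm, bin_scores=bin_scores,
                pearson_r=r, n_bins_passing=n_pass, retained=retained,
            )
        )
    return out


def classify_variants(
    pip: Mapping[str, float],
    correlations: Sequence[VariantScoreCorrelation],
    pip_min: float = 0.3,
    cor_min: float = 0.2,
) -> dict[str, str]:
    """Partition PIP-passing variants by correlation sign.

    Variants with PIP > ``pip_min`` get "positive"/"negative" when their
    retained correlation exceeds ``cor_min`` in magnitude, else "none";
    variants at or below the PIP threshold are omitted.
    """
    groups: dict[str, str] = {}
    by_id = {c.variant_id: c for c in correlations}
    for vid, p in pip.items():
        if not 0 <= p <= 1:
            raise ValueError(f"PIP {p} for {vid} outside [0, 1]")
        if p <= pip_min:
            continue
        c = by_id.get(vid)
        if c is None or not c.retained or not np.isfinite(c.pearson_r) \
                or abs(c.pearson_r) <= cor_min:
            groups[vid] = "none"
        else:
            groups[vid] = "positive" if c.pearson_r > 0 else "negative"
    return groups


# ---------------------------------------------------------------------------
# nearest gene
# ---------------------------------------------------------------------------

def nearest_gene(
    variants: Sequence[VariantRecord],
    gene_table: pd.DataFrame,
) -> dict[str, list[str]]:
    """Nearest gene(s) per variant by distance to the gene interval.

    ``gene_table`` needs columns (gene, chrom, start, end) with 0-based
    half-open intervals.  Distance is 0 inside the gene body; ties return
    every tied gene.  Variants on chromosomes without genes get no
    assignment (logged).
    """
    out: dict[str, list[str]] = {}
    by_chrom = {c: g for c, g in gene_table.groupby("chrom")}
    for v in variants:
        genes = by_chrom.get(v.chrom)
        if genes is None or len(genes) == 0:
            logger.info("nearest_gene: no genes on chromosome %s for %s", v.chrom, v.id)
            continue
        pos0 = v.pos - 1
        start = genes["start"].to_numpy()
        end = genes["end"].to_numpy()
        dist = np.where(
            (pos0 >= start) & (pos0 < end),
            0,
            np.minimum(np.abs(pos0 - start), np.abs(pos0 - (end - 1))),
        )
        best = dist.min()
        out[v.id] = list(genes["gene"].to_numpy()[dist == best])
    return out


# ---------------------------------------------------------------------------
# regulon enrichment
# ---------------------------------------------------------------------------

def regulon_enrichment(
    target_genes: set,
    regulons: Sequence[Regulon],
    background_genes: set,
    or_kind: str = "conditional",
) -> pd.DataFrame:
    """One-sided Fisher enrichment of the target genes in each regulon.

    Per regulon, the 2x2 table over the background is
    (in-target x in-regulon); p is the hypergeometric upper tail and the
    reported odds ratio is the conditional MLE (``or_kind="sample"`` gives
    the sample odds ratio instead).  BH across regulons.
    """
    targets = set(target_genes) & set(background_genes)
    if set(target_genes) - set(background_genes):
        raise ValueError("target_genes must be a subset of background_genes")
    bg = set(background_genes)
    rows = []
    for reg in regulons:
        rg = set(reg.targets) & bg
        a = len(targets & rg)
        b = len(rg - targets)
        c = len(targets - rg)
        d = len(bg) - a - b - c
        table = np.array([[a, b], [c, d]])
        if not targets:
            p = 1.0
            orv = np.nan
        else:
            p = float(fisher_exact(table, alternative="greater")[1])
            if or_kind == "conditional":
                orv = float(odds_ratio(table, kind="conditional").statistic)
            else:
                orv = float(odds_ratio(table, kind="sample").statistic)
        rows.append({"tf": reg.tf, "overlap": a, "regulon_size": len(rg),
                     "odds_ratio": orv, "p": p})
    df = pd.DataFrame(rows)
    if len(df):
        df["fdr"] = multipletests(df["p"], method="fdr_bh")[1]
    return df


# ---------------------------------------------------------------------------
# fine-mapping prior export
# ---------------------------------------------------------------------------

def export_finemapping_priors(
    enrichment: EnrichmentTable,
    annotations: np.ndarray,
    variants: Sequence[VariantRecord],
    path,
    p_max: float = 0.05,
) -> np.ndarray:
    """Write the annotation columns of significantly enriched topics
    (enrichment p < ``p_max``) as an .annot-style TSV for external
    fine-mapping tools.  Returns the selected topic indices."""
    p = np.asarray(enrichment.p, dtype=float)
    keep = np.flatnonzero(p < p_max)
    A = np.atleast_2d(np.asarray(annotations))
    if A.shape[0] != len(variants):
        A = A.T
    if keep.size == 0:
        warnings.warn("no topic with significant enrichment; empty prior export")
        write_annotation(np.zeros((len(variants), 0), dtype=int), variants, path)
        return keep
    write_annotation(A[:, keep], variants, path)
    return keep
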