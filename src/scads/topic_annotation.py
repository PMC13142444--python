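"""Per-topic open-chromatin calls and variant-level annotations.

For each topic the pipeline (i) soft-partitions reads into a topic
pseudobulk, (ii) estimates a GC-dependent background rate from the lower
component of a two-component count mixture fitted within GC bins,
(iii) tests each region's log2 fold change over that background with a MAP
estimate under a weak Gaussian prior and a Laplace-approximation standard
error, and (iv) calls regions open at BH FDR < 0.05 (per topic).  Open
regions are then projected onto variants to give the binary annotations
A_k consumed by stratified LD-score regression.  Everything outside the
peak set is treated as closed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.special import gammaln
from scipy.stats import norm
from statsmodels.stats.multitest import multipletests

from .io_formats import GenomicRegion, VariantRecord

__all__ = [
    "TopicAnnotation",
    "VariantAnnotation",
    "estimate_gc_baseline",
    "lfc_map_test",
    "call_open_regions",
    "build_variant_annotation",
    "annotation_qc",
    "annotate_topics",
]

#: weak Gaussian prior SD on the log2 fold change
LFC_PRIOR_SD = 2.0
#: pseudobulk depth below which the power warning fires (reads)
MIN_PSEUDOBULK_DEPTH = 1e7
#: topics annotating less than this fraction of variants are excluded
MIN_GENOME_FRACTION = 0.005


@dataclass
class TopicAnnotation:
    """Per-topic open/closed calls with the statistics behind them."""

    I: np.ndarray            # K x J binary
    baseline: np.ndarray     # K x J baseline rates f0 (strictly positive)
    lfc: np.ndarray          # K x J MAP log2 fold changes
    lfc_se: np.ndarray       # K x J standard errors
    pvals: np.ndarray        # K x J one-sided p-values
    pseudobulk_depth: np.ndarray = field(default_factory=lambda: np.empty(0))

    @property
    def K(self) -> int:
        return self.I.shape[0]


@dataclass
class VariantAnnotation:
    """Variant-level projection of the open-region calls."""

    A: np.ndarray                 # variants x K binary
    v: np.ndarray                 # per-region variant counts v_j
    genome_fraction: np.ndarray   # per-topic fraction of variants annotated

    @property
    def K(self) -> int:
        return self.A.shape[1]


# ---------------------------------------------------------------------------
# GC-aware baseline
# ---------------------------------------------------------------------------

def _poisson_mixture_lower_mean(y: np.ndarray, max_iter: int = 200, tol: float = 1e-8):
    """Mean of the lower component of a two-component Poisson mixture (EM).

    Counts may be non-integer (soft-assigned pseudobulk reads); the Poisson
    pmf is extended with the gamma function.  Falls back to the sample mean
    when the mixture is degenerate.
    """
    y = np.asarray(y, dtype=float)
    if y.size < 4 or np.allclose(y, y[0]):
        return float(max(y.mean(), 1e-8)), False
    mu0 = max(float(np.quantile(y, 0.25)), 1e-6)
    mu1 = max(float(np.quantile(y, 0.95)), mu0 * 2 + 1e-6)
    w = 0.7
    ll_prev = -np.inf
    for _ in range(max_iter):
        # log Poisson densities (continuous extension)
        l0 = y * np.log(mu0) - mu0 - gammaln(y + 1.0)
        l1 = y * np.log(mu1) - mu1 - gammaln(y + 1.0)
        a = np.log(w) + l0
        b = np.log1p(-w) + l1
        m = np.maximum(a, b)
        lse = m + np.log(np.exp(a - m) + np.exp(b - m))
        resp0 = np.exp(a - lse)
        w = float(np.clip(resp0.mean(), 1e-6, 1 - 1e-6))
        s0 = resp0.sum()
        s1 = y.size - s0
        mu0 = max(float((resp0 * y).sum() / max(s0, 1e-12)), 1e-8)
        mu1 = max(float(((1 - resp0) * y).sum() / max(s1, 1e-12)), mu0 + 1e-8)
        ll = float(lse.sum())
        if abs(ll - ll_prev) <= tol * (abs(ll_prev) + 1.0):
            break
        ll_prev = ll
    return min(mu0, mu1), True


def estimate_gc_baseline(
    pseudobulk_row: np.ndarray,
    gc: np.ndarray,
    topic_total_reads: float,
    n_bins: int = 10,
    smooth_window: int = 3,
) -> np.ndarray:
    """GC-dependent background *rate* for one topic.

    Regions are binned by GC decile; a two-component count mixture is fitted
    per bin and the lower component's mean taken as the bin's background
    count, smoothed across adjacent GC bins by local averaging, and finally
    normalized by ``topic_total_reads`` so the result is comparable to the
    topic's region distribution f_kj.
    """
    y = np.asarray(pseudobulk_row, dtype=float)
    gc = np.asarray(gc, dtype=float)
    if topic_total_reads <= 0:
        raise ValueError("topic_total_reads must be positive")
    if y.shape != gc.shape:
        raise ValueError("pseudobulk and gc length mismatch")

    uniq = np.unique(gc[np.isfinite(gc)])
    if uniq.size <= 1:
        mu, ok = _poisson_mixture_lower_mean(y)
        if not ok:
            warnings.warn("degenerate counts with uniform GC: flat baseline")
        return np.full_like(y, max(mu, 1e-8) / topic_total_reads)

    edges = np.quantile(gc, np.linspace(0, 1, n_bins + 1))
    edges = np.unique(edges)
    bin_idx = np.clip(np.searchsorted(edges, gc, side="right") - 1, 0, len(edges) - 2)
    n_eff = len(edges) - 1
    mus = np.empty(n_eff)
    for b in range(n_eff):
        sel = bin_idx == b
        if sel.sum() == 0:
            mus[b] = np.nan
            continue
        mus[b], _ = _poisson_mixture_lower_mean(y[sel])
    # fill empty bins from neighbors, then smooth by local averaging
    if np.isnan(mus).any():
        idx = np.arange(n_eff)
        good = ~np.isnan(mus)
        mus = np.interp(idx, idx[good], mus[good])
    if smooth_window > 1 and n_eff > 1:
        half = smooth_window // 2
        padded = np.pad(mus, half, mode="edge")
        kernel = np.ones(2 * half + 1) / (2 * half + 1)
        mus = np.convolve(padded, kernel, mode="valid")
    baseline_counts = np.maximum(mus[bin_idx], 1e-8)
    return baseline_counts / topic_total_reads


# ---------------------------------------------------------------------------
# LFC MAP test
# ---------------------------------------------------------------------------

def estimate_lfc_overdispersion(
    pseudobulk: np.ndarray,
    mu0: np.ndarray,
) -> float:
    """Extra log2-scale variance of background regions beyond Poisson.

    Background (closed) regions center at log2 fold change 0 by the
    definition of the baseline.  Their spread is estimated robustly from
    the left half of the LFC distribution (lfc <= 0, immune to the open
    regions' right tail and to how large the open fraction is), scaled as
    a half-normal MAD; the expected Poisson contribution 1/(mu0 ln(2)^2)
    (delta method) is subtracted and the excess floored at zero.  When
    counts really are Poisson around the baseline the estimate is ~0 and
    the calibrated test reduces to the plain Poisson test.
    """
    y = np.asarray(pseudobulk, dtype=float).ravel()
    mu0 = np.asarray(mu0, dtype=float).ravel()
    lfc0 = np.log2((y + 0.5) / mu0)
    left = lfc0[lfc0 <= 0]
    if left.size < 10:
        return 0.0
    mad = np.median(-left)
    s2 = (1.4826 * mad) ** 2
    pois = float(np.median(1.0 / (np.maximum(mu0, 0.5) * np.log(2.0) ** 2)))
    return max(s2 - pois, 0.0)


def lfc_map_test(
    pseudobulk: np.ndarray,
    baseline: np.ndarray,
    topic_total_reads: np.ndarray | float | None = None,
    prior_sd: float = LFC_PRIOR_SD,
    extra_log2_var: np.ndarray | float = 0.0,
    max_iter: int = 50,
):
    """MAP log2 fold change over the baseline, with Laplace SE, z and p.

    Model per region: y ~ Poisson(mu0 * 2^b) with mu0 the baseline
    *expected count* and prior b ~ N(0, prior_sd^2) on the log2 scale.
    When ``topic_total_reads`` is given, ``baseline`` is interpreted as a
    rate and the expected count is baseline * topic_total_reads; otherwise
    ``baseline`` is used directly as the expected count.

    ``extra_log2_var`` adds region-to-region background dispersion (per
    topic) to the squared SE used for the z statistic, so the test stays
    calibrated when background rates vary beyond Poisson sampling (see
    :func:`estimate_lfc_overdispersion`).

    Returns (lfc, lfc_se, z, pvals); the p-value is one-sided (open
    direction, b > 0).
    """
    y = np.atleast_2d(np.asarray(pseudobulk, dtype=float))
    f0 = np.atleast_2d(np.asarray(baseline, dtype=float))
    if (f0 <= 0).any():
        raise ValueError("baseline must be strictly positive")
    if topic_total_reads is not None:
        T = np.atleast_1d(np.asarray(topic_total_reads, dtype=float)).reshape(-1, 1)
        mu0 = f0 * T
    else:
        mu0 = f0

    ln2 = np.log(2.0)
    tau2 = prior_sd ** 2
    # Newton iterations on b; objective l(b) = y*b*ln2 - mu0*2^b - b^2/(2 tau2)
    with np.errstate(divide="ignore"):
        b = np.log2(np.maximum(y, 0.5) / mu0)
    b = np.clip(b, -5 * prior_sd, 5 * prior_sd)
    for _ in range(max_iter):
        mu = mu0 * np.exp2(b)
        grad = (y - mu) * ln2 - b / tau2
        hess = -mu * ln2 ** 2 - 1.0 / tau2
        step = grad / hess
        b = b - np.clip(step, -4.0, 4.0)
        if np.max(np.abs(step)) < 1e-10:
            break
    mu = mu0 * np.exp2(b)
    se = 1.0 / np.sqrt(mu * ln2 ** 2 + 1.0 / tau2)
    extra = np.asarray(extra_log2_var, dtype=float)
    if extra.ndim == 1:
        extra = extra.reshape(-1, 1)
    se_test = np.sqrt(se ** 2 + extra)
    z = b / se_test
    p = norm.sf(z)
    squeeze = np.asarray(pseudobulk).ndim == 1
    if squeeze:
        return b[0], se_test[0], z[0], p[0]
    return b, se_test, z, p


def call_open_regions(pvals: np.ndarray, fdr: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg open-region calls, applied within each topic row."""
    p = np.atleast_2d(np.asarray(pvals, dtype=float))
    out = np.zeros_like(p, dtype=np.int8)
    for k in range(p.shape[0]):
        if p.shape[1] == 0:
            continue
        out[k] = multipletests(p[k], alpha=fdr, method="fdr_bh")[0]
    if np.asarray(pvals).ndim == 1:
        return out[0]
    return out


# ---------------------------------------------------------------------------
# variant projection
# ---------------------------------------------------------------------------

def _merge_intervals(starts, ends):
    order = np.argsort(starts, kind="stable")
    ms, me = [], []
    for s, e in zip(starts[order], ends[order]):
        if ms and s <= me[-1]:
            me[-1] = max(me[-1], e)
        else:
            ms.append(s)
            me.append(e)
    return np.asarray(ms), np.asarray(me)


def build_variant_annotation(
    I: np.ndarray,
    regions: Sequence[GenomicRegion],
    variants: Sequence[VariantRecord],
) -> VariantAnnotation:
    """Project per-topic open-region calls onto variants.

    ``A[p, k] = 1`` iff ``pos_p - 1`` lies in some open region of topic k
    (overlapping open regions are merged per topic first).  ``v[j]`` counts
    variants in region j on the original (unmerged) peak set, used as the
    weights in the cell-score formula.
    """
    I = np.atleast_2d(np.asarray(I))
    K, J = I.shape
    if J != len(regions):
        raise ValueError("I columns must match region count")
    P = len(variants)

    chroms = np.array([r.chrom for r in regions])
    starts = np.array([r.start for r in regions])
    ends = np.array([r.end for r in regions])
    vchrom = np.array([v.chrom for v in variants])
    vpos0 = np.array([v.pos - 1 for v in variants])  # 0-based

    A = np.zeros((P, K), dtype=np.int8)
    v = np.zeros(J, dtype=np.int64)

    for chrom in np.unique(chroms):
        rsel = np.flatnonzero(chroms == chrom)
        vsel = np.flatnonzero(vchrom == chrom)
        if vsel.size == 0:
            continue
        pos = vpos0[vsel]
        # per-region variant counts on the unmerged peak set
        order = np.argsort(pos, kind="stable")
        spos = pos[order]
        for j in rsel:
            lo = np.searchsorted(spos, starts[j], side="left")
            hi = np.searchsorted(spos, ends[j] - 1, side="right")
            v[j] = hi - lo
        # per-topic membership on the merged open set
        for k in range(K):
            open_j = rsel[I[k, rsel] == 1]
            if open_j.size == 0:
                continue
            ms, me = _merge_intervals(starts[open_j], ends[open_j])
            iv = np.searchsorted(ms, pos, side="right") - 1
            inside = (iv >= 0) & (pos < me[np.clip(iv, 0, len(me) - 1)])
            A[vsel[inside], k] = 1

    genome_fraction = A.mean(axis=0) if P else np.zeros(K)
    return VariantAnnotation(A=A, v=v, genome_fraction=np.asarray(genome_fraction, dtype=float))


# ---------------------------------------------------------------------------
# QC
# ---------------------------------------------------------------------------

def annotation_qc(
    annotation: VariantAnnotation,
    pseudobulk_depth: np.ndarray,
    min_depth: float = MIN_PSEUDOBULK_DEPTH,
    min_fraction: float = MIN_GENOME_FRACTION,
) -> dict:
    """Flag underpowered topics (depth < 10M reads) and tiny annotations
    (< 0.5% of variants; excluded from the cell score)."""
    depth = np.asarray(pseudobulk_depth, dtype=float)
    frac = np.asarray(annotation.genome_fraction, dtype=float)
    return {
        "pseudobulk_depth": depth.tolist(),
        "genome_fraction": frac.tolist(),
        "power_warning": (depth < min_depth).tolist(),
        "excluded": (frac < min_fraction).tolist(),
    }


# ---------------------------------------------------------------------------
# convenience driver used by the pipeline
# ---------------------------------------------------------------------------

def annotate_topics(
    pseudobulk: np.ndarray,
    gc: np.ndarray,
    variants: Sequence[VariantRecord],
    regions: Sequence[GenomicRegion],
    fdr: float = 0.05,
) -> tuple[TopicAnnotation, VariantAnnotation]:
    """Run baseline estimation, the LFC test and variant projection for all
    topics of a pseudobulk matrix (K x regions)."""
    Y = np.atleast_2d(np.asarray(pseudobulk, dtype=float))
    K, J = Y.shape
    depths = Y.sum(axis=1)
    baseline = np.empty_like(Y)
    extra = np.empty(K)
    for k in range(K):
        baseline[k] = estimate_gc_baseline(Y[k], gc, depths[k])
        extra[k] = estimate_lfc_overdispersion(Y[k], baseline[k] * depths[k])
    lfc, se, z, p = lfc_map_test(
        Y, baseline, topic_total_reads=depths, extra_log2_var=extra
    )
    I = call_open_regions(p, fdr=fdr)
    topic_ann = TopicAnnotation(
        I=I, baseline=baseline, lfc=lfc, lfc_se=se, pvals=p, pseudobulk_depth=depths
    )
    var_ann = build_variant_annotation(I, regions, variants)
    return topic_ann, var_ann
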