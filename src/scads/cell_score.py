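"""Per-cell disease-relevance scores reconstructed from topic-level results.

The score of cell i is the expected heritability enrichment of the variants
in its open chromatin,

    c_hat_i = sum_k l_ik s_k e_k / sum_k l_ik s_k,

a convex combination of the topic enrichments e_k with weights l_ik s_k,
where s_k is the variant-weighted open size of topic k.  Its variance is
the quadratic form of the same weights with Cov(e_k, e_m); z, one-sided p
and BH-FDR follow.  Topics annotating < 0.5% of variants are excluded from
both sums.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.stats import norm
from statsmodels.stats.multitest import multipletests

from .topic_annotation import VariantAnnotation

__all__ = [
    "topic_sizes",
    "compute_cell_scores",
    "cell_score_variance",
    "cell_score_tests",
    "true_cell_enrichment",
    "build_cell_score_table",
]


def topic_sizes(
    annotation: VariantAnnotation | None = None,
    I: np.ndarray | None = None,
    v: np.ndarray | None = None,
    variant_weighted: bool = True,
) -> np.ndarray:
    """Open size s_k of each topic.

    By default the variant-weighted sum s_k = sum_j I_kj v_j (the form the
    score's denominator requires); ``variant_weighted=False`` gives the
    unweighted region count sum_j I_kj.
    """
    if annotation is not None:
        # VariantAnnotation stores A (variants x K) built from merged open
        # regions; the column sums equal sum_j I_kj v_j up to merged overlaps.
        if not variant_weighted:
            raise ValueError("pass I explicitly for the unweighted variant")
        return annotation.A.sum(axis=0).astype(float)
    I = np.atleast_2d(np.asarray(I))
    if variant_weighted:
        v = np.asarray(v, dtype=float)
        return I @ v
    return I.sum(axis=1).astype(float)


def _score_weights(L: np.ndarray, s: np.ndarray, excluded: np.ndarray | None):
    L = np.atleast_2d(np.asarray(L, dtype=float))
    s = np.asarray(s, dtype=float)
    if excluded is None:
        excluded = np.zeros(s.size, dtype=bool)
    excluded = np.asarray(excluded, dtype=bool)
    inc = ~excluded
    W = L[:, inc] * s[inc][None, :]
    return W, inc


def compute_cell_scores(
    L: np.ndarray,
    s: np.ndarray,
    e: np.ndarray,
    excluded: np.ndarray | None = None,
) -> np.ndarray:
    """c_hat_i = sum_k l_ik s_k e_k / sum_k l_ik s_k over included topics.

    Cells with zero total weight (or NaN loadings from dropped cells) get
    NaN scores and are flagged by the caller.
    """
    W, inc = _score_weights(L, s, excluded)
    e = np.asarray(e, dtype=float)[inc]
    denom = W.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        scores = (W @ e) / denom
    bad = ~np.isfinite(scores)
    if bad.any():
        warnings.warn(f"{int(bad.sum())} cell(s) with zero topic weight: score undefined")
        scores = np.where(np.isfinite(scores), scores, np.nan)
    return scores


def cell_score_variance(
    L: np.ndarray,
    s: np.ndarray,
    cov_e: np.ndarray,
    excluded: np.ndarray | None = None,
    full_double_sum: bool = True,
) -> np.ndarray:
    """Var(c_hat_i) = sum_{k,m} (l_ik s_k)(l_im s_m) Cov(e_k, e_m) / S_i^2.

    ``full_double_sum=False`` restores the literal half-sum over m <= k
    (off-diagonal terms counted once) for comparison.
    """
    W, inc = _score_weights(L, s, excluded)
    C = np.asarray(cov_e, dtype=float)[np.ix_(inc, inc)]
    if not full_double_sum:
        C = np.tril(C)
    S = W.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        var = np.einsum("ik,km,im->i", W, C, W) / (S * S)
    return np.where(np.isfinite(var), var, np.nan)


def cell_score_tests(
    scores: np.ndarray,
    variances: np.ndarray,
    fdr: float = 0.05,
) -> pd.DataFrame:
    """One-sided z-test of enrichment > 1 per cell, BH-corrected.

    z_i = (c_hat_i - 1)/sqrt(Var_i); p_i = upper-tail normal probability;
    BH across all scored cells.  Cells with NaN scores are left untested.
    """
    scores = np.asarray(scores, dtype=float)
    variances = np.asarray(variances, dtype=float)
    z = np.full_like(scores, np.nan)
    p = np.full_like(scores, np.nan)
    ok = np.isfinite(scores) & np.isfinite(variances)
    pos = ok & (variances > 0)
    z[pos] = (scores[pos] - 1.0) / np.sqrt(variances[pos])
    p[pos] = norm.sf(z[pos])
    zero = ok & (variances == 0)
    if zero.any():
        exact_null = np.isclose(scores[zero], 1.0)
        z[zero] = np.where(exact_null, 0.0, np.inf * np.sign(scores[zero] - 1.0))
        p[zero] = np.where(exact_null, 0.5, (scores[zero] < 1.0).astype(float))
        if (~exact_null).any():
            warnings.warn("zero variance with score != 1: p set to 0/1")
    q = np.full_like(scores, np.nan)
    tested = np.isfinite(p)
    if tested.any():
        q[tested] = multipletests(p[tested], alpha=fdr, method="fdr_bh")[1]
    return pd.DataFrame(
        {"score": scores, "variance": variances, "z": z, "p": p, "fdr": q,
         "significant": (q <= fdr) & tested}
    )


def true_cell_enrichment(
    L: np.ndarray,
    I_true: np.ndarray,
    v: np.ndarray,
    e_true: np.ndarray,
) -> np.ndarray:
    """Ground-truth per-cell enrichment from the simulation truth.

    Same functional form as the score, with the true open masks, variant
    counts and topic enrichments (no exclusion)."""
    s = topic_sizes(I=I_true, v=v)
    return compute_cell_scores(L, s, e_true, excluded=None)


def build_cell_score_table(
    barcodes,
    L: np.ndarray,
    s: np.ndarray,
    e_post: np.ndarray,
    cov_e: np.ndarray,
    excluded: np.ndarray | None = None,
    fdr: float = 0.05,
) -> pd.DataFrame:
    """Assemble the full per-cell table (barcode, score, variance, z, p, fdr)."""
    scores = compute_cell_scores(L, s, e_post, excluded)
    var = cell_score_variance(L, s, cov_e, excluded)
    tab = cell_score_tests(scores, var, fdr=fdr)
    tab.insert(0, "barcode", list(barcodes))
    inc = ~np.asarray(
        excluded if excluded is not None else np.zeros(len(s), dtype=bool), dtype=bool
    )
    tab["n_topics_used"] = int(inc.sum())
    return tab
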