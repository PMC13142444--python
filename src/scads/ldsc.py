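"""Self-contained stratified LD-score regression.

Three pieces feed the cell score:

* annotation LD scores  l_{A_k,p} = sum_q A_k(q) r~^2_{pq}  from a reference
  genotype panel, with the standard small-sample bias adjustment
  r~^2 = r^2 - (1 - r^2)/(n - 2);
* per-topic heritability enrichment e_hat_k with a leave-one-block-out
  jackknife standard error w_k, from the weighted regression of chi^2 on
  [1, N*l_total, N*l_{A_k}] (one topic at a time, free intercept);
* the covariance approximation Cov(e_k, e_m) = w_k w_m Cor(A_k, A_m) and an
  adaptive-shrinkage (uniform-mixture empirical Bayes) posterior mean of the
  enrichments.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

__all__ = [
    "LdScoreSet",
    "EnrichmentTable",
    "SldscResult",
    "compute_ld_scores",
    "sldsc_fit",
    "enrichment_covariance",
    "shrink_enrichments",
]


@dataclass
class LdScoreSet:
    """Per-variant LD scores for each annotation plus the all-variant total."""

    annot: np.ndarray        # P x K
    total: np.ndarray        # P
    window_bp: int
    adjusted: bool = True

    @property
    def n_variants(self) -> int:
        return self.total.shape[0]


@dataclass
class SldscResult:
    """One topic's stratified regression output."""

    tau0: float
    tau_k: float
    e_hat: float
    se: float
    p: float
    M: int
    M_k: int
    intercept: float = np.nan


@dataclass
class EnrichmentTable:
    """Per-topic enrichment estimates, uncertainties and shrunken means."""

    tau: np.ndarray
    e_hat: np.ndarray
    se: np.ndarray
    p: np.ndarray
    e_post: np.ndarray
    genome_fraction: np.ndarray
    excluded: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=bool))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "topic": np.arange(len(self.e_hat)),
                "tau": self.tau,
                "e_hat": self.e_hat,
                "se": self.se,
                "p": self.p,
                "e_post": self.e_post,
                "genome_fraction": self.genome_fraction,
                "excluded": self.excluded,
            }
        )


# ---------------------------------------------------------------------------
# LD scores
# ---------------------------------------------------------------------------

def compute_ld_scores(
    genotypes: np.ndarray,
    annotations: np.ndarray,
    positions: np.ndarray | None = None,
    window_bp: int = 1_000_000,
    adjust: bool = True,
    chunk: int = 512,
) -> LdScoreSet:
    """Annotation LD scores from a reference dosage panel.

    Parameters
    ----------
    genotypes
        individuals x variants dosage matrix.
    annotations
        variants x K binary annotation matrix.
    positions
        physical positions (monotone within the panel); pairs farther apart
        than ``window_bp`` contribute nothing.  ``None`` means no windowing.
    adjust
        apply the bias adjustment r^2 - (1 - r^2)/(n - 2); requires n >= 3.

    Monomorphic variants get r^2 = 0 against all others (and against
    themselves), hence zero LD-score contributions.
    """
    G = np.asarray(genotypes, dtype=np.float64)
    n, P = G.shape
    if n < 2:
        raise ValueError("need at least 2 individuals")
    if adjust and n < 3:
        raise ValueError("bias adjustment requires at least 3 individuals")
    A = np.atleast_2d(np.asarray(annotations))
    if A.shape[0] != P:
        A = A.T
    if A.shape[0] != P:
        raise ValueError("annotation rows must match variant count")
    K = A.shape[1]

    mu = G.mean(axis=0)
    sd = G.std(axis=0)
    poly = sd > 0
    Z = np.zeros_like(G)
    Z[:, poly] = (G[:, poly] - mu[poly]) / sd[poly]

    if positions is None:
        # no windowing: treat all pairs as in range
        positions = np.zeros(P, dtype=np.int64)
    positions = np.asarray(positions)

    lA = np.zeros((P, K))
    lT = np.zeros(P)
    Af = A.astype(np.float64)
    ones = np.ones(P)
    for lo in range(0, P, chunk):
        hi = min(lo + chunk, P)
        w_lo = int(np.searchsorted(positions, positions[lo] - window_bp, side="left"))
        w_hi = int(np.searchsorted(positions, positions[hi - 1] + window_bp, side="right"))
        R = (Z[:, lo:hi].T @ Z[:, w_lo:w_hi]) / n      # chunk x window correlations
        r2 = R * R
        if adjust:
            r2 = r2 - (1.0 - r2) / (n - 2)
        # zero out monomorphic pairs and pairs outside the bp window
        pmask = poly[w_lo:w_hi][None, :] & poly[lo:hi][:, None]
        inwin = (
            np.abs(positions[w_lo:w_hi][None, :] - positions[lo:hi][:, None])
            <= window_bp
        )
        r2 = np.where(pmask & inwin, r2, 0.0)
        lA[lo:hi] = r2 @ Af[w_lo:w_hi]
        lT[lo:hi] = r2 @ ones[w_lo:w_hi]
    return LdScoreSet(annot=lA, total=lT, window_bp=int(window_bp), adjusted=adjust)


# ---------------------------------------------------------------------------
# stratified regression
# ---------------------------------------------------------------------------

def _jackknife(full: float, deleted: np.ndarray) -> float:
    """Delete-one-block jackknife SE."""
    nb = deleted.size
    mean = deleted.mean()
    var = (nb - 1) / nb * np.sum((deleted - mean) ** 2)
    return float(np.sqrt(var))


def sldsc_fit(
    chi2: np.ndarray,
    N: np.ndarray | float,
    ld_total: np.ndarray,
    ld_annot: np.ndarray,
    M: int,
    M_k: int,
    n_blocks: int = 200,
    intercept_free: bool = False,
    chisq_max: float | None = None,
) -> SldscResult:
    """Stratified LD-score regression for a single annotation.

    Regresses chi^2_p on [1, N*l_total,p, N*l_{A_k},p] by weighted least
    squares (weights 1/max(l_total, 1)), and reports the heritability
    enrichment of the annotation,

        e_hat = (h^2(A_k)/M_k) / (h^2_total/M),

    with a leave-one-block-out jackknife SE and a p-value from the jackknife
    z-test of (proportion of h^2) - (proportion of variants).

    By default the intercept is constrained to 1 (no confounding), which is
    what identifies the genome-wide coefficient tau_0 on reference panels
    whose LD scores vary little; ``intercept_free=True`` restores the
    unconstrained regression.

    ``chisq_max`` optionally excludes variants with huge test statistics
    from the regression (the convention of LD-score software on
    biobank-scale data, e.g. max(80, 0.001 N)); with sparse causal
    architectures on small panels those variants carry most of the
    enrichment signal, so the default keeps every variant.
    """
    chi2 = np.asarray(chi2, dtype=float)
    if M_k == 0:
        raise ValueError("annotation contains no variants (M_k = 0)")
    Nv = np.broadcast_to(np.asarray(N, dtype=float), chi2.shape)
    if isinstance(chisq_max, str):  # "default": the LDSC-software rule
        chisq_max = max(80.0, 0.001 * float(np.median(Nv)))
    if chisq_max is not None:
        keep = chi2 <= chisq_max
        chi2 = chi2[keep]
        Nv = Nv[keep]
        ld_total = np.asarray(ld_total, dtype=float)[keep]
        ld_annot = np.asarray(ld_annot, dtype=float)[keep]
    P = chi2.size
    lT = np.asarray(ld_total, dtype=float)
    lA = np.asarray(ld_annot, dtype=float)
    if intercept_free:
        X = np.column_stack([np.ones(P), Nv * lT, Nv * lA])
        y = chi2
    else:
        X = np.column_stack([Nv * lT, Nv * lA])
        y = chi2 - 1.0
    w = 1.0 / np.maximum(lT, 1.0)

    n_blocks = int(min(n_blocks, max(P // 10, 2)))
    edges = np.linspace(0, P, n_blocks + 1).astype(int)

    Xw = X * w[:, None]
    XtWX_full = X.T @ Xw
    XtWy_full = Xw.T @ y
    if np.linalg.matrix_rank(XtWX_full) < X.shape[1]:
        raise ValueError("rank-deficient design (constant LD-score column?)")

    def _estimates(theta):
        tau0, tauk = (theta[1], theta[2]) if intercept_free else (theta[0], theta[1])
        h2_tot = M * tau0 + M_k * tauk
        h2_in = M_k * (tau0 + tauk)
        prop_h2 = h2_in / h2_tot if h2_tot != 0 else np.nan
        e = prop_h2 / (M_k / M)
        return e, prop_h2, tau0, tauk

    theta_full = np.linalg.solve(XtWX_full, XtWy_full)
    e_full, prop_full, tau0, tauk = _estimates(theta_full)

    e_del = np.empty(n_blocks)
    d_del = np.empty(n_blocks)
    prop_var = M_k / M
    for b in range(n_blocks):
        lo, hi = edges[b], edges[b + 1]
        Xb = X[lo:hi]
        Xbw = Xw[lo:hi]
        A_b = XtWX_full - Xb.T @ Xbw
        c_b = XtWy_full - Xbw.T @ y[lo:hi]
        theta_b = np.linalg.solve(A_b, c_b)
        e_b, prop_b, _, _ = _estimates(theta_b)
        e_del[b] = e_b
        d_del[b] = prop_b - prop_var

    se = _jackknife(e_full, e_del)
    se_d = _jackknife(prop_full - prop_var, d_del)
    if se_d > 0:
        zstat = (prop_full - prop_var) / se_d
        p = 2.0 * norm.sf(abs(zstat))
    else:
        p = 1.0 if np.isclose(prop_full, prop_var) else 0.0
    return SldscResult(
        tau0=float(tau0),
        tau_k=float(tauk),
        e_hat=float(e_full),
        se=float(se),
        p=float(p),
        M=int(M),
        M_k=int(M_k),
        intercept=float(theta_full[0]) if intercept_free else 1.0,
    )


# ---------------------------------------------------------------------------
# covariance approximation and shrinkage
# ---------------------------------------------------------------------------

def enrichment_covariance(w: np.ndarray, annotations: np.ndarray) -> np.ndarray:
    """Cov(e_k, e_m) = w_k w_m Cor(A_k, A_m) across variants.

    The LD-score correlation is approximated by the annotation correlation;
    constant annotations get zero off-diagonal correlation (with a warning).
    The diagonal is exactly w_k^2.
    """
    w = np.asarray(w, dtype=float)
    A = np.atleast_2d(np.asarray(annotations, dtype=float))
    if A.shape[1] != w.size:
        A = A.T
    if A.shape[1] != w.size:
        raise ValueError("annotation columns must match number of topics")
    K = w.size
    sd = A.std(axis=0)
    const = sd == 0
    if const.any():
        warnings.warn(
            "constant annotation(s): off-diagonal correlation set to 0"
        )
    corr = np.eye(K)
    ok = ~const
    if ok.sum() >= 2:
        sub = np.corrcoef(A[:, ok], rowvar=False)
        corr[np.ix_(ok, ok)] = sub
    np.fill_diagonal(corr, 1.0)
    return np.outer(w, w) * corr


def _uniform_mixture_grid(delta_hat: np.ndarray, w: np.ndarray) -> np.ndarray:
    wmin = max(float(np.min(w[w > 0], initial=np.inf)), 1e-6) / 10.0
    dmax = max(2.0 * float(np.max(np.abs(delta_hat), initial=0.0)), wmin * 2)
    grid = [wmin]
    while grid[-1] < dmax:
        grid.append(grid[-1] * np.sqrt(2.0))
    return np.asarray(grid)


def shrink_enrichments(
    e_hat: np.ndarray,
    w: np.ndarray,
    null_weight: float = 1.0,
    max_iter: int = 2000,
    tol: float = 1e-10,
    return_mixture: bool = False,
):
    """Adaptive-shrinkage posterior means of the enrichments.

    Effects delta_k = e_hat_k - 1 are modeled as a mixture of a point mass
    at 0 and symmetric uniforms U(-a_m, a_m) over a geometric grid of
    half-widths; observations delta_hat_k ~ N(delta_k, w_k^2).  Mixture
    weights are fitted by maximum-likelihood EM across topics and the
    returned value is 1 + E[delta_k | delta_hat_k].  ``null_weight`` > 1
    adds prior counts on the point mass (the convention of large-scale
    adaptive shrinkage); with only K topic-level observations the default
    is the unpenalized MLE.  Topics with w_k ~ 0 are returned as-is.
    """
    e_hat = np.atleast_1d(np.asarray(e_hat, dtype=float))
    w = np.atleast_1d(np.asarray(w, dtype=float))
    if (w < 0).any():
        raise ValueError("standard errors must be nonnegative")
    delta = e_hat - 1.0
    tiny = w <= 1e-12
    if tiny.all():
        return e_hat.copy()

    d = delta[~tiny]
    s = w[~tiny]
    grid = _uniform_mixture_grid(d, s)
    Mn = grid.size + 1  # component 0 = point mass

    # component likelihood matrix  (topics x components)
    lik = np.empty((d.size, Mn))
    lik[:, 0] = norm.pdf(d, loc=0.0, scale=s)
    post_mean_comp = np.zeros((d.size, Mn))
    for m, a in enumerate(grid, start=1):
        upper = (d + a) / s
        lower = (d - a) / s
        Phi = norm.cdf(upper) - norm.cdf(lower)
        lik[:, m] = Phi / (2.0 * a)
        # mean of N(d, s^2) truncated to [-a, a]
        alpha = (-a - d) / s
        beta = (a - d) / s
        num = norm.pdf(alpha) - norm.pdf(beta)
        with np.errstate(invalid="ignore", divide="ignore"):
            tm = d + s * num / np.maximum(Phi, 1e-300)
        # degenerate truncation: fall back to nearest edge
        tm = np.where(Phi > 1e-300, tm, np.clip(d, -a, a))
        post_mean_comp[:, m] = tm
    lik = np.maximum(lik, 1e-300)

    pi = np.full(Mn, 1.0 / Mn)
    prior_counts = np.ones(Mn)
    prior_counts[0] = max(null_weight, 1.0)
    ll_prev = -np.inf
    for _ in range(max_iter):
        joint = lik * pi[None, :]
        tot = joint.sum(axis=1, keepdims=True)
        resp = joint / tot
        counts = resp.sum(axis=0) + prior_counts - 1.0
        counts = np.maximum(counts, 0.0)
        pi = counts / counts.sum()
        ll = float(np.log(tot).sum())
        if abs(ll - ll_prev) < tol * (abs(ll_prev) + 1.0):
            break
        ll_prev = ll

    joint = lik * pi[None, :]
    resp = joint / joint.sum(axis=1, keepdims=True)
    d_post = (resp * post_mean_comp).sum(axis=1)

    out = e_hat.copy()
    out[~tiny] = 1.0 + d_post
    if return_mixture:
        return out, pi, grid
    return out
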