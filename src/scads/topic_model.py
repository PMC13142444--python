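"""Grade-of-membership (topic) model for scATAC-seq counts via Poisson NMF.

The count model is multinomial per cell,

    x_i1..x_iJ ~ Multinomial(s_i; pi_i1..pi_iJ),   pi_ij = sum_k f_kj l_ik,

with cell loadings l_ik (rows of L sum to 1) and per-topic region
distributions f_kj (rows of F sum to 1).  Fitting goes through the
equivalent Poisson NMF  x_ij ~ Poisson(sum_k L'_ik F'_kj)  maximized by
EM/multiplicative updates, whose fixed points coincide with the multinomial
MLE after reparameterization.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .io_formats import CellRegionMatrix

try:
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is a hard dependency in practice
    _HAVE_NUMBA = False

    def njit(*a, **k):
        def deco(f):
            return f

        return deco if not (len(a) == 1 and callable(a[0])) else a[0]


__all__ = [
    "TopicFit",
    "PoissonNmfFit",
    "fit_topics",
    "poisson_to_multinomial",
    "loglik",
    "pseudobulk_counts",
]


@dataclass
class PoissonNmfFit:
    """Nonnegative Poisson factors: L_prime (cells x K), F_prime (K x regions)."""

    L_prime: np.ndarray
    F_prime: np.ndarray

    def __post_init__(self):
        if (self.L_prime < 0).any() or (self.F_prime < 0).any():
            raise ValueError("Poisson NMF factors must be nonnegative")


@dataclass
class TopicFit:
    """Multinomial topic-model parameters.

    Rows of ``L`` (cells x K) and of ``F`` (K x regions) sum to one.  Cells
    dropped before fitting (zero depth) carry NaN loadings.
    """

    L: np.ndarray
    F: np.ndarray
    K: int
    loglik_trace: np.ndarray = field(default_factory=lambda: np.empty(0))
    converged: bool = True

    def __post_init__(self):
        self.L = np.asarray(self.L, dtype=float)
        self.F = np.asarray(self.F, dtype=float)
        if self.L.shape[1] != self.K or self.F.shape[0] != self.K:
            raise ValueError("inconsistent K")


# ---------------------------------------------------------------------------
# EM kernels (operate on the CSR structure of the count matrix)
# ---------------------------------------------------------------------------

@njit(cache=False)
def _em_half_updates(indptr, indices, data, L, F, Fsum, Lsum):
    """One full EM iteration: update L (with old F), then F (with new L).

    Returns sum_nz x*log(lambda) evaluated at the post-update parameters'
    *pre-F-update* lambda for the L pass and accumulates the F numerators;
    the Poisson log-likelihood is recomputed by the caller.
    """
    n, K = L.shape
    J = F.shape[1]
    # --- L update ---
    for i in range(n):
        lo, hi = indptr[i], indptr[i + 1]
        acc = np.zeros(K)
        for idx in range(lo, hi):
            j = indices[idx]
            lam = 0.0
            for k in range(K):
                lam += L[i, k] * F[k, j]
            if lam <= 0.0:
                continue
            r = data[idx] / lam
            for k in range(K):
                acc[k] += r * F[k, j]
        for k in range(K):
            L[i, k] = L[i, k] * acc[k] / Fsum[k]
    # --- F update ---
    RF = np.zeros((K, J))
    for i in range(n):
        lo, hi = indptr[i], indptr[i + 1]
        for idx in range(lo, hi):
            j = indices[idx]
            lam = 0.0
            for k in range(K):
                lam += L[i, k] * F[k, j]
            if lam <= 0.0:
                continue
            r = data[idx] / lam
            for k in range(K):
                RF[k, j] += r * L[i, k]
    for k in range(K):
        Lsum[k] = 0.0
    for i in range(n):
        for k in range(K):
            Lsum[k] += L[i, k]
    for k in range(K):
        for j in range(J):
            F[k, j] = F[k, j] * RF[k, j] / Lsum[k]


@njit(cache=False)
def _xlog_lambda(indptr, indices, data, L, F):
    """sum over nonzeros of x_ij * log(sum_k L_ik F_kj)."""
    n = L.shape[0]
    K = L.shape[1]
    out = 0.0
    for i in range(n):
        lo, hi = indptr[i], indptr[i + 1]
        for idx in range(lo, hi):
            j = indices[idx]
            lam = 0.0
            for k in range(K):
                lam += L[i, k] * F[k, j]
            if lam <= 0.0:
                out = -np.inf
                return out
            out += data[idx] * np.log(lam)
    return out


@njit(cache=False)
def _pseudobulk_kernel(indptr, indices, data, L, F, out, leftover):
    """y_kj = sum_i x_ij * L_ik F_kj / sum_k' L_ik' F_k'j (topic-partitioned reads).

    Entries whose model probability is zero accumulate into ``leftover``
    (handled by the caller: assigned by loadings alone)."""
    n, K = L.shape
    for i in range(n):
        lo, hi = indptr[i], indptr[i + 1]
        for idx in range(lo, hi):
            j = indices[idx]
            lam = 0.0
            for k in range(K):
                lam += L[i, k] * F[k, j]
            if lam <= 0.0:
                for k in range(K):
                    leftover[k, j] += data[idx] * L[i, k]
                continue
            r = data[idx] / lam
            for k in range(K):
                out[k, j] += r * L[i, k] * F[k, j]


def _poisson_loglik(counts_csr, L, F):
    """Poisson log-likelihood up to the constant sum log(x!)."""
    xlog = _xlog_lambda(counts_csr.indptr, counts_csr.indices, counts_csr.data, L, F)
    return xlog - float(L.sum(axis=0) @ F.sum(axis=1))


# ---------------------------------------------------------------------------
# public operations
# ---------------------------------------------------------------------------

def fit_topics(
    counts: CellRegionMatrix | sp.spmatrix | np.ndarray,
    K: int,
    seed: int = 0,
    max_iter: int = 300,
    tol: float = 1e-8,
) -> TopicFit:
    """Fit the K-topic model by EM on the Poisson NMF parameterization.

    Zero-depth cells are dropped before fitting (with a warning) and carry
    NaN loadings in the returned fit.  Reproducible given ``seed``.
    """
    if isinstance(counts, CellRegionMatrix):
        X = counts.counts
    else:
        X = sp.csr_matrix(counts)
    X = sp.csr_matrix(X, dtype=np.float64)
    n, J = X.shape
    if K < 1:
        raise ValueError("K must be >= 1")
    if K > min(n, J):
        raise ValueError(f"K={K} exceeds min(cells, regions)={min(n, J)}")

    depths = np.asarray(X.sum(axis=1)).ravel()
    keep = depths > 0
    n_dropped = int((~keep).sum())
    if n_dropped:
        warnings.warn(f"dropping {n_dropped} zero-depth cell(s) before fitting")
        Xf = X[keep]
    else:
        Xf = X
    nf = Xf.shape[0]
    total = float(Xf.sum())

    rng = np.random.default_rng(seed)
    # uniform random init scaled so that sum(L F) matches the total counts
    L = rng.uniform(0.5, 1.5, size=(nf, K))
    F = rng.uniform(0.5, 1.5, size=(K, J))
    scale = total / float(L.sum(axis=0) @ F.sum(axis=1))
    F *= scale

    Fsum = F.sum(axis=1)
    Lsum = np.zeros(K)
    trace = []
    prev = -np.inf
    converged = False
    for _ in range(max_iter):
        _em_half_updates(Xf.indptr, Xf.indices, Xf.data, L, F, Fsum, Lsum)
        Fsum = F.sum(axis=1)
        ll = _poisson_loglik(Xf, L, F)
        trace.append(ll)
        if np.isfinite(prev) and abs(ll - prev) <= tol * (abs(prev) + 1e-12):
            converged = True
            break
        prev = ll
    if not converged:
        warnings.warn(
            f"topic model EM did not converge within {max_iter} iterations; "
            "returning the best iterate"
        )

    fit = poisson_to_multinomial(PoissonNmfFit(L, F.T))
    if n_dropped:
        Lfull = np.full((n, K), np.nan)
        Lfull[keep] = fit.L
        fit = TopicFit(Lfull, fit.F, K, loglik_trace=np.array(trace), converged=converged)
    else:
        fit = TopicFit(fit.L, fit.F, K, loglik_trace=np.array(trace), converged=converged)
    return fit


def poisson_to_multinomial(fit: PoissonNmfFit) -> TopicFit:
    """Convert Poisson factors (L', F') to topic parameters (L, F).

    With topic scales u_k = sum_j F'_jk:  f_kj = F'_jk / u_k and
    l_ik = L'_ik u_k / sum_k L'_ik u_k.  The per-read model probability
    pi_ij = sum_k f_kj l_ik equals lambda_ij / (sum_j lambda_ij).
    """
    Lp = np.asarray(fit.L_prime, dtype=float)
    Fp = np.asarray(fit.F_prime, dtype=float)  # regions x K
    u = Fp.sum(axis=0)
    if (u <= 0).any():
        raise ValueError("topic with all-zero rates cannot be normalized")
    F = (Fp / u).T  # K x regions
    w = Lp * u
    denom = w.sum(axis=1, keepdims=True)
    if (denom <= 0).any():
        raise ValueError("cell with all-zero loadings cannot be normalized")
    L = w / denom
    return TopicFit(L, F, K=Lp.shape[1])


def loglik(counts, fit: TopicFit) -> float:
    """Multinomial log-likelihood sum_ij x_ij log(pi_ij), constants dropped."""
    if isinstance(counts, CellRegionMatrix):
        X = counts.counts
    else:
        X = sp.csr_matrix(counts)
    X = sp.csr_matrix(X, dtype=np.float64)
    if X.shape != (fit.L.shape[0], fit.F.shape[1]):
        raise ValueError("count matrix and fit dimensions disagree")
    L = np.ascontiguousarray(np.nan_to_num(fit.L))
    F = np.ascontiguousarray(fit.F)
    return float(_xlog_lambda(X.indptr, X.indices, X.data, L, F))


def pseudobulk_counts(counts, fit: TopicFit) -> np.ndarray:
    """Partition each region's reads across topics: K x regions matrix.

    y_kj = sum_i x_ij * l_ik f_kj / pi_ij, so that column sums equal the
    region's total reads exactly.  Reads at entries with zero model
    probability are assigned by loadings alone (with a warning).
    """
    if isinstance(counts, CellRegionMatrix):
        X = counts.counts
    else:
        X = sp.csr_matrix(counts)
    X = sp.csr_matrix(X, dtype=np.float64)
    n, J = X.shape
    K = fit.K
    if fit.L.shape[0] != n or fit.F.shape[1] != J:
        raise ValueError("count matrix and fit dimensions disagree")
    L = np.ascontiguousarray(np.nan_to_num(fit.L))
    F = np.ascontiguousarray(fit.F)
    out = np.zeros((K, J))
    leftover = np.zeros((K, J))
    _pseudobulk_kernel(X.indptr, X.indices, X.data, L, F, out, leftover)
    if leftover.any():
        warnings.warn(
            "regions with zero model probability but positive counts: "
            "their reads were assigned by loadings alone"
        )
        # leftover is x * l_ik with rows of L summing to 1, so reads are conserved
        out += leftover
    return out
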