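"""Synthetic-data generators for the full pipeline.

* Simulator I: scATAC counts from a Poisson NMF model with log-normal
  open/closed rates (open:closed ratio 7.25), Dirichlet(1/K) cell loadings
  and log-normal sequencing depths (median 20,000, sdlog 0.173);
* block-LD genotypes (AR(1) latent-Gaussian haplotypes);
* annotation-stratified mixture-of-normals GWAS traits with exact realized
  heritability and marginal summary statistics;
* the 200-trait null suite (no enriched topic);
* Simulator II: Bernoulli pseudobulk-probability accessibility with two
  haplotype draws and probabilities capped at 0.9.

Every generator is deterministic given (parameters, seed).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .io_formats import CellRegionMatrix, GenomicRegion, GenotypePanel, VariantRecord

logger = logging.getLogger(__name__)

__all__ = [
    "ScatacSimTruth",
    "GwasSimTruth",
    "random_open_masks",
    "simulate_topic_profiles",
    "simulate_scatac",
    "simulate_genotypes",
    "simulate_gwas",
    "simulate_null_suite",
    "simulate_scatac_bernoulli",
]

#: open-to-closed rate ratio matching peak vs non-peak read depth
OPEN_CLOSED_RATIO = 7.25
#: median per-cell depth and SD of log-depth
DEPTH_MEDIAN = 20_000
DEPTH_SDLOG = 0.173
#: default within-class coefficient of variation of the region rates
DEFAULT_RATE_CV = 0.3


@dataclass
class ScatacSimTruth:
    """Ground truth of one Simulator-I draw."""

    F_prime: np.ndarray          # J x K Poisson rates f'_jk
    L_prime: np.ndarray          # cells x K mixture weights (rows sum to 1)
    open_mask: np.ndarray        # K x J binary I_kj
    depths: np.ndarray           # s_i
    L: np.ndarray                # multinomial loadings (== L_prime here)
    F: np.ndarray                # K x J multinomial topic distributions
    params: dict = field(default_factory=dict)


@dataclass
class GwasSimTruth:
    """Ground truth of one simulated GWAS trait."""

    beta0: np.ndarray            # baseline effects (standardized scale)
    beta_k: np.ndarray           # P x K annotation effects
    beta_total: np.ndarray
    causal: np.ndarray           # any nonzero effect
    h2: float
    pi_b: float
    pi_k: np.ndarray
    y: np.ndarray
    Z: np.ndarray
    N: int

    def per_variant_h2(self) -> np.ndarray:
        """Realized heritability contribution of each variant."""
        return self.beta_total ** 2

    def true_topic_enrichment(self, annotations: np.ndarray) -> np.ndarray:
        """Realized e_k = (h^2 per variant in A_k) / (h^2 per variant overall)."""
        A = np.atleast_2d(np.asarray(annotations))
        if A.shape[0] != self.beta_total.size:
            A = A.T
        h = self.per_variant_h2()
        overall = h.mean()
        out = np.empty(A.shape[1])
        for k in range(A.shape[1]):
            sel = A[:, k] == 1
            out[k] = h[sel].mean() / overall if sel.any() and overall > 0 else np.nan
        return out


# ---------------------------------------------------------------------------
# Simulator I: scATAC counts
# ---------------------------------------------------------------------------

def random_open_masks(K: int, J: int, p_open: float = 0.2, seed: int = 0) -> np.ndarray:
    """K x J open/closed masks; every region is open in at least one topic
    (the peak set is the union of per-topic peaks)."""
    rng = np.random.default_rng(seed)
    masks = rng.random((K, J)) < p_open
    none_open = ~masks.any(axis=0)
    if none_open.any():
        forced = rng.integers(0, K, size=int(none_open.sum()))
        masks[forced, np.flatnonzero(none_open)] = True
    return masks.astype(np.int8)


def simulate_topic_profiles(
    K: int,
    J: int,
    open_masks: np.ndarray,
    cv: float = DEFAULT_RATE_CV,
    ratio: float = OPEN_CLOSED_RATIO,
    seed: int = 0,
) -> np.ndarray:
    """Per-topic Poisson region rates F' (J x K).

    Closed regions draw log f'_jk ~ N(f0, sigma^2), open regions
    N(f0 + log(ratio), sigma^2) with sigma^2 = log(1 + cv^2) giving the
    requested within-class coefficient of variation.  Each topic's rates
    are normalized to sum to one, so a pure-topic cell's total rate is ~1
    and the cell depth is controlled entirely by s_i.
    """
    if cv < 0:
        raise ValueError("cv must be nonnegative")
    open_masks = np.atleast_2d(np.asarray(open_masks))
    if open_masks.shape != (K, J):
        raise ValueError(f"open_masks shape {open_masks.shape} != ({K}, {J})")
    rng = np.random.default_rng(seed)
    sigma2 = np.log1p(cv ** 2)
    sigma = np.sqrt(sigma2)
    # anchor: median closed rate 1 pre-normalization; open = ratio x closed
    logf = rng.normal(0.0, sigma, size=(K, J))
    logf += np.where(open_masks == 1, np.log(ratio), 0.0)
    F_prime = np.exp(logf).T  # J x K
    F_prime /= F_prime.sum(axis=0, keepdims=True)
    return F_prime


def simulate_scatac(
    F_prime: np.ndarray,
    n_cells: int,
    open_masks: np.ndarray,
    alpha: float | None = None,
    depth_median: float = DEPTH_MEDIAN,
    depth_sdlog: float = DEPTH_SDLOG,
    seed: int = 0,
    chrom: str = "1",
    region_bp: int = 500,
    region_gap: int = 1500,
) -> tuple[CellRegionMatrix, ScatacSimTruth]:
    """Simulator I: x_ij ~ Poisson(s_i sum_k l'_ik f'_jk).

    Loadings are Dirichlet(alpha, ..., alpha) with alpha = 1/K by default;
    depths are log-normal with median ``depth_median`` and log-SD
    ``depth_sdlog``.  Regions are laid out as uniform synthetic peaks with
    GC content drawn uniformly (the rates are GC-independent by design).
    """
    F_prime = np.asarray(F_prime, dtype=float)
    J, K = F_prime.shape
    if alpha is None:
        alpha = 1.0 / K
    rng = np.random.default_rng(seed)
    L_prime = rng.dirichlet(np.full(K, alpha), size=n_cells)
    depths = np.exp(rng.normal(np.log(depth_median), depth_sdlog, size=n_cells))

    rates = (L_prime @ F_prime.T) * depths[:, None]
    counts = rng.poisson(rates.astype(np.float64))
    X = sp.csr_matrix(counts)

    gc = rng.uniform(0.3, 0.7, size=J)
    regions = [
        GenomicRegion(chrom, i * (region_bp + region_gap),
                      i * (region_bp + region_gap) + region_bp, gc=float(gc[i]))
        for i in range(J)
    ]
    barcodes = [f"cell_{i}" for i in range(n_cells)]

    # multinomial parameterization: columns of F' sum to 1 already, so the
    # topic distributions equal F'^T and the loadings are unchanged
    u = F_prime.sum(axis=0)
    F = (F_prime / u).T
    w = L_prime * u
    L = w / w.sum(axis=1, keepdims=True)

    truth = ScatacSimTruth(
        F_prime=F_prime,
        L_prime=L_prime,
        open_mask=np.atleast_2d(np.asarray(open_masks)).astype(np.int8),
        depths=depths,
        L=L,
        F=F,
        params={
            "n_cells": n_cells,
            "K": K,
            "J": J,
            "alpha": alpha,
            "depth_median": depth_median,
            "depth_sdlog": depth_sdlog,
            "seed": seed,
        },
    )
    return CellRegionMatrix(X, barcodes, regions), truth


# ---------------------------------------------------------------------------
# block-LD genotypes
# ---------------------------------------------------------------------------

def simulate_genotypes(
    n_ind: int,
    n_variants: int,
    block_size: int = 200,
    rho: float = 0.9,
    maf_range: tuple[float, float] = (0.05, 0.5),
    pos_spacing: int = 1_000,
    chrom: str = "1",
    seed: int = 0,
) -> GenotypePanel:
    """AR(1)-block latent-Gaussian haplotype genotypes.

    Within each block of ``block_size`` variants the latent Gaussians follow
    Corr(z_p, z_q) = rho^|p-q|; two independent haplotypes are thresholded
    at each variant's allele frequency (uniform in ``maf_range``) and summed
    to dosages in {0, 1, 2}.  Blocks are independent.
    """
    if not 0 <= rho < 1:
        raise ValueError("rho must be in [0, 1)")
    lo, hi = maf_range
    if not (0 < lo <= hi <= 0.5):
        raise ValueError("maf_range must be within (0, 0.5]")
    rng = np.random.default_rng(seed)
    mafs = rng.uniform(lo, hi, size=n_variants)
    thresholds = _norm_ppf(mafs)
    # jittered positions (still strictly increasing) so variants do not
    # systematically alias with any regular peak grid
    offsets = rng.integers(0, max(pos_spacing, 1), size=n_variants)

    dos = np.empty((n_ind, n_variants), dtype=np.int8)
    innov_sd = np.sqrt(1.0 - rho ** 2)
    for start in range(0, n_variants, block_size):
        stop = min(start + block_size, n_variants)
        width = stop - start
        z = np.empty((2 * n_ind, width))
        z[:, 0] = rng.standard_normal(2 * n_ind)
        for t in range(1, width):
            z[:, t] = rho * z[:, t - 1] + innov_sd * rng.standard_normal(2 * n_ind)
        haps = (z < thresholds[start:stop][None, :]).astype(np.int8)
        dos[:, start:stop] = haps[:n_ind] + haps[n_ind:]

    variants = [
        VariantRecord(f"rs{i}", chrom=chrom, pos=int(1 + i * pos_spacing + offsets[i]))
        for i in range(n_variants)
    ]
    return GenotypePanel(dos, variants)


def _norm_ppf(q):
    from scipy.stats import norm

    return norm.ppf(q)


# ---------------------------------------------------------------------------
# GWAS traits and summary statistics
# ---------------------------------------------------------------------------

def simulate_gwas(
    genotypes: GenotypePanel | np.ndarray,
    annotations: np.ndarray | None,
    pi_b: float,
    pi_k: np.ndarray | float,
    h2: float,
    seed: int = 0,
) -> tuple[GwasSimTruth, list[VariantRecord]]:
    """Additive quantitative trait with annotation-stratified causal mixture.

    beta_p0 ~ pi_b N(0, 1) + (1 - pi_b) delta_0 for every variant;
    beta_pk ~ pi_k N(0, 1) + (1 - pi_k) delta_0 only where A_k(p) = 1.
    Effects act on standardized genotypes and are rescaled so the realized
    genetic variance fraction equals ``h2`` exactly; marginal summary
    statistics come from per-variant simple regression of y on X_p.
    """
    if not 0 <= pi_b <= 1:
        raise ValueError("pi_b must be in [0, 1]")
    if not 0 <= h2 < 1:
        raise ValueError("h2 must be in [0, 1)")
    if isinstance(genotypes, GenotypePanel):
        G = genotypes.dosages
        vrecs = genotypes.variants
    else:
        G = np.asarray(genotypes)
        vrecs = [VariantRecord(f"rs{i}") for i in range(G.shape[1])]
    n, P = G.shape
    rng = np.random.default_rng(seed)

    if annotations is None:
        A = np.zeros((P, 0), dtype=np.int8)
    else:
        A = np.atleast_2d(np.asarray(annotations))
        if A.shape[0] != P:
            A = A.T
    K = A.shape[1]
    pi_k = np.broadcast_to(np.asarray(pi_k, dtype=float), (K,))

    mu = G.mean(axis=0)
    sd = G.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    Xs = (G - mu) / sd

    def _draw_effects():
        beta0 = np.where(rng.random(P) < pi_b, rng.standard_normal(P), 0.0)
        beta_k = np.zeros((P, K))
        for k in range(K):
            sel = A[:, k] == 1
            hit = sel & (rng.random(P) < pi_k[k])
            beta_k[hit, k] = rng.standard_normal(int(hit.sum()))
        return beta0, beta_k

    beta0, beta_k = _draw_effects()
    if h2 > 0 and not (beta0.any() or beta_k.any()):
        beta0, beta_k = _draw_effects()
        if not (beta0.any() or beta_k.any()):
            raise ValueError("no causal variants drawn (twice); increase pi_b")

    beta_total = beta0 + beta_k.sum(axis=1)
    eps = rng.standard_normal(n)

    if h2 == 0:
        beta0[:] = 0.0
        beta_k[:] = 0.0
        beta_total[:] = 0.0
        y = eps
    else:
        g = Xs @ beta_total
        g = g - g.mean()
        eps = eps - eps.mean()
        # orthogonalize the noise against the genetic value, then scale the
        # two components to variances h2 and 1 - h2 exactly
        gnorm2 = float(g @ g)
        eps = eps - (eps @ g) / gnorm2 * g
        scale_g = np.sqrt(h2 * n / gnorm2)
        scale_e = np.sqrt((1.0 - h2) * n / float(eps @ eps))
        g *= scale_g
        eps *= scale_e
        beta0 *= scale_g
        beta_k *= scale_g
        beta_total *= scale_g
        y = g + eps

    # marginal summary statistics: Z from simple regression on standardized X
    yc = y - y.mean()
    ysd = yc.std()
    r = (Xs.T @ yc) / (n * max(ysd, 1e-300))
    r = np.clip(r, -0.999999, 0.999999)
    Z = r * np.sqrt(n - 2) / np.sqrt(1.0 - r ** 2)

    truth = GwasSimTruth(
        beta0=beta0, beta_k=beta_k, beta_total=beta_total,
        causal=beta_total != 0, h2=h2, pi_b=pi_b, pi_k=np.asarray(pi_k),
        y=y, Z=Z, N=n,
    )
    sumstats = [
        VariantRecord(v.id, v.chrom, v.pos, v.a1, v.a2, N=float(n), Z=float(z))
        for v, z in zip(vrecs, Z)
    ]
    return truth, sumstats


def simulate_null_suite(
    genotypes: GenotypePanel | np.ndarray,
    annotations: np.ndarray,
    n_traits: int = 200,
    pi_b: float = 2.5e-4,
    h2: float = 0.5,
    seed: int = 0,
):
    """``n_traits`` independent traits with no annotation enrichment
    (pi_k = 0 for every topic); yields (truth, sumstats) pairs."""
    A = np.atleast_2d(np.asarray(annotations))
    K = A.shape[1] if A.shape[0] != 0 else 0
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(n_traits)
    out = []
    for child in children:
        child_seed = int(child.generate_state(1)[0] % (2 ** 31))
        out.append(
            simulate_gwas(genotypes, annotations, pi_b=pi_b,
                          pi_k=np.zeros(K), h2=h2, seed=child_seed)
        )
    return out


# ---------------------------------------------------------------------------
# Simulator II: Bernoulli pseudobulk-probability accessibility
# ---------------------------------------------------------------------------

def simulate_scatac_bernoulli(
    pseudobulk: np.ndarray,
    n_cells,
    s: float = 30_000,
    r: float = 0.3,
    p_cap: float = 0.9,
    seed: int = 0,
    cell_type_names=None,
):
    """Accessibility in {0, 1, 2} from per-cell-type pseudobulk profiles.

    For cell type c and peak j the accessibility probability is

        p_jc = (X_jc / sum_j X_jc) * (s * 0.5 * (1 - r)) + r * (s / J) * 0.5,

    capped at ``p_cap``; each cell draws two independent Bernoulli(p_jc)
    haplotypes and sums them.  Returns (matrix cells x peaks, labels, p).
    """
    X = np.atleast_2d(np.asarray(pseudobulk, dtype=float))
    if (X < 0).any():
        raise ValueError("pseudobulk must be nonnegative")
    if not 0 <= r <= 1:
        raise ValueError("r must be in [0, 1]")
    J, C = X.shape
    n_cells = np.broadcast_to(np.asarray(n_cells, dtype=int), (C,))
    if cell_type_names is None:
        cell_type_names = [f"type{c}" for c in range(C)]

    colsum = X.sum(axis=0)
    if (colsum <= 0).any():
        raise ValueError("cell type with zero pseudobulk reads")
    p = (X / colsum) * (s * 0.5 * (1.0 - r)) + r * (s / J) * 0.5
    n_capped = int((p > p_cap).sum())
    if n_capped:
        logger.info("simulate_scatac_bernoulli: capped %d peak probabilities", n_capped)
    p = np.minimum(p, p_cap)

    rng = np.random.default_rng(seed)
    mats, labels = [], []
    for c in range(C):
        pc = p[:, c]
        draws = (rng.random((n_cells[c], J)) < pc).astype(np.int8)
        draws += (rng.random((n_cells[c], J)) < pc).astype(np.int8)
        mats.append(draws)
        labels.extend(f"{cell_type_names[c]}_{i + 1}" for i in range(n_cells[c]))
    return np.vstack(mats), labels, p
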