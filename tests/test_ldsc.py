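"""Stratified LD-score regression: oracles, calibration, shrinkage."""

import numpy as np
import pytest
from scipy.stats import norm

from scads import simulate as sim
from scads.ldsc import (
    compute_ld_scores,
    enrichment_covariance,
    shrink_enrichments,
    sldsc_fit,
)


def brute_force_ld_scores(G, A, positions, window_bp, adjust=True):
    """Quadratic double-sum oracle."""
    G = np.asarray(G, dtype=float)
    n, P = G.shape
    K = A.shape[1]
    lA = np.zeros((P, K))
    lT = np.zeros(P)
    sd = G.std(axis=0)
    for p in range(P):
        for q in range(P):
            if abs(positions[p] - positions[q]) > window_bp:
                continue
            if sd[p] == 0 or sd[q] == 0:
                continue
            r = np.corrcoef(G[:, p], G[:, q])[0, 1]
            r2 = r * r
            if adjust:
                r2 = r2 - (1 - r2) / (n - 2)
            lT[p] += r2
            for k in range(K):
                if A[q, k]:
                    lA[p, k] += r2
    return lA, lT


class TestComputeLdScores:
    def test_independent_variants_no_ld_limit(self, rng):
        # rho=0: lA ~ A_k(p) (self term only, up to sampling noise)
        panel = sim.simulate_genotypes(500, 30, block_size=1, rho=0.0, seed=1)
        A = (rng.random((30, 1)) < 0.5).astype(int)
        ld = compute_ld_scores(panel.dosages, A, adjust=True, window_bp=10)
        np.testing.assert_allclose(ld.annot[:, 0], A[:, 0], atol=0.05)

    def test_three_variant_hand_panel(self):
        G = np.array([[0, 1, 2], [1, 1, 0], [2, 0, 1], [0, 2, 2], [1, 0, 0]])
        A = np.array([[1], [0], [1]])
        pos = np.array([0, 10, 20])
        ld = compute_ld_scores(G, A, positions=pos, window_bp=100)
        lA, lT = brute_force_ld_scores(G, A, pos, 100)
        np.testing.assert_allclose(ld.annot, lA, rtol=1e-10)
        np.testing.assert_allclose(ld.total, lT, rtol=1e-10)

    def test_brute_force_oracle_100_variants(self, rng):
        panel = sim.simulate_genotypes(60, 100, block_size=20, rho=0.7, seed=4)
        A = (rng.random((100, 2)) < 0.3).astype(int)
        pos = np.array([v.pos for v in panel.variants])
        ld = compute_ld_scores(panel.dosages, A, positions=pos, window_bp=8000)
        lA, lT = brute_force_ld_scores(panel.dosages, A, pos, 8000)
        np.testing.assert_allclose(ld.annot, lA, rtol=1e-9, atol=1e-12)
        np.testing.assert_allclose(ld.total, lT, rtol=1e-9, atol=1e-12)

    def test_full_annotation_equals_total(self, rng):
        panel = sim.simulate_genotypes(50, 40, block_size=10, rho=0.8, seed=5)
        A = np.ones((40, 1), dtype=int)
        ld = compute_ld_scores(
            panel.dosages, A, positions=np.array([v.pos for v in panel.variants])
        )
        np.testing.assert_allclose(ld.annot[:, 0], ld.total, rtol=1e-12)

    def test_containment_unadjusted(self, rng):
        # without bias adjustment r^2 >= 0, so subset LD scores never exceed total
        panel = sim.simulate_genotypes(50, 60, block_size=15, rho=0.8, seed=6)
        A = (rng.random((60, 1)) < 0.5).astype(int)
        ld = compute_ld_scores(
            panel.dosages, A, adjust=False,
            positions=np.array([v.pos for v in panel.variants]),
        )
        assert (ld.annot[:, 0] <= ld.total + 1e-12).all()
        assert (ld.annot >= 0).all()

    def test_too_few_individuals_rejected(self):
        with pytest.raises(ValueError):
            compute_ld_scores(np.array([[0, 1], [1, 2]]), np.ones((2, 1)), adjust=True)


class TestSldscFit:
    @pytest.fixture(scope="class")
    def panel_and_ld(self):
        panel = sim.simulate_genotypes(500, 4000, seed=7)
        rng = np.random.default_rng(8)
        A = np.zeros((4000, 2), dtype=np.int8)
        A[rng.choice(4000, 400, replace=False), 0] = 1
        A[rng.choice(4000, 400, replace=False), 1] = 1
        pos = np.array([v.pos for v in panel.variants])
        ld = compute_ld_scores(panel.dosages, A, positions=pos, window_bp=300_000)
        return panel, A, ld

    def test_null_and_enriched_recovery(self, panel_and_ld):
        panel, A, ld = panel_and_ld
        hits_enr, hits_null = 0, 0
        n_rep = 12
        for rep in range(n_rep):
            gw, _ = sim.simulate_gwas(
                panel, A[:, :1], pi_b=2e-3, pi_k=np.array([4e-2]), h2=0.5,
                seed=900 + rep,
            )
            chi2 = gw.Z ** 2
            r_enr = sldsc_fit(chi2, panel.n_individuals, ld.total, ld.annot[:, 0],
                              M=4000, M_k=400, n_blocks=100)
            r_null = sldsc_fit(chi2, panel.n_individuals, ld.total, ld.annot[:, 1],
                               M=4000, M_k=400, n_blocks=100)
            hits_enr += r_enr.e_hat > 1
            hits_null += abs(r_null.e_hat - 1) < 2 * r_null.se
        assert hits_enr >= int(0.75 * n_rep)
        assert hits_null >= int(0.75 * n_rep)

    def test_extreme_enrichment(self, panel_and_ld):
        # all heritability inside the annotation -> point estimate >> 1
        panel, A, ld = panel_and_ld
        gw, _ = sim.simulate_gwas(
            panel, A[:, :1], pi_b=0.0, pi_k=np.array([0.2]), h2=0.5, seed=99
        )
        r = sldsc_fit(gw.Z ** 2, panel.n_individuals, ld.total, ld.annot[:, 0],
                      M=4000, M_k=400, n_blocks=100)
        assert r.e_hat > 5

    def test_duplication_invariance(self, panel_and_ld):
        panel, A, ld = panel_and_ld
        gw, _ = sim.simulate_gwas(panel, None, pi_b=2e-3, pi_k=0.0, h2=0.3, seed=55)
        chi2 = gw.Z ** 2
        base = sldsc_fit(chi2, 500, ld.total, ld.annot[:, 0], M=4000, M_k=400,
                         n_blocks=50)
        dup = sldsc_fit(
            np.tile(chi2, 2), 500, np.tile(ld.total, 2), np.tile(ld.annot[:, 0], 2),
            M=4000, M_k=400, n_blocks=50, chisq_max=None,
        )
        assert dup.e_hat == pytest.approx(
            sldsc_fit(chi2, 500, ld.total, ld.annot[:, 0], M=4000, M_k=400,
                      n_blocks=50, chisq_max=None).e_hat,
            rel=1e-9,
        )
        assert np.isfinite(base.se)

    def test_empty_annotation_rejected(self, panel_and_ld):
        panel, A, ld = panel_and_ld
        with pytest.raises(ValueError, match="M_k"):
            sldsc_fit(np.ones(4000), 500, ld.total, ld.annot[:, 0], M=4000, M_k=0)

    def test_jackknife_se_tracks_empirical_sd(self, panel_and_ld):
        # empirical SD of e_hat across independent traits vs mean reported SE
        panel, A, ld = panel_and_ld
        e_hats, ses = [], []
        for rep in range(100):
            gw, _ = sim.simulate_gwas(panel, None, pi_b=5e-3, pi_k=0.0, h2=0.4,
                                      seed=3000 + rep)
            r = sldsc_fit(gw.Z ** 2, 500, ld.total, ld.annot[:, 0],
                          M=4000, M_k=400, n_blocks=100)
            e_hats.append(r.e_hat)
            ses.append(r.se)
        ratio = np.std(e_hats) / np.mean(ses)
        assert 0.5 < ratio < 2.0


class TestEnrichmentCovariance:
    def test_disjoint_half_annotations(self):
        A = np.zeros((100, 2), dtype=int)
        A[:50, 0] = 1
        A[50:, 1] = 1
        w = np.array([0.5, 2.0])
        cov = enrichment_covariance(w, A)
        assert cov[0, 1] == pytest.approx(-w[0] * w[1], rel=1e-12)

    def test_identical_annotations(self, rng):
        a = (rng.random(80) < 0.4).astype(int)
        A = np.column_stack([a, a])
        w = np.array([1.5, 0.7])
        cov = enrichment_covariance(w, A)
        assert cov[0, 1] == pytest.approx(w[0] * w[1], rel=1e-12)

    def test_diagonal_is_w_squared(self, rng):
        A = (rng.random((60, 3)) < 0.5).astype(int)
        w = np.array([1.0, 2.0, 0.3])
        cov = enrichment_covariance(w, A)
        np.testing.assert_allclose(np.diag(cov), w ** 2, rtol=1e-12)

    def test_constant_annotation_zero_offdiag(self, rng):
        A = np.column_stack([np.ones(50, dtype=int), (rng.random(50) < 0.5).astype(int)])
        with pytest.warns(UserWarning, match="constant"):
            cov = enrichment_covariance(np.array([1.0, 1.0]), A)
        assert cov[0, 1] == 0.0

    def test_symmetry(self, rng):
        A = (rng.random((100, 4)) < 0.3).astype(int)
        w = rng.uniform(0.5, 2.0, size=4)
        cov = enrichment_covariance(w, A)
        np.testing.assert_allclose(cov, cov.T, rtol=1e-12)


def quadrature_posterior_mean(delta_hat, w, pi, grid):
    """Fine-grid numerical integration of the uniform-mixture posterior mean."""
    post_num, post_den = 0.0, 0.0
    # point mass
    lik0 = norm.pdf(delta_hat, 0, w)
    post_den += pi[0] * lik0
    for m, a in enumerate(grid, start=1):
        xs = np.linspace(-a, a, 20_001)
        dens = norm.pdf(delta_hat, xs, w) / (2 * a)
        lik = np.trapezoid(dens, xs)
        mean_x = np.trapezoid(xs * dens, xs) / lik if lik > 0 else 0.0
        post_num += pi[m] * lik * mean_x
        post_den += pi[m] * lik
    return post_num / post_den


class TestShrinkEnrichments:
    def test_no_noise_limit(self):
        e = np.array([3.0, 0.5, 1.2])
        out = shrink_enrichments(e, np.zeros(3))
        np.testing.assert_allclose(out, e)

    def test_null_fixed_point(self):
        out = shrink_enrichments(np.ones(5), np.full(5, 2.0))
        np.testing.assert_allclose(out, 1.0, atol=1e-8)

    def test_noisy_nulls_shrink_precise_signal_stays(self):
        e = np.array([1.0] * 20 + [11.0])
        w = np.array([3.0] * 20 + [0.5])
        out = shrink_enrichments(e, w)
        assert np.abs(out[:20] - 1.0).max() < 0.5
        assert out[20] > 9.5

    def test_single_topic_defined(self):
        out = shrink_enrichments(np.array([4.0]), np.array([1.0]))
        assert np.isfinite(out[0])
        assert 1.0 <= out[0] <= 4.0

    def test_sign_preservation(self, rng):
        # symmetric mixture centered at 0 never pushes past 1 to the other side
        e = rng.uniform(1.0, 8.0, size=10)
        w = rng.uniform(0.5, 3.0, size=10)
        out = shrink_enrichments(e, w)
        assert (out >= 1.0 - 1e-8).all()

    def test_matches_quadrature_oracle(self):
        # the implementation's posterior means, recomputed by numerical
        # integration under the implementation's own fitted mixture
        e = np.array([1.0, 2.0, 6.0, 0.4, 1.5])
        w = np.array([1.0, 1.2, 1.0, 0.8, 1.1])
        out, pi, grid = shrink_enrichments(e, w, return_mixture=True)
        for k, (dh, ww) in enumerate(zip(e - 1.0, w)):
            quad = quadrature_posterior_mean(dh, ww, pi, grid)
            assert out[k] - 1.0 == pytest.approx(quad, abs=1e-4)
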