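"""Downstream analytics: CPM correlations, classification, genes, regulons."""

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
from scipy.stats import hypergeom

from scads.downstream import (
    Regulon,
    classify_variants,
    export_finemapping_priors,
    nearest_gene,
    regulon_enrichment,
    variant_score_correlation,
)
from scads.io_formats import CellRegionMatrix, GenomicRegion, VariantRecord
from scads.ldsc import EnrichmentTable


def make_counts(counts, pitch=1000, width=500):
    n, J = counts.shape
    regions = [GenomicRegion("1", j * pitch, j * pitch + width) for j in range(J)]
    return CellRegionMatrix(sp.csr_matrix(counts), [f"c{i}" for i in range(n)], regions)


class TestVariantScoreCorrelation:
    def test_perfectly_linear_cpm_gives_r_one(self):
        # 10 cells in 5 bins of 2; reads at one region grow linearly with score
        n = 10
        counts = np.zeros((n, 2), dtype=int)
        scores = np.arange(n, dtype=float)
        for i in range(n):
            counts[i, 0] = 100 * (1 + i // 2)  # variant region: linear per bin
            counts[i, 1] = 1000 - counts[i, 0]  # keep library size constant
        mat = make_counts(counts)
        variants = [VariantRecord("v", "1", 250)]
        (res,) = variant_score_correlation(mat, scores, np.arange(n), variants,
                                           n_bins=5)
        assert res.retained
        assert res.pearson_r == pytest.approx(1.0, abs=1e-9)

    def test_cpm_definition(self):
        # bin accessibility 50, library 1e6 -> CPM 50
        counts = np.zeros((5, 2), dtype=int)
        counts[:, 0] = 10          # variant region: 50 reads in the only bin
        counts[:, 1] = 199_990     # library fills to 1e6
        mat = make_counts(counts)
        (res,) = variant_score_correlation(
            mat, np.arange(5.0), np.arange(5), [VariantRecord("v", "1", 250)],
            n_bins=1,
        )
        assert res.cpm[0] == pytest.approx(50.0)

    def test_single_passing_bin_not_retained(self):
        counts = np.zeros((10, 2), dtype=int)
        counts[8:, 0] = 500       # only the top bin has reads at the variant
        counts[:, 1] = 1000
        mat = make_counts(counts)
        (res,) = variant_score_correlation(
            mat, np.arange(10.0), np.arange(10), [VariantRecord("v", "1", 250)],
            n_bins=5,
        )
        assert res.n_bins_passing == 1
        assert not res.retained and np.isnan(res.pearson_r)

    def test_depth_rescaling_invariance(self, rng):
        counts = rng.poisson(20, size=(20, 6))
        scores = rng.random(20)
        mat1 = make_counts(counts)
        mat2 = make_counts(counts * 3)
        v = [VariantRecord("v", "1", 2250)]
        r1 = variant_score_correlation(mat1, scores, np.arange(20), v, n_bins=4)
        r2 = variant_score_correlation(mat2, scores, np.arange(20), v, n_bins=4)
        np.testing.assert_allclose(r1[0].cpm, r2[0].cpm, rtol=1e-12)

    def test_fewer_cells_than_bins_rejected(self, rng):
        mat = make_counts(rng.poisson(5, size=(3, 2)))
        with pytest.raises(ValueError):
            variant_score_correlation(mat, np.arange(3.0), np.arange(3),
                                      [VariantRecord("v", "1", 250)], n_bins=5)


class TestClassifyVariants:
    def _cor(self, vid, r, retained=True):
        from scads.downstream import VariantScoreCorrelation

        return VariantScoreCorrelation(vid, np.ones(5), np.ones(5), r, 5, retained)

    def test_strong_negative_correlation(self):
        groups = classify_variants({"v": 0.999}, [self._cor("v", -0.978)])
        assert groups["v"] == "negative"

    def test_below_pip_threshold_excluded(self):
        groups = classify_variants({"v": 0.25}, [self._cor("v", 0.9)])
        assert "v" not in groups

    def test_weak_correlation_is_none(self):
        groups = classify_variants({"v": 0.5}, [self._cor("v", 0.1)])
        assert groups["v"] == "none"

    def test_partition_exclusive_exhaustive(self, rng):
        cors = [self._cor(f"v{i}", float(r), retained=i % 3 != 0)
                for i, r in enumerate(rng.uniform(-1, 1, size=30))]
        pip = {f"v{i}": float(p) for i, p in enumerate(rng.random(30))}
        groups = classify_variants(pip, cors)
        assert set(groups) == {v for v, p in pip.items() if p > 0.3}
        assert set(groups.values()) <= {"positive", "negative", "none"}


class TestNearestGene:
    def _genes(self):
        return pd.DataFrame(
            {"gene": ["g1", "g2", "g3"], "chrom": ["1", "1", "2"],
             "start": [1000, 5000, 100], "end": [2000, 6000, 200]}
        )

    def test_inside_gene_body(self):
        out = nearest_gene([VariantRecord("v", "1", 1500)], self._genes())
        assert out["v"] == ["g1"]

    def test_equidistant_tie_returns_both(self):
        genes = pd.DataFrame(
            {"gene": ["g1", "g2"], "chrom": ["1", "1"],
             "start": [1000, 4999], "end": [2000, 6000]}
        )
        # 0-based 3499 is 1500 from g1's right edge (1999) and from g2's start
        out = nearest_gene([VariantRecord("v", "1", 3500)], genes)
        assert sorted(out["v"]) == ["g1", "g2"]

    def test_chromosome_without_genes(self):
        out = nearest_gene([VariantRecord("v", "9", 100)], self._genes())
        assert "v" not in out

    def test_brute_force_oracle(self, rng):
        genes = pd.DataFrame(
            {"gene": [f"g{i}" for i in range(30)],
             "chrom": rng.choice(["1", "2"], size=30),
             "start": (s := rng.integers(0, 100_000, size=30)),
             "end": s + rng.integers(100, 5000, size=30)}
        )
        variants = [VariantRecord(f"v{i}", str(rng.choice(["1", "2"])),
                                  int(rng.integers(1, 110_000)))
                    for i in range(50)]
        out = nearest_gene(variants, genes)
        for v in variants:
            sub = genes[genes["chrom"] == v.chrom]
            if len(sub) == 0:
                assert v.id not in out
                continue
            pos0 = v.pos - 1
            dists = {}
            for _, g in sub.iterrows():
                if g["start"] <= pos0 < g["end"]:
                    d = 0
                else:
                    d = min(abs(pos0 - g["start"]), abs(pos0 - (g["end"] - 1)))
                dists[g["gene"]] = d
            best = min(dists.values())
            assert sorted(out[v.id]) == sorted(g for g, d in dists.items() if d == best)


class TestRegulonEnrichment:
    def test_zero_overlap_p_one(self):
        bg = {f"g{i}" for i in range(100)}
        reg = Regulon("tf", frozenset({f"g{i}" for i in range(10)}))
        targets = {f"g{i}" for i in range(90, 95)}
        df = regulon_enrichment(targets, [reg], bg)
        assert df["p"][0] == pytest.approx(1.0, abs=1e-9)

    def test_hypergeometric_tail_oracle(self):
        # background 1000, regulon 50, targets 10, overlap 5
        bg = {f"g{i}" for i in range(1000)}
        reg = Regulon("tf", frozenset({f"g{i}" for i in range(50)}))
        targets = {f"g{i}" for i in range(5)} | {f"g{i}" for i in range(500, 505)}
        df = regulon_enrichment(targets, [reg], bg)
        expected = sum(hypergeom.pmf(x, 1000, 50, 10) for x in range(5, 11))
        assert df["p"][0] == pytest.approx(expected, rel=1e-9)
        assert df["overlap"][0] == 5

    def test_regulon_equals_background_uninformative(self):
        bg = {f"g{i}" for i in range(40)}
        reg = Regulon("tf", frozenset(bg))
        df = regulon_enrichment({"g0", "g1"}, [reg], bg)
        assert df["p"][0] == pytest.approx(1.0)

    def test_bh_across_regulons(self, rng):
        bg = {f"g{i}" for i in range(500)}
        regs = [Regulon(f"tf{k}", frozenset(rng.choice(sorted(bg), 30, replace=False)))
                for k in range(10)]
        targets = set(rng.choice(sorted(bg), 20, replace=False))
        df = regulon_enrichment(targets, regs, bg)
        assert (df["fdr"] >= df["p"] - 1e-12).all()

    def test_empty_regulon_rejected(self):
        with pytest.raises(ValueError):
            Regulon("tf", frozenset())


class TestExportFinemappingPriors:
    def _table(self, p):
        K = len(p)
        return EnrichmentTable(
            tau=np.zeros(K), e_hat=np.ones(K), se=np.ones(K), p=np.array(p),
            e_post=np.ones(K), genome_fraction=np.full(K, 0.1),
            excluded=np.zeros(K, dtype=bool),
        )

    def test_significant_columns_exported(self, tmp_path):
        variants = [VariantRecord(f"rs{i}", "1", i + 1) for i in range(4)]
        A = np.arange(12).reshape(4, 3) % 2
        keep = export_finemapping_priors(
            self._table([0.01, 0.2, 0.04]), A, variants, tmp_path / "prior.tsv"
        )
        np.testing.assert_array_equal(keep, [0, 2])
        from scads.io_formats import read_annotation

        back, ids = read_annotation(tmp_path / "prior.tsv")
        assert back.shape == (4, 2)
        np.testing.assert_array_equal(back, A[:, [0, 2]])

    def test_no_significant_topic_warns_empty(self, tmp_path):
        variants = [VariantRecord("rs0", "1", 1)]
        with pytest.warns(UserWarning, match="no topic"):
            keep = export_finemapping_priors(
                self._table([0.5, 0.9]), np.ones((1, 2), dtype=int), variants,
                tmp_path / "prior.tsv",
            )
        assert keep.size == 0
        df = pd.read_csv(tmp_path / "prior.tsv", sep="\t")
        assert len(df) == 1 and not [c for c in df.columns if c.startswith("ANNOT")]

    def test_row_count_equals_variant_count(self, tmp_path):
        variants = [VariantRecord(f"rs{i}", "1", i + 1) for i in range(7)]
        export_finemapping_priors(
            self._table([0.01]), np.ones((7, 1), dtype=int), variants,
            tmp_path / "prior.tsv",
        )
        df = pd.read_csv(tmp_path / "prior.tsv", sep="\t")
        assert len(df) == 7
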