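"""Model/Results front end for the full pipeline.

``SCADSModel`` is built from the in-memory inputs (count matrix, summary
statistics, genotype panel); ``fit()`` runs topic modeling, per-topic
annotation, stratified LD-score regression (one topic at a time) and the
cell-score reconstruction, and returns a ``SCADSResults`` carrying the
estimates, their uncertainties, QC flags and a ``summary()`` table.
``run_pipeline`` is the file-based wrapper used by the CLI.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cell_score import build_cell_score_table, topic_sizes
from .io_formats import (
    CellRegionMatrix,
    GenotypePanel,
    read_counts,
    read_genotypes,
    read_sumstats,
    write_annotation,
    write_cell_scores,
)
from .ldsc import (
    EnrichmentTable,
    compute_ld_scores,
    enrichment_covariance,
    shrink_enrichments,
    sldsc_fit,
)
from .topic_annotation import (
    MIN_GENOME_FRACTION,
    annotate_topics,
    annotation_qc,
)
from .topic_model import TopicFit, fit_topics, pseudobulk_counts

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "SCADSModel", "SCADSResults", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Paths and parameters for a file-based pipeline run."""

    counts: str
    regions: str
    barcodes: str
    sumstats: str
    genotypes: str
    genotype_variants: str
    K: int
    out_dir: str = "scads_out"
    baseline: str | None = None
    fdr_regions: float = 0.05
    fdr_cells: float = 0.05
    window_bp: int = 1_000_000
    n_blocks: int = 200
    seed: int = 0
    max_iter: int = 300

    def __post_init__(self):
        if self.K < 1:
            raise ValueError("K must be >= 1")
        for thr in (self.fdr_regions, self.fdr_cells):
            if not 0 < thr < 1:
                raise ValueError("FDR thresholds must be in (0, 1)")


@dataclass
class SCADSResults:
    """Everything a fitted pipeline produced."""

    topic_fit: TopicFit
    pseudobulk: np.ndarray
    topic_annotation: object
    variant_annotation: object
    enrichment: EnrichmentTable
    cov_e: np.ndarray
    cell_scores: pd.DataFrame
    qc: dict
    params: dict = field(default_factory=dict)

    def summary(self) -> str:
        et = self.enrichment.to_frame()
        n_sig = int(self.cell_scores["significant"].sum())
        lines = [
            "SCADS results",
            "=" * 60,
            f"cells: {self.topic_fit.L.shape[0]}   regions: {self.topic_fit.F.shape[1]}   "
            f"topics: {self.topic_fit.K}",
            "",
            "Per-topic heritability enrichment:",
            et.to_string(
                index=False,
                formatters={
                    "tau": "{:.3g}".format, "e_hat": "{:.3f}".format,
                    "se": "{:.3f}".format, "p": "{:.2e}".format,
                    "e_post": "{:.3f}".format, "genome_fraction": "{:.4f}".format,
                },
            ),
            "",
            f"significant cells (BH FDR <= {self.params.get('fdr_cells', 0.05)}): "
            f"{n_sig} / {len(self.cell_scores)}",
        ]
        warn = [k for k, v in zip(range(len(self.qc["power_warning"])),
                                  self.qc["power_warning"]) if v]
        if warn:
            lines.append(
                f"warning: topics {warn} have pseudobulk depth < 1e7 reads "
                "(annotation may be underpowered)"
            )
        return "\n".join(lines)


class SCADSModel:
    """Cell-level disease-relevance model for scATAC-seq + GWAS data.

    Parameters
    ----------
    counts
        cells x regions read-count matrix with region coordinates and GC.
    sumstats
        DataFrame with columns SNP, A1, A2, N, Z (or a list of
        VariantRecord); variant ids must match the genotype panel.
    genotypes
        reference panel for LD computation, with positioned variants.
    K
        number of topics; pick roughly the number of expected cell types.
    baseline_annotations
        optional variants x B matrix regressed alongside each topic
        annotation; when absent the regression uses the total LD score only.
    """

    def __init__(
        self,
        counts: CellRegionMatrix,
        sumstats,
        genotypes: GenotypePanel,
        K: int,
        baseline_annotations: np.ndarray | None = None,
        fdr_regions: float = 0.05,
        fdr_cells: float = 0.05,
        window_bp: int = 1_000_000,
        n_blocks: int = 200,
        max_iter: int = 300,
    ):
        self.counts = counts
        if isinstance(sumstats, pd.DataFrame):
            self.sumstats = sumstats
        else:
            self.sumstats = pd.DataFrame(
                {"SNP": [v.id for v in sumstats], "N": [v.N for v in sumstats],
                 "Z": [v.Z for v in sumstats]}
            )
        self.genotypes = genotypes
        self.K = int(K)
        self.baseline_annotations = baseline_annotations
        self.fdr_regions = fdr_regions
        self.fdr_cells = fdr_cells
        self.window_bp = window_bp
        self.n_blocks = n_blocks
        self.max_iter = max_iter

    # -- stage helpers (exposed so the CLI can run stages separately) -------

    def fit_topics(self, seed: int = 0) -> TopicFit:
        return fit_topics(self.counts, self.K, seed=seed, max_iter=self.max_iter)

    def _align_sumstats(self):
        panel_ids = [v.id for v in self.genotypes.variants]
        ss = self.sumstats.set_index("SNP")
        missing = [i for i in panel_ids if i not in ss.index]
        if missing:
            raise ValueError(
                f"{len(missing)} panel variants absent from sumstats "
                f"(e.g. {missing[:3]})"
            )
        ss = ss.loc[panel_ids]
        return ss["Z"].to_numpy(dtype=float), ss["N"].to_numpy(dtype=float)

    def fit(self, seed: int = 0, topic_fit: TopicFit | None = None) -> SCADSResults:
        """Run fit -> annotate -> enrich (one topic at a time) -> score."""
        if topic_fit is None:
            logger.info("fitting %d-topic model", self.K)
            topic_fit = self.fit_topics(seed=seed)
        Y = pseudobulk_counts(self.counts, topic_fit)

        logger.info("deriving topic annotations")
        gc = self.counts.gc
        topic_ann, var_ann = annotate_topics(
            Y, gc, self.genotypes.variants, self.counts.regions,
            fdr=self.fdr_regions,
        )
        qc = annotation_qc(var_ann, topic_ann.pseudobulk_depth)
        excluded = np.asarray(qc["excluded"], dtype=bool)

        logger.info("computing LD scores (window %d bp)", self.window_bp)
        positions = np.array([v.pos for v in self.genotypes.variants])
        ld = compute_ld_scores(
            self.genotypes.dosages, var_ann.A, positions=positions,
            window_bp=self.window_bp,
        )

        Z, N = self._align_sumstats()
        chi2 = Z ** 2
        M = self.genotypes.n_variants
        K = self.K

        tau = np.full(K, np.nan)
        e_hat = np.full(K, np.nan)
        se = np.full(K, np.nan)
        pvals = np.full(K, np.nan)
        for k in range(K):
            M_k = int(var_ann.A[:, k].sum())
            if M_k == 0 or excluded[k]:
                excluded[k] = True
                continue
            res = sldsc_fit(
                chi2, N, ld.total, ld.annot[:, k], M=M, M_k=M_k,
                n_blocks=self.n_blocks,
            )
            tau[k], e_hat[k], se[k], pvals[k] = res.tau_k, res.e_hat, res.se, res.p

        inc = ~excluded
        e_post = np.ones(K)
        if inc.any():
            e_post[inc] = shrink_enrichments(e_hat[inc], se[inc])
        enrichment = EnrichmentTable(
            tau=tau, e_hat=e_hat, se=se, p=pvals, e_post=e_post,
            genome_fraction=var_ann.genome_fraction, excluded=excluded,
        )

        w = np.where(np.isfinite(se), se, 0.0)
        cov_e = enrichment_covariance(w, var_ann.A)

        s = topic_sizes(I=topic_ann.I, v=var_ann.v)
        table = build_cell_score_table(
            self.counts.barcodes, topic_fit.L, s, e_post, cov_e,
            excluded=excluded, fdr=self.fdr_cells,
        )
        return SCADSResults(
            topic_fit=topic_fit,
            pseudobulk=Y,
            topic_annotation=topic_ann,
            variant_annotation=var_ann,
            enrichment=enrichment,
            cov_e=cov_e,
            cell_scores=table,
            qc=qc,
            params={
                "K": self.K, "seed": seed, "fdr_regions": self.fdr_regions,
                "fdr_cells": self.fdr_cells, "window_bp": self.window_bp,
                "n_blocks": self.n_blocks,
            },
        )


def run_pipeline(config: PipelineConfig) -> SCADSResults:
    """File-based end-to-end run: read inputs, fit, write every artifact."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "read inputs"
    try:
        counts = read_counts(config.counts, config.regions, config.barcodes)
        sumstats = read_sumstats(config.sumstats)
        panel = read_genotypes(config.genotypes, config.genotype_variants)
        ss_df = pd.DataFrame(
            {"SNP": [v.id for v in sumstats], "N": [v.N for v in sumstats],
             "Z": [v.Z for v in sumstats]}
        )
        model = SCADSModel(
            counts, ss_df, panel, K=config.K,
            fdr_regions=config.fdr_regions, fdr_cells=config.fdr_cells,
            window_bp=config.window_bp, n_blocks=config.n_blocks,
            max_iter=config.max_iter,
        )
        stage = "fit"
        results = model.fit(seed=config.seed)
        stage = "write outputs"
        np.savetxt(out / "L.tsv", results.topic_fit.L, delimiter="\t")
        np.savetxt(out / "F.tsv", results.topic_fit.F, delimiter="\t")
        write_annotation(
            results.variant_annotation.A, panel.variants, out / "annotations.tsv"
        )
        results.enrichment.to_frame().to_csv(
            out / "enrichment.tsv", sep="\t", index=False
        )
        write_cell_scores(results.cell_scores, out / "cell_scores.tsv")
        with open(out / "qc.json", "w") as fh:
            json.dump(results.qc, fh, indent=2)
        manifest = {
            "version": __version__,
            "seed": config.seed,
            "K": config.K,
            "fdr_regions": config.fdr_regions,
            "fdr_cells": config.fdr_cells,
            "window_bp": config.window_bp,
            "n_blocks": config.n_blocks,
            "inputs": {
                "counts": str(config.counts), "regions": str(config.regions),
                "barcodes": str(config.barcodes), "sumstats": str(config.sumstats),
                "genotypes": str(config.genotypes),
            },
        }
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2)
        with open(out / "run.log", "w") as fh:
            fh.write(results.summary() + "\n")
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage '{stage}': {exc}") from exc
    return results
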