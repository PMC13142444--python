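"""Readers and writers for the external formats the pipeline touches.

Coordinate conventions, used consistently everywhere in the package:

* genomic regions are BED-style 0-based half-open intervals ``[start, end)``;
* variant positions are VCF-style 1-based;
* a variant at position ``pos`` lies in region ``[start, end)`` iff
  ``start <= pos - 1 < end``.

All text formats are plain whitespace/tab-delimited; gzipped variants
(``.gz`` suffix) are accepted transparently.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

logger = logging.getLogger(__name__)

__all__ = [
    "GenomicRegion",
    "VariantRecord",
    "CellRegionMatrix",
    "GenotypePanel",
    "FormatError",
    "read_counts",
    "write_counts",
    "read_regions_bed",
    "write_regions_bed",
    "gc_content_from_fasta",
    "read_sumstats",
    "write_sumstats",
    "read_genotypes",
    "write_genotypes",
    "read_annotation",
    "write_annotation",
    "read_cell_scores",
    "write_cell_scores",
]


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


def _open_text(path, mode="rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


@dataclass(frozen=True)
class GenomicRegion:
    """A 0-based half-open genomic interval, optionally with GC content."""

    chrom: str
    start: int
    end: int
    gc: float | None = None

    def __post_init__(self):
        if self.start < 0 or self.start >= self.end:
            raise FormatError(
                f"invalid region {self.chrom}:{self.start}-{self.end}; "
                "require 0 <= start < end"
            )
        if self.gc is not None and not (0.0 <= self.gc <= 1.0):
            raise FormatError(f"GC content {self.gc} outside [0, 1]")

    def __len__(self) -> int:
        return self.end - self.start

    def contains_variant(self, pos: int) -> bool:
        """Whether a 1-based variant position falls in this region."""
        return self.start <= pos - 1 < self.end


@dataclass(frozen=True)
class VariantRecord:
    """A variant with 1-based position and optional GWAS summary fields."""

    id: str
    chrom: str = "1"
    pos: int = 1
    a1: str = "A"
    a2: str = "G"
    N: float | None = None
    Z: float | None = None

    def __post_init__(self):
        if self.pos < 1:
            raise FormatError(f"variant {self.id}: position {self.pos} < 1")
        if self.Z is not None and not np.isfinite(self.Z):
            raise FormatError(f"variant {self.id}: non-finite Z")


@dataclass
class CellRegionMatrix:
    """Sparse cells x regions read-count matrix with labels.

    ``counts`` is kept as CSR with nonnegative integer-valued entries.
    """

    counts: sp.csr_matrix
    barcodes: list[str]
    regions: list[GenomicRegion]

    def __post_init__(self):
        self.counts = sp.csr_matrix(self.counts)
        n, j = self.counts.shape
        if n != len(self.barcodes) or j != len(self.regions):
            raise FormatError(
                f"matrix shape {self.counts.shape} inconsistent with "
                f"{len(self.barcodes)} barcodes / {len(self.regions)} regions"
            )
        data = self.counts.data
        if data.size:
            if data.min() < 0:
                raise FormatError("negative count entries")
            if not np.allclose(data, np.round(data)):
                raise FormatError("non-integer count entries")

    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_regions(self) -> int:
        return self.counts.shape[1]

    @property
    def depths(self) -> np.ndarray:
        """Per-cell total read counts s_i."""
        return np.asarray(self.counts.sum(axis=1)).ravel()

    @property
    def gc(self) -> np.ndarray:
        out = np.array([r.gc if r.gc is not None else np.nan for r in self.regions])
        return out


@dataclass
class GenotypePanel:
    """Reference genotype dosages (individuals x variants, values in {0,1,2})."""

    dosages: np.ndarray
    variants: list[VariantRecord] = field(default_factory=list)

    def __post_init__(self):
        self.dosages = np.asarray(self.dosages)
        if self.dosages.ndim != 2:
            raise FormatError("dosage matrix must be 2-D")
        bad = ~np.isin(self.dosages, (0, 1, 2))
        if bad.any():
            raise FormatError("dosages outside {0, 1, 2}")
        if self.variants and len(self.variants) != self.dosages.shape[1]:
            raise FormatError("variant sidecar length mismatch")

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    def allele_frequencies(self) -> np.ndarray:
        return self.dosages.mean(axis=0) / 2.0


# ---------------------------------------------------------------------------
# regions / barcodes
# ---------------------------------------------------------------------------

def read_regions_bed(path) -> list[GenomicRegion]:
    """Read BED regions; an optional numeric 4th column is taken as GC content."""
    regions = []
    with _open_text(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) < 3:
                raise FormatError(f"{path}:{ln}: fewer than 3 BED columns")
            gc = None
            if len(parts) >= 4:
                try:
                    gc = float(parts[3])
                except ValueError:
                    gc = None
            regions.append(
                GenomicRegion(parts[0], int(parts[1]), int(parts[2]), gc=gc)
            )
    return regions


def write_regions_bed(regions: Sequence[GenomicRegion], path) -> None:
    with _open_text(path, "wt") as fh:
        for r in regions:
            if r.gc is not None:
                fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.gc:.6g}\n")
            else:
                fh.write(f"{r.chrom}\t{r.start}\t{r.end}\n")


def gc_content_from_fasta(regions: Sequence[GenomicRegion], fasta_path) -> list[GenomicRegion]:
    """Attach GC fractions computed from a FASTA sequence source."""
    from Bio import SeqIO  # deferred; only needed when a FASTA is supplied

    seqs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(fasta_path), "fasta")}
    out = []
    for r in regions:
        if r.chrom not in seqs:
            raise FormatError(f"chromosome {r.chrom} absent from {fasta_path}")
        seq = seqs[r.chrom][r.start:r.end]
        if not seq:
            raise FormatError(f"region {r.chrom}:{r.start}-{r.end} beyond sequence end")
        gc = (seq.count("G") + seq.count("C")) / len(seq)
        out.append(GenomicRegion(r.chrom, r.start, r.end, gc=gc))
    return out


def _read_barcodes(path) -> list[str]:
    with _open_text(path) as fh:
        return [line.strip().split("\t")[0] for line in fh if line.strip()]


# ---------------------------------------------------------------------------
# count matrix
# ---------------------------------------------------------------------------

def read_counts(
    matrix_path,
    regions_path,
    barcodes_path,
    orientation: str = "auto",
) -> CellRegionMatrix:
    """Read a Matrix Market count matrix with BED regions and a barcode list.

    Parameters
    ----------
    orientation
        ``"auto"`` infers whether the matrix is cells x regions or
        regions x cells from the list lengths; ``"cells"`` / ``"regions"``
        force the interpretation of the MTX rows.  Square matrices are
        ambiguous and require an explicit orientation.
    """
    mat = scipy.io.mmread(str(matrix_path))
    mat = sp.csr_matrix(mat)
    regions = read_regions_bed(regions_path)
    barcodes = _read_barcodes(barcodes_path)
    n_c, n_r = len(barcodes), len(regions)

    rows, cols = mat.shape
    if orientation == "auto":
        if rows == cols and n_c == n_r:
            raise FormatError(
                "square matrix with equally many barcodes and regions is "
                "ambiguous; pass orientation='cells' or 'regions'"
            )
        if (rows, cols) == (n_c, n_r):
            pass
        elif (rows, cols) == (n_r, n_c):
            mat = sp.csr_matrix(mat.T)
        else:
            raise FormatError(
                f"matrix shape {mat.shape} matches neither "
                f"(cells={n_c}, regions={n_r}) nor its transpose"
            )
    elif orientation == "cells":
        if (rows, cols) != (n_c, n_r):
            raise FormatError(f"matrix shape {mat.shape} != ({n_c}, {n_r})")
    elif orientation == "regions":
        if (rows, cols) != (n_r, n_c):
            raise FormatError(f"matrix shape {mat.shape} != ({n_r}, {n_c})")
        mat = sp.csr_matrix(mat.T)
    else:
        raise ValueError(f"unknown orientation {orientation!r}")

    return CellRegionMatrix(mat, barcodes, regions)


def write_counts(matrix: CellRegionMatrix, matrix_path, regions_path, barcodes_path) -> None:
    """Write a CellRegionMatrix as MTX + BED + barcode list (cells x regions)."""
    coo = matrix.counts.tocoo()
    scipy.io.mmwrite(
        str(matrix_path),
        sp.coo_matrix(
            (coo.data.astype(np.int64), (coo.row, coo.col)), shape=matrix.counts.shape
        ),
        field="integer",
    )
    write_regions_bed(matrix.regions, regions_path)
    with _open_text(barcodes_path, "wt") as fh:
        fh.write("\n".join(matrix.barcodes) + "\n")


# ---------------------------------------------------------------------------
# GWAS summary statistics
# ---------------------------------------------------------------------------

_SUMSTATS_COLS = ("SNP", "A1", "A2", "N", "Z")


def read_sumstats(path) -> list[VariantRecord]:
    """Read LDSC-dialect summary statistics (SNP, A1, A2, N, Z).

    Rows with missing/non-finite Z are dropped; the drop count is logged.
    """
    df = pd.read_csv(path, sep=r"\s+")
    missing = [c for c in _SUMSTATS_COLS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    z = pd.to_numeric(df["Z"], errors="coerce")
    keep = np.isfinite(z.to_numpy(dtype=float))
    n_drop = int((~keep).sum())
    if n_drop:
        logger.info("read_sumstats: dropped %d rows with missing Z", n_drop)
    df = df.loc[keep]
    z = z[keep]
    recs = []
    for snp, a1, a2, n, zz in zip(df["SNP"], df["A1"], df["A2"], df["N"], z):
        recs.append(VariantRecord(str(snp), a1=str(a1), a2=str(a2), N=float(n), Z=float(zz)))
    return recs


def write_sumstats(records: Sequence[VariantRecord], path) -> None:
    with _open_text(path, "wt") as fh:
        fh.write("SNP\tA1\tA2\tN\tZ\n")
        for r in records:
            fh.write(f"{r.id}\t{r.a1}\t{r.a2}\t{r.N:g}\t{r.Z:.6g}\n")


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------

def read_genotypes(path, variants_path=None) -> GenotypePanel:
    """Read a tabular dosage matrix (individuals x variants).

    The main file is a TSV whose header row holds variant ids; entries must
    be in {0, 1, 2}.  An optional sidecar TSV (``id chrom pos a1 a2``) in the
    same variant order supplies positions.
    """
    df = pd.read_csv(path, sep="\t")
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise FormatError(f"{path}: empty genotype file")
    dos = df.to_numpy()
    if not np.isin(dos, (0, 1, 2)).all():
        raise FormatError(f"{path}: dosages outside {{0,1,2}}")
    variants = [VariantRecord(str(c)) for c in df.columns]
    if variants_path is not None:
        side = pd.read_csv(variants_path, sep="\t")
        if len(side) != len(variants):
            raise FormatError("variant sidecar length mismatch")
        variants = [
            VariantRecord(str(r["id"]), str(r["chrom"]), int(r["pos"]), str(r["a1"]), str(r["a2"]))
            for _, r in side.iterrows()
        ]
    return GenotypePanel(dos.astype(np.int8), variants)


def write_genotypes(panel: GenotypePanel, path, variants_path=None) -> None:
    ids = [v.id for v in panel.variants] or [f"v{i}" for i in range(panel.n_variants)]
    pd.DataFrame(panel.dosages, columns=ids).to_csv(path, sep="\t", index=False)
    if variants_path is not None:
        pd.DataFrame(
            {
                "id": ids,
                "chrom": [v.chrom for v in panel.variants],
                "pos": [v.pos for v in panel.variants],
                "a1": [v.a1 for v in panel.variants],
                "a2": [v.a2 for v in panel.variants],
            }
        ).to_csv(variants_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# annotations & per-cell scores
# ---------------------------------------------------------------------------

def write_annotation(annotation: np.ndarray, variants: Sequence[VariantRecord], path) -> None:
    """Write a variant annotation matrix as an .annot-style TSV.

    ``annotation`` is (variants,) or (variants, K) binary.
    """
    ann = np.asarray(annotation)
    if ann.ndim == 1:
        ann = ann.reshape(-1, 1)
    if ann.shape[0] != len(variants):
        raise FormatError(
            f"annotation rows {ann.shape[0]} != variant count {len(variants)}"
        )
    cols = {"SNP": [v.id for v in variants],
            "CHR": [v.chrom for v in variants],
            "BP": [v.pos for v in variants]}
    for k in range(ann.shape[1]):
        cols[f"ANNOT_{k}"] = ann[:, k].astype(int)
    pd.DataFrame(cols).to_csv(path, sep="\t", index=False)


def read_annotation(path) -> tuple[np.ndarray, list[str]]:
    df = pd.read_csv(path, sep="\t")
    acols = [c for c in df.columns if c.startswith("ANNOT_")]
    return df[acols].to_numpy(dtype=int), list(df["SNP"].astype(str))


_CELL_SCORE_COLS = ["barcode", "score", "variance", "z", "p", "fdr"]


def write_cell_scores(table: pd.DataFrame, path) -> None:
    """Write the per-cell score table as TSV with a deterministic column order."""
    missing = [c for c in _CELL_SCORE_COLS if c not in table.columns]
    if missing:
        raise FormatError(f"cell-score table missing column(s) {missing}")
    extra = [c for c in table.columns if c not in _CELL_SCORE_COLS]
    table[_CELL_SCORE_COLS + extra].to_csv(path, sep="\t", index=False)


def read_cell_scores(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
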