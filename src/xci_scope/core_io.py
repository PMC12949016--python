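"""Shared data types, 10x-triplet readers/writers, QC filters and log-normalization.

The central container is :class:`AnnotatedCountMatrix`: a sparse cells x genes
raw count matrix joined to per-cell metadata (sample, sex, cell type, broad
lineage) and a gene annotation table carrying chromosome coordinates and the
XCI class of every X-linked gene (inactivated / escapee / PAR / unclassified).
All dosage statistics downstream read the *raw* counts; log-normalized values
are a parallel layer used only for correlation- and rank-based analyses.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.io import mmread, mmwrite

logger = logging.getLogger("xci_scope")

XCI_STATUSES = ("inactivated", "escapee", "PAR", "unclassified", "not_X")
AUTOSOMES = tuple(str(i) for i in range(1, 23))
#: chromosome sort order used whenever genes are laid out along the genome
CHROM_ORDER = AUTOSOMES + ("X", "Y")

ANNOTATION_COLUMNS = ["gene_id", "symbol", "chromosome", "start", "end", "xci_status"]
CELL_META_COLUMNS = ["barcode", "sample_id", "sex", "cell_type", "broad_lineage"]


def _open_text(path, mode="rt"):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class QCThresholds:
    """Cell/gene quality-control cutoffs.

    Defaults are the single-nucleus settings: at least 1500 reads and 1000
    detected genes per cell, at most 5% mitochondrial reads (20% for whole
    cells), and genes kept only when expressed in at least 10 cells.
    """

    min_counts_per_cell: int = 1500
    min_genes_per_cell: int = 1000
    max_mito_fraction: float = 0.05
    min_cells_per_gene: int = 10

    def __post_init__(self):
        if min(self.min_counts_per_cell, self.min_genes_per_cell, self.min_cells_per_gene) <= 0:
            raise ValueError("QC thresholds must be strictly positive")
        if not 0.0 < self.max_mito_fraction <= 1.0:
            raise ValueError("max_mito_fraction must be in (0, 1]")

    @classmethod
    def for_cells(cls, **kw) -> "QCThresholds":
        """Whole-cell preset (mitochondrial cutoff 20%)."""
        kw.setdefault("max_mito_fraction", 0.20)
        return cls(**kw)


@dataclass
class AnnotatedCountMatrix:
    """Sparse cells x genes raw counts with aligned cell metadata and gene annotation.

    ``cell_meta`` is indexed by barcode with columns sample_id, sex, cell_type
    and broad_lineage; ``genes`` is indexed by gene_id with columns symbol,
    chromosome, start, end and xci_status. ``normalized`` optionally holds a
    parallel log-normalized layer of the same shape.
    """

    counts: sp.csr_matrix
    cell_meta: pd.DataFrame
    genes: pd.DataFrame
    normalized: sp.csr_matrix | None = None

    def __post_init__(self):
        self.counts = sp.csr_matrix(self.counts)
        if self.counts.nnz and self.counts.data.min() < 0:
            raise ValueError("counts must be non-negative")
        n_cells, n_genes = self.counts.shape
        if len(self.cell_meta) != n_cells:
            raise ValueError(
                f"cell_meta has {len(self.cell_meta)} rows but matrix has {n_cells} cells"
            )
        if len(self.genes) != n_genes:
            raise ValueError(
                f"gene annotation has {len(self.genes)} rows but matrix has {n_genes} genes"
            )
        if not self.cell_meta.index.is_unique:
            raise ValueError("cell barcodes must be unique")
        if not self.genes.index.is_unique:
            raise ValueError("gene_ids must be unique")
        bad = ~self.genes["xci_status"].isin(XCI_STATUSES)
        if bad.any():
            raise ValueError(f"unknown xci_status values: {set(self.genes['xci_status'][bad])}")
        on_x = self.genes["chromosome"].astype(str) == "X"
        if ((self.genes["xci_status"] != "not_X") & ~on_x).any():
            raise ValueError("non-X genes must carry xci_status='not_X'")
        if ((self.genes["xci_status"] == "not_X") & on_x).any():
            raise ValueError("X genes must carry an XCI class (not 'not_X')")
        if (self.genes["start"] > self.genes["end"]).any():
            raise ValueError("gene start must be <= end (1-based inclusive)")

    # -- convenience -------------------------------------------------------
    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]

    @property
    def cell_ids(self) -> pd.Index:
        return self.cell_meta.index

    @property
    def gene_ids(self) -> pd.Index:
        return self.genes.index

    def subset_cells(self, mask) -> "AnnotatedCountMatrix":
        mask = np.asarray(mask)
        if mask.dtype == bool:
            idx = np.flatnonzero(mask)
        else:
            idx = mask
        return AnnotatedCountMatrix(
            counts=self.counts[idx],
            cell_meta=self.cell_meta.iloc[idx],
            genes=self.genes,
            normalized=None if self.normalized is None else self.normalized[idx],
        )

    def subset_genes(self, mask) -> "AnnotatedCountMatrix":
        mask = np.asarray(mask)
        if mask.dtype == bool:
            idx = np.flatnonzero(mask)
        else:
            idx = mask
        return AnnotatedCountMatrix(
            counts=self.counts[:, idx],
            cell_meta=self.cell_meta,
            genes=self.genes.iloc[idx],
            normalized=None if self.normalized is None else self.normalized[:, idx],
        )

    def to_anndata(self):
        """Export as an AnnData (obs = cell_meta, var = gene annotation)."""
        import anndata as ad

        return ad.AnnData(X=self.counts.copy(), obs=self.cell_meta.copy(), var=self.genes.copy())


# ---------------------------------------------------------------------------
# readers / writers (CellRanger triplet dialect: matrix is genes x cells)
# ---------------------------------------------------------------------------


def read_count_matrix(
    matrix_path,
    features_path,
    barcodes_path,
    cell_meta_path,
    annotation_path,
) -> AnnotatedCountMatrix:
    """Read a 10x triplet plus metadata/annotation tables into an AnnotatedCountMatrix.

    The Matrix Market file is features x barcodes (CellRanger convention) and
    is transposed to cells x genes. Genes are joined to the annotation by
    gene_id, falling back to symbol; genes absent from the annotation get a
    default class (``unclassified`` on X, ``not_X`` otherwise).
    """
    with _open_text(matrix_path, "rb") as fh:
        mat = sp.csr_matrix(mmread(fh).T)
    features = pd.read_csv(features_path, sep="\t", header=None)
    barcodes = pd.read_csv(barcodes_path, sep="\t", header=None)[0].astype(str)
    if mat.shape[1] != len(features):
        raise ValueError(
            f"{features_path}: {len(features)} features but matrix has {mat.shape[1]} rows"
        )
    if mat.shape[0] != len(barcodes):
        raise ValueError(
            f"{barcodes_path}: {len(barcodes)} barcodes but matrix has {mat.shape[0]} columns"
        )
    gene_ids = features[0].astype(str)
    symbols = features[1].astype(str) if features.shape[1] > 1 else gene_ids

    annotation = read_annotation(annotation_path)
    genes = _join_annotation(gene_ids, symbols, annotation)

    cell_meta = pd.read_csv(cell_meta_path, sep="\t", dtype=str)
    cell_meta = cell_meta.set_index("barcode").reindex(barcodes.values)
    if cell_meta["sample_id"].isna().any():
        missing = int(cell_meta["sample_id"].isna().sum())
        raise ValueError(f"{cell_meta_path}: {missing} barcodes missing from cell metadata")
    return AnnotatedCountMatrix(counts=mat, cell_meta=cell_meta, genes=genes)


def _join_annotation(gene_ids: pd.Series, symbols: pd.Series, annotation: pd.DataFrame) -> pd.DataFrame:
    ann = annotation.set_index("gene_id")
    if not ann.index.is_unique:
        logger.warning("annotation has duplicated gene_ids; keeping first occurrence")
        ann = ann[~ann.index.duplicated(keep="first")]
    by_symbol = annotation.drop_duplicates("symbol", keep="first").set_index("symbol")

    rows = []
    for gid, sym in zip(gene_ids, symbols):
        if gid in ann.index:
            rec = ann.loc[gid]
        elif sym in by_symbol.index:
            rec = by_symbol.loc[sym]
            logger.warning("gene %s joined to annotation by symbol %s", gid, sym)
        else:
            rows.append((gid, sym, "unknown", 0, 0, "not_X"))
            continue
        chrom = str(rec["chromosome"])
        status = rec["xci_status"]
        if pd.isna(status) or status == "":
            status = "unclassified" if chrom == "X" else "not_X"
        rows.append((gid, sym, chrom, int(rec["start"]), int(rec["end"]), status))
    genes = pd.DataFrame(rows, columns=ANNOTATION_COLUMNS).set_index("gene_id")
    genes.index = genes.index.astype(str)
    return genes


def read_annotation(path) -> pd.DataFrame:
    ann = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "symbol": str, "chromosome": str})
    missing = set(ANNOTATION_COLUMNS) - set(ann.columns)
    if missing:
        raise ValueError(f"{path}: annotation is missing columns {sorted(missing)}")
    # genes on X lacking an explicit class default to 'unclassified'
    on_x = ann["chromosome"].astype(str) == "X"
    blank = ann["xci_status"].isna() | (ann["xci_status"] == "")
    ann.loc[on_x & blank, "xci_status"] = "unclassified"
    ann.loc[~on_x & blank, "xci_status"] = "not_X"
    ann.loc[~on_x & (ann["xci_status"] != "not_X"), "xci_status"] = "not_X"
    return ann


def write_count_matrix(m: AnnotatedCountMatrix, matrix_path, features_path, barcodes_path) -> None:
    """Write the triplet layout (matrix stored genes x cells, integer field)."""
    with _open_text(matrix_path, "wb") as fh:
        mmwrite(fh, sp.coo_matrix(m.counts.T.astype(np.int64)), field="integer")
    with _open_text(features_path, "wt") as fh:
        for gid, sym in zip(m.gene_ids, m.genes["symbol"]):
            fh.write(f"{gid}\t{sym}\tGene Expression\n")
    with _open_text(barcodes_path, "wt") as fh:
        for bc in m.cell_ids:
            fh.write(f"{bc}\n")


def write_cell_meta(m: AnnotatedCountMatrix, path) -> None:
    out = m.cell_meta.reset_index().rename(columns={"index": "barcode"})
    if "barcode" not in out.columns:
        out = out.rename(columns={out.columns[0]: "barcode"})
    with _open_text(path, "wt") as fh:
        out.to_csv(fh, sep="\t", index=False)


def write_annotation(genes: pd.DataFrame, path) -> None:
    out = genes.reset_index()
    if "gene_id" not in out.columns:
        out = out.rename(columns={out.columns[0]: "gene_id"})
    with _open_text(path, "wt") as fh:
        out[ANNOTATION_COLUMNS].to_csv(fh, sep="\t", index=False)


# ---------------------------------------------------------------------------
# QC filters
# ---------------------------------------------------------------------------


def mito_mask(m: AnnotatedCountMatrix) -> np.ndarray:
    """Mitochondrial genes are identified by the 'MT-' symbol prefix."""
    return m.genes["symbol"].astype(str).str.startswith("MT-").to_numpy()


def filter_cells(m: AnnotatedCountMatrix, q: QCThresholds = QCThresholds()) -> AnnotatedCountMatrix:
    """Drop low-quality cells (low counts, few genes, or high mitochondrial fraction)."""
    totals = np.asarray(m.counts.sum(axis=1)).ravel()
    detected = np.asarray((m.counts > 0).sum(axis=1)).ravel()
    mito = mito_mask(m)
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_frac = np.where(
            totals > 0, np.asarray(m.counts[:, mito].sum(axis=1)).ravel() / np.maximum(totals, 1), 0.0
        )
    keep = (
        (totals >= q.min_counts_per_cell)
        & (detected >= q.min_genes_per_cell)
        & (mito_frac <= q.max_mito_fraction)
    )
    if not keep.any():
        logger.warning("filter_cells removed every cell")
    return m.subset_cells(keep)


def filter_genes(m: AnnotatedCountMatrix, min_cells: int = 10) -> AnnotatedCountMatrix:
    """Keep genes expressed (nonzero) in at least ``min_cells`` cells."""
    n_expressing = np.asarray((m.counts > 0).sum(axis=0)).ravel()
    return m.subset_genes(n_expressing >= min_cells)


def remove_mito_genes(m: AnnotatedCountMatrix) -> AnnotatedCountMatrix:
    """Drop MT- genes (expected to be ambient reads in nuclei preparations).

    Applied after per-cell QC so totals used for QC include the full matrix.
    """
    mito = mito_mask(m)
    if mito.any():
        logger.info("removing %d mitochondrial genes (of %d)", int(mito.sum()), m.n_genes)
    return m.subset_genes(~mito)


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------


def log_normalize(m: AnnotatedCountMatrix, scale_factor: float = 10_000.0) -> sp.csr_matrix:
    """Per-cell library-size normalization followed by log1p.

    value = ln(1 + count / cell_total * scale_factor). Zeros map to zero and
    the within-cell ordering of values is preserved. Raw counts are untouched;
    dosage ratios always use the raw layer.
    """
    totals = np.asarray(m.counts.sum(axis=1)).ravel()
    if (totals == 0).any():
        raise ValueError("cells with zero total counts present; run filter_cells first")
    norm = m.counts.astype(np.float64).tocsr(copy=True)
    row_scale = scale_factor / totals
    norm.data *= np.repeat(row_scale, np.diff(norm.indptr))
    norm.data = np.log1p(norm.data)
    return norm


def attach_normalized(m: AnnotatedCountMatrix, scale_factor: float = 10_000.0) -> AnnotatedCountMatrix:
    """Return a copy of ``m`` with the log-normalized layer filled in."""
    return replace(m, normalized=log_normalize(m, scale_factor))
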