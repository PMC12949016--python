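"""Equal-depth pseudobulk aggregation, variance stabilization, PCA with projection.

Samples are equalized to the same number of cells (uniform downsampling of
barcodes), highly variable genes are selected on log-normalized expression,
raw counts are aggregated per sample, and the sample x gene matrix is
variance-stabilized with median-of-ratios size factors followed by
log2(x/sf + 1) — a pluggable, documented simplification of a regularized-log
transform whose downstream uses here (PCA, Spearman) depend only on the
stabilization. The PCA model persists its centering/scaling vectors and
loadings so new pseudobulk samples (e.g. spatial sections) can be projected
into the same component space.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .core_io import AnnotatedCountMatrix, log_normalize

logger = logging.getLogger("xci_scope")


# ---------------------------------------------------------------------------
# downsampling / HVG / aggregation
# ---------------------------------------------------------------------------


def downsample_equal(
    m: AnnotatedCountMatrix, n_per_sample: int = 253, seed: int | None = None
) -> AnnotatedCountMatrix:
    """Uniformly sample ``n_per_sample`` barcodes per sample without replacement.

    If a sample holds fewer cells, n drops to the cohort minimum (warning).
    Deterministic under a fixed seed.
    """
    rng = np.random.default_rng(seed)
    sizes = m.cell_meta.groupby("sample_id").size()
    n = int(n_per_sample)
    if (sizes < n).any():
        n = int(sizes.min())
        logger.warning("smallest sample has %d cells; downsampling all samples to %d", n, n)
    keep = np.zeros(m.n_cells, dtype=bool)
    pos = np.arange(m.n_cells)
    for sid in sizes.index:
        cells = pos[(m.cell_meta["sample_id"] == sid).to_numpy()]
        keep[rng.choice(cells, size=n, replace=False)] = True
    return m.subset_cells(keep)


def select_hvg(m: AnnotatedCountMatrix, n_top: int = 2000) -> list:
    """Top ``n_top`` genes by variance of log-normalized expression.

    Ties break deterministically by gene_id. With fewer genes than n_top,
    all are returned with a warning.
    """
    norm = m.normalized if m.normalized is not None else log_normalize(m)
    mean = np.asarray(norm.mean(axis=0)).ravel()
    sq = np.asarray(norm.multiply(norm).mean(axis=0)).ravel()
    var = np.maximum(sq - mean**2, 0.0)
    order = sorted(zip(-var, m.gene_ids))  # descending variance, gene_id tiebreak
    if m.n_genes < n_top:
        logger.warning("only %d genes available (< n_top=%d); returning all", m.n_genes, n_top)
        n_top = m.n_genes
    return [g for _, g in order[:n_top]]


def aggregate_pseudobulk(
    m: AnnotatedCountMatrix, genes: list | None = None, min_gene_count: int = 10
) -> pd.DataFrame:
    """Samples x genes matrix of summed raw counts (restricted to ``genes``).

    Genes whose total count across all samples falls below ``min_gene_count``
    are dropped.
    """
    if genes is None:
        sub = m
    else:
        idx = m.gene_ids.get_indexer(pd.Index(genes))
        if (idx < 0).any():
            raise ValueError("some requested genes are absent from the matrix")
        sub = m.subset_genes(idx)
    samples = list(dict.fromkeys(sub.cell_meta["sample_id"]))
    rows = []
    for sid in samples:
        mask = (sub.cell_meta["sample_id"] == sid).to_numpy()
        rows.append(np.asarray(sub.counts[mask].sum(axis=0)).ravel())
    pb = pd.DataFrame(np.vstack(rows), index=pd.Index(samples, name="sample_id"), columns=sub.gene_ids)
    keep = pb.sum(axis=0) >= min_gene_count
    return pb.loc[:, keep]


# ---------------------------------------------------------------------------
# variance stabilization
# ---------------------------------------------------------------------------


def size_factors(pb: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors (genes with a zero in any sample are
    excluded from the geometric-mean reference)."""
    counts = pb.to_numpy(dtype=float)
    positive = (counts > 0).all(axis=0)
    if not positive.any():
        raise ValueError("no gene is positive in every sample; cannot form size factors")
    logc = np.log(counts[:, positive])
    ref = logc.mean(axis=0)
    sf = np.exp(np.median(logc - ref[None, :], axis=1))
    return pd.Series(sf, index=pb.index, name="size_factor")


def variance_stabilize(pb: pd.DataFrame) -> pd.DataFrame:
    """Size-factor-normalized log2 transform: log2(count / sf + 1).

    Genes with zero counts in all samples are dropped first.
    """
    pb = pb.loc[:, pb.sum(axis=0) > 0]
    sf = size_factors(pb)
    return np.log2(pb.div(sf, axis=0) + 1.0)


# ---------------------------------------------------------------------------
# PCA with projection
# ---------------------------------------------------------------------------


@dataclass
class PCAModel:
    """Centering/scaling vectors, orthonormal loadings, scores and variance
    explained; supports projecting new samples onto the same axes."""

    gene_list: list
    center: np.ndarray
    scale: np.ndarray
    loadings: np.ndarray  # genes x PCs, orthonormal columns
    scores: pd.DataFrame  # samples x PCs
    variance_explained: np.ndarray

    @property
    def n_components(self) -> int:
        return self.loadings.shape[1]

    def save(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        pcs = [f"PC{i+1}" for i in range(self.n_components)]
        pd.DataFrame(
            {"gene_id": self.gene_list, "center": self.center, "scale": self.scale}
        ).to_csv(outdir / "center_scale.tsv", sep="\t", index=False)
        pd.DataFrame(self.loadings, index=self.gene_list, columns=pcs).to_csv(
            outdir / "loadings.tsv", sep="\t", index_label="gene_id"
        )
        self.scores.to_csv(outdir / "scores.tsv", sep="\t", index_label="sample_id")
        pd.DataFrame({"pc": pcs, "variance_explained": self.variance_explained}).to_csv(
            outdir / "variance_explained.tsv", sep="\t", index=False
        )

    @classmethod
    def load(cls, outdir) -> "PCAModel":
        outdir = Path(outdir)
        cs = pd.read_csv(outdir / "center_scale.tsv", sep="\t")
        loadings = pd.read_csv(outdir / "loadings.tsv", sep="\t", index_col="gene_id")
        scores = pd.read_csv(outdir / "scores.tsv", sep="\t", index_col="sample_id")
        ve = pd.read_csv(outdir / "variance_explained.tsv", sep="\t")["variance_explained"]
        return cls(
            gene_list=list(cs["gene_id"]),
            center=cs["center"].to_numpy(),
            scale=cs["scale"].to_numpy(),
            loadings=loadings.to_numpy(),
            scores=scores,
            variance_explained=ve.to_numpy(),
        )


def pca_fit(matrix: pd.DataFrame) -> PCAModel:
    """PCA of a samples x genes matrix after centering and unit-variance scaling.

    Constant genes are dropped (warning). Components are sign-fixed so each
    PC's largest-|loading| gene has a positive loading; variance explained is
    non-increasing by construction.
    """
    if len(matrix) < 2:
        raise ValueError("PCA needs at least 2 samples")
    x = matrix.to_numpy(dtype=float)
    center = x.mean(axis=0)
    scale = x.std(axis=0, ddof=1)
    keep = scale > 0
    if not keep.all():
        logger.warning("dropping %d constant genes before PCA", int((~keep).sum()))
    x, center, scale = x[:, keep], center[keep], scale[keep]
    z = (x - center) / scale
    u, s, vt = np.linalg.svd(z, full_matrices=False)
    nz = s > s[0] * 1e-12 if s.size else np.zeros(0, dtype=bool)
    u, s, vt = u[:, nz], s[nz], vt[nz]
    loadings = vt.T
    signs = np.sign(loadings[np.abs(loadings).argmax(axis=0), np.arange(loadings.shape[1])])
    signs[signs == 0] = 1.0
    loadings *= signs[None, :]
    scores = z @ loadings
    var_explained = s**2 / np.sum(s**2)
    pcs = [f"PC{i+1}" for i in range(loadings.shape[1])]
    return PCAModel(
        gene_list=list(matrix.columns[keep]),
        center=center,
        scale=scale,
        loadings=loadings,
        scores=pd.DataFrame(scores, index=matrix.index, columns=pcs),
        variance_explained=var_explained,
    )


def pca_project(model: PCAModel, new_rows: pd.DataFrame, max_missing: float = 0.2) -> pd.DataFrame:
    """Project new samples (same transform as training) onto the model axes.

    Rows are reindexed to the model's gene list. More than ``max_missing`` of
    the model genes absent is an error (silent zero-fill is forbidden); up to
    that fraction is zero-filled on the standardized scale with a warning.
    """
    present = new_rows.columns.intersection(model.gene_list)
    frac_missing = 1.0 - len(present) / len(model.gene_list)
    if frac_missing > max_missing:
        raise ValueError(
            f"{frac_missing:.0%} of model genes missing from new samples (> {max_missing:.0%})"
        )
    x = new_rows.reindex(columns=model.gene_list).to_numpy(dtype=float)
    z = (x - model.center) / model.scale
    if frac_missing > 0:
        logger.warning("zero-filling %.1f%% missing model genes", 100 * frac_missing)
        z = np.nan_to_num(z, nan=0.0)
    scores = z @ model.loadings
    return pd.DataFrame(scores, index=new_rows.index, columns=model.scores.columns)


def sample_correlation(transformed_pb: pd.DataFrame, method: str = "spearman") -> pd.DataFrame:
    """Symmetric sample x sample correlation of transformed pseudobulk profiles."""
    if len(transformed_pb) < 2:
        raise ValueError("need at least 2 samples")
    const = transformed_pb.std(axis=1) == 0
    if const.any():
        logger.warning("constant sample vectors: %s", list(transformed_pb.index[const]))
    return transformed_pb.T.corr(method=method)


def hierarchical_order(transformed_pb: pd.DataFrame) -> list:
    """Sample ordering from hierarchical clustering on Euclidean distances."""
    from scipy.cluster.hierarchy import leaves_list, linkage

    link = linkage(transformed_pb.to_numpy(), method="average", metric="euclidean")
    return [transformed_pb.index[i] for i in leaves_list(link)]


def ranked_loadings(model: PCAModel, pc: int, direction: str = "positive") -> pd.Series:
    """Genes ordered by signed loading on ``pc`` (1-based) in one direction.

    The positive list ranks by descending loading, the negative list by
    ascending; exported as a pre-ranked list for external enrichment.
    """
    if not 1 <= pc <= model.n_components:
        raise ValueError(f"pc must be in 1..{model.n_components}")
    load = pd.Series(model.loadings[:, pc - 1], index=model.gene_list, name=f"PC{pc}_loading")
    if direction == "positive":
        return load.sort_values(ascending=False)
    if direction == "negative":
        return load.sort_values(ascending=True)
    raise ValueError("direction must be 'positive' or 'negative'")
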