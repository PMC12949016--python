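"""Reference-normalized relative dosage along chromosomes and the XaXa-like classifier.

A simplified expression-based copy-dosage inference: genes with adequate mean
expression are laid out along the genome, log-normalized expression is
centered on the per-gene mean of a designated reference population (immune
cells by default, treated as copy-neutral infiltrate), and a moving average
along each chromosome smooths per-gene noise into segment-level shifts. The
per-cell proportion of non-PAR X genes whose smoothed residual exceeds the
gain threshold quantifies inferred X duplication; joint thresholds on the
X/A ratio (>0.036) and this proportion (>0.5) call XaXa-like cells.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .core_io import CHROM_ORDER, AnnotatedCountMatrix

logger = logging.getLogger("xci_scope")

#: GRCh38 pseudoautosomal intervals on X (1-based inclusive)
PAR_REGIONS = ((10_001, 2_781_479), (155_701_383, 156_030_895))

XA_THRESHOLD = 0.036
DUP_THRESHOLD = 0.5


@dataclass
class RelativeDosageMatrix:
    """Smoothed, reference-centered log-expression (cells x retained genes).

    Genes are ordered chromosome-then-start. Values near 0 are copy-neutral
    relative to the reference; sustained positive values indicate gained
    dosage (two active X's look like an X gain).
    """

    values: np.ndarray
    genes: pd.DataFrame
    cell_ids: pd.Index
    expression_cutoff: float = 0.1
    window: int = 101
    gain_threshold: float = 0.15
    loss_threshold: float = -0.15

    def __post_init__(self):
        if self.window < 3 or self.window % 2 == 0:
            raise ValueError("window must be odd and >= 3")


def _moving_average(block: np.ndarray, window: int) -> np.ndarray:
    """Row-wise moving average with windows clipped at the block edges.

    Each position i averages x[max(0,i-h) : i+h+1] (h = window//2), divided
    by the actual window length; window membership is symmetric (j in W_i iff
    i in W_j), so the window-length-weighted mean is exactly preserved.
    """
    n = block.shape[1]
    h = window // 2
    cs = np.concatenate([np.zeros((block.shape[0], 1)), np.cumsum(block, axis=1)], axis=1)
    lo = np.maximum(np.arange(n) - h, 0)
    hi = np.minimum(np.arange(n) + h + 1, n)
    sums = cs[:, hi] - cs[:, lo]
    return sums / (hi - lo)[None, :]


def infer_relative_dosage(
    m: AnnotatedCountMatrix,
    reference_cell_ids,
    expression_cutoff: float = 0.1,
    window: int = 101,
    gain_threshold: float = 0.15,
    loss_threshold: float = -0.15,
    scale_factor: float = 10_000.0,
) -> RelativeDosageMatrix:
    """Reference-centered smoothed log-expression along the genome.

    Steps: (1) drop genes with mean raw count < ``expression_cutoff`` across
    all cells; (2) log-normalize (library size, log1p); (3) subtract the
    per-gene mean over the reference cells; (4) moving average of width
    ``window`` within each chromosome; (5) subtract each cell's median
    smoothed value (cell-specific technical offsets are shared across the
    genome, and most of the genome is copy-neutral). Chromosomes with fewer
    than window/4 genes degenerate to their chromosome mean (with a warning).
    """
    ref_idx = m.cell_ids.get_indexer(pd.Index(reference_cell_ids))
    if len(ref_idx) == 0 or (ref_idx < 0).any():
        raise ValueError("reference cell ids empty or not all present in the matrix")

    mean_count = np.asarray(m.counts.mean(axis=0)).ravel()
    retained = mean_count >= expression_cutoff
    if not retained.any():
        raise ValueError("no genes pass the expression cutoff")

    # genome order: chromosome then start
    genes = m.genes.loc[retained].copy()
    chrom_rank = genes["chromosome"].astype(str).map(
        {c: i for i, c in enumerate(CHROM_ORDER)}
    ).fillna(len(CHROM_ORDER))
    order = np.lexsort((genes["start"].to_numpy(), chrom_rank.to_numpy()))
    genes = genes.iloc[order]

    totals = np.asarray(m.counts.sum(axis=1)).ravel().astype(float)
    if (totals == 0).any():
        raise ValueError("cells with zero totals present; run filter_cells first")
    sub = m.counts[:, np.flatnonzero(retained)[order]].toarray().astype(float)
    logexpr = np.log1p(sub / totals[:, None] * scale_factor)
    logexpr -= logexpr[ref_idx].mean(axis=0)[None, :]

    smoothed = np.empty_like(logexpr)
    chroms = genes["chromosome"].astype(str).to_numpy()
    for chrom in dict.fromkeys(chroms):
        cols = np.flatnonzero(chroms == chrom)
        block = logexpr[:, cols]
        if len(cols) < window / 4:
            logger.warning(
                "chromosome %s has %d genes (< window/4); using chromosome mean", chrom, len(cols)
            )
            smoothed[:, cols] = block.mean(axis=1, keepdims=True)
        else:
            smoothed[:, cols] = _moving_average(block, window)
    smoothed -= np.median(smoothed, axis=1, keepdims=True)

    return RelativeDosageMatrix(
        values=smoothed,
        genes=genes,
        cell_ids=m.cell_ids,
        expression_cutoff=expression_cutoff,
        window=window,
        gain_threshold=gain_threshold,
        loss_threshold=loss_threshold,
    )


def in_par(genes: pd.DataFrame, par_regions=PAR_REGIONS) -> np.ndarray:
    """True for genes overlapping a pseudoautosomal interval (or flagged PAR)."""
    on_x = (genes["chromosome"].astype(str) == "X").to_numpy()
    overlap = np.zeros(len(genes), dtype=bool)
    for lo, hi in par_regions:
        overlap |= (genes["start"].to_numpy() <= hi) & (genes["end"].to_numpy() >= lo)
    return on_x & (overlap | (genes["xci_status"] == "PAR").to_numpy())


def _viterbi_gain_states(values: np.ndarray, sd: float, gain: float, stay: float = 1 - 1e-4) -> np.ndarray:
    """Most likely loss/neutral/gain state path along one chromosome, per cell.

    A 3-state Gaussian HMM with fixed emission means (-gain, 0, +gain),
    shared emission sd and sticky transitions; copy-state runs span many
    genes, so persistence pools evidence along the chromosome. Returns the
    Viterbi state index (0=loss, 1=neutral, 2=gain) per (cell, gene).
    """
    n_cells, n_genes = values.shape
    means = np.array([-gain, 0.0, gain])
    log_trans = np.full((3, 3), np.log((1 - stay) / 2))
    np.fill_diagonal(log_trans, np.log(stay))
    emit = -((values[:, :, None] - means[None, None, :]) ** 2) / (2 * sd**2)
    score = emit[:, 0, :].copy()
    back = np.empty((n_cells, n_genes, 3), dtype=np.int8)
    for j in range(1, n_genes):
        cand = score[:, :, None] + log_trans[None, :, :]
        back[:, j] = cand.argmax(axis=1)
        score = cand.max(axis=1) + emit[:, j]
    states = np.empty((n_cells, n_genes), dtype=np.int8)
    states[:, -1] = score.argmax(axis=1)
    rows = np.arange(n_cells)
    for j in range(n_genes - 1, 0, -1):
        states[:, j - 1] = back[rows, j, states[:, j]]
    return states


def x_duplication_proportion(
    d: RelativeDosageMatrix, par_regions=PAR_REGIONS, method: str = "hmm"
) -> pd.Series:
    """Per-cell proportion of retained non-PAR X genes in the gain state.

    The PARs sit on both sex chromosomes and do not report X dosage, so they
    are excluded. With ``method='hmm'`` (default) gain states come from the
    3-state Gaussian HMM over the smoothed residuals, which pools evidence
    along the chromosome the way the full copy-number HMM does; the emission
    noise is the spread of the reference-like neutral residuals (robust sd of
    all smoothed X values with the center removed). ``method='threshold'``
    flags genes whose smoothed value exceeds ``gain_threshold`` directly.
    NaN when no non-PAR X gene survived filtering.
    """
    on_x = (d.genes["chromosome"].astype(str) == "X").to_numpy()
    usable = on_x & ~in_par(d.genes, par_regions)
    if not usable.any():
        logger.warning("no non-PAR X genes retained; x_dup_proportion is NaN")
        return pd.Series(np.nan, index=d.cell_ids, name="x_dup_proportion")
    block = d.values[:, usable]
    if method == "threshold":
        prop = (block > d.gain_threshold).mean(axis=1)
    elif method == "hmm":
        resid = block - np.median(block, axis=1, keepdims=True)
        sd = max(float(1.4826 * np.median(np.abs(resid))), 1e-3)
        states = _viterbi_gain_states(block, sd=sd, gain=d.gain_threshold)
        prop = (states == 2).mean(axis=1)
        logger.info(
            "gain-state calibration: HMM emission means ±%.3f, sd %.4f (robust, from "
            "centered residual spread)", d.gain_threshold, sd,
        )
    else:
        raise ValueError("method must be 'hmm' or 'threshold'")
    return pd.Series(prop, index=d.cell_ids, name="x_dup_proportion")


def classify_xaxa(
    profile: pd.DataFrame,
    xa_threshold: float = XA_THRESHOLD,
    dup_threshold: float = DUP_THRESHOLD,
) -> pd.Series:
    """XaXa-like call: X/A ratio > xa_threshold AND X-dup proportion > dup_threshold.

    XY cells and cells with missing inputs are 'not_applicable'.
    """
    ratio = profile["xa_ratio_all"]
    dup = profile["x_dup_proportion"]
    missing = ratio.isna() | dup.isna()
    if (missing & (profile["sex"] != "XY")).any():
        logger.warning(
            "%d XX cells missing ratio or duplication inputs -> not_applicable",
            int((missing & (profile["sex"] != "XY")).sum()),
        )
    call = np.where((ratio > xa_threshold) & (dup > dup_threshold), "XaXa_like", "XaXi")
    call = np.where((profile["sex"] == "XY").to_numpy() | missing.to_numpy(), "not_applicable", call)
    return pd.Series(call, index=profile.index, name="xaxa_call")


def dosage_ratio_correlation(profile: pd.DataFrame):
    """Spearman rho between X/A ratio and X-dup proportion over XISTneg cells."""
    sub = profile[profile["xist_status"] == "XISTneg"][["xa_ratio_all", "x_dup_proportion"]].dropna()
    if len(sub) < 3:
        raise ValueError("need at least 3 XISTneg cells with complete inputs")
    if sub["xa_ratio_all"].nunique() < 2 or sub["x_dup_proportion"].nunique() < 2:
        logger.warning("constant input vector; correlation undefined")
        return np.nan, np.nan
    rho, p = spearmanr(sub["xa_ratio_all"], sub["x_dup_proportion"])
    return float(rho), float(p)
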