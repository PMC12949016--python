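"""Per-cell X-to-autosome dosage ratios and XIST stratification.

The X/A ratio — summed raw counts over X-linked genes divided by the summed
raw counts over autosomes (chromosomes 1-22; Y excluded from both) — is a
per-cell proxy for X dosage: XaXi cells sit at the XY level, cells with two
active X's near twice that. Stratifying the numerator by XCI gene class
(inactivated vs escapee) separates genes silenced on the inactive X, whose
dosage doubles on reactivation, from escapees, whose dosage is invariant.
"""

from __future__ import annotations

import logging
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

from .core_io import AUTOSOMES, AnnotatedCountMatrix

logger = logging.getLogger("xci_scope")

GENE_CLASSES = ("all", "inactivated", "escapee")
XIST_STATUSES = ("XISTpos", "XISTneg", "XY")


def xa_ratio(
    m: AnnotatedCountMatrix,
    gene_class: str = "all",
    exclude_xist: bool = False,
) -> np.ndarray:
    """Per-cell X/A ratio for a gene class ('all', 'inactivated' or 'escapee').

    'all' sums every X-linked gene (including PAR and unclassified genes);
    the class-restricted variants share the same autosomal denominator, so
    the classes decompose the overall ratio exactly. A cell with zero
    autosomal counts yields NaN (flagged missing, never a silent 0).
    """
    if gene_class not in GENE_CLASSES:
        raise ValueError(f"gene_class must be one of {GENE_CLASSES}")
    chrom = m.genes["chromosome"].astype(str)
    auto = chrom.isin(AUTOSOMES).to_numpy()
    on_x = (chrom == "X").to_numpy()
    if gene_class == "all":
        num_mask = on_x
    else:
        num_mask = on_x & (m.genes["xci_status"] == gene_class).to_numpy()
    if exclude_xist:
        num_mask = num_mask & (m.genes["symbol"] != "XIST").to_numpy()
    num = np.asarray(m.counts[:, num_mask].sum(axis=1), dtype=float).ravel()
    den = np.asarray(m.counts[:, auto].sum(axis=1), dtype=float).ravel()
    out = np.full(m.n_cells, np.nan)
    ok = den > 0
    if (~ok).any():
        logger.warning("%d cells have zero autosomal counts; X/A ratio set to NaN", int((~ok).sum()))
    out[ok] = num[ok] / den[ok]
    return out


def classify_xist_status(
    m: AnnotatedCountMatrix, xist_gene: str = "XIST", min_count: int = 1
) -> pd.Series:
    """Per-cell XIST status: XY cells -> 'XY'; XX cells -> XISTpos when the
    raw XIST count is >= min_count, else XISTneg."""
    hit = np.flatnonzero(
        (m.gene_ids == xist_gene) | (m.genes["symbol"] == xist_gene).to_numpy()
    )
    if len(hit) == 0:
        raise ValueError(f"{xist_gene} absent from the annotation; cannot stratify")
    xist_counts = np.asarray(m.counts[:, hit[0]].todense()).ravel()
    sex = m.cell_meta["sex"].to_numpy()
    status = np.where(sex == "XY", "XY", np.where(xist_counts >= min_count, "XISTpos", "XISTneg"))
    return pd.Series(status, index=m.cell_ids, name="xist_status")


def compute_xci_profile(
    m: AnnotatedCountMatrix,
    xist_gene: str = "XIST",
    xist_min_count: int = 1,
    exclude_xist: bool = False,
) -> pd.DataFrame:
    """Per-cell XCI profile: class-stratified X/A ratios plus XIST status.

    ``x_dup_proportion`` starts as NaN and is filled by the relative-dosage
    stage; ``xaxa_call`` starts as 'not_applicable' and is filled by the
    classifier.
    """
    profile = pd.DataFrame(index=m.cell_ids)
    profile["sample_id"] = m.cell_meta["sample_id"].to_numpy()
    profile["sex"] = m.cell_meta["sex"].to_numpy()
    if "broad_lineage" in m.cell_meta:
        profile["broad_lineage"] = m.cell_meta["broad_lineage"].to_numpy()
    if "cell_type" in m.cell_meta:
        profile["cell_type"] = m.cell_meta["cell_type"].to_numpy()
    profile["xa_ratio_all"] = xa_ratio(m, "all", exclude_xist=exclude_xist)
    profile["xa_ratio_inactivated"] = xa_ratio(m, "inactivated")
    profile["xa_ratio_escapee"] = xa_ratio(m, "escapee")
    profile["xist_status"] = classify_xist_status(m, xist_gene, xist_min_count)
    profile["x_dup_proportion"] = np.nan
    profile["xaxa_call"] = "not_applicable"
    return profile


def summarize_by_group(
    profile: pd.DataFrame,
    gene_classes: tuple = ("all", "inactivated", "escapee"),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Group central values of the X/A ratios and rank-sum contrasts vs XY.

    Groups are the XIST statuses (XISTpos/XISTneg XX cells and XY cells).
    Both mean and median are reported per (group, gene_class). The contrasts
    XISTpos-vs-XY and XISTneg-vs-XY use a two-sided Wilcoxon rank-sum test;
    groups with fewer than 2 cells are skipped with a warning.
    """
    col_of = {
        "all": "xa_ratio_all",
        "inactivated": "xa_ratio_inactivated",
        "escapee": "xa_ratio_escapee",
    }
    summary_rows, test_rows = [], []
    for cls in gene_classes:
        col = col_of[cls]
        for status in XIST_STATUSES:
            vals = profile.loc[profile["xist_status"] == status, col].dropna()
            summary_rows.append(
                (cls, status, len(vals), float(vals.mean()) if len(vals) else np.nan,
                 float(vals.median()) if len(vals) else np.nan)
            )
        for status in ("XISTpos", "XISTneg"):
            a = profile.loc[profile["xist_status"] == status, col].dropna()
            b = profile.loc[profile["xist_status"] == "XY", col].dropna()
            if len(a) < 2 or len(b) < 2:
                logger.warning("contrast %s vs XY skipped (<2 cells in a group)", status)
                continue
            stat, p = mannwhitneyu(a, b, alternative="two-sided")
            test_rows.append((cls, f"{status}_vs_XY", len(a), len(b), float(stat), float(p)))
    summary = pd.DataFrame(
        summary_rows, columns=["gene_class", "group", "n_cells", "mean", "median"]
    )
    tests = pd.DataFrame(
        test_rows, columns=["gene_class", "contrast", "n_a", "n_b", "statistic", "p_value"]
    )
    return summary, tests
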