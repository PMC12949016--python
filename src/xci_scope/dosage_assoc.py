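"""Per-gene association with X dosage and rank-based gene-set scoring.

Treats the per-cell X/A ratio as a continuous dosage covariate and computes
a tie-corrected Spearman correlation per gene against log-normalized
expression, with BH-adjusted p-values and Storey q-values; the run can
exclude X-linked genes so dosage-responsive autosomal programs can be read
without the trivial self-correlation of the numerator. Gene-set activity per
cell is scored with a rank-sum (Mann-Whitney U) statistic over capped
expression ranks, which is invariant to any monotone transform of a cell's
expression values.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu, rankdata, t as t_dist
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger("xci_scope")


# ---------------------------------------------------------------------------
# Spearman correlation with dosage
# ---------------------------------------------------------------------------


def storey_qvalues(p: np.ndarray, lam: float = 0.5) -> np.ndarray:
    """Storey q-values with the single-lambda pi0 estimator.

    pi0 = min(1, #{p > lam} / (m (1 - lam))); q_(i) = min over j>=i of
    pi0 * m * p_(j) / j.
    """
    p = np.asarray(p, dtype=float)
    m = p.size
    if m == 0:
        return p
    pi0 = min(1.0, (p > lam).sum() / (m * (1.0 - lam)))
    order = np.argsort(p)
    ranked = p[order]
    q = pi0 * m * ranked / np.arange(1, m + 1)
    q = np.minimum.accumulate(q[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(q, 1.0)
    return out


def correlate_with_dosage(
    normalized,
    genes: pd.DataFrame,
    xa_ratios: np.ndarray,
    include_x_genes: bool = True,
) -> pd.DataFrame:
    """Tie-corrected Spearman rho of each gene's log-normalized expression
    against the per-cell X/A ratio.

    Cells with a missing ratio are dropped (complete observations). Constant
    genes carry missing rho and are excluded from the BH adjustment and the
    q-value computation. The result is sorted by descending |rho|. Excluding
    X genes removes chromosome-X rows without altering any autosomal gene's
    statistic.
    """
    ratios = np.asarray(xa_ratios, dtype=float)
    ok = ~np.isnan(ratios)
    if ok.sum() < 3:
        raise ValueError("need at least 3 cells with a defined X/A ratio")
    dense = normalized[ok].toarray() if hasattr(normalized, "toarray") else np.asarray(normalized)[ok]
    genes = genes.copy()
    if not include_x_genes:
        keep = (genes["chromosome"].astype(str) != "X").to_numpy()
        dense, genes = dense[:, keep], genes.loc[keep]
    n = dense.shape[0]

    rx = rankdata(ratios[ok])
    rg = rankdata(dense, axis=0)
    rx = (rx - rx.mean()) / rx.std()
    sd = rg.std(axis=0)
    constant = sd == 0
    rg = rg - rg.mean(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = (rg * rx[:, None]).mean(axis=0) / np.where(constant, np.nan, sd)
    rho = np.clip(rho, -1.0, 1.0)
    # two-sided p from the t approximation (as the classical test statistic)
    with np.errstate(invalid="ignore", divide="ignore"):
        tstat = rho * np.sqrt((n - 2) / np.maximum(1 - rho**2, 1e-300))
    p = 2.0 * t_dist.sf(np.abs(tstat), df=n - 2)

    res = pd.DataFrame(
        {
            "gene_id": genes.index,
            "symbol": genes["symbol"].to_numpy(),
            "chromosome": genes["chromosome"].astype(str).to_numpy(),
            "rho": rho,
            "p_value": np.where(constant, np.nan, p),
        }
    ).set_index("gene_id")
    res["p_adjusted"] = np.nan
    res["q_value"] = np.nan
    informative = ~res["p_value"].isna()
    if informative.any():
        pv = res.loc[informative, "p_value"].to_numpy()
        res.loc[informative, "p_adjusted"] = multipletests(pv, method="fdr_bh")[1]
        res.loc[informative, "q_value"] = storey_qvalues(pv)
    res["include_x_genes"] = include_x_genes
    return res.reindex(res["rho"].abs().sort_values(ascending=False, kind="mergesort").index)


# ---------------------------------------------------------------------------
# rank-based gene-set score
# ---------------------------------------------------------------------------


def signature_score(
    normalized,
    gene_ids: pd.Index,
    gene_set,
    r_max: int = 1500,
) -> pd.Series:
    """Per-cell gene-set activity from capped expression ranks.

    Genes are ranked per cell by descending expression (average ranks on
    ties); ranks beyond ``r_max`` are set to r_max + 1. With R the sum of the
    set genes' capped ranks and n_s the set size, U' = R - n_s(n_s+1)/2 and
    score = 1 - U'/(n_s * r_max), clipped to [0, 1]. A set occupying the top
    ranks scores 1; a set entirely beyond the ceiling scores 0. Depends only
    on within-cell ranks, hence invariant to monotone transforms.
    """
    gene_ids = pd.Index(gene_ids)
    set_idx = gene_ids.get_indexer(pd.Index(list(dict.fromkeys(gene_set))))
    set_idx = set_idx[set_idx >= 0]
    if len(set_idx) == 0:
        raise ValueError("gene set has empty intersection with the matrix genes")
    n_s = len(set_idx)
    dense = normalized.toarray() if hasattr(normalized, "toarray") else np.asarray(normalized)
    ranks = rankdata(-dense, axis=1, method="average")
    ranks = np.minimum(ranks, r_max + 1)
    r_sum = ranks[:, set_idx].sum(axis=1)
    u = r_sum - n_s * (n_s + 1) / 2.0
    score = 1.0 - u / (n_s * r_max)
    return pd.Series(np.clip(score, 0.0, 1.0), name="signature_score")


def compare_group_scores(
    scores: pd.Series,
    labels: pd.Series,
    stratify_by: pd.Series | None = None,
    group_a: str = "XaXa_like",
    group_b: str = "XaXi",
) -> pd.DataFrame:
    """Two-sided rank-sum test of score differences per stratum, BH across strata."""
    if stratify_by is None:
        stratify_by = pd.Series("all", index=scores.index)
    rows = []
    for stratum in sorted(stratify_by.unique()):
        in_s = stratify_by == stratum
        a = scores[in_s & (labels == group_a)].dropna()
        b = scores[in_s & (labels == group_b)].dropna()
        if len(a) < 2 or len(b) < 2:
            logger.warning("stratum %s skipped (<2 cells in a group)", stratum)
            continue
        stat, p = mannwhitneyu(a, b, alternative="two-sided")
        rows.append((stratum, len(a), len(b), float(a.median()), float(b.median()), float(stat), float(p)))
    res = pd.DataFrame(
        rows, columns=["stratum", "n_a", "n_b", "median_a", "median_b", "statistic", "p_value"]
    ).set_index("stratum")
    if len(res):
        res["p_adjusted"] = multipletests(res["p_value"].to_numpy(), method="fdr_bh")[1]
    return res
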