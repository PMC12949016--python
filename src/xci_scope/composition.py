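"""Cell-type composition statistics: KL bias score and permutation proportion test.

The bias score asks, for each cell type, how far its distribution across
samples departs from the overall distribution of cells across samples
(empirical KL divergence; 0 = perfectly proportional, ln(S) = concentrated
in one of S samples). The proportion test shuffles group labels over cells
to build the permutation null of the log2 proportional difference per cell
type, with the add-one p-value estimator, BH FDR across cell types, and a
bootstrap percentile confidence interval.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger("xci_scope")


def composition_table(
    cell_meta: pd.DataFrame, sample_col: str = "sample_id", type_col: str = "cell_type"
) -> pd.DataFrame:
    """Samples x cell-types count table from per-cell metadata."""
    t = pd.crosstab(cell_meta[sample_col], cell_meta[type_col])
    return t.loc[:, t.sum(axis=0) > 0]


# ---------------------------------------------------------------------------
# bias score
# ---------------------------------------------------------------------------


def bias_score(table: pd.DataFrame) -> pd.DataFrame:
    """Per-cell-type KL divergence between its sample distribution and the
    overall cell distribution across samples.

    For type k with n_ks cells in sample s: p_k(s) = n_ks / n_k and
    q(s) = n_s / n; kl_k = sum_s p_k(s) ln(p_k(s)/q(s)) with 0 ln 0 = 0.
    scaled_score = n_k * kl_k (weights abundant types); normalized_score =
    kl_k / ln(S) in [0, 1]. A type spread proportionally to sample sizes
    scores 0; a type confined to one of S equal samples scores ln(S).
    """
    counts = table.to_numpy(dtype=float)
    n_samples = counts.shape[0]
    if n_samples < 2:
        raise ValueError("bias score needs at least 2 samples")
    n = counts.sum()
    q = counts.sum(axis=1) / n
    out = []
    for j, ct in enumerate(table.columns):
        n_k = counts[:, j].sum()
        if n_k == 0:
            out.append((ct, 0, np.nan, np.nan, np.nan))
            continue
        p = counts[:, j] / n_k
        nz = p > 0
        kl = float(np.sum(p[nz] * np.log(p[nz] / q[nz])))
        out.append((ct, int(n_k), kl, n_k * kl, kl / np.log(n_samples)))
    return pd.DataFrame(
        out, columns=["cell_type", "n_cells", "kl_divergence", "scaled_score", "normalized_score"]
    ).set_index("cell_type")


# ---------------------------------------------------------------------------
# permutation proportion test
# ---------------------------------------------------------------------------


def _log2fd(counts_a, counts_b, n_a, n_b, pseudocount=0.5):
    """log2 proportional difference with a half-cell pseudocount (keeps
    zero-count types finite; applied symmetrically to both groups)."""
    k = counts_a.shape[-1]
    pa = (counts_a + pseudocount) / (n_a + pseudocount * k)
    pb = (counts_b + pseudocount) / (n_b + pseudocount * k)
    return np.log2(pa / pb)


def permutation_proportion_test(
    cell_meta: pd.DataFrame,
    group_a,
    group_b,
    sample_col: str = "sample_id",
    type_col: str = "cell_type",
    n_perm: int = 5000,
    n_boot: int = 5000,
    seed: int | None = None,
    fdr_alpha: float = 0.05,
    log2fd_cut: float = 1.0,
) -> pd.DataFrame:
    """Permutation test for differential cell-type proportions between two
    sample groups.

    ``group_a``/``group_b`` are collections of sample ids. Group labels are
    shuffled over the pooled cells (equivalently, the group-A type counts are
    multivariate-hypergeometric draws from the pooled composition). The
    two-sided p-value counts permuted |log2FD| >= |observed| with the
    (+1)/(+1) estimator, so the smallest attainable p is 1/(n_perm+1). FDR
    is Benjamini-Hochberg across cell types; the CI is the 2.5-97.5
    percentile range of bootstrap (cells resampled with replacement within
    each group) log2FDs. 'significant' flags fdr < 0.05 and |log2FD| > 1.
    """
    rng = np.random.default_rng(seed)
    in_a = cell_meta[sample_col].isin(list(group_a))
    in_b = cell_meta[sample_col].isin(list(group_b))
    if not in_a.any() or not in_b.any():
        raise ValueError("both groups must contain at least one cell")
    types = sorted(set(cell_meta.loc[in_a | in_b, type_col]))
    counts_a = (
        cell_meta.loc[in_a, type_col].value_counts().reindex(types, fill_value=0).to_numpy(float)
    )
    counts_b = (
        cell_meta.loc[in_b, type_col].value_counts().reindex(types, fill_value=0).to_numpy(float)
    )
    n_a, n_b = counts_a.sum(), counts_b.sum()
    pooled = (counts_a + counts_b).astype(int)

    observed = _log2fd(counts_a, counts_b, n_a, n_b)

    perm_a = rng.multivariate_hypergeometric(pooled, int(n_a), size=n_perm).astype(float)
    perm_b = pooled[None, :] - perm_a
    perm_fd = _log2fd(perm_a, perm_b, n_a, n_b)
    exceed = (np.abs(perm_fd) >= np.abs(observed)[None, :]).sum(axis=0)
    p = (exceed + 1) / (n_perm + 1)

    boot_a = rng.multinomial(int(n_a), counts_a / n_a, size=n_boot).astype(float)
    boot_b = rng.multinomial(int(n_b), counts_b / n_b, size=n_boot).astype(float)
    boot_fd = _log2fd(boot_a, boot_b, n_a, n_b)
    ci_low = np.percentile(boot_fd, 2.5, axis=0)
    ci_high = np.percentile(boot_fd, 97.5, axis=0)

    fdr = multipletests(p, method="fdr_bh")[1]
    res = pd.DataFrame(
        {
            "cell_type": types,
            "count_a": counts_a.astype(int),
            "count_b": counts_b.astype(int),
            "observed_log2FD": observed,
            "p_value": p,
            "fdr": fdr,
            "ci_low": ci_low,
            "ci_high": ci_high,
            "n_permutations": n_perm,
            "n_bootstraps": n_boot,
        }
    ).set_index("cell_type")
    res["significant"] = (res["fdr"] < fdr_alpha) & (res["observed_log2FD"].abs() > log2fd_cut)
    return res
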