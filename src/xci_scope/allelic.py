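"""Allele-specific expression from per-cell SNP counts.

Consumes the cellsnp-lite style layout (base VCF + sparse AD/DP matrices),
maps SNPs to genes by coordinate containment, filters on aggregate depth and
minor-allele fraction, and calls biallelic vs monoallelic expression per
(cell, gene). A cell showing reads from both alleles of a normally
inactivated X gene carries two active X's (reactivation / XCI failure); a
cell with doubled dosage but monoallelic reads carries a duplicated Xa.
XIST allele sharing across XIST+ cells of one sample probes whether they
silence a common X (clonality). The 2x2 association of XaXa-like vs XaXi
classification with biallelic vs monoallelic calls is tested with a Yates
continuity-corrected chi-square.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.io import mmread
from scipy.stats import chi2

logger = logging.getLogger("xci_scope")

REGION_CLASSES = (
    "exonic",
    "intronic",
    "UTR",
    "splicing",
    "ncRNA_exonic",
    "ncRNA_intronic",
    "intergenic",
)


@dataclass
class AllelicCountSet:
    """Per-SNP x per-cell alternate (AD) and total (DP) read depths.

    ``snps`` has columns chromosome, position (1-based), ref_allele,
    alt_allele, gene_id (may be NA before gene assignment; "MULTI" marks
    SNPs contained in more than one gene) and region_class.
    """

    snps: pd.DataFrame
    alt_depth: sp.csr_matrix
    total_depth: sp.csr_matrix
    cell_ids: pd.Index

    def __post_init__(self):
        self.alt_depth = sp.csr_matrix(self.alt_depth)
        self.total_depth = sp.csr_matrix(self.total_depth)
        if self.alt_depth.shape != self.total_depth.shape:
            raise ValueError("AD and DP matrices must have identical shapes")
        if self.alt_depth.shape != (len(self.snps), len(self.cell_ids)):
            raise ValueError(
                f"matrices are {self.alt_depth.shape} but there are "
                f"{len(self.snps)} SNPs and {len(self.cell_ids)} cells"
            )
        if (self.alt_depth > self.total_depth).nnz:
            raise ValueError("corrupt input: AD exceeds DP somewhere")

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    def subset_snps(self, mask) -> "AllelicCountSet":
        idx = np.flatnonzero(mask) if np.asarray(mask).dtype == bool else np.asarray(mask)
        return AllelicCountSet(
            snps=self.snps.iloc[idx].reset_index(drop=True),
            alt_depth=self.alt_depth[idx],
            total_depth=self.total_depth[idx],
            cell_ids=self.cell_ids,
        )


# ---------------------------------------------------------------------------
# reading & gene assignment
# ---------------------------------------------------------------------------


def read_allelic_counts(vcf_path, ad_matrix_path, dp_matrix_path, barcodes_path) -> AllelicCountSet:
    """Read a cellsnp-lite style output (VCF + AD/DP MTX + barcodes).

    Multi-allelic VCF records are skipped (their matrix rows are dropped with
    a logged count). AD > DP anywhere is a hard error.
    """
    import pysam

    from .core_io import _open_text

    with _open_text(ad_matrix_path, "rb") as fh:
        ad = sp.csr_matrix(mmread(fh))
    with _open_text(dp_matrix_path, "rb") as fh:
        dp = sp.csr_matrix(mmread(fh))
    barcodes = pd.read_csv(barcodes_path, sep="\t", header=None)[0].astype(str)

    rows, keep = [], []
    n_records = 0
    with pysam.VariantFile(str(vcf_path)) as vcf:
        for i, rec in enumerate(vcf.fetch()):
            n_records += 1
            alts = rec.alts or ()
            if len(alts) != 1 or len(rec.ref) != 1 or len(alts[0]) != 1:
                continue
            rows.append((str(rec.chrom), int(rec.pos), rec.ref, alts[0], pd.NA, "exonic"))
            keep.append(i)
    n_skipped = n_records - len(keep)
    if n_skipped:
        logger.info("skipped %d multi-allelic/non-SNP VCF records", n_skipped)
    if n_records != ad.shape[0]:
        raise ValueError(
            f"{vcf_path}: {n_records} VCF records but AD matrix has {ad.shape[0]} rows"
        )
    if ad.shape[1] != len(barcodes):
        raise ValueError(
            f"{barcodes_path}: {len(barcodes)} barcodes but matrices have {ad.shape[1]} columns"
        )
    snps = pd.DataFrame(
        rows, columns=["chromosome", "position", "ref_allele", "alt_allele", "gene_id", "region_class"]
    )
    keep = np.asarray(keep, dtype=int)
    return AllelicCountSet(
        snps=snps,
        alt_depth=ad[keep],
        total_depth=dp[keep],
        cell_ids=pd.Index(barcodes.values, name="barcode"),
    )


def map_snps_to_genes(s: AllelicCountSet, genes: pd.DataFrame) -> AllelicCountSet:
    """Assign each SNP to the gene whose interval contains it (1-based inclusive).

    SNPs falling in more than one gene get gene_id="MULTI" and are removed by
    :func:`filter_snps`; SNPs outside every gene keep a missing gene_id.
    """
    out = s.snps.copy()
    assigned = []
    for chrom, pos in zip(out["chromosome"].astype(str), out["position"]):
        sub = genes[(genes["chromosome"].astype(str) == chrom)]
        hits = sub[(sub["start"] <= pos) & (pos <= sub["end"])]
        if len(hits) == 0:
            assigned.append(pd.NA)
        elif len(hits) == 1:
            assigned.append(hits.index[0])
        else:
            assigned.append("MULTI")
    out["gene_id"] = assigned
    n_multi = int((out["gene_id"] == "MULTI").sum())
    if n_multi:
        logger.info("%d SNPs contained in multiple genes (flagged MULTI)", n_multi)
    return AllelicCountSet(
        snps=out, alt_depth=s.alt_depth, total_depth=s.total_depth, cell_ids=s.cell_ids
    )


# ---------------------------------------------------------------------------
# filtering
# ---------------------------------------------------------------------------


def filter_snps(s: AllelicCountSet, min_count: int = 20, min_maf: float = 0.05) -> AllelicCountSet:
    """Keep SNPs with aggregate depth >= min_count, aggregate minor-allele
    fraction >= min_maf, and an unambiguous single-gene assignment."""
    dp_tot = np.asarray(s.total_depth.sum(axis=1)).ravel()
    ad_tot = np.asarray(s.alt_depth.sum(axis=1)).ravel()
    with np.errstate(invalid="ignore", divide="ignore"):
        maf = np.where(dp_tot > 0, np.minimum(ad_tot, dp_tot - ad_tot) / np.maximum(dp_tot, 1), 0.0)
    gene_ok = s.snps["gene_id"].notna() & (s.snps["gene_id"] != "MULTI")
    keep = (dp_tot >= min_count) & (maf >= min_maf) & gene_ok.to_numpy()
    return s.subset_snps(keep)


# ---------------------------------------------------------------------------
# biallelic / monoallelic calling
# ---------------------------------------------------------------------------


class AllelicCallTable(NamedTuple):
    """Gene-level and cell-aggregate biallelic/monoallelic calls."""

    gene_calls: pd.DataFrame  # columns: cell_id, gene_id, call, expressed_allele
    cell_calls: pd.Series  # index cell_id -> {biallelic, monoallelic, uninformative}


def aggregate_gene_calls(calls, rule: str = "majority") -> str:
    """Collapse a cell's informative gene calls into one label.

    ``majority``: majority vote, ties -> biallelic. ``any``: biallelic if any
    gene is. ``all``: biallelic only if every informative gene is.
    """
    calls = [c for c in calls if c != "uninformative"]
    if not calls:
        return "uninformative"
    n_bi = sum(c == "biallelic" for c in calls)
    n_mono = len(calls) - n_bi
    if rule == "majority":
        return "biallelic" if n_bi >= n_mono else "monoallelic"
    if rule == "any":
        return "biallelic" if n_bi > 0 else "monoallelic"
    if rule == "all":
        return "biallelic" if n_mono == 0 else "monoallelic"
    raise ValueError(f"unknown aggregation rule {rule!r}")


def call_allelic_expression(
    s: AllelicCountSet,
    genes: pd.DataFrame,
    gene_class: str = "inactivated",
    min_reads_per_allele: int = 1,
    cells: pd.Index | None = None,
    rule: str = "majority",
) -> AllelicCallTable:
    """Call biallelic vs monoallelic expression per (cell, gene).

    A gene is biallelic in a cell when some single SNP shows at least
    ``min_reads_per_allele`` reads on *both* alleles; monoallelic when the
    gene has >=2 reads, all on one allele per SNP; uninformative otherwise.
    The per-cell aggregate is a majority vote over informative genes with
    ties resolved to biallelic (configurable via ``rule``).
    """
    if gene_class == "all_X":
        wanted = genes.index[genes["chromosome"].astype(str) == "X"]
    elif gene_class in ("inactivated", "escapee"):
        wanted = genes.index[genes["xci_status"] == gene_class]
    else:
        raise ValueError("gene_class must be one of 'inactivated', 'escapee', 'all_X'")
    snp_mask = s.snps["gene_id"].isin(wanted).to_numpy()
    sub = s.subset_snps(snp_mask)
    if sub.n_snps == 0:
        logger.warning("no SNPs map to %s genes; empty call table", gene_class)
        return AllelicCallTable(
            gene_calls=pd.DataFrame(columns=["cell_id", "gene_id", "call", "expressed_allele"]),
            cell_calls=pd.Series(dtype=object),
        )

    ad = sub.alt_depth.toarray()
    dp = sub.total_depth.toarray()
    ref = dp - ad
    cell_index = sub.cell_ids
    col_sel = np.arange(len(cell_index)) if cells is None else cell_index.get_indexer(cells)

    records = []
    gene_ids = sub.snps["gene_id"].to_numpy()
    for gid in pd.unique(gene_ids):
        rows = np.flatnonzero(gene_ids == gid)
        a, r, d = ad[rows][:, col_sel], ref[rows][:, col_sel], dp[rows][:, col_sel]
        both = ((a >= min_reads_per_allele) & (r >= min_reads_per_allele)).any(axis=0)
        total = d.sum(axis=0)
        per_snp_mono = (a == 0) | (r == 0)
        mono = (~both) & (total >= 2) & per_snp_mono.all(axis=0)
        a_tot, r_tot = a.sum(axis=0), r.sum(axis=0)
        for j in np.flatnonzero(both | mono):
            if both[j]:
                call, allele = "biallelic", "both"
            else:
                call = "monoallelic"
                allele = "alt" if a_tot[j] > 0 else "ref"
            records.append((cell_index[col_sel[j]], gid, call, allele))
    gene_calls = pd.DataFrame(records, columns=["cell_id", "gene_id", "call", "expressed_allele"])
    if gene_calls.empty:
        logger.warning("no informative (cell, gene) pairs for class %s", gene_class)
        return AllelicCallTable(gene_calls=gene_calls, cell_calls=pd.Series(dtype=object))
    cell_calls = gene_calls.groupby("cell_id")["call"].apply(lambda c: aggregate_gene_calls(c, rule))
    return AllelicCallTable(gene_calls=gene_calls, cell_calls=cell_calls)


# ---------------------------------------------------------------------------
# XIST allele sharing
# ---------------------------------------------------------------------------


def xist_allele_sharing(
    s: AllelicCountSet,
    profile: pd.DataFrame,
    xist_gene: str = "XIST",
) -> pd.DataFrame:
    """Per-sample fraction of XIST+ cells expressing the sample-majority XIST allele.

    For each XIST SNP and XIST-positive cell the expressed allele is ref, alt
    or both; per sample, all single-allele (cell, SNP) observations are
    compared to that SNP's within-sample majority allele. A fraction near 1
    means the sample's XaXi cells silence a shared X. Cells observed with
    both alleles count against sharing. Returns one row per sample with
    n_informative and sharing_fraction (NaN when not evaluable).
    """
    xist_rows = np.flatnonzero((s.snps["gene_id"] == xist_gene).to_numpy())
    samples = profile["sample_id"].unique()
    if len(xist_rows) == 0:
        logger.warning("no XIST SNPs passed filtering; sharing not evaluable")
        return pd.DataFrame(
            {"sample_id": samples, "n_informative": 0, "sharing_fraction": np.nan}
        )
    ad = s.alt_depth[xist_rows].toarray()
    dp = s.total_depth[xist_rows].toarray()
    ref = dp - ad
    pos = s.cell_ids.get_indexer(profile.index)
    rows_out = []
    for sid in samples:
        in_sample = (profile["sample_id"] == sid).to_numpy() & (
            profile["xist_status"] == "XISTpos"
        ).to_numpy()
        cols = pos[in_sample]
        cols = cols[cols >= 0]
        if len(cols) == 0:
            rows_out.append((sid, 0, np.nan))
            continue
        a, r = ad[:, cols], ref[:, cols]
        is_alt = (a > 0) & (r == 0)
        is_ref = (r > 0) & (a == 0)
        is_both = (a > 0) & (r > 0)
        n_obs = int(is_alt.sum() + is_ref.sum() + is_both.sum())
        if n_obs == 0:
            rows_out.append((sid, 0, np.nan))
            continue
        # per-SNP majority among single-allele observations
        agree = 0
        for k in range(a.shape[0]):
            n_alt, n_ref = int(is_alt[k].sum()), int(is_ref[k].sum())
            agree += max(n_alt, n_ref)
        rows_out.append((sid, n_obs, agree / n_obs))
    return pd.DataFrame(rows_out, columns=["sample_id", "n_informative", "sharing_fraction"])


# ---------------------------------------------------------------------------
# Yates chi-square
# ---------------------------------------------------------------------------


class ContingencyResult(NamedTuple):
    chi2_yates: float
    p_two_sided: float


def contingency_test(table) -> ContingencyResult:
    """2x2 chi-square with Yates continuity correction.

    chi2 = N(|ad - bc| - N/2)^2 / (r1 r2 c1 c2), clipped at 0 when
    |ad - bc| <= N/2; p from the chi-square distribution with 1 df.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("table must be a non-negative 2x2 matrix")
    a, b, c, d = t.ravel()
    n = t.sum()
    r1, r2 = a + b, c + d
    c1, c2 = a + c, b + d
    if min(r1, r2, c1, c2) == 0:
        raise ValueError("contingency table has a zero margin")
    diff = abs(a * d - b * c)
    stat = 0.0 if diff <= n / 2 else n * (diff - n / 2) ** 2 / (r1 * r2 * c1 * c2)
    return ContingencyResult(chi2_yates=float(stat), p_two_sided=float(chi2.sf(stat, df=1)))
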