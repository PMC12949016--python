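"""Synthetic multi-sample snRNA-seq cohorts with known XCI ground truth.

The generator emulates the cohort structure the analysis is built for: a few
tumor samples, each a mixture of broad lineages, where XX cells are XaXi
(normal XCI; XIST+ and monoallelic for inactivated X genes), XaXa-reactivated
(XIST-, biallelic, ~2x dosage of inactivated X genes), or Xa-duplicated
(XIST-, monoallelic at doubled depth). Immune and endothelial lineages stay
XaXi, mirroring their infiltrative origin in teratomas, and XaXi cells within
a sample share one inactive X (clonality).

Counts are negative binomial (Gamma-Poisson) with per-entry Bernoulli
dropout. Per-gene baseline means are Gamma-distributed; X-linked gene means
are scaled so the expected XaXi X-to-autosome ratio matches ``xa_ratio_target``
(default 0.029, the XIST-positive level observed in tumors), which places the
XaXa-like population on the far side of the 0.036 classification boundary.
Escapee genes run at ``escapee_xx_factor`` (default 4/3) of the XY level in
every XX cell regardless of XCI state, so escapee dosage is invariant across
groups.

Allelic truth: every simulated X SNP is heterozygous in XX donors with
independent per-donor phase (which haplotype carries the alternate allele);
XY donors are hemizygous, so all their reads fall on one allele. Read depths
are Poisson at ``allelic_depth_mean`` scaled by the cell's dosage state, with
a per-SNP-per-cell coverage Bernoulli (UMI capture is shallow) and a small
allele-error rate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .core_io import (
    AnnotatedCountMatrix,
    write_annotation,
    write_cell_meta,
    write_count_matrix,
    _open_text,
)
from .allelic import AllelicCountSet

logger = logging.getLogger("xci_scope")

XCI_STATES = ("XY", "XaXi", "XaXa_reactivated", "Xa_duplicated")

#: default cell types and the broad lineage each belongs to
DEFAULT_CELL_TYPES = {
    "fibroblast": "stroma",
    "epithelial": "epithelia",
    "neuron": "neuroectoderm",
    "endothelial": "endothelia",
    "macrophage": "immune",
    "T_cell": "immune",
}

# GRCh38 pseudoautosomal intervals on X (1-based inclusive)
PAR1 = (10_001, 2_781_479)
PAR2 = (155_701_383, 156_030_895)
XIST_LOCUS = (73_820_651, 73_852_753)


@dataclass
class SimulationConfig:
    """Knobs of the cohort generator; defaults define the reference cohort."""

    n_samples: int = 3
    cells_per_sample: tuple = (2000, 2000, 1000)
    sex_per_sample: tuple = ("XX", "XX", "XY")
    cell_types: tuple = tuple(DEFAULT_CELL_TYPES)
    cell_type_proportions: tuple = (
        (0.30, 0.25, 0.15, 0.10, 0.12, 0.08),
        (0.20, 0.15, 0.30, 0.10, 0.15, 0.10),
        (0.25, 0.20, 0.20, 0.15, 0.12, 0.08),
    )
    xaxa_fraction_per_lineage: dict = field(
        default_factory=lambda: {
            "stroma": 0.35,
            "epithelia": 0.35,
            "neuroectoderm": 0.35,
            "endothelia": 0.0,
            "immune": 0.0,
        }
    )
    xa_dup_fraction: float = 0.05
    samples_with_xaxa: tuple | None = None  # default: every XX sample
    n_autosomal_genes: int = 2000
    n_inactivated_X: int = 300
    n_escapee_X: int = 60
    n_PAR_genes: int = 20
    baseline_mean: float = 2.0
    nb_dispersion: float = 2.0  # NB size; variance = m + m^2/size
    dosage_multiplier: float = 2.0
    escapee_xx_factor: float = 4.0 / 3.0
    xa_ratio_target: float = 0.029
    xist_mean_xaxi: float = 5.0
    dropout_rate: float = 0.1
    n_snps_per_X_gene: int = 2
    n_snps_xist: int = 6
    allelic_depth_mean: float = 5.0
    snp_coverage_rate: float = 0.25
    allelic_error_rate: float = 0.005
    seed: int = 0

    def __post_init__(self):
        if not (len(self.cells_per_sample) == len(self.sex_per_sample) == self.n_samples):
            raise ValueError("cells_per_sample and sex_per_sample must have n_samples entries")
        if len(self.cell_type_proportions) != self.n_samples:
            raise ValueError("cell_type_proportions must have one vector per sample")
        for props in self.cell_type_proportions:
            if len(props) != len(self.cell_types):
                raise ValueError("each proportion vector must cover every cell type")
            if abs(sum(props) - 1.0) > 1e-9:
                raise ValueError("cell type proportions must sum to 1")
        for frac in list(self.xaxa_fraction_per_lineage.values()) + [
            self.xa_dup_fraction,
            self.dropout_rate,
            self.snp_coverage_rate,
            self.allelic_error_rate,
        ]:
            if not 0.0 <= frac <= 1.0:
                raise ValueError("fractions must lie in [0, 1]")
        if any(s not in ("XX", "XY") for s in self.sex_per_sample):
            raise ValueError("sex_per_sample entries must be 'XX' or 'XY'")
        if self.samples_with_xaxa is not None:
            xx = {i for i, s in enumerate(self.sex_per_sample) if s == "XX"}
            bad = set(self.samples_with_xaxa) - xx
            if bad and any(self.xaxa_fraction_per_lineage.values()):
                raise ValueError(
                    f"samples {sorted(bad)} are XY and cannot carry XaXa-reactivated cells"
                )

    @property
    def sample_ids(self):
        return [f"S{i + 1:02d}" for i in range(self.n_samples)]


@dataclass
class Cohort:
    """Bundle returned by :func:`simulate_cohort`."""

    matrix: AnnotatedCountMatrix
    allelic: AllelicCountSet
    truth: pd.DataFrame
    config: SimulationConfig


# ---------------------------------------------------------------------------
# gene panel
# ---------------------------------------------------------------------------


def build_gene_table(cfg: SimulationConfig) -> pd.DataFrame:
    """Gene annotation of the synthetic genome: autosomes 1-22 plus X."""
    rows = []
    per_chrom = int(np.ceil(cfg.n_autosomal_genes / 22))
    g = 0
    for chrom in range(1, 23):
        for j in range(per_chrom):
            if g >= cfg.n_autosomal_genes:
                break
            start = 100_000 + j * 100_000
            rows.append((f"AUTO{g:05d}", f"A{g:05d}", str(chrom), start, start + 20_000, "not_X"))
            g += 1
    # PAR genes: half in PAR1, half in PAR2
    n_par1 = cfg.n_PAR_genes // 2
    for j in range(cfg.n_PAR_genes):
        if j < n_par1:
            start = PAR1[0] + 10_000 + j * 50_000
        else:
            start = PAR2[0] + 5_000 + (j - n_par1) * 20_000
        rows.append((f"PARX{j:04d}", f"P{j:04d}", "X", start, start + 10_000, "PAR"))
    # non-PAR X genes interleave inactivated and escapee along the chromosome
    n_x = cfg.n_inactivated_X + cfg.n_escapee_X
    statuses = ["inactivated"] * cfg.n_inactivated_X + ["escapee"] * cfg.n_escapee_X
    rng = np.random.default_rng(cfg.seed + 101)
    order = rng.permutation(n_x)
    span_start, span_end = 3_000_000, 150_000_000
    step = (span_end - span_start) // max(n_x, 1)
    i_in = i_es = 0
    for j in range(n_x):
        status = statuses[order[j]]
        start = span_start + j * step
        if start < XIST_LOCUS[1] and start + 20_000 > XIST_LOCUS[0]:
            start = XIST_LOCUS[1] + 10_000  # keep clear of the XIST locus
        if status == "inactivated":
            gid, sym = f"XIN{i_in:04d}", f"XI{i_in:04d}"
            i_in += 1
        else:
            gid, sym = f"XES{i_es:04d}", f"XE{i_es:04d}"
            i_es += 1
        rows.append((gid, sym, "X", start, start + 20_000, status))
    rows.append(("XIST", "XIST", "X", XIST_LOCUS[0], XIST_LOCUS[1], "unclassified"))
    genes = pd.DataFrame(
        rows, columns=["gene_id", "symbol", "chromosome", "start", "end", "xci_status"]
    ).set_index("gene_id")
    return genes


# ---------------------------------------------------------------------------
# cohort simulation
# ---------------------------------------------------------------------------


def _assign_states(cfg: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Per-cell truth table (sample, sex, cell type, lineage, XCI state, haplotypes)."""
    lineage_of = dict(zip(cfg.cell_types, [DEFAULT_CELL_TYPES.get(t, "stroma") for t in cfg.cell_types]))
    # honor explicit lineage mapping when default cell types are used
    lineage_of.update({t: l for t, l in DEFAULT_CELL_TYPES.items() if t in cfg.cell_types})
    xaxa_samples = (
        set(cfg.samples_with_xaxa)
        if cfg.samples_with_xaxa is not None
        else {i for i, s in enumerate(cfg.sex_per_sample) if s == "XX"}
    )
    records = []
    for s_idx, (sid, n, sex, props) in enumerate(
        zip(cfg.sample_ids, cfg.cells_per_sample, cfg.sex_per_sample, cfg.cell_type_proportions)
    ):
        types = rng.choice(len(cfg.cell_types), size=n, p=np.asarray(props, dtype=float))
        # shared inactive X within the sample (clonality assumption)
        xi_hap = rng.choice(["A", "B"])
        xa_hap = "B" if xi_hap == "A" else "A"
        for c in range(n):
            ct = cfg.cell_types[types[c]]
            lin = lineage_of[ct]
            if sex == "XY":
                state, inact, active = "XY", None, "A"
            else:
                p_xaxa = cfg.xaxa_fraction_per_lineage.get(lin, 0.0) if s_idx in xaxa_samples else 0.0
                p_dup = cfg.xa_dup_fraction if (s_idx in xaxa_samples and p_xaxa > 0) else 0.0
                u = rng.random()
                if u < p_xaxa:
                    state, inact, active = "XaXa_reactivated", None, "AB"
                elif u < p_xaxa + p_dup:
                    state, inact, active = "Xa_duplicated", None, xa_hap
                else:
                    state, inact, active = "XaXi", xi_hap, xa_hap
            records.append((f"{sid}_c{c:05d}", sid, sex, ct, lin, state, inact, active))
    truth = pd.DataFrame.from_records(
        records,
        columns=[
            "cell_id",
            "sample_id",
            "sex",
            "cell_type",
            "broad_lineage",
            "xci_state",
            "inactive_hap",
            "active_hap",
        ],
    ).set_index("cell_id")
    return truth


def _dosage_factors(genes: pd.DataFrame, truth: pd.DataFrame, cfg: SimulationConfig) -> np.ndarray:
    """cells x genes multiplicative dosage factors encoding the XCI state."""
    n_cells, n_genes = len(truth), len(genes)
    status = genes["xci_status"].to_numpy()
    is_inact = status == "inactivated"
    is_esc = status == "escapee"
    is_par = status == "PAR"
    is_xist = genes.index.to_numpy() == "XIST"

    fac = np.ones((n_cells, n_genes))
    state = truth["xci_state"].to_numpy()
    esc = cfg.escapee_xx_factor
    dup = cfg.dosage_multiplier
    for st, (f_in, f_es, f_par) in {
        "XY": (1.0, 1.0, 1.0),
        "XaXi": (1.0, esc, 1.0),
        "XaXa_reactivated": (dup, esc, 1.0),
        "Xa_duplicated": (dup, 2.0, 1.5),
    }.items():
        rows = state == st
        if not rows.any():
            continue
        fac[np.ix_(rows, is_inact)] = f_in
        fac[np.ix_(rows, is_esc)] = f_es
        fac[np.ix_(rows, is_par)] = f_par
    fac[:, is_xist] = 0.0  # XIST handled through its own mean below
    return fac


def simulate_cohort(cfg: SimulationConfig) -> Cohort:
    """Draw a full cohort (counts, allelic counts, truth) from the configuration."""
    rng = np.random.default_rng(cfg.seed)
    genes = build_gene_table(cfg)
    truth = _assign_states(cfg, rng)

    status = genes["xci_status"].to_numpy()
    is_auto = ~(genes["chromosome"] == "X").to_numpy()
    is_xist = genes.index.to_numpy() == "XIST"

    base = rng.gamma(shape=2.0, scale=cfg.baseline_mean / 2.0, size=len(genes))
    base = np.maximum(base, 0.05 * cfg.baseline_mean)
    # calibrate X-linked means so the expected XaXi X/A ratio hits the target
    s_auto = base[is_auto].sum()
    w = np.where(status == "escapee", cfg.escapee_xx_factor, 1.0)
    s_x = (base * w)[(~is_auto) & (~is_xist)].sum()
    x_scale = (cfg.xa_ratio_target * s_auto - cfg.xist_mean_xaxi) / s_x
    if x_scale <= 0:
        raise ValueError("xa_ratio_target too small for the configured XIST mean")
    base[(~is_auto) & (~is_xist)] *= x_scale
    base[is_xist] = 1.0  # placeholder; XIST mean is state-dependent

    fac = _dosage_factors(genes, truth, cfg)
    mean = fac * base[None, :]
    mean[truth["xci_state"].to_numpy() == "XaXi", np.flatnonzero(is_xist)[0]] = cfg.xist_mean_xaxi

    lam = rng.gamma(shape=cfg.nb_dispersion, scale=np.maximum(mean, 1e-12) / cfg.nb_dispersion)
    counts = rng.poisson(lam).astype(np.int64)
    if cfg.dropout_rate > 0:
        counts[rng.random(counts.shape) < cfg.dropout_rate] = 0

    cell_meta = truth[["sample_id", "sex", "cell_type", "broad_lineage"]].copy()
    matrix = AnnotatedCountMatrix(
        counts=sp.csr_matrix(counts), cell_meta=cell_meta, genes=genes
    )
    allelic = _simulate_allelic(cfg, genes, truth, fac, rng)
    return Cohort(matrix=matrix, allelic=allelic, truth=truth, config=cfg)


def _simulate_allelic(cfg, genes, truth, fac, rng) -> AllelicCountSet:
    """Per-SNP x per-cell ref/alt depths at heterozygous X SNPs."""
    x_genes = genes[genes["chromosome"] == "X"]
    snp_rows = []
    for gid, rec in x_genes.iterrows():
        n_snps = cfg.n_snps_xist if gid == "XIST" else cfg.n_snps_per_X_gene
        span = max(rec["end"] - rec["start"], n_snps + 1)
        for k in range(n_snps):
            pos = int(rec["start"] + (k + 1) * span // (n_snps + 1))
            ref, alt = rng.choice(["A", "C", "G", "T"], size=2, replace=False)
            snp_rows.append((str(rec["chromosome"]), pos, ref, alt, gid, "exonic"))
    snps = pd.DataFrame(
        snp_rows, columns=["chromosome", "position", "ref_allele", "alt_allele", "gene_id", "region_class"]
    ).sort_values(["chromosome", "position"], kind="mergesort").reset_index(drop=True)

    n_snps, n_cells = len(snps), len(truth)
    gene_col = {g: j for j, g in enumerate(genes.index)}
    snp_gene_idx = snps["gene_id"].map(gene_col).to_numpy()

    # per-donor phase: True where haplotype A carries the alternate allele
    donors = list(dict.fromkeys(truth["sample_id"]))
    phase = {d: rng.random(n_snps) < 0.5 for d in donors}

    # expression factor per (cell, snp) from the dosage model; XIST uses its own mean
    is_xist_snp = (snps["gene_id"] == "XIST").to_numpy()
    depth_factor = fac[:, snp_gene_idx].T.copy()  # snps x cells
    xaxi_cells = (truth["xci_state"] == "XaXi").to_numpy()
    depth_factor[np.ix_(is_xist_snp, xaxi_cells)] = 1.0

    covered = rng.random((n_snps, n_cells)) < cfg.snp_coverage_rate
    dp = np.where(covered, rng.poisson(cfg.allelic_depth_mean * depth_factor), 0).astype(np.int64)

    # fraction of reads carrying haplotype A, per (snp, cell)
    state = truth["xci_state"].to_numpy()
    active = truth["active_hap"].to_numpy()
    p_hap_a = np.zeros((n_snps, n_cells))
    mono_a = (active == "A") & (state != "XaXa_reactivated")
    mono_b = (active == "B") & (state != "XaXa_reactivated")
    p_hap_a[:, mono_a] = 1.0
    p_hap_a[:, mono_b] = 0.0
    p_hap_a[:, state == "XaXa_reactivated"] = 0.5
    # escapee genes leak reads from the inactive X in XaXi cells (partial escape)
    esc_snp = (snps["gene_id"].map(genes["xci_status"]) == "escapee").to_numpy()
    leak = 1.0 / cfg.escapee_xx_factor  # Xa share when Xi contributes the rest
    xaxi_a = xaxi_cells & (active == "A")
    xaxi_b = xaxi_cells & (active == "B")
    p_hap_a[np.ix_(esc_snp, xaxi_a)] = leak
    p_hap_a[np.ix_(esc_snp, xaxi_b)] = 1.0 - leak
    # XIST is expressed from the inactive X
    inact_a = xaxi_cells & (truth["inactive_hap"] == "A").to_numpy()
    p_hap_a[np.ix_(is_xist_snp, inact_a)] = 1.0
    p_hap_a[np.ix_(is_xist_snp, xaxi_cells & ~inact_a)] = 0.0

    # haplotype A depth -> alt depth through the per-donor phase, plus allele error
    hap_a_reads = rng.binomial(dp, p_hap_a)
    donor_of_cell = truth["sample_id"].to_numpy()
    alt_on_a = np.column_stack([phase[d] for d in donors])  # snps x donors
    donor_idx = np.array([donors.index(d) for d in donor_of_cell])
    a_is_alt = alt_on_a[:, donor_idx]
    ad = np.where(a_is_alt, hap_a_reads, dp - hap_a_reads)
    if cfg.allelic_error_rate > 0:
        flips_to_ref = rng.binomial(ad, cfg.allelic_error_rate)
        flips_to_alt = rng.binomial(dp - ad, cfg.allelic_error_rate)
        ad = ad - flips_to_ref + flips_to_alt

    return AllelicCountSet(
        snps=snps,
        alt_depth=sp.csr_matrix(ad),
        total_depth=sp.csr_matrix(dp),
        cell_ids=pd.Index(truth.index, name="barcode"),
    )


# ---------------------------------------------------------------------------
# fixture writer (external formats consumed by core_io / allelic)
# ---------------------------------------------------------------------------


def write_fixture(outdir, cohort: Cohort, overwrite: bool = False) -> dict:
    """Write the cohort in the on-disk layouts the readers consume.

    Emits the 10x triplet (matrix.mtx, features.tsv, barcodes.tsv), cell
    metadata and gene annotation TSVs, the cellsnp-style allelic layout
    (cellSNP.base.vcf + AD/DP Matrix Market + barcodes), and truth.tsv.
    """
    outdir = Path(outdir)
    if outdir.exists() and any(outdir.iterdir()) and not overwrite:
        raise FileExistsError(f"{outdir} is not empty (pass overwrite=True)")
    outdir.mkdir(parents=True, exist_ok=True)

    paths = {
        "matrix": outdir / "matrix.mtx",
        "features": outdir / "features.tsv",
        "barcodes": outdir / "barcodes.tsv",
        "cell_meta": outdir / "cell_meta.tsv",
        "annotation": outdir / "annotation.tsv",
        "vcf": outdir / "cellSNP.base.vcf",
        "ad": outdir / "cellSNP.tag.AD.mtx",
        "dp": outdir / "cellSNP.tag.DP.mtx",
        "snp_barcodes": outdir / "cellSNP.samples.tsv",
        "truth": outdir / "truth.tsv",
    }
    m = cohort.matrix
    write_count_matrix(m, paths["matrix"], paths["features"], paths["barcodes"])
    write_cell_meta(m, paths["cell_meta"])
    write_annotation(m.genes, paths["annotation"])
    cohort.truth.reset_index().to_csv(paths["truth"], sep="\t", index=False)

    s = cohort.allelic
    with _open_text(paths["vcf"], "wt") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=DP,Number=1,Type=Integer,Description="Total depth">\n')
        for chrom in dict.fromkeys(s.snps["chromosome"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        dp_tot = np.asarray(s.total_depth.sum(axis=1)).ravel().astype(int)
        for i, rec in s.snps.iterrows():
            fh.write(
                f"{rec['chromosome']}\t{rec['position']}\t.\t{rec['ref_allele']}\t"
                f"{rec['alt_allele']}\t.\tPASS\tDP={dp_tot[i]}\n"
            )
    from scipy.io import mmwrite

    with _open_text(paths["ad"], "wb") as fh:
        mmwrite(fh, sp.coo_matrix(s.alt_depth.astype(np.int64)), field="integer")
    with _open_text(paths["dp"], "wb") as fh:
        mmwrite(fh, sp.coo_matrix(s.total_depth.astype(np.int64)), field="integer")
    with _open_text(paths["snp_barcodes"], "wt") as fh:
        for bc in s.cell_ids:
            fh.write(f"{bc}\n")
    return {k: str(v) for k, v in paths.items()}
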