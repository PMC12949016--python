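"""End-to-end orchestration: simulate/load -> QC -> dosage -> relative dosage ->
XaXa classification -> allelic calling -> composition -> pseudobulk PCA ->
dosage correlation, driven by one config with a single global seed, emitting
plain-TSV stage outputs and a machine-readable JSON report."""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import allelic as al
from . import cnv_x, composition, dosage_assoc, pseudobulk_pca, xci_dosage
from .core_io import (
    AnnotatedCountMatrix,
    QCThresholds,
    attach_normalized,
    filter_cells,
    filter_genes,
    read_count_matrix,
    remove_mito_genes,
)
from .synthetic_data import Cohort, SimulationConfig, simulate_cohort

logger = logging.getLogger("xci_scope")

STAGES = ("qc", "dosage", "cnv", "allelic", "composition", "pseudobulk", "correlate")


@dataclass
class PipelineConfig:
    """Resolved run configuration; one global seed governs every stochastic stage."""

    output_dir: str = "xci_scope_run"
    seed: int = 0
    # input: either a simulation config or on-disk paths
    simulate: dict | None = None
    input_paths: dict | None = None
    stages: dict = field(default_factory=lambda: {s: True for s in STAGES})
    qc: dict = field(default_factory=dict)  # QCThresholds fields
    min_cells_per_gene: int = 10
    xist_min_count: int = 1
    reference_lineage: str = "immune"
    expression_cutoff: float = 0.1
    window: int = 101
    gain_threshold: float = 0.15
    xa_threshold: float = 0.036
    dup_threshold: float = 0.5
    snp_min_count: int = 20
    snp_min_maf: float = 0.05
    min_reads_per_allele: int = 1
    composition_group_a: list | None = None
    composition_group_b: list | None = None
    n_perm: int = 5000
    n_boot: int = 5000
    n_per_sample: int = 253
    n_hvg: int = 2000
    exclude_x_genes: bool = False

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def resolved(self) -> dict:
        return dataclasses.asdict(self)


def _load_inputs(cfg: PipelineConfig):
    if cfg.simulate is not None:
        sim = SimulationConfig(**{**cfg.simulate, "seed": cfg.seed})
        cohort = simulate_cohort(sim)
        return cohort.matrix, cohort.allelic, cohort.truth
    if cfg.input_paths is None:
        raise ValueError("config must provide either 'simulate' or 'input_paths'")
    p = cfg.input_paths
    m = read_count_matrix(
        p["matrix"], p["features"], p["barcodes"], p["cell_meta"], p["annotation"]
    )
    allelic_set = None
    if all(k in p for k in ("vcf", "ad", "dp", "snp_barcodes")):
        allelic_set = al.read_allelic_counts(p["vcf"], p["ad"], p["dp"], p["snp_barcodes"])
    return m, allelic_set, None


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute the enabled stages in dependency order; returns the report dict.

    Writes stage outputs (TSV), the resolved config (YAML) and report.json
    into ``cfg.output_dir``. Inputs are never mutated in place.
    """
    outdir = Path(cfg.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / "resolved_config.yaml", "w") as fh:
        yaml.safe_dump(cfg.resolved(), fh, sort_keys=True)
    handler = logging.FileHandler(outdir / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    report: dict = {"seed": cfg.seed}
    try:
        m, allelic_set, truth = _load_inputs(cfg)
        report["input"] = {"n_cells": m.n_cells, "n_genes": m.n_genes}

        if cfg.stages.get("qc", True):
            q = QCThresholds(**cfg.qc) if cfg.qc else QCThresholds()
            logger.info(
                "QC thresholds: counts>=%d genes>=%d mito<=%.2f gene-in>=%d cells",
                q.min_counts_per_cell, q.min_genes_per_cell, q.max_mito_fraction,
                cfg.min_cells_per_gene,
            )
            m = filter_cells(m, q)
            m = remove_mito_genes(m)
            m = filter_genes(m, cfg.min_cells_per_gene)
            report["qc"] = {"n_cells": m.n_cells, "n_genes": m.n_genes}
        m = attach_normalized(m)

        profile = None
        if cfg.stages.get("dosage", True):
            profile = xci_dosage.compute_xci_profile(m, xist_min_count=cfg.xist_min_count)
            summary, tests = xci_dosage.summarize_by_group(profile)
            summary.to_csv(outdir / "dosage_group_summary.tsv", sep="\t", index=False)
            tests.to_csv(outdir / "dosage_group_tests.tsv", sep="\t", index=False)
            report["dosage"] = {
                "groups": summary.to_dict(orient="records"),
                "tests": tests.to_dict(orient="records"),
            }

        if cfg.stages.get("cnv", True):
            if profile is None:
                raise RuntimeError("stage 'cnv' requires the 'dosage' stage output")
            ref_ids = m.cell_ids[(m.cell_meta["broad_lineage"] == cfg.reference_lineage).to_numpy()]
            logger.info("reference population: %d %s cells", len(ref_ids), cfg.reference_lineage)
            dosage = cnv_x.infer_relative_dosage(
                m, ref_ids, cfg.expression_cutoff, cfg.window, cfg.gain_threshold
            )
            profile["x_dup_proportion"] = cnv_x.x_duplication_proportion(dosage)
            logger.info(
                "thresholds applied: xa>%.3f, dup>%.2f, gain>%.2f",
                cfg.xa_threshold, cfg.dup_threshold, cfg.gain_threshold,
            )
            profile["xaxa_call"] = cnv_x.classify_xaxa(profile, cfg.xa_threshold, cfg.dup_threshold)
            tallies = profile["xaxa_call"].value_counts().to_dict()
            report["cnv"] = {"xaxa_call_tally": {k: int(v) for k, v in tallies.items()}}
            xistneg = profile[profile["xist_status"] == "XISTneg"]
            if len(xistneg) >= 3 and xistneg["x_dup_proportion"].notna().all():
                rho, p = cnv_x.dosage_ratio_correlation(profile)
                report["cnv"]["spearman_ratio_vs_dup"] = {"rho": rho, "p": p}

        if profile is not None:
            profile.to_csv(outdir / "xci_profile.tsv", sep="\t", index_label="barcode")

        if cfg.stages.get("allelic", True) and allelic_set is not None:
            if profile is None:
                raise RuntimeError("stage 'allelic' requires the 'dosage' stage output")
            mapped = al.map_snps_to_genes(allelic_set, m.genes)
            filtered = al.filter_snps(mapped, cfg.snp_min_count, cfg.snp_min_maf)
            logger.info("SNPs: %d raw, %d after filtering", allelic_set.n_snps, filtered.n_snps)
            calls = al.call_allelic_expression(
                filtered, m.genes, "inactivated", cfg.min_reads_per_allele
            )
            calls.gene_calls.to_csv(outdir / "allelic_gene_calls.tsv", sep="\t", index=False)
            sharing = al.xist_allele_sharing(filtered, profile)
            sharing.to_csv(outdir / "xist_sharing.tsv", sep="\t", index=False)
            cells = calls.cell_calls
            joined = profile.join(cells.rename("allelic_call"), how="inner")
            informative = joined[joined["allelic_call"].isin(["biallelic", "monoallelic"])]
            sub = informative[informative["xaxa_call"].isin(["XaXa_like", "XaXi"])]
            report["allelic"] = {
                "n_snps_filtered": int(filtered.n_snps),
                "n_informative_cells": int(len(informative)),
                "xist_sharing": sharing.to_dict(orient="records"),
            }
            if len(sub):
                table = pd.crosstab(sub["xaxa_call"], sub["allelic_call"]).reindex(
                    index=["XaXa_like", "XaXi"], columns=["biallelic", "monoallelic"], fill_value=0
                )
                try:
                    res = al.contingency_test(table.to_numpy())
                    report["allelic"]["contingency"] = {
                        "table": table.to_dict(),
                        "chi2_yates": res.chi2_yates,
                        "p": res.p_two_sided,
                    }
                except ValueError as err:
                    logger.warning("contingency test skipped: %s", err)

        if cfg.stages.get("composition", True):
            table = composition.composition_table(m.cell_meta)
            bias = composition.bias_score(table)
            bias.to_csv(outdir / "bias_scores.tsv", sep="\t")
            report["composition"] = {"bias_scores": bias["normalized_score"].round(6).to_dict()}
            ga, gb = cfg.composition_group_a, cfg.composition_group_b
            if ga is None or gb is None:
                samples = list(table.index)
                if len(samples) >= 2:
                    ga, gb = samples[:1], samples[1:]
            if ga and gb:
                prop = composition.permutation_proportion_test(
                    m.cell_meta, ga, gb, n_perm=cfg.n_perm, n_boot=cfg.n_boot, seed=cfg.seed
                )
                prop.to_csv(outdir / "proportion_test.tsv", sep="\t")
                report["composition"]["proportion_test"] = {
                    "group_a": list(ga),
                    "group_b": list(gb),
                    "significant": list(prop.index[prop["significant"]]),
                }

        if cfg.stages.get("pseudobulk", True):
            down = pseudobulk_pca.downsample_equal(m, cfg.n_per_sample, seed=cfg.seed)
            down = attach_normalized(down)
            hvg = pseudobulk_pca.select_hvg(down, cfg.n_hvg)
            pb = pseudobulk_pca.aggregate_pseudobulk(down, hvg)
            vst = pseudobulk_pca.variance_stabilize(pb)
            model = pseudobulk_pca.pca_fit(vst)
            model.save(outdir / "pca_model")
            corr = pseudobulk_pca.sample_correlation(vst)
            corr.to_csv(outdir / "sample_correlation.tsv", sep="\t")
            report["pseudobulk"] = {
                "n_cells_per_sample": int(min(cfg.n_per_sample, m.cell_meta.groupby("sample_id").size().min())),
                "n_hvg": len(hvg),
                "variance_explained": [round(float(v), 4) for v in model.variance_explained],
            }

        if cfg.stages.get("correlate", True):
            if profile is None:
                raise RuntimeError("stage 'correlate' requires the 'dosage' stage output")
            corr = dosage_assoc.correlate_with_dosage(
                m.normalized, m.genes, profile["xa_ratio_all"].to_numpy(),
                include_x_genes=not cfg.exclude_x_genes,
            )
            corr.to_csv(outdir / "dosage_correlation.tsv", sep="\t")
            top = corr.head(10)
            report["correlate"] = {
                "n_genes_tested": int(corr["p_value"].notna().sum()),
                "top_abs_rho": {g: round(float(r), 4) for g, r in top["rho"].items()},
            }

        if truth is not None and profile is not None and "xaxa_call" in profile:
            merged = profile.join(truth["xci_state"])
            elevated = merged["xci_state"].isin(["XaXa_reactivated", "Xa_duplicated"])
            xx = merged["sex"] == "XX"
            called = merged["xaxa_call"] == "XaXa_like"
            report["truth_recovery"] = {
                "simulated_elevated_fraction": round(float(elevated[xx].mean()), 4),
                "called_xaxa_fraction": round(float(called[xx].mean()), 4),
            }
    finally:
        logger.removeHandler(handler)
        handler.close()

    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return report
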