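"""Optional benchmarks against the published processed-data deposit.

The study's processed count matrices live on Zenodo (10.5281/zenodo.17469320);
the raw genotypic data are not public. This script is NOT part of the
automated checks: it expects a locally downloaded copy of the deposit,
exported to the triplet + metadata layout this package reads (matrix.mtx,
features.tsv, barcodes.tsv, cell_meta.tsv, annotation.tsv), and recomputes
the dosage group values (overall/inactivated/escapee X/A ratios per XIST
group), the detected inactivated/escapee gene counts, and the pseudobulk
sample-correlation matrix.

Usage:
    python scripts/external_benchmark.py --data /path/to/deposit --out bench.json
"""

from __future__ import annotations

import argparse
import json
from pathlib import Path

import numpy as np

from xci_scope.core_io import attach_normalized, read_count_matrix
from xci_scope.pseudobulk_pca import (
    aggregate_pseudobulk,
    downsample_equal,
    pca_fit,
    sample_correlation,
    select_hvg,
    variance_stabilize,
)
from xci_scope.xci_dosage import compute_xci_profile, summarize_by_group


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--data", type=Path, required=True, help="directory with the exported deposit")
    ap.add_argument("--out", type=Path, required=True)
    ap.add_argument("--seed", type=int, default=7)
    ap.add_argument("--n-per-sample", type=int, default=253)
    args = ap.parse_args()

    d = args.data
    m = read_count_matrix(
        d / "matrix.mtx", d / "features.tsv", d / "barcodes.tsv",
        d / "cell_meta.tsv", d / "annotation.tsv",
    )
    m = attach_normalized(m)

    profile = compute_xci_profile(m)
    summary, tests = summarize_by_group(profile)

    expressed = np.asarray((m.counts > 0).sum(axis=0)).ravel() > 0
    n_inact = int(((m.genes["xci_status"] == "inactivated").to_numpy() & expressed).sum())
    n_esc = int(((m.genes["xci_status"] == "escapee").to_numpy() & expressed).sum())

    down = attach_normalized(downsample_equal(m, args.n_per_sample, seed=args.seed))
    hvg = select_hvg(down, 2000)
    vst = variance_stabilize(aggregate_pseudobulk(down, hvg))
    model = pca_fit(vst)
    corr = sample_correlation(vst)

    out = {
        "group_values": summary.to_dict(orient="records"),
        "group_tests": tests.to_dict(orient="records"),
        "n_inactivated_detected": n_inact,
        "n_escapee_detected": n_esc,
        "variance_explained": [float(v) for v in model.variance_explained],
        "sample_correlation": corr.round(4).to_dict(),
    }
    args.out.parent.mkdir(parents=True, exist_ok=True)
    with open(args.out, "w") as fh:
        json.dump(out, fh, indent=2)
    print(json.dumps(out, indent=2))


if __name__ == "__main__":
    main()
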