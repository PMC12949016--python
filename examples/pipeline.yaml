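# Full pipeline on a freshly simulated reference cohort.
# For on-disk data, replace `simulate:` with:
#   input_paths:
#     matrix: data/matrix.mtx
#     features: data/features.tsv
#     barcodes: data/barcodes.tsv
#     cell_meta: data/cell_meta.tsv
#     annotation: data/annotation.tsv
#     vcf: data/cellSNP.base.vcf
#     ad: data/cellSNP.tag.AD.mtx
#     dp: data/cellSNP.tag.DP.mtx
#     snp_barcodes: data/cellSNP.samples.tsv
output_dir: xci_scope_run
seed: 7
simulate: {}            # defaults: 2 XX samples x 2000 cells + 1 XY x 1000
reference_lineage: immune
xa_threshold: 0.036
dup_threshold: 0.5
n_perm: 5000
n_boot: 5000
n_per_sample: 253
n_hvg: 2000
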