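# Methods

This note documents the models and procedures implemented in `xci-scope`, the
assumptions behind them, the defaults that matter, and what the synthetic
cohort does and does not emulate.

## Background and scope

In XX somatic cells, dosage compensation is achieved by X-chromosome
inactivation (XCI): the lncRNA *XIST* coats one X (the inactive X, Xi) and
silences most of its genes. Tumor cells can depart from this state in two
ways that both present as roughly doubled X-linked expression: reactivation
of (or failure to ever silence) the Xi, giving two active X's (XaXa), or loss
of the Xi with duplication of the active X (Xa-duplication). The two are
distinguishable only at the allele level — a reactivated Xi contributes reads
from the second haplotype (biallelic expression of normally inactivated
genes), whereas a duplicated Xa stays monoallelic at doubled depth.
`xci-scope` implements the full chain of evidence for single-nucleus RNA-seq
cohorts: dosage ratio, XIST stratification, expression-inferred X
duplication, joint XaXa-like classification, and allele-specific
confirmation, plus cohort-level composition and pseudobulk statistics.

## X/A dosage ratio (`xci_dosage`)

Per cell, the X/A ratio is the sum of raw counts over X-linked genes divided
by the sum over autosomal genes (chromosomes 1–22; Y is excluded from both
sides). Raw counts are used deliberately: the ratio is scale-free (invariant
to multiplying a cell's counts by a constant), so no normalization is
needed, and normalization could only distort it. The numerator is stratified
by XCI class of the gene: *inactivated* genes (silenced on Xi) double their
contribution when a second X is active, *escapee* genes (expressed from both
Xa and Xi) do not, and PAR/unclassified genes are counted only in the
overall ratio. The three class ratios share the denominator, so they
decompose the overall ratio exactly. A cell with zero autosomal counts gets
a missing value, never a silent zero.

XIST status uses the raw XIST count: XX cells with at least
`xist_min_count` (default 1: one UMI is the minimal positive evidence, and
the threshold is a knob) are XIST-positive; XY cells are their own stratum.
Group summaries report both mean and median per (XIST group, gene class) and
two-sided Wilcoxon rank-sum contrasts of each XX group against XY.

## Relative dosage along chromosomes and the XaXa-like call (`cnv_x`)

A simplified reference-normalized dosage inference: genes with mean raw
count ≥ 0.1 across cells are laid out chromosome-by-chromosome in coordinate
order; expression is library-size normalized and log1p-transformed; the
per-gene mean over a designated copy-neutral reference population — immune
cells by default, being infiltrative rather than tumor-derived — is
subtracted; a moving average of 101 genes is taken within each chromosome;
and each cell's median smoothed value is subtracted (cell-specific technical
offsets are shared genome-wide while most of the genome is copy-neutral).
The moving average uses windows clipped at chromosome ends and divided by
their actual length; window membership is then symmetric, so the
window-length-weighted mean per chromosome is exactly preserved. Chromosomes
with fewer than window/4 genes fall back to their chromosome mean.

Gain states are called from the smoothed residuals by a 3-state Gaussian
HMM (Viterbi): emission means at −0.15 / 0 / +0.15 (the loss/gain
thresholds), a shared emission sd estimated robustly from the centered
residual spread, and sticky transitions (stay probability 1 − 1e−4). The
HMM is the default because a duplicated X shifts the per-gene residual by
only ~0.2 on the natural-log scale — close to the 0.15 threshold — and the
chromosome-long persistence of the state is what makes the call reliable;
plain per-gene thresholding (`method="threshold"`) is retained as the
simpler alternative. The per-cell *X-duplication proportion* is the fraction
of retained non-PAR X genes in the gain state; the pseudoautosomal regions
(GRCh38 PAR1 X:10001–2,781,479 and PAR2 X:155,701,383–156,030,895) sit on
both sex chromosomes and are excluded.

A cell is called **XaXa-like** when its overall X/A ratio exceeds 0.036 and
its X-duplication proportion exceeds 0.5 (strict inequalities); XY cells and
cells with missing inputs are `not_applicable`. Both thresholds are
configurable, and every threshold actually applied is written to the run
log and report.

## Allele-specific analysis (`allelic`)

Input is the cellsnp-lite layout: a base VCF of candidate SNPs plus sparse
AD (alternate) and DP (total) depth matrices. Multi-allelic records are
skipped; AD exceeding DP anywhere is treated as corrupt input. SNPs are
assigned to genes by coordinate containment; SNPs contained in more than one
gene are dropped, as are SNPs with aggregate depth < 20 or aggregate
minor-allele fraction < 0.05.

Per (cell, gene): **biallelic** if a single SNP shows at least one read on
each allele (`min_reads_per_allele`, default 1; 2 available for stringency);
**monoallelic** if the gene has ≥ 2 reads, each SNP individually one-sided
(two SNPs of opposite phase must not fake biallelic evidence);
uninformative otherwise. The per-cell aggregate over informative genes of a
class is a majority vote with ties resolved to biallelic ("any" and "all"
rules are available — the aggregation rule is genuinely open and is exposed
as a parameter). XIST allele sharing is evaluated per sample over
XIST-positive cells: for each XIST SNP, single-allele observations are
compared to the SNP's within-sample majority allele; a sharing fraction
near 1 indicates a shared Xi, i.e. clonal XCI. The 2×2 association of
XaXa-like/XaXi classification with biallelic/monoallelic calls is tested
with the Yates continuity-corrected chi-square, implemented in closed form
(clipped at zero when |ad − bc| ≤ N/2) with the p-value from χ²(1).

## Composition statistics (`composition`)

The **bias score** of a cell type is the empirical KL divergence between its
distribution over samples, p_k(s) = n_ks/n_k, and the overall cell
distribution q(s) = n_s/n, with 0·ln 0 = 0. It is 0 exactly when the type is
spread proportionally to sample sizes and reaches ln(S) when confined to one
of S equal samples. Three variants are reported: the raw divergence, the
divergence scaled by the type's cell count (n_k·kl, weighting abundant
types — "scaled by the total number of cells" admits a multiplicative or a
divisive reading, and reporting all variants keeps either available), and
the divergence normalized by ln(S) into [0, 1].

The **permutation proportion test** compares cell-type proportions between
two sample groups by shuffling group labels over the pooled cells —
implemented exactly as multivariate hypergeometric draws of the group-A
composition from the pooled counts. The statistic is the log2 proportional
difference with a half-cell pseudocount added symmetrically to both groups
(keeps zero-count types finite without biasing the sign); the two-sided
p-value counts permuted |log2FD| ≥ |observed| with the add-one estimator, so
the smallest attainable p is 1/(n_perm + 1). p-values are BH-adjusted across
cell types; confidence intervals are 2.5–97.5 bootstrap percentiles with
cells resampled with replacement within each group. Defaults are 5,000
permutations and 5,000 bootstraps (the source protocol states 5,000 in its
methods and 10,000 in one figure legend; 5,000 is the default and the count
is a config knob). The permutation unit is the cell within the pooled
groups; shuffling between matched sample pairs is a documented alternative
not implemented here.

## Pseudobulk PCA (`pseudobulk_pca`)

Samples are downsampled to a common cell count (default 253, the size of
the smallest sample in the motivating cohort) before aggregation so
composition, not depth, drives the analysis. The top 2,000 variable genes
are chosen by variance of log-normalized expression with deterministic
gene-id tie-breaks, after downsampling (matching the stated order of the
source protocol). Raw counts are summed per sample over those genes; genes
below 10 aggregate counts are dropped. Variance stabilization uses
median-of-ratios size factors followed by log2(count/sf + 1) — a documented
simplification of the regularized-log transform: the exact rlog shrinkage
estimator belongs to an external package, and the downstream uses here (PCA
and Spearman correlation) depend only on the stabilization; the transform is
a pluggable function. PCA centers and unit-scales genes (sd with one
delta degree of freedom), takes the SVD, fixes each component's sign so its
largest-|loading| gene is positive, and persists the centering/scaling
vectors, loadings, scores and variance fractions as TSVs so new pseudobulk
samples (e.g. spatial sections) can be projected onto the identical axes:
project(x) = ((x − center)/scale)·loadings. Projection refuses silently
zero-filling more than 20% of the model genes. Sample relationships are
summarized by Spearman correlation of the transformed profiles, with
hierarchical (Euclidean) ordering available, and per-PC gene loadings are
exported as pre-ranked lists for external enrichment.

## Dosage association and signature scores (`dosage_assoc`)

Treating the per-cell X/A ratio as a continuous dosage covariate, each
gene's log-normalized expression is Spearman-correlated against it
(tie-corrected, via Pearson on ranks; two-sided p from the classical t
approximation; cells with a missing ratio dropped pairwise). The run can
exclude X-linked genes so autosomal dosage-responsive programs are read
without the numerator's self-correlation; the X filter provably leaves every
autosomal gene's statistic unchanged. Multiplicity is handled with BH
adjustment plus Storey q-values using the single-λ (0.5) π₀ estimator — the
spline-smoothed estimator is less reproducible and the single-λ variant is
standard and documented. Output is sorted by |rho| descending.

Gene-set activity per cell uses capped expression ranks: genes are ranked
descending within the cell (average ranks on ties), ranks beyond r_max
(default 1,500, the conventional ceiling for this scorer) are set to
r_max + 1, and with R the set's rank sum and n_s its size,
U′ = R − n_s(n_s+1)/2 and score = 1 − U′/(n_s·r_max), clipped to [0, 1]. A
set occupying the top ranks scores exactly 1; a set entirely beyond the
ceiling scores ~0 (floor n_s(n_s−1)/2 short of exact zero). The score
depends only on within-cell ranks and is therefore invariant to any
monotone transform of a cell's expression values. Group contrasts
(XaXa-like vs XaXi per lineage stratum) use two-sided rank-sum tests with
BH across strata.

## Synthetic cohorts (`synthetic_data`)

The generator emulates the cohort the analysis is designed for and provides
exact ground truth. Defaults (the reference conditions used by the tests and
the acceptance script):

| parameter | default | rationale |
|---|---|---|
| samples | 2 XX × 2,000 cells + 1 XY × 1,000 | multi-sample cohort with an XY control |
| cell types | 6 types over 5 broad lineages | stroma/epithelia/neuroectoderm (tumor) + endothelia/immune (infiltrate) |
| XaXa fraction | 0.35 of tumor-lineage XX cells | a robust XaXa compartment confined to tumor lineages |
| Xa-duplication fraction | 0.05 | the minority monoallelic-at-double-dosage population |
| genes | 2,000 autosomal + 300 inactivated + 60 escapee + 20 PAR + XIST | desk-scale down-sampling of the ~392/82 XCI reference classes |
| count model | negative binomial, size 2.0, baseline mean 2.0 | standard UMI overdispersion |
| X-gene mean scale | calibrated so E[XaXi X/A] = 0.029 | places XaXi at the observed XIST-positive level, so 0.036 is the operative boundary |
| escapee XX factor | 4/3 | partial escape: Xi contributes ~1/3 of the Xa level, invariant across XCI states |
| XIST mean | 5 in XaXi cells, 0 otherwise | expressed from the Xi only |
| dropout | 0.1 per entry | XIST dropout is the main XISTneg misclassification source; sweepable |
| allelic depth | Poisson mean 5 × dosage, coverage 0.25, allele error 0.005 | shallow UMI capture with rare wrong-allele reads |
| SNPs | 2 per X gene, 6 on XIST, per-donor random phase | XIST is long and SNP-dense; donors have independent genotypes |

State semantics: XaXi cells share one Xi per sample (clonality) and express
inactivated genes monoallelically from the Xa; XaXa-reactivated cells double
inactivated-gene dosage and split reads ~50/50; Xa-duplicated cells double
dosage but stay monoallelic; XY cells are hemizygous (all reads one allele)
and XIST-free.

What the generator does **not** emulate: batch effects, doublets, ambient
RNA, cell-type-specific expression programs (gene means are shared across
cell types, so composition statistics see labels, not transcriptomes),
gene-length or mappability biases, reference bias in allele counting, and
incomplete XCI skewing. Passing tests therefore demonstrate correctness of
the statistical machinery under the stated generative model, not robustness
to every artifact of real snRNA-seq data.

## Numerical choices and problem sizes

Determinism: a single integer seed drives every stochastic stage
(simulation, downsampling, permutations, bootstraps); identical seeds give
byte-identical reports. Ties: HVG selection and ranked loadings break ties
by gene id; biallelic/monoallelic majority votes break ties toward
biallelic; rank ties use average ranks. Degenerate inputs produce explicit
missing values (zero autosomal counts, constant correlation inputs, absent
non-PAR X genes) or errors (zero-margin contingency tables, zero-total
cells at normalization, empty gene-set intersections) — never silent zeros.
The test suite and acceptance script run the reference cohort at 5,000
cells × ~2,400 genes and the calibration study at 200 null simulations ×
1,000 permutations; these sizes give binomial standard errors comfortably
inside the asserted bounds while keeping a full run in the tens of seconds.

## Known limitations

The relative-dosage stage is a deliberate simplification of full
HMM-based CNV inference (no per-chromosome noise model, no subclustering,
no i3/i6 state machinery) — sufficient because the only quantity consumed
downstream is the per-cell proportion of X in the gain state. The rlog
substitution above is exact only in its variance-stabilizing intent. The
allele-level analysis does not phase SNPs across genes and does not model
reference bias. The packaged XCI gene classes in the synthetic annotation
are generated labels, not the published consensus lists; analyses of real
data must supply a real annotation table (gene_id, symbol, chromosome,
start, end, xci_status).
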