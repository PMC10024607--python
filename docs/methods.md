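# Methods

This note documents the models and procedures implemented in `merfishpipe`,
the defaults that matter, the choices made where the design was genuinely
open, and what the synthetic-data tests do and do not establish.

## Synthetic data generator

The generator produces the two data modalities the pipeline consumes, with
planted ground truth throughout.

**Counts.** Molecule counts are negative binomial with mean µ and
dispersion θ, parameterized so Var = µ + µ²/θ (θ → ∞ recovers Poisson).
Sampling is gamma–Poisson, so outputs are exact NB draws. snRNA-seq cells
carry a multiplicative lognormal(0, 0.3) size factor emulating UMI-depth
variation — this is what makes the log10(total counts) covariate in the DE
model necessary. MERFISH counts scale proportionally with nucleus volume.

**Geometry.** Tissue domains are named axis-aligned rectangles (pia strip,
cortical layers, corpus callosum band, striatum, ventricle) with per-domain
cell-type composition weights; cells are placed uniformly within their
rectangle. Each domain carries its own cell count (default 300). Nucleus
volumes are lognormal with a default median of 400 µm³ and σ = 0.35 —
typical of cortical nuclei and comfortably above the 100 µm³ QC floor.

**Planted effects.** Age effects multiply the old-age NB mean of a chosen
(gene, cell type) by exp(LFC). The activation gradient adds
a·exp(−d/L) to the NB mean of a chosen gene set in a target cell type,
where d is the distance to the nearest reference-type cell — by
construction the gene-set score and the distance-curve machinery can detect
it. The LPS response adds Poisson(δ) molecules to +LPS cells of one type,
giving an additive mean shift of exactly δ.

**What a green test establishes.** The generator produces idealized data:
no segmentation errors, no doublets, no spatial autocorrelation of depth,
no batch structure, rectangular domains with hard boundaries, and a single
z-plane. Tests against it verify algorithmic correctness and statistical
calibration, not robustness to real-data artifacts.

## Panel selection

Age DE fits, per gene and per population, the NB GLM with log link

    y_i ~ C(age) + log10(total_counts) + intercept,

juvenile as reference, against the reduced model without the age term, and
compares them with a 1-df likelihood-ratio test. "Log-transformed counts
fed to an NB model" is internally inconsistent; the NB GLM on raw counts
with a log link reproduces the intended covariate structure and is what is
implemented. The per-gene dispersion α (Var = µ + αµ²) is estimated once
by maximum likelihood on the reduced design (method-of-moments fallback on
non-convergence, clipped to [10⁻⁶, 10]) and held fixed in both fits, so
the LRT compares nested mean models. BH-FDR is applied across all genes in
all populations. Simulated null calibration: rejection at α = 0.05 falls
in [0.02, 0.09] over 500 null genes.

The aging panel keeps, among genes with FDR < 10⁻⁶ and age coefficient
> 1.5, the top 5 per major type and top 2 per cluster (coefficient-sorted,
lexicographic tie-break). Markers are one-vs-rest Welch t-tests on log1p
expression with the four criteria: expressed in ≥ 40% of the population,
FDR < 0.05, mean ≥ 2-fold higher than outside, expressed fraction ≥ 3×
the outside fraction; top 15 per population by fold change, then a greedy
pass guarantees every population ≥ 2 panel markers.

## Codebook and probe design

**Codebook.** All C(20, 4) = 4,845 weight-4 words are enumerated; a seeded
shuffle is scanned greedily, keeping each word at Hamming distance ≥ 4
from all kept words. 500 such trials are scored by the population variance
of per-bit usage; the largest-then-most-balanced code with ≥ 200 words
wins. Codes of 205–222 words result (the constant-weight packing bound is
C(20,3)/C(4,3) = 285). Minimum distance is asserted by full pairwise scan.

**Gene assignment.** The expected molecule load of bit b is the sum over
genes on b of abundance-weighted mean expression. Starting from a seeded
random assignment, pairwise swaps (gene↔gene and gene→unused barcode) are
accepted iff they strictly lower the across-bit load variance; random-order
sweeps repeat until none improves. Although the procedure is described in
the field as simulated annealing, the stated acceptance rule is strictly
greedy; a temperature schedule is deliberately not used. On ≤ 4-gene
instances the result matches brute-force enumeration.

**Target regions.** Every 30-nt window is scored: GC fraction within
[0.30, 0.70]; nearest-neighbor Tm at 300 mM Na⁺ (5 nM probe) within
[60, 80] °C — a formamide correction (−0.6 °C/%) is available but defaults
to 0, since the acceptance band is expressed on uncorrected Tm (applying
the 30% correction would put essentially all 30-mers below 55 °C and make
the filter unsatisfiable); isoform and gene specificity ≥ 0.75, computed
as the fraction of the window's 17-mers unique to the target
isoform/gene against a supplied transcriptome index; and no 16-mer shared
with an rRNA/tRNA blacklist ("no homology longer than 15 nt"). Passing
windows are tiled greedily left to right without overlap; a seeded random
downsample caps the count at 92.

**Assembly.** Each probe is primer (20 nt) + readout + 30-nt target +
readout + readout + promoter (20 nt) = 130 nt. The three readouts are
drawn from the four defined by the gene's barcode on-bits; the omitted
readout follows a seeded shuffle of a balanced exclusion list, so each
readout appears in exactly ⌈3n/4⌉ ± 1 of a gene's n probes.

## QC and normalization

The MERFISH cascade runs in a fixed order: optional doublet removal
(pluggable boolean scorer, no-op by default) → cells with < 20 molecules
or < 5 detected genes removed → volume < 100 µm³ or > 3× the median
volume removed (median computed on the cells surviving the count filter) →
a two-sided 2% quantile trim on total volume-normalized expression (cells
strictly outside the quantiles removed; boundary values kept). The cascade
is idempotent. Normalization divides counts by volume, rescales each cell
to sum to 250, applies log1p, and Z-scores per gene; all three layers are
retained. Dual decoding runs are reconciled by mutual nearest-neighbor
nucleus matching within 5 µm, with unmatched nuclei dropped.

## Integration, imputation, label transfer

Both modalities, restricted to the shared panel and Z-scored, are
concatenated and reduced by full-SVD PCA. The modality aligner is a
contract (reduce the distance between modality centroids without permuting
cells); the built-in default matches per-modality centroids per PC, which
removes a constant modality offset exactly. Iterative correction tools can
be plugged in as a callable. Imputation averages, unweighted, the full
profiles of the 10 nearest snRNA-seq cells in the first 30 aligned PCs
(exact kNN; verified identical to an O(n²) oracle). Validation: per-gene
Pearson r across 150-µm spatial bins (half-open bins anchored at each
section's bounding-box corner, empty bins excluded), and per (type,
region) Pearson r across genes of mean measured vs. imputed profiles.
Label transfer trains a seeded MLP (one hidden layer of 64 units) on the
first 25 joint PCs.

## Spatial domains

Each cell's neighborhood is summarized by counts of every cell cluster
within 100 µm in the same section, excluding the cell itself (including it
would inject the cell's own label into its niche). PCA retains
min(20, n_clusters − 1) components, then seeded k-means (k-means++, 10
restarts) with k = 20 over-segments; an average-linkage hierarchy of the
k-means centers guides a user-supplied merge map. Merging is deliberately
manual: anatomical naming is a judgment call the pipeline exposes as
configuration rather than automates.

## Proximity and activation statistics

µ_true is the mean number of B cells within 30 µm of each A cell. The
null jitters every B cell independently by Uniform(−100, 100) µm in x and
y and recounts, 1000 times; enrichment = log₂(µ_true/µ_bg),
Z = (µ_true − µ_bg)/σ_bg, P = 2(1 − Φ(|Z|)) with the standard normal CDF
(Z is already standardized), BH-FDR across ordered pairs. A cells are
never jittered, so (A, B) and (B, A) are distinct statistics. **Edge
caveat:** the jitter null is anti-conservative when the tissue extent is
comparable to the jitter radius (boundary cells jitter out of the imaged
window, deflating µ_bg); at a 600-µm window the empirical test size is
0.16, at the realistic 3-mm section scale it is 0.05.

Gene-set scores rank genes by mean expression into 25 equal-size bins and
draw 50 control genes per set gene from the matching bin (seeded, set
members excluded); score = mean set expression − mean control expression
per cell. The score is translation-detecting: adding c to the set genes
shifts scores by ≈ c. Distance curves pair each scored cell with its
nearest reference-type cell within 80 µm (per section), evaluate the mean
and SEM (sd/√n, no independence correction across overlapping windows) on
a 1-µm grid with a 30-µm sliding window clipped to [0, 80], and subtract
the unweighted grid mean, reporting it as the curve's constant. Curves
pool sections by default.

## Gene modules

With X the Z-scored cells × genes matrix and X = USVᵀ, the gene
representation is G = V₅₀S₅₀ and the correlation proxy GGᵀ (= XᵀX when 50
reaches the rank). The proxy is Z-scored globally over off-diagonal
entries and entries with Z < 0.1 are zeroed — literally, so negative-Z
entries vanish too. Genes are embedded in 2-D and clustered with DBSCAN
(min_samples = 5; eps defaults to 5% of the embedding bounding-box
diagonal — k-NN-distance knee rules fail on the many exactly-coincident
zero-affinity genes). The default embedding is deterministic: the leading
eigenvectors of the affinity matrix scaled by √eigenvalue (a Laplacian
embedding cannot separate the typically highly disconnected sparsified
graph); UMAP is pluggable. Candidate modules are kept iff their mean
intra-module correlation beats 1000 seeded label permutations at
p = (1 + #null ≥ obs)/(1 + n_perm), BH-FDR < 0.1.

**Selection-bias caveat.** The permutation null tests a module *given* its
membership, but membership was chosen by clustering the same matrix. On
null data the selection step occasionally isolates a small clump of
chance-correlated genes that the permutation test then certifies; at a
realistic scale (2000 cells × 300 genes) this affects ≲ 2% of genes in
the occasional run and none in most runs, but at small cell counts it is
common. This bias is inherent to the select-then-test design; treat
retained modules on small datasets with caution.

## Condition response

Within one cell type, each gene's Z-scored expression is modeled by OLS as
y ~ C(condition) + intercept against the intercept-only null (F-test, 1
numerator df). For a two-level factor the coefficient is exactly the
difference of group means, which the implementation computes in closed
form (verified against statsmodels). The LPS contrast uses
reference-age animals under both conditions; the age contrast uses
untreated animals. Coefficients are Z-scored across genes within each cell
type (pooling types would let an inflammatory type's large effects mask
others), and a gene is up-regulated for a contrast iff Z > 2 and
FDR < 10⁻⁴ (both strict); the categories both/lps/age/neither partition
all rows.

## Known limitations

* No image-level simulation or decoding; the pipeline starts at cell-by-gene
  tables.
* The jitter proximity null is 2-D and edge-biased at small windows (above).
* The gene-module permutation test does not correct for selection (above).
* Batch correction beyond modality centroid alignment, community detection,
  and doublet scoring are deliberately pluggable contracts, not
  implementations.
* Distances are 2-D Euclidean within a section throughout; 3-D tissue is
  out of scope.
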