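# Methods

This note documents the models and procedures implemented in `spearatac`,
the defaults and why they were chosen, what the synthetic-data generator
does and does not emulate, and the numerical conventions that make runs
reproducible.

## Screen model

A pooled CRISPRi screen with an accessibility read-out produces two
linked raw inputs per sample:

1. a **targeted sgRNA enrichment library** — paired FASTQ files in which
   Read1 starts with the 20-nt sgRNA spacer (placed there by a custom
   sequencing primer) and the index read carries the 16-nt droplet cell
   barcode; and
2. a **fragments file** — one Tn5-to-Tn5 accessible fragment per line
   with its cell barcode, in the 10x dialect (0-based half-open,
   +4/−5 offset already applied). Each fragment contributes exactly two
   insertion events, at `start` and `end − 1`. All interval logic in the
   package is 0-based half-open, so BED files need no coordinate shifts.

## sgRNA assignment

Barcodes resolve against the whitelist with at most one mismatch. The
index precomputes every single-substitution variant of every whitelist
barcode; a variant claimed by two barcodes is ambiguous and never
resolves, and an exact match always beats a one-mismatch match.
Specificity over yield is deliberate: a wrong cell assignment poisons
every downstream per-target statistic, while a lost read costs only
depth.

Spacers must match the library exactly, anchored at read position 0. A
small scan window (0–3 bp leading offset) is available for libraries with
staggered primers; mismatch-tolerant spacer matching is available but off
by default.

A cell is assigned to its top-count sgRNA iff its total sgRNA read count
is ≥ `min_counts` (default 20) and the top sgRNA holds ≥ `min_specificity`
(default 0.8) of them. The count threshold is applied to the *total*
sgRNA reads of the cell, per the rule's plain reading; ties for the top
count leave the cell unassigned. Specificity is computed per individual
sgRNA by default — the stricter reading — with an optional mode summing
counts across sgRNAs sharing a target before the ratio. Counts are raw
reads (the enrichment library carries no UMIs; PCR duplication inflates
all cells similarly and the specificity ratio is scale-free).

## QC and matrices

Per-cell quality is fragment count and TSS enrichment. Since the
enrichment threshold (4) is only meaningful relative to a window
convention, the package fixes one: mean per-bp insertion rate within
±50 bp of the nearest TSS over the mean per-bp rate in the two distal
flanks 1,901–2,000 bp away, with a +1 pseudocount on the flank total. A
uniform insertion profile scores ≈ 1. Cells need enrichment ≥ 4 and
≥ 1,000 fragments (defaults). No doublet filtering is performed: screen
populations do not form the discrete clusters heterotypic-doublet
detection relies on.

Tile matrices bin insertions into fixed 500-bp genome windows
(`tile = floor(position / tile_size)`); peak matrices count insertions in
sorted, non-overlapping half-open intervals. Both conserve insertions:
the grand total is twice the number of in-range fragments.

Pseudobulk profiles are per-group summed counts rescaled so each group
column sums to 10⁶; fold changes are log2 ratios of scaled values with a
pseudocount of 1.

**LSI.** Counts are binarized; term frequency is each entry over its cell
total, scaled as `log(1 + tf·10⁴)`; inverse document frequency is
`log(1 + n_cells / (1 + feature frequency))`; the TF-IDF matrix is
decomposed by rank-`d` truncated SVD (default d = 30, on the 25,000 most
accessible features for genome-wide matrices). Single-pass LSI is used
rather than iterative re-selection of features: the downstream consumers
here (purity kNN on their own differential tiles, visualization) are
robust to that simplification, and it removes a dependency on graph
clustering. Components whose absolute correlation with log10 cell depth
exceeds 0.75 are *flagged*, not silently dropped — dropping is an
explicit switch, so the decision is visible and reproducible. SVD runs
with a seeded start vector and a deterministic sign convention (largest
loading positive), making embeddings identical across reruns.

## Motif deviations

For cell *i* and motif peak set *S*: observed `o = Σ_{p∈S} X_ip`,
expected `e = T_i · Σ_{p∈S} f_p` (cell total times population peak-weight
of the set), raw deviation `Y = (o − e)/e`. Backgrounds: both bias
covariates (GC fraction, log1p mean accessibility) are standardized and
gridded into 25 × 25 bins; each peak draws 50 background peaks uniformly
(with replacement) from its own bin, seeded. Binned sampling was chosen
over nearest-neighbor sampling in covariate space because it is simpler,
exactly reproducible, and satisfies the actual contract — a bias-matched
null — which is all downstream analysis relies on. The corrected
deviation subtracts the background mean of Y; the z-score divides by the
background standard deviation (ddof = 1). Degenerate cases are explicit
NaN: motifs with no matching peaks, zero expectations, and background
spreads at floating-point noise (sd ≤ 1e-12, i.e. effectively identical
backgrounds) rather than astronomically large z values.

Averaging for perturbation scores uses corrected deviations; the
Wilcoxon differential test uses z-scores. Motif variability (std of z
across cells) ranks redundant motifs within a family; only the most
variable member of each family is retained for scoring and networks,
with ties broken lexicographically.

## Perturbation scoring

ΔD tables subtract the NT group's mean deviation per motif; the NT row
is identically zero, and swapping the roles of target and NT negates ΔD.
Cross-screen ranking takes, per screen, each motif's maximum |ΔD| over
targets, then ranks motifs by the mean of those maxima across screens.
Exclusion of outlier NT sgRNAs (identified by pseudobulk PCA review) is a
configuration list, not an automatic rule — that judgement is the
analyst's.

The Wilcoxon path subsamples each side to 250 cells (seeded) and
restricts the background to NT cells depth-matched to target cells
within a [0.95, 1/0.95] fragment-count ratio window, paired greedily;
if nothing matches it falls back to all NT cells with a warning. The
test is the two-sided rank-sum with tie-corrected normal approximation,
BH-corrected across motifs. Under null simulations its type-I error at
α = 0.05 is ≈ 0.05 (measured 0.051–0.055 over 200 × 20 replicates).

## Differential peaks

The binomial test evaluates, per peak, the target group's summed count
`k` out of its total `n` against `p0 = (background count + 1) /
(background total + n_peaks)` — add-one smoothing keeps `p0 > 0` — with
a two-sided exact binomial p-value and BH correction. **Known property:**
because `p0` is itself estimated from a finite background, the test
treats an estimated proportion as fixed; with equal-sized arms the
discrepancy variance is roughly double what the test assumes, and the
measured type-I error under equal-rate null simulations is ≈ 0.13 at
α = 0.05 (across Poisson rates 0.05–1.0). This anti-conservatism is
inherent to this class of marker test; treat its FDRs as enrichment
rankings rather than calibrated error rates, and prefer the Wilcoxon
path when calibration matters. The default significance filter is
|log2FC| > 0.5 and FDR < 0.1 (FDR < 0.05 available as a parameter).

Time-course analysis takes the union of peaks with |log2FC| > 1 at any
timepoint, then keeps those with |log2FC| > 0.25 in at least one
timepoint. Peak modules are k-means (k = 4 for single-timepoint, k = 6
for time-course heatmaps) on log2 pseudobulk rows z-scored across groups,
10 seeded restarts, constant rows dropped. Motif enrichment per module
is the upper-tail hypergeometric against all tested peaks, BH-corrected.

## Purity refinement

For each target: pseudobulk log2FC target-vs-NT per tile, keeping only
tiles whose sign is consistent for *every* individual sgRNA of the target
("reproducibly regulated" is not defined quantitatively by the upstream
procedure; sign consistency is this package's operationalization, and is
flagged as an interpretation). The top 5,000 increasing and 5,000
decreasing such tiles (fewer if unavailable; ties broken by absolute
scaled difference then tile id) feed an LSI embedding of the target ∪ NT
cell set; each target cell's PurityRatio is the fraction of its k = 20
nearest neighbors (cosine, excluding itself) assigned to the target, and
the assignment is kept iff the ratio exceeds 0.9 (strictly). Neighbors
are found in the 30-dimensional LSI space, not a 2-D projection — 2-D
embeddings distort neighborhoods; a UMAP (n_neighbors = 40,
min_dist = 0.4, cosine) is available for visualization only. NT cells
are never purity-filtered.

The strictness of the cut matters: requiring ≥ 19 of 20 neighbors means
the kept fraction of *genuine* target cells depends steeply on how
separated the target and NT populations are. In synthetic screens with
strongly separated populations (fold 6 on 15% of tiles; ≈ 12σ between
population means along the discriminant axis of the embedding) ≥ 95% of
genuine cells are kept and ≥ 90% of planted mislabeled cells fall below
0.9; at ≈ 6σ only ~75% of genuine cells survive while detection of
mislabeled cells remains > 95%. For weakly-responding targets the filter
therefore trades recall for precision, which is its purpose.

## TF–TF differential networks

Pearson correlation (Spearman available) of corrected deviations over a
target's cells minus the same over NT cells gives Δr ∈ [−2, 2],
symmetric with zero diagonal; zero-variance motifs are flagged NaN and
excluded. Rows of Δr are clustered by complete-linkage agglomerative
clustering on Euclidean distances and the dendrogram cut at k = 5
modules — the defaults of the standard hierarchical-clustering call this
mirrors — with the linkage and metric recorded in the result.

## Synthetic screens

The generator emulates the two raw inputs with full ground truth.
Defaults are the package's reference study conditions: 12 targets × 3
sgRNAs + 3 non-targeting sgRNAs, 67 cells per sgRNA (≈ 200 per target
arm), log-normal read depth (median 100 sgRNA reads/cell, σ = 0.3), 16-bp
barcodes and 20-bp spacers mutually ≥ 2 mismatches apart, 5% read
contamination (a read drawing a uniformly random other spacer), 0.1%
per-base sequencing error; 1,500 peaks with Gamma(2) baseline rates
scaled to 4,000 expected insertions per cell, log-normal per-cell depth
factors (σ = 0.5), 20 disjoint 50-peak motifs, and each target doubling
its own motif's peak rates. Counts are Poisson
`X_ip ~ Poisson(d_i λ_p e_ip)` — sparse accessibility counts at these
depths are near-Poisson — with a Gamma–Poisson overdispersion switch for
robustness experiments. GC is drawn independently of effects so that
bias-matched backgrounds cannot absorb true signal; a confounded mode
(perturbed peaks GC-shifted +0.15) exists to demonstrate why the
matching matters. Doublets, when enabled, add a second cell's
independent draw under one barcode. A fragments-file emitter lays the
peaks on a synthetic chromosome with TSS sites at peak midpoints, so QC,
tile and peak matrices are exercised end-to-end; the per-peak insertion
counts of the emitted fragments reproduce the count matrix exactly.

What the generator does **not** emulate: genomic sequence (no real
motifs or GC computed from sequence), chromatin co-accessibility
structure beyond the injected effects, batch effects, ambient
contamination that correlates between barcodes, or knock-down phenotypes
such as dropout over time. Passing tests therefore demonstrate that the
pipeline recovers the structure it models — assignment truth, injected
motif effects, planted correlation blocks — not that it is robust to
every artifact of real screens.

All randomness flows from explicit seeds (numpy `SeedSequence` children
per stage); every seeded stage is byte-identical across reruns, and the
CLI writes a manifest of output checksums.

## Problem sizes used in the checks

The acceptance computations run at desk scale, chosen to keep the full
suite fast while leaving comfortable statistical margins: the 12-target
recovery screen at ≈ 2,600 cells × 1,500 peaks; network recovery at 40
motifs, 5 blocks (ρ = 0.6), 300 cells/arm, 10 seeds; purity detection at
300 cells/arm, 1,000 tiles, 30 planted mislabels, 3 seeds; calibration
at 200 replicates (20 motifs or 200 peaks each, 100 cells/arm). The
printed-arithmetic checks (cost per cell, assignment rate, differential
fractions) use the published run's own counts as inputs.

## Known limitations

- The binomial marker test is anti-conservative by construction (see
  above); it is retained because it reproduces the reference procedure,
  with the Wilcoxon path as the calibrated alternative.
- Purity refinement assumes the target's true effect is strong enough to
  separate its cells from controls; for null-like targets it removes
  most cells (by design, this is indistinguishable from misassignment).
- Iterative LSI feature re-selection and graph clustering are out of
  scope; peak calling, read alignment, and footprinting are upstream or
  external steps.
- The 10-bp plasmid barcode read-out is not implemented; spacer
  sequencing is the recommended and supported route.
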