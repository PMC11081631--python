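# Methods

`pigcorr` implements a pipeline that asks whether the visible pigmentation of
cultured retinal pigment epithelium (RPE) cells predicts their transcriptional
state, one cell at a time. Each cell is photographed as a bright-field z-stack
before being picked for single-cell RNA sequencing, so a per-cell color
measurement can be paired with a per-cell expression profile. The package
covers the full analysis — color quantification, brightness normalization,
clustering, gene–color correlation, and gene-set enrichment — together with a
synthetic-data generator that plants known signal so every stage can be
validated without any external download.

## Color quantification

A picked cell sits at a fixed position in the image (the instrument centers
it), so no segmentation is needed: a circular region of interest (ROI) of
radius 50 px at (195, 169) on a 400×330 px canvas covers the cell. For each of
the 21 z-planes and each RGB channel, the mean intensity inside the disk and
the mean over all remaining pixels (the background) are computed, and the
background mean is subtracted per plane. The per-plane differences are then
averaged across the stack, giving (ΔR, ΔG, ΔB) with an across-plane SD.

Conventions the underlying description leaves open, fixed here:

- Pixel coordinates are 0-based, (x, y) = (column, row), origin top-left; a
  pixel belongs to the disk when its center satisfies
  (px−cx)² + (py−cy)² ≤ r². Both are configurable through `RoiSpec`.
- The background mean is computed per plane (not once per stack).
- The across-plane SD uses the population convention (divide by n);
  `sd_mode="sample"` switches it.
- Planes with a saturated ROI (≥1 % of disk pixels at 255) are kept but the
  cell is flagged (`saturated` column).
- Stacks are read as R, G, B; the mCherry fluorescence channel of the
  acquisition protocol plays no role in the analysis and is ignored.

As QC, the 3×3 Pearson matrix of (ΔR, ΔG, ΔB) across cells is reported; on
this kind of bright-field data the three channels are nearly collinear
(r > 0.99), which is what justifies collapsing them into a single brightness
number. A zero-variance channel yields a missing entry, never a 0.

## Brightness and its normalization

Adding a virtual white background gives corrected channels
(Rcorr, Gcorr, Bcorr) = (255, 255, 255) + (ΔR, ΔG, ΔB); the brightness proxy
is the luma-weighted sum Y = 0.299·Rcorr + 0.587·Gcorr + 0.114·Bcorr. A
corrected channel above 255 (a cell locally brighter than its background,
within noise) is replaced by the largest value below 255, implemented as
255 − ε with ε = 2⁻²⁰ (configurable); the same clamp applies to Y itself in
the degenerate Δ = 0 case, keeping the subsequent logit finite. A corrected
channel ≤ 0 is a measurement error and raises.

Because Y piles up just under the white point, it is mapped to the real line
with a logit, Ynorm = ln(Y / (255 − Y)); natural log by default, base
configurable. Ynorm is the pigmentation covariate used downstream (darker
cell ⇒ smaller Ynorm). The weighted sum is evaluated as
B + wR·(R−B) + wG·(G−B) — algebraically identical since the weights sum to
one, but exact in floating point for gray cells, where Y must equal 255 + d
with no residue. Besides the luma weighting, blue-only and plain-mean proxies
are available (`proxy=` flag); with near-collinear channels the three differ
only marginally, and luma is the default used by the enrichment stage.

## Clustering

The transcriptome side follows a standard single-cell workflow with the
parameters this analysis specifies: library-size log-normalization
(ln(1 + 10⁴·count/total)), per-gene z-scoring (population SD, no clipping by
default; a clip flag exists), PCA on all genes (no variable-feature
selection by default), a k = 20 nearest-neighbor graph on the first 6
components, shared-nearest-neighbor Jaccard edge weights pruned below 1/15,
and Louvain modularity clustering at resolution 0.4. Labels are renumbered
0..K−1 by decreasing cluster size.

Two determinism choices are deliberate. PCA signs follow the convention that
each component's largest-|loading| gene is positive. Before building the
graph, cells are re-ordered canonically (lexicographic on their score rows,
cell id as tiebreak), so the partition is exactly invariant to the order in
which cells arrive — shuffling the input produces the identical clustering.
Louvain randomness is seeded. Per-cluster color summaries (n, mean, median,
quartiles of Y and Ynorm) provide the violin-plot table linking clusters to
pigmentation, and `marker_fraction` reports per-cluster detection rates of a
marker gene.

## Gene–color correlation

For each lineage separately, the Pearson correlation r between every gene's
scaled expression row and Ynorm is computed (population-moment estimator).
Pearson correlation is invariant to per-gene affine maps, so r is identical
on log-normalized and z-scored data; the pipeline computes it on the scaled
matrix to mirror the upstream convention. Genes with zero expression
variance get a missing r and are excluded from the ranking (logged); in the
pipeline, genes detected in fewer than 3 cells are excluded before scaling
(threshold configurable). Genes are ranked by |r| descending with
lexicographic tie-breaking for reproducibility, and top-k tables of positive
and negative correlates (k = 20 by default) are emitted alongside a `.rnk`
file interoperable with external preranked tools.

## Preranked enrichment

Enrichment uses the weighted running-sum statistic on the |r| ranking: at a
set member the sum rises by |r|^p normalized by the set's total weight
(p = 1 by default; p = 0 gives the classic Kolmogorov–Smirnov form), at a
non-member it falls by 1/(N − N_hit). ES is the signed maximum deviation from
zero (ties resolved toward the positive extremum); the leading edge is the
members at or before the extremum (after it, for ES < 0). Sets are gated to
[15, 500] members after restriction to the ranked universe (configurable).

The null is gene-label permutation: random same-size sets drawn from the
universe, n_perm = 1000 by default, fully seeded (each set derives an
independent substream keyed by its name, so results are independent of
collection order). The p-value conditions on the observed ES sign,
p = (1 + b)/(1 + m) with m the same-sign null draws and b those at least as
extreme, and NES = ES / mean(|null ES| of the same sign). This simple
permutation scheme has a hard p-value floor of 1/(1 + m) ≥ 1/(1 + n_perm);
adaptive multilevel p-value refinement, which would push below that floor, is
deliberately out of scope. FDR control is Benjamini–Hochberg across the
tested sets — the convention of permutation-based preranked tools — rather
than the NES-histogram FDR of the original GSEA; the two are not identical.

Significant sets (FDR < 0.05) are split by NES sign. Because the ranking is
by |r|, a positive NES means concentration near the top of the
absolute-correlation ranking, i.e. the set's members are strongly correlated
with brightness in either direction; output naming follows the convention
"brightness-correlated" (NES > 0) / "brightness-uncorrelated" (NES < 0) with
this caveat. Whether the leading edge is sign-consistent is not asserted —
the signed r of each leading-edge gene is available in the correlation
tables for inspection. Lineages are analyzed independently and the
significant lists intersected; only pathways enriched in every lineage
survive.

## Synthetic data

The generator defines the conditions under which the pipeline is validated.

**Images.** Each cell is a disk of radius 50 px at (195, 169) on a 400×330
canvas, 21 planes (all configurable). Every pixel has a shared gray base:
background level 200 outside the disk, 200·(1 − pigment·depth_factor) inside
(depth_factor = 1 by default, so a pigment level of 0.5 on background 200
gives in-disk 100 exactly in the noise-free case). Per plane, a shared
Gaussian pixel noise (SD 2), a scalar plane jitter (SD 1), and a small
independent per-channel noise (SD 0.5) are added, then values are rounded
and clipped to 8 bits. Because the channel-specific noise is tiny and
averages over ~7 850 disk pixels × 21 planes, the per-cell ΔR/ΔG/ΔB are
nearly collinear across a cohort (r > 0.99), reproducing the QC premise.
Pigment levels are drawn uniformly on [0.1, 0.9] per cell — the true
distribution in culture is unknown, and the uniform choice is a declared
assumption, not an inference.

**Counts.** Gene g in cell c is negative-binomial with mean
m·exp(βz_c − β²/2) and dispersion θ (θ = 2, baseline mean 10 for planted
genes; background genes have log-uniform means on [0.2, 20] and θ = 2),
where z is the standardized true Ynorm. The slope β for a planted gene is
calibrated so the Pearson correlation of its log-normalized expression with
Ynorm equals `target_rho`: the predicted r is computed from the exact NB
conditional moments of ln(1 + count·10⁴/T) (with T the design-expected
library size) via r = sd(E[y|z])·corr(E[y|z], z)/√(var(E[y|z]) + E var[y|z]),
and β is found by bracketed root-finding (tolerance 10⁻⁴, cached per
design). This is the variance-decomposition slope made exact: a first-order
β = ρ/√(1−ρ²)·σ_resid underestimates the slope at low counts, where the
log1p transform attenuates the signal. If the predicted r saturates below
the target (low mean, high dispersion), calibration raises rather than
returning a biased gene. Across 200 seeds at n = 500 the mean realized r
sits within 0.005 of the target for |ρ| ≤ 0.7.

**Bundles.** A study bundle holds, per lineage, cell metadata (with the true
pigment), a count matrix (same gene universe and the same planted sets in
every lineage), the analytic true Ynorm, and — when images are enabled —
per-cell image parameters from which stacks are regenerated lazily (a full
3×96-cell study is ~2.4 GB of pixels, so the pipeline streams
generate → measure → discard; `--save-images` materializes TIFFs). Planted
counts are generated against the *true* Ynorm; the analysis then measures
Ynorm from the images, as it would on real data. The measurement error is
dominated by 8-bit quantization and is negligible against the pigment spread
(measured vs true Ynorm correlate at r > 0.999), so realized gene
correlations against measured brightness track the planted targets. All
randomness derives from one root seed through named substreams (images,
counts, sets, lineages), making bundles and partial reruns byte-identical.

**What the generator does not emulate:** optics (point-spread function,
defocus between planes), UMI/barcode chemistry, doublets, batch or
cell-cycle structure, gene–gene correlation beyond the shared brightness
covariate, and any real pathway biology. Passing recovery tests therefore
demonstrates that the pipeline's statistics behave as designed under the
stated model — not that the biological conclusions transfer to any
particular real dataset.

## Problem sizes and numerical choices

Default validation sizes, chosen to exercise the asymptotics the statistics
rely on while staying desk-scale: recovery studies use 3 lineages × 500
cells × 2 000 genes with one 30-gene planted set (member target ρ = 0.5) and
50 decoy sets at n_perm = 1000; null-calibration studies use 300 cells,
2 000 genes, 50 decoy sets, n_perm = 500 over 50 seeds; the end-to-end run
uses the full image geometry at 3 × 96 cells. Degenerate inputs fail loudly:
empty rankings, constant Ynorm, zero-total cells, ROIs touching the canvas
edge, sets with zero hit weight, and unreachable correlation targets all
raise with the offending ids in the message.

## Known limitations

- The permutation p-value floor (≈ 1/n_perm) bounds how small BH-adjusted
  values can get; with ~50 tested sets, a single true positive cannot reach
  an adjusted value below ~50/n_perm regardless of effect size. Raising
  n_perm, or the out-of-scope multilevel scheme, is the remedy on real data.
- Louvain modularity at a fixed resolution is a heuristic; only strongly
  separated planted structure is guaranteed to be recovered exactly.
- The NB count model has no zero-inflation; sparse real data may behave
  differently at very low baseline means.
- The brightness proxy assumes the instrument's fixed ROI actually covers
  the cell; off-center cells would bias Δ toward zero.
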