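# Methods

This note documents the models, parameter choices and numerical decisions
behind `folliscape`, and what the synthetic benchmarks do and do not show
about real tissue.

## Synthetic scenes and cohorts

**Scene model.** A tile is a rectangle in continuous μm coordinates
(origin top-left, y downward, rasterisation rounds half-up). Follicles are
non-overlapping ellipses (axis ratio U(0.7, 1.0), orientation uniform),
placed by rejection sampling; an infeasible specification fails loudly
after a bounded number of attempts. Within each compartment every
phenotype is a homogeneous Poisson process at its configured density
(cells/1000 μm²). Spatial co-localization between a phenotype pair (A, B)
is generated Thomas-style: a fraction κ ∈ [0, 1] of B cells are Gaussian
offspring (scale σ, default 5 μm) of uniformly chosen A parents in the
same compartment, the rest independent. κ is the generative
co-localization dial; the Morisita-Horn index measured downstream is
monotone in it.

An optional hard-core radius (`min_separation_um`, default 0) thins the
pattern so no two nuclei are closer than the given distance, visiting
candidates in random order so no phenotype is preferentially retained and
programmed phenotype fractions stay unbiased. The pure Poisson default is
kept for all spatial statistics; the hard core (6 μm ≈ a lymphocyte
nucleus) is used for the detection/classification benchmark scenes, where
unresolvably overlapping nuclei would otherwise measure the point process
rather than the detector.

**Rendering.** Each marker yields a 2-channel image: DAPI (every cell) and
positive stain (marker-positive cells). Cells are Gaussian blobs
(σ = blob_radius/2, default radius 3 μm, intensity jitter 15%), combined
by maximum, over a constant background (0.05) with additive Gaussian noise
(sd 0.02) at 0.5 μm/pixel. Rendering refuses sub-pixel blob radii.

**Cohorts.** Per patient, phenotype densities get independent lognormal
random effects (log-sd 0.35, a realistic between-patient spread) and each
coupled pair gets κ ~ U(0.05, 0.95) by default. Time to progression is
exponential with rate `baseline · exp(Σ βⱼ zⱼ)` where zⱼ are the
cohort-standardised *true* generator features, with administrative
censoring at the horizon (default 12 years). The exponential
proportional-hazards model is the simplest whose Cox fit is unbiased,
which is what the recovery tests require. FLIPI (low/intermediate/high at
the frequencies of a typical advanced-stage FL cohort) and treatment are
sampled independently of the features, so FLIPI is a pure adjustment
covariate in the synthetic analyses.

What the generator does **not** emulate: nuclear texture and shape,
autofluorescence, spectral bleed-through between channels, staining
batch effects, irregular (non-elliptical) follicles, and tissue folds.
Passing benchmarks therefore demonstrate the correctness and statistical
calibration of the pipeline, not its performance on real stained tissue.

## Detection

The detector is a deliberately small encoder-decoder network
(conv–pool–conv–upsample–conv, ~3k parameters) with two heads: a 1×1
sigmoid convolution producing a centroid heatmap, and a pooled linear
count head producing a global cell count through a softplus. Training
minimises a weighted MSE to Gaussian-disk targets (σ = 3 px; weight
1 + 9·target, so sparse blob pixels are not drowned out by background)
plus λ·|ĉ − c|/(c + 1), the count regulariser (λ = 1). Networks are
implemented in a small NumPy engine (`folliscape.nn`: im2col convolutions,
hand-written backprop verified against central differences, Adam), which
keeps training single-threaded, seconds-fast and bit-reproducible under a
fixed seed. Inference on large tiles runs in overlapping 256 px chunks
whose margin exceeds the receptive field, so stitching is exact.

Centroids are heatmap peaks above τ = 0.5 with minimum separation
d_min = 5 μm (both configurable; borders included). Evaluation matches
predictions to truth one-to-one by greedy ascending-distance pairing
within a radius (default 8 μm): matched → TP, unmatched predictions → FP,
unmatched truth → FN. Greedy pairing is maximal but not maximum: on
sparse instances it agrees with an optimal (Hungarian) assignment ~99% of
the time, and can differ on dense noisy instances; the tests pin the
sparse-regime agreement. With both sets empty, precision/recall are
reported as 1 with an explicit degenerate flag.

## Phenotyping

Patches (28×28 px at 0.5 μm/px, zero-padded at edges) centred on detected
cells are classified by a VGG-style stack (conv-conv-pool ×2 → dense →
2-way softmax). A cell is positive when p_pos ≥ p_neg — an exact tie is
positive. One caution documented by the shuffle control: with a cleanly
separable stain feature, a single label-shuffled training run inherits the
chance imbalance between stain groups and its held-out AUC scatters widely
around 0.5; only the average over shuffles is anchored at chance.

Cross-plane merging treats each marker plane's positive centroids as one
layer: planes are processed in order, each new centroid greedily matched
(ascending distance, one-to-one per plane pair) to an existing
consolidated cell within the merge radius (default 5 μm ≈ half a
lymphocyte diameter), positions updated as running means, unmatched
centroids opening new cells. Every input centroid ends in exactly one
output cell. Duplicates within one plane (closer than d_min) are removed
with a warning. Phenotype labels are conjunctions of marker states;
a cell's canonical label lists its positive markers in panel order, while
query labels like `CD4+CD8+` constrain only the markers they mention.

## Compartments

Tissue is segmented from DAPI by Otsu thresholding (or a fixed threshold),
binary closing, hole filling and small-object removal, then vectorised to
μm-frame polygons by marching-squares contours with even-odd hole
handling. Follicle polygons are consumed from GeoJSON (repair of invalid
rings; overlapping follicles unioned with a warning) — follicle
segmentation itself is manual/external by design. Intra = ∪follicles ∩
tissue, inter = tissue − intra, so area additivity is exact. Polygon
boundaries count as inside (closed-set convention). Cells outside tissue
are excluded and logged; an exclusion rate above 20% warns. Densities pool
counts and areas over a patient's tiles before dividing — unbiased under
unequal tile tissue content, unlike averaging per-tile densities.

## Spatial statistics

Quadrats are Voronoi cells of a hexagonal seed lattice (default pitch
50 μm; for very sparse phenotypes the cohort analyses use 25 μm so the
expected count per quadrat stays O(1)), clipped to the compartment, empty
quadrats dropped. Because a point's Voronoi cell is exactly the region
nearest its seed, cell-to-quadrat assignment uses a KD-tree nearest-seed
lookup — identical to polygon membership but much faster; polygon clipping
is only performed for areas and export. The Morisita-Horn denominator is
written so both addends swap under x ↔ y, making the index bit-exactly
symmetric.

Per-patient co-localization concatenates quadrat count vectors across the
patient's tiles (keeping the quadrat scale constant) rather than averaging
per-tile indices. Known small-count behaviour, verified by test: for two
independent Poisson patterns with mean μ per quadrat, MH ≈ μ/(μ+1), so
the index rises with quadrat size and with density even without true
co-localization. In the survival-linkage simulations this makes the
measured MH an attenuated readout of the generative κ (Spearman ≈ 0.7
under the default between-patient density variation).

Nearest-neighbour profiles search per tile (distances never cross tile
boundaries), exclude the reference cell itself (distances strictly
positive), and label each candidate with the first candidate phenotype it
matches.

## Association statistics

* Group comparison: two-sided unpaired rank-sum (the "Wilcoxon" of common
  usage for unpaired data is the Mann-Whitney test). Exact p by full
  enumeration of group assignments with midranks when both n ≤ 8;
  tie-corrected normal approximation otherwise (SciPy).
* Multiplicity: Benjamini-Hochberg step-up (statsmodels), applied within
  feature families — densities and co-localizations are corrected
  separately.
* Median split: patients strictly above the cohort median form the high
  arm (ties low; with distinct values and even n the split is exactly
  50/50). Kaplan-Meier curves and the two-tailed log-rank test via
  lifelines. On tiny fully-observed samples the asymptotic log-rank p and
  the exact permutation p necessarily differ (the permutation p cannot go
  below 1/#arrangements); the oracle test therefore compares asymptotic vs
  permutation p at n = 30 via the Savage-scores equivalence.
* Cox: lifelines `CoxPHFitter` (Efron ties), Wald CIs; non-convergence and
  monotone likelihood surface as an explicit flag, never silently. FLIPI
  enters as an ordinal 0/1/2 score by default (one-hot optional). At least
  k + 1 events are required for k covariates.
* Spearman: exact permutation p (all n! rank pairings) for n ≤ 9, t
  approximation otherwise; constant inputs are reported missing.
* Missing features are excluded pairwise per test; features with more than
  50% missingness are dropped with a warning.

## Benchmark problem sizes

Chosen so the full default test suite runs in a few minutes on one CPU
while keeping every check statistically meaningful: detector/classifier
trained once per session on 20 easy 128×128 μm tiles (10 epochs / 3
epochs); detection metrics on 10–30 held-out tiles; Cox recovery on 100
cohorts of n = 200 (true features, no imaging); the survival-linkage power
analog on 50 measured cohorts of 40 patients × 2 tiles of 800×800 μm
(pair densities 0.5/1000 μm² inter-follicularly, κ ~ U(0,1) linked at
log-HR −1.5); co-expression recovery pooled over three 800×800 μm scenes
(~4,500 CD8+ cells, so the binomial 3σ band around the programmed 1.6% is
informative). The acceptance script uses the same designs with 30 power
replicates.

## Known limitations

* The detector and classifier are benchmarked on easy, well-separated
  synthetic scenes; no claim is made about crowded real tissue, stain
  artefacts, or cross-panel generalisation beyond the synthetic analog.
* Raw Morisita-Horn at sparse counts confounds abundance with
  co-location (see above); per-patient density is therefore always carried
  alongside MH in the association analyses.
* Follicle annotation is consumed, not produced.
* Greedy matching/merging is order-stable and fast but not globally
  optimal; ties in merge distance are broken by plane processing order.
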