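# Methods

This note documents the models and procedures implemented in `tribune`, the
choices made where the design was genuinely open, and what the synthetic
benchmarks do and do not demonstrate.

## Data model

An expression matrix is a cells × markers table of non-negative, finite
intensities with unique marker names and cell identifiers (unique within a
sample), optionally carrying per-cell sample ids and x/y centroids in image
units. Logic tables are validated strictly: entries must lie in {−1, 0, 1},
every cell type needs at least one +1 marker, and the labels `other`,
`undefined` and the empty string are reserved and rejected as user cell-type
names. Marker matching between logic and expression tables is exact and
case-sensitive, and a logic marker missing from the expression table is a
hard error — silently dropping it would silently change scores. A hierarchy
is an ordered list of logic tables whose non-root parents must be declared
at an earlier level.

On disk a hierarchy is either a directory of
`<order>_<level>__<parent>.csv` files (root parent `root`) or an XLSX
workbook (sheet order = level order, cell A1 = `parent=<label>`); the two
dialects are read into identical objects, which the test suite checks
table-for-table. The workbook parent-link convention is this package's own;
there is no standard encoding to follow.

## Preprocessing

A recipe is an ordered list of steps from {`clip_percentile(p)`, `log1p`,
`zscore`, `arcsinh(c)`, `minmax`}, each applied per marker — marker scales
are incommensurable, so no step is ever global. Steps run in user-declared
order. The imaging default is clip(99.9) → log1p → z-score → arcsinh(5);
clipping before the log keeps single hot pixels from dominating the
z-scores. The suspension default is clip(99.5) → minmax, the usual
"divide by a percentile-defined maximum" rescaling. `log` is implemented as
log1p because raw intensity tables routinely contain exact zeros; a plain
log would force an arbitrary pseudo-count. Percentiles use linear
interpolation between order statistics throughout the package, so test
values are exact. Z-scoring is computed across the whole input matrix by
default; per-sample standardization can be had by running samples
separately.

## SOM engine

Online Kohonen training: square grid, Gaussian neighborhood on grid
coordinates, Euclidean best-matching-unit rule, one randomly drawn cell per
step. Defaults: σ = 1.0 (grid units), learning rate 0.5. Both decay
exponentially to 1% of their initial values by the last step; an earlier
variant that decayed only to a third of the initial rate left enough
late-step jitter that a single-node map would finish visibly off the data
centroid, so the faster tail was adopted. The codebook is initialized from
a seeded sample of distinct cells (PCA-plane initialization is available via
`init="pca"`).

* Grid size: node count `G = round(5√N)`, side `ceil(√G)` clamped to
  [2, 50]. The heuristic fixes only a node count; the square shape and clamp
  are this package's choice.
* Iterations: `min(max(100·nodes, N), 200 000)` — roughly 100 updates per
  node, at least one pass over the cells, capped for very large inputs;
  overridable via `som.n_iterations`.
* Quantization error is the *unsquared* mean Euclidean distance to the BMU.
* Ties in BMU search go to the lowest node index (first argmin).
* Hyperparameter tuning is a seeded random search over
  (σ, lr) ∈ [0.001, 5]², log-uniform, default 20 trials; trial 1 always
  evaluates the package defaults, so tuning can never return a worse Q than
  not tuning. All trials share one training seed so candidates are compared
  on equal footing. When enabled, tuning runs per hierarchy level.

## Scoring and label assignment

Node medians (even occupancy → mean of the two middle values; empty nodes
dropped) are min-max scaled per marker **across nodes** before scoring, so
both the node values and the references lie in [0, 1], every squared
deviation is ≤ 1, and the score is a true [0, 1] similarity — which is what
makes fixed thresholds like 0.04 meaningful. The positive-marker reference
is the 99th percentile across nodes rather than the maximum, for robustness
against a single extreme node; the negative reference is the column minimum
(0 after scaling). The normalizer is `1/|M_i|`, the count of non-neutral
markers for that cell type: without it, types with more constrained markers
could not be compared on one scale. Neutral markers contribute to neither
the sum nor the normalizer.

Rule order is: `other` first (best score < `other_threshold`), then
`undefined` (gap < `undefined_threshold`), then argmax with ties broken by
logic-table row order. A tie implies a zero gap, so any positive
`undefined_threshold` already catches it; the explicit tie-break only
matters when both thresholds are zero. With a single candidate type the gap
is defined as the score itself. Threshold defaults (0.04, 0.001) are on the
[0, 1] score scale and are deliberately permissive; raising either can only
grow its ambiguous class, which the suite asserts as a monotonicity
property.

Small subsets (≤ `min_cluster_size`, default 1000 cells) skip clustering and
run the identical pipeline with cells standing in for nodes. Degenerate
corner: a single-cell subset scales to all zeros, every type scores exactly
1, and the cell is labeled `undefined` under any positive
`undefined_threshold` — this is documented, intended behavior (one cell
carries no contrast to score against).

## Hierarchy traversal

Levels run in declared order. A deeper table receives the cells whose
*deepest label so far* equals its parent label, rather than strictly the
immediately preceding level's label: with sibling branches (say, immune
subtypes at level 2 and stromal subtypes at level 3) the strict reading
would starve every branch but the first, because cells not covered by an
intermediate table hold a not-evaluated sentinel there. Cells labeled
`other`/`undefined` never cascade. A level whose parent population is empty
is skipped with a warning, not an error. Per-level SOM seeds are
`seed + level_index`, so levels differ but a run is exactly reproducible.
Cells whose label has no deeper table simply keep it as their final label.

## Metrics

Rand index (plain, pair-counting — the adjusted variant is exposed
separately to avoid conflation), accuracy, weighted F1, Cohen's κ and the
multi-class Matthews correlation are computed with scikit-learn behind the
module surface; the test suite verifies each against brute-force
implementations of the textbook formulas (pair enumeration for Rand,
confusion-matrix algebra for the rest) to 1e-9. Pielou's evenness is
`J = H / ln S` with natural-log Shannon entropy `H` over observed class
proportions and `S` observed classes; `S = 1` is defined as `J = 0`.
`other`/`undefined` predictions are ordinary classes during evaluation
unless `ignore_ambiguous` is set, which drops those cells first.

## Synthetic benchmarks

The generator draws marker intensities from truncated Gaussians on a
[0, 1]-ish scale: positive-role markers around 0.8, negative and neutral
around 0.2, s.d. 0.1, plus additive N(0, 0.05²) noise, clipped at zero.
Class counts follow the requested proportions exactly (largest-remainder
rounding, ties to earlier classes). The returned logic hierarchy encodes
exactly the roles used for generation. Presets:

* **default** — 6 populations (tumor, stroma, T, B, macrophage,
  endothelium) × 12 markers, two dedicated positive markers per type,
  proportions 0.30/0.25/0.15/0.12/0.10/0.08, 20 000 cells. At separation
  (0.8 − 0.2)/0.1 = 6 s.d. the mixture is essentially noiseless for a
  well-specified classifier (nearest-centroid accuracy ≥ 0.999, asserted),
  so the pipeline's ≥ 0.95 recovery bar measures the method, not the data.
* **hierarchical** — the same populations under root classes
  Tumor/Stromal/Immune, with shared CD45 (immune) and Vimentin (stromal)
  signals; exercises two-level cascading.
* **hard** — overlapping means (0.6 vs 0.4) and a positive marker shared
  between two types; deliberately triggers the `undefined` path.
* **spatial** — cells placed uniformly inside circular domains with
  per-domain composition on a rectangular field; domain centers may be
  fixed explicitly (the preset separates two domains by more than the
  100-unit neighbor radius so compositions do not mix at the boundary).

What passing these benchmarks does **not** show: robustness to lognormal
intensity tails, segmentation spillover, uneven staining, batch effects or
miscalibrated logic tables — none of which the generator models. The
truncated-Gaussian model is the simplest structure satisfying the
logic-table semantics, chosen deliberately over intensity realism.

## Spatial module

Neighbors are the *other* cells within Euclidean distance ≤ r (closed ball,
self excluded; default r = 100 coordinate units); a cell with no neighbors
gets a one-hot on its own type so rows always sum to 1. The implementation
uses a k-d tree but is contractually identical to the O(n²) rule, which the
suite asserts exactly. RCNs are k-means (k-means++, 10 restarts, seeded) on
the composition vectors, default k = 10; fewer than k distinct RCNs can
survive when clusters empty out.

## Problem sizes and determinism

The test suite and `scripts/acceptance.py` run the flat and hierarchical
benchmarks at 20 000 cells, the ambiguous mixture at 5 000 and the spatial
benchmark at 4 000 — sizes at which every behavior of interest (SOM path,
per-cell fallback, cascading, ambiguity, RCN recovery) is exercised while a
full run stays in the seconds range. All randomness flows from explicit
integer seeds through `numpy.random.default_rng`; identical inputs and seeds
give bit-identical codebooks, labels and output files (CSV floats are
written with 17 significant digits and parsed with round-trip precision).

## Known limitations

* Labels can only come from the logic table; unknown populations surface as
  `other`/`undefined` rather than as discovered types.
* Scores are bounded similarities, not calibrated probabilities.
* No batch-effect correction and no rectangular/toroidal/hexagonal SOM
  topologies; no GPU or batch training.
* Cross-sample RCN harmonization is out of scope: RCN ids are arbitrary
  per run.
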