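# tribune

Knowledge-based hierarchical cell phenotyping for multiplexed imaging and
suspension proteomic single-cell tables.

Multiplexed imaging technologies (t-CyCIF, CODEX, MIBI-TOF) and mass
cytometry measure dozens of protein markers per cell. Turning those
measurements into cell-type labels usually means either manual gating —
hard, experiment-specific thresholds that do not transfer between batches —
or training supervised models on expert-annotated cells, which are expensive
to produce for every new marker panel. `tribune` takes a third route: the
user writes down *panel knowledge* as a logic table and the package does the
rest, with no per-marker thresholds and no training labels.

## Method

The inputs are a cells × markers expression table and a hierarchy of logic
tables `L(c, m) ∈ {−1, 0, 1}`: marker `m` is expected present (+1), absent
(−1) or uninformative (0) in cell type `c`. Every cell type must have at
least one positive marker. For each hierarchy level:

1. **Cluster.** Cells are quantized with a self-organizing map (SOM) on a
   square grid sized by the `G = 5√N` node-count heuristic. Map quality is
   the quantization error `Q = (1/m) Σ_q ‖x_q − w_{i_q}‖`, the mean
   Euclidean distance of each cell to its best-matching node; σ and the
   learning rate can be tuned by seeded random search over `[0.001, 5]²`
   minimizing `Q`.
2. **Summarize.** Each occupied node becomes one row of a node matrix: the
   per-marker median over its member cells, then min-max scaled per marker
   across nodes into `[0, 1]`.
3. **Score.** For cell type `i`, the expected value of marker `j` is the
   99th percentile of the scaled column if `L(i,j) = +1` (robust maximum)
   and the column minimum if `L(i,j) = −1`; neutral markers are excluded.
   The node score is the bounded squared-error similarity

   `s_i(n_k) = (1/|M_i|) Σ_{j∈M_i} [1 − (v_kj − v̂_ij)²] ∈ [0, 1]`,

   where `M_i` is the set of non-neutral markers for type `i`.
4. **Label.** Each node takes the argmax cell type — unless its best score
   falls below `other_threshold` (default 0.04), which yields **"other"**
   (low signal across all candidates), or its best-vs-runner-up gap falls
   below `undefined_threshold` (default 0.001), which yields
   **"undefined"** (ambiguous identity). Every cell inherits its node's
   label. Subsets at or below `min_cluster_size` (default 1000 cells) skip
   the SOM and are scored per cell, so rare populations are not absorbed
   into coarse clusters.
5. **Recurse.** Each deeper logic table runs only on the cells currently
   carrying its parent label; "other"/"undefined" cells never cascade.

The package also ships preprocessing recipes (percentile clipping, log1p,
z-score, arcsinh with cofactor 5, min-max), the standard evaluation panel
(Rand index, accuracy, weighted F1, Cohen's κ, Matthews correlation,
Pielou's evenness), a ground-truthed synthetic-data generator, and a spatial
module that computes neighbor-composition vectors within a radius (default
100 units) and clusters them with k-means (default k = 10) into recurrent
cellular neighborhoods (RCNs).

## Worked example

```python
import tribune as tb

# 20,000 synthetic cells: 6 populations, 12 markers, known ground truth
sim = tb.simulate(tb.default_spec(n_cells=20_000, seed=42))
result = tb.run(sim.expression, sim.hierarchy, tb.RunConfig(seed=42))

report = tb.evaluate(result.final_labels(), sim.truth["final"])
print("accuracy      ", round(report.accuracy, 4))
print("weighted F1   ", round(report.weighted_f1, 4))
print("Cohen's kappa ", round(report.cohens_kappa, 4))
print("Pielou (pred) ", round(tb.pielou_evenness(result.final_labels()), 4))
```

prints

```
accuracy       1.0
weighted F1    1.0
Cohen's kappa  1.0
Pielou (pred)  0.9371
```

i.e. on this well-separated benchmark every one of the 20,000 cells is
assigned its true population (the SOM collapses each population onto a set
of pure nodes, and node medians sit exactly where the logic table expects
them); the Pielou value is the evenness of the predicted composition, below
1 because the simulated populations have unequal sizes.

The same pipeline is available from the shell:

```bash
tribune simulate --preset default --seed 42 --out sim/
tribune run --expression sim/cells.csv --logic sim/logic/ \
        --id-column cell_id --seed 42 --out labels.csv
tribune evaluate --pred labels.csv --truth sim/truth.csv
tribune rcn --labels labeled.csv --radius 100 --k 10 --seed 0 --out rcn.csv
tribune validate --logic sim/logic/
```

Exit codes: 0 success, 2 validation error, 1 runtime error.

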