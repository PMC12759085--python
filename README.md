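# morphlineage

Quantitative building blocks for studying how a developing tissue — for
example a zebrafish explant elongating into a tail-like structure — couples
cell-fate progression to cell movement. The package is aimed at
developmental biologists who already have (i) clustered time-series
single-cell RNA-seq with per-pair integrated embeddings and (ii) 3D cell
tracks exported from a spot tracker (Imaris-style CSV), and who want the
downstream statistics as reusable, tested code rather than one-off scripts.

Four analyses are provided, each with a ground-truthed synthetic generator
so the whole pipeline runs and is testable without any external data:

1. **Temporal lineage coupling (KNN).** For adjacent timepoints sharing an
   embedding, every later-timepoint cell is assigned a *source state*: the
   modal cluster among its k = 10 nearest earlier-timepoint cells
   (Euclidean distance; frequency ties resolved by the single nearest
   cell). For a later cluster c′ and earlier cluster c, the transition
   fraction is

   f(c → c′) = |{cells of c′ with source c}| / |c′|,

   and a lineage-graph edge is retained iff f > 0.20 (strict). Chaining
   over all adjacent pairs yields a directed graph over
   (cluster, timepoint) nodes.

2. **Track decomposition.** The observed trajectory OT of each cell mixes
   tissue elongation and cell-intrinsic migration. At least three
   non-migratory anchor cells (enveloping-layer epithelial cells) define
   the elongation trajectory ET as their centroid path; the migration
   trajectory is MT(t) = OT(t) − (ET(t) − ET(t₀)), so
   OT ≡ MT + ΔET exactly. Tracker gaps of ≤ 3 frames are linearly
   interpolated; longer gaps split tracks. Movement directions are
   projected to a 2D plane and binned into rose-plot histograms; a
   least-squares circle fit quantifies rotational migration.

3. **Neighbor retention.** Neighbors are cells within 15 μm (inclusive).
   Between timepoints t₀ < t₁ a cell's retention rate is
   |N(t₀) ∩ N(t₁)| / |N(t₀)| ∈ [0, 1] — near 1 for collective movement,
   decaying as cells rearrange. Rates grouped by interval length are
   compared by one-way ANOVA with Tukey HSD post hoc.

4. **Pseudo-bulk similarity.** Cluster expression profiles (mean of
   log-normalized expression) are correlated (Pearson) between a query
   dataset and a reference atlas over marker genes, giving a similarity
   heatmap and per-cluster best-match annotation.

## Worked example

`examples/01_lineage_coupling.py` simulates four developmental stages with
four cell states whose parent structure is the transition matrix below
(rows = later cluster, columns = earlier cluster), then recovers the
lineage graph:

```
candidate edges: 33, retained: 27

retained edges for the first timepoint pair:
  c0 (t0) -> c0 (t1): fraction 0.50 (50 cells)
  c1 (t0) -> c0 (t1): fraction 0.30 (30 cells)
  c1 (t0) -> c1 (t1): fraction 0.50 (50 cells)
  ...
recovered edge set equals ground truth (> 0.20 fractions): True
```

Each printed fraction is the share of the later cluster's 100 cells whose
nearest earlier neighbors sit in the named parent cluster; the generator's
two exact-0.20 transitions are correctly *not* retained because retention
requires strictly more than 20%. The other examples
(`02_track_decomposition.py`, `03_neighbor_retention.py`,
`04_pseudobulk_annotation.py`) walk through the remaining analyses the
same way — e.g. the neighbor-retention example prints mean rates falling
from 0.727 (frames 1–5) to 0.181 (frames 1–44) with ANOVA
F = 48.31, p ≈ 1e-25, the collective-to-dispersive signature.

A thin CLI wraps the same library calls:

```bash
morphlineage all --config run.yaml --seed 1 --out results/
morphlineage neighbors --tracks tracks.csv --radius 15 --pairs "1:5,1:10,1:20"
```

Every run writes a `manifest.json` with the resolved config, input
checksums and per-stage outputs; identical config + seed reproduces
byte-identical analytic outputs.

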