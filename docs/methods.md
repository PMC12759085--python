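# Methods

This note documents the models and numerical conventions behind
morphlineage's four analyses and its synthetic-data generators, the
defaults and why they were chosen, and what the synthetic benchmarks do —
and do not — demonstrate about real data.

## Temporal lineage coupling

**Model.** A developmental time series is a sequence of timepoint slices,
each holding cell ids, a low-dimensional embedding and per-cell cluster
labels. For an adjacent pair embedded in one shared space, each
later-timepoint cell is assigned a source state: the modal cluster among
its k nearest earlier-timepoint cells by Euclidean distance. On a modal
frequency tie, the cluster of the single nearest cell wins and the
assignment is flagged `tie_broken`. Cluster-level transition fractions are
counts over the *full* later-cluster size (every cell receives an
assignment, so there is no missingness), and an edge is retained iff its
fraction strictly exceeds the threshold ("more than 20%" with the default
0.20).

**Defaults.** k = 10 and threshold = 0.20 are the values used in the
tailbud-explant trajectory analyses this package operationalizes; both are
ordinary function arguments. k larger than the earlier population degrades
gracefully to "all earlier cells".

**Numerical conventions.** Distance ties at the k-th neighbor are resolved
deterministically by ascending (distance, cell-id) lexicographic order —
embeddings are real-valued so exact ties are rare, but reproducibility
should not depend on that. The distance metric is Euclidean in whatever
embedding is supplied; the package is agnostic to how the embedding was
built (integration, PCA, dimensionality) and records D in its outputs.

**Per-pair embeddings.** Time-series integration tools are typically run
per adjacent pair, so a middle timepoint has different coordinates in the
two pairs it belongs to. The package models this explicitly with
`AdjacentPair` and `chain_pairs`; `chain_timepoints` remains for data with
one global embedding. This distinction is not cosmetic: in a single static
embedding, a cluster that draws cells from two separated parent clusters
is itself spatially split, which corrupts neighbor labels for the *next*
pair — arbitrary split/merge structures are only cleanly recoverable with
per-pair spaces, which is also what re-integrating each pair produces.

## Track decomposition

**Model.** Tracks are time-ordered 3D positions (μm) at integer frame
indices (3 min/frame cadence by default; the interval is metadata, not
used in computation). The elongation trajectory ET is the centroid of at
least three anchor tracks over their common support. The migration
trajectory subtracts only *net* elongation displacement:
MT(t) = OT(t) − (ET(t) − ET(t₀)). Anchoring MT at the cell's own start was
a genuine design choice — plain "OT − ET" would re-center every cell near
the origin and lose its physical position; the chosen convention preserves
start points and makes OT ≡ MT + ΔET an exact identity (machine
precision).

**Gaps.** Trackers that allow gap closing (maximum gap 3 frames here)
export tracks with missing frames. Gaps of ≤ `max_gap` missing frames are
linearly interpolated and flagged; longer gaps split the track into
independently analyzed segments (`id#0`, `id#1`, …). Interpolation happens
before centroid/decomposition so anchor support is contiguous.

**Directions.** Displacements over a configurable window of frames are
projected to a 2D plane and binned into 16 equal bins over [0°, 360°),
angles counter-clockwise from the plane's +x axis. The default plane is
the two highest-variance axes of anchor displacement (the elongation
plane, by SVD), falling back to all supplied tracks when no anchors are
present; literal `"xy"`/`"xz"`/`"yz"` and explicit 2×3 bases are accepted.
Zero-length projections carry no angle; they are excluded from bins and
tallied, so binned counts plus the tally always equal the number of steps.

**Circle fit.** Rotational migration is quantified by projecting an MT
onto its best-fit plane (SVD) and solving the algebraic (Kåsa)
least-squares circle. Kåsa is biased for sparse, noisy short arcs but
exact for full circles and adequate at the noise levels tested; it is
linear and deterministic, which we value over the marginal accuracy of
iterative geometric fits.

## Neighbor retention

Neighbors are all *other* cells within the radius (default 15 μm),
boundary inclusive — "within a 15 μm radius" is read as ≤ — computed with
a k-d tree and symmetric by construction. The retention rate between two
timepoints is shared-neighbor count over initial-neighbor count, matched
by cell identity, with each timepoint's neighbor sets recomputed fresh
from the cells present in that frame (cells that disappear simply cannot
be shared). Cells with zero initial neighbors have an undefined rate; they
are excluded from the table and tallied separately rather than being
assigned 0.

Interval groups are compared with a one-way ANOVA (scipy) and Tukey HSD
pairwise adjusted p-values (statsmodels). Tukey was chosen as the post hoc
because the target analyses report ANOVA-adjusted pairwise p-values
without naming a procedure, and Tukey HSD is the standard choice for
all-pairs comparisons after a one-way ANOVA.

## Pseudo-bulk similarity

Cluster profiles are the mean of each cluster's cells on the
log-normalized scale (mean, not sum, so profiles are cluster-size
invariant; sum is available). Similarity is Pearson correlation over a
marker gene set intersected with both gene universes (≥ 3 genes required);
marker discovery is out of scope — markers are an input. Cross-dataset
gene-id harmonization is by an explicit mapping table only, never inferred
orthology. Zero-variance profiles yield NaN rather than 0 (a constant
profile has no defined correlation) and are excluded from best-match
argmax; argmax ties are broken by reference column order and flagged.
Identical profiles are reported at exactly 1.0, bypassing the last-ulp
round-off of the normalized dot product.

## Synthetic-data generators

The generators define the benchmark conditions; their defaults are fixed
and not tuned per experiment.

* **Timepoint series.** Earlier-timepoint clusters are isotropic Gaussian
  blobs (sd 1.0) with centers spaced `cluster_separation` (default 10·sd)
  along the first embedding axis; each later cluster's cells are divided
  over parent populations by *exact largest-remainder counts* of its
  transition-matrix row and drawn around the parent's center. Exact counts
  (rather than i.i.d. multinomial draws) make the true edge fractions
  equal the realized proportions exactly, so recovery tests are crisp —
  e.g. a 0.20 matrix entry with 100 cells/cluster produces a fraction of
  exactly 0.20, probing the strict retention rule.
* **Explant tracks.** Anchors follow a shared linear drift
  (default 1 μm/frame) from uniform starts in a 50 μm box; deep cells add
  a circle (default radius 5 μm, period 20 frames, random phase) in the
  plane orthogonal to the drift — mimicking tailbud rotation relative to
  the elongation axis and making plane recovery unambiguous — plus
  isotropic Gaussian positional noise. The ambient positional noise of
  real tracking data is not known from the source analyses; `noise_sd` is
  a free parameter (benchmarks use 0 and 10% of the rotation radius).
* **Expression pair.** Both datasets share a disjoint marker-block
  structure: cluster j elevates its own block of markers by
  `marker_effect` (default 2.0) over a baseline of 1.0, with per-cell
  Gaussian noise, 50 cells/cluster; the true correspondence is the
  identity. For two clusters with disjoint m-gene blocks among G genes the
  noiseless off-diagonal Pearson is −m/(G − m) in closed form, which the
  tests pin down.

All generators are bit-reproducible from their seed
(`numpy.random.default_rng`).

**What passing synthetic benchmarks shows — and doesn't.** The generators
emulate the *geometry* the methods rely on (separated clusters, rigid
drift plus rotation, marker-block specificity), not the messiness of real
data: no batch effects or imperfect integration, no cluster-boundary
ambiguity, no tracking misassignment, no count-distribution realism
(over-dispersion, dropout), no tissue mechanics. Passing means the
algorithms are implemented correctly and recover known structure under
their stated assumptions; it does not certify performance when those
assumptions degrade.

## Problem sizes and runtime

The bundled benchmarks use ≤ 2,400 cells across 6 timepoints, ≤ 120
tracks × 200 frames, and ≤ 250 cells × 60 genes — sizes at which the exact
O(n²) oracles used for cross-checking stay trivially cheap while every
code path (ties, thresholds, gaps, isolated cells, degenerate profiles) is
exercised. The test suite and the acceptance script each complete in well
under a minute on one CPU.

## Known limitations

* The KNN assignment is brute-force-verified only up to a few hundred
  cells per timepoint; at atlas scale the k-d tree path is the one
  exercised, with the documented tie rule but no exhaustive oracle.
* `chain_timepoints` trusts the caller's slice order as stage order;
  passing a reversed series produces a reversed-direction graph, not an
  error.
* The Kåsa circle fit underestimates radii for short noisy arcs (< half a
  revolution).
* Tukey HSD assumes approximately equal group variances; strongly unequal
  interval-group variances would warrant Games–Howell, which is not
  implemented.
* Pseudo-bulk correlation inherits marker quality: non-specific markers
  make best-match annotation unstable, and the package deliberately does
  not attempt marker discovery.
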