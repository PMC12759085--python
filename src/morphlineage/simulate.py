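"""Ground-truthed synthetic inputs for every pipeline stage.

Three generators emulate the data the analyses consume, with the ground
truth returned alongside so that recovery can be verified exactly:

* ``simulate_timepoint_series`` — clustered Gaussian blobs per timepoint in
  a shared embedding, with a known cluster-to-cluster transition matrix
  (the parentage structure the lineage-coupling KNN should recover).
* ``simulate_explant_tracks`` — an elongating tissue: anchor cells follow a
  shared drift (tissue elongation), deep cells add circular migration in a
  plane orthogonal to the drift, both with isotropic positional noise.
* ``simulate_expression_pair`` — two cluster-labeled expression datasets
  sharing a disjoint marker-block structure, with the identity as the true
  cluster correspondence.

Parent populations are allocated by exact largest-remainder counts rather
than i.i.d. draws, so the true transition fractions equal the realized
per-cluster proportions exactly. All generators are bit-reproducible from
their seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .lineage import AdjacentPair, LineageEdge, LineageGraph, TimepointSlice
from .pseudobulk import PseudobulkInput
from .tracks import CellTrack, Trajectory

__all__ = [
    "TimeSeriesSimSpec",
    "TrackSimSpec",
    "simulate_timepoint_series",
    "simulate_explant_tracks",
    "simulate_expression_pair",
]


@dataclass(frozen=True)
class TimeSeriesSimSpec:
    """Parameters for the clustered time-series generator.

    ``transition_matrix`` is row-stochastic with rows indexing *later*
    clusters and columns *earlier* clusters: entry (j, i) is the fraction
    of later cluster j's cells whose parent population is earlier cluster
    i. The same matrix applies to every adjacent timepoint pair.
    """

    n_timepoints: int
    clusters_per_timepoint: int
    cells_per_cluster: int
    transition_matrix: np.ndarray
    embedding_dim: int = 2
    cluster_separation: float = 10.0
    cluster_sd: float = 1.0
    seed: int = 0

    def __post_init__(self):
        tm = np.asarray(self.transition_matrix, dtype=float)
        object.__setattr__(self, "transition_matrix", tm)
        c = self.clusters_per_timepoint
        if self.n_timepoints < 2:
            raise ValueError("n_timepoints must be >= 2")
        if c < 1:
            raise ValueError("clusters_per_timepoint must be >= 1")
        if self.cells_per_cluster < 1:
            raise ValueError("cells_per_cluster must be >= 1")
        if self.embedding_dim < 1:
            raise ValueError("embedding_dim must be >= 1")
        if self.cluster_sd <= 0:
            raise ValueError("cluster_sd must be > 0")
        if tm.shape != (c, c):
            raise ValueError(
                f"transition_matrix must be ({c}, {c}), got {tm.shape}"
            )
        if np.any(tm < 0):
            raise ValueError("transition_matrix entries must be non-negative")
        if not np.allclose(tm.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("transition_matrix rows must each sum to 1")


@dataclass(frozen=True)
class TrackSimSpec:
    """Parameters for the elongating-tissue track generator.

    Anchor cells move by the shared elongation drift only; deep cells add a
    circle of ``rotation_radius`` traversed in ``rotation_period`` frames,
    lying in the plane orthogonal to ``elongation_velocity`` (falling back
    to the xy-plane for zero drift). ``frame_interval`` records the imaging
    cadence in minutes (default 3) as metadata.
    """

    n_anchor: int
    n_deep: int
    n_frames: int
    elongation_velocity: tuple = (1.0, 0.0, 0.0)  # length units / frame
    rotation_radius: float = 5.0
    rotation_period: int = 20
    noise_sd: float = 0.0
    frame_interval: float = 3.0  # minutes
    arena_size: float = 50.0  # start positions drawn uniformly in this box
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(
            self, "elongation_velocity", tuple(float(v) for v in self.elongation_velocity)
        )
        if self.n_anchor < 3:
            raise ValueError("n_anchor must be >= 3 (decomposition needs >= 3 anchors)")
        if self.n_deep < 0:
            raise ValueError("n_deep must be >= 0")
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")
        if self.rotation_radius < 0:
            raise ValueError("rotation_radius must be >= 0")
        if self.rotation_period < 1:
            raise ValueError("rotation_period must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def _largest_remainder_counts(fractions: np.ndarray, total: int) -> np.ndarray:
    """Integer counts summing to ``total`` proportional to ``fractions``,
    rounded by the largest-remainder rule (ties to the lower index)."""
    raw = fractions * total
    base = np.floor(raw).astype(int)
    rem = raw - base
    short = total - base.sum()
    order = np.lexsort((np.arange(len(rem)), -rem))
    base[order[:short]] += 1
    return base


def simulate_timepoint_series(spec: TimeSeriesSimSpec):
    """Generate a clustered time series plus its ground-truth lineage graph.

    Mirrors a per-pair-integrated time series: each adjacent timepoint pair
    gets its own shared embedding space, in which the earlier timepoint's
    clusters sit as separated Gaussian blobs (centers spaced
    ``cluster_separation`` apart along the first axis) and each later
    cluster's cells are split over parent populations by exact
    largest-remainder counts of its transition-matrix row, every cell drawn
    around its *parent* cluster's center. A middle timepoint keeps its cell
    ids and cluster labels across the two pairs it belongs to; only its
    coordinates differ between pair spaces.

    Returns ``(pairs, truth)`` — a list of :class:`AdjacentPair` and the
    ground-truth :class:`LineageGraph` whose edge fractions are the
    realized parent proportions (counts / cells_per_cluster).
    """
    rng = np.random.default_rng(spec.seed)
    c, m, d = spec.clusters_per_timepoint, spec.cells_per_cluster, spec.embedding_dim
    centers = np.zeros((c, d))
    centers[:, 0] = np.arange(c) * spec.cluster_separation
    labels = [f"c{i}" for i in range(c)]

    cell_ids = {
        t: [f"t{t}_c{j}_{s}" for j in range(c) for s in range(m)]
        for t in range(spec.n_timepoints)
    }
    cluster_labels = [labels[j] for j in range(c) for _ in range(m)]

    # parent-population counts per (pair, later cluster): fixed by the matrix
    parent_counts = np.stack(
        [_largest_remainder_counts(spec.transition_matrix[j], m) for j in range(c)]
    )

    pairs = []
    edges = []
    nodes = [(lab, t) for t in range(spec.n_timepoints) for lab in labels]
    for t in range(spec.n_timepoints - 1):
        earlier_emb = np.vstack(
            [
                centers[j] + rng.normal(0.0, spec.cluster_sd, size=(m, d))
                for j in range(c)
            ]
        )
        later_rows = []
        for j in range(c):
            for i in range(c):
                n = int(parent_counts[j, i])
                if n:
                    later_rows.append(
                        centers[i] + rng.normal(0.0, spec.cluster_sd, size=(n, d))
                    )
        later_emb = np.vstack(later_rows)
        pairs.append(
            AdjacentPair(
                earlier=TimepointSlice(t, cell_ids[t], earlier_emb, cluster_labels),
                later=TimepointSlice(t + 1, cell_ids[t + 1], later_emb, cluster_labels),
            )
        )
        for j in range(c):
            for i in range(c):
                n = int(parent_counts[j, i])
                if n:
                    edges.append(
                        LineageEdge(
                            earlier_cluster=labels[i],
                            earlier_timepoint=t,
                            later_cluster=labels[j],
                            later_timepoint=t + 1,
                            fraction=n / m,
                            n_cells=n,
                            retained=True,
                        )
                    )
    truth = LineageGraph(nodes=nodes, edges=edges, threshold=0.0)
    return pairs, truth


def simulate_explant_tracks(spec: TrackSimSpec):
    """Generate anchor + deep cell tracks for an elongating tissue.

    Returns ``(tracks, true_et, true_mt)`` where ``true_et`` is the
    noiseless anchor-centroid trajectory and ``true_mt`` maps each track id
    to its noiseless migration trajectory (constant start position for
    anchors; the migration circle for deep cells).
    """
    rng = np.random.default_rng(spec.seed)
    v = np.asarray(spec.elongation_velocity, dtype=float)
    t = np.arange(spec.n_frames)
    drift = np.outer(t, v)

    # rotation plane orthogonal to the elongation axis (xy for zero drift)
    if np.allclose(v, 0):
        u1, u2 = np.array([1.0, 0, 0]), np.array([0, 1.0, 0])
    else:
        vn = v / np.linalg.norm(v)
        probe = np.array([0.0, 0.0, 1.0])
        if abs(probe @ vn) > 0.9:
            probe = np.array([0.0, 1.0, 0.0])
        u1 = probe - (probe @ vn) * vn
        u1 /= np.linalg.norm(u1)
        u2 = np.cross(vn, u1)

    tracks = []
    true_mt = {}
    anchor_true = []
    for a in range(spec.n_anchor):
        start = rng.uniform(0, spec.arena_size, size=3)
        clean = start + drift
        anchor_true.append(clean)
        noisy = clean + rng.normal(0.0, spec.noise_sd, size=(spec.n_frames, 3))
        tid = f"A{a}"
        tracks.append(CellTrack(tid, t, noisy, role="anchor"))
        true_mt[tid] = Trajectory(t, np.tile(start, (spec.n_frames, 1)))
    true_et = Trajectory(t, np.mean(anchor_true, axis=0))

    omega = 2 * np.pi / spec.rotation_period
    for dcell in range(spec.n_deep):
        center = rng.uniform(0, spec.arena_size, size=3)
        phase = rng.uniform(0, 2 * np.pi)
        circle = spec.rotation_radius * (
            np.outer(np.cos(omega * t + phase), u1)
            + np.outer(np.sin(omega * t + phase), u2)
        )
        clean_mt = center + circle
        noisy = clean_mt + drift + rng.normal(0.0, spec.noise_sd, size=(spec.n_frames, 3))
        tid = f"D{dcell}"
        tracks.append(CellTrack(tid, t, noisy, role="deep"))
        true_mt[tid] = Trajectory(t, clean_mt)
    return tracks, true_et, true_mt


def simulate_expression_pair(
    n_clusters: int,
    n_genes: int,
    markers_per_cluster: int,
    noise_sd: float,
    seed: int,
    marker_effect: float = 2.0,
    cells_per_cluster: int = 50,
    baseline: float = 1.0,
):
    """Generate a query/reference dataset pair with shared marker structure.

    Cluster j in *both* datasets up-regulates its own disjoint block of
    ``markers_per_cluster`` genes by ``marker_effect`` above ``baseline``
    (log-normalized scale); per-cell expression adds isotropic Gaussian
    noise of ``noise_sd``. The true correspondence is the identity
    permutation; returned as ``(query, reference, correspondence)`` where
    correspondence maps query cluster label -> reference cluster label.
    """
    if markers_per_cluster * n_clusters > n_genes:
        raise ValueError(
            f"marker blocks need {markers_per_cluster * n_clusters} genes "
            f"but only {n_genes} are available"
        )
    if n_clusters < 1 or markers_per_cluster < 1:
        raise ValueError("n_clusters and markers_per_cluster must be >= 1")
    rng = np.random.default_rng(seed)
    genes = [f"g{g}" for g in range(n_genes)]
    labels = [f"c{j}" for j in range(n_clusters)]
    means = np.full((n_clusters, n_genes), float(baseline))
    markers = {}
    for j in range(n_clusters):
        block = slice(j * markers_per_cluster, (j + 1) * markers_per_cluster)
        means[j, block] += marker_effect
        markers[labels[j]] = genes[block]

    def make_dataset():
        expr = np.repeat(means, cells_per_cluster, axis=0)
        expr = expr + rng.normal(0.0, noise_sd, size=expr.shape)
        np.maximum(expr, 0.0, out=expr)
        cl = np.repeat(labels, cells_per_cluster).tolist()
        return PseudobulkInput(
            expression=expr, cluster_labels=cl, gene_ids=genes, markers=markers
        )

    query = make_dataset()
    reference = make_dataset()
    correspondence = dict(zip(labels, labels))
    return query, reference, correspondence
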