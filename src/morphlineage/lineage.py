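"""KNN-based temporal lineage coupling across adjacent timepoints.

Given two timepoints of a developmental time series that share a
low-dimensional embedding (e.g. a batch-integrated PCA/UMAP space), every
cell of the later timepoint is assigned a *source state*: the modal cluster
among its k nearest earlier-timepoint cells. Aggregating those assignments
per later cluster yields a directed lineage graph over (cluster, timepoint)
nodes, in which a cluster-to-cluster connection is retained only when more
than a threshold fraction (default 20%) of the later cluster's cells trace
back to the same earlier cluster.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

__all__ = [
    "TimepointSlice",
    "AdjacentPair",
    "SourceAssignment",
    "LineageEdge",
    "LineageGraph",
    "assign_source_states",
    "build_lineage_graph",
    "chain_timepoints",
    "chain_pairs",
]


@dataclass(frozen=True)
class TimepointSlice:
    """Cells of one developmental timepoint in a shared embedding.

    Parameters
    ----------
    timepoint_label : ordered stage identifier (e.g. hpf value).
    cell_ids : unique per-cell identifiers.
    embedding : (n_cells, D) real coordinates, D >= 1.
    cluster_labels : categorical label per cell.
    """

    timepoint_label: object
    cell_ids: tuple
    embedding: np.ndarray
    cluster_labels: tuple

    def __post_init__(self):
        emb = np.asarray(self.embedding, dtype=float)
        object.__setattr__(self, "embedding", emb)
        object.__setattr__(self, "cell_ids", tuple(self.cell_ids))
        object.__setattr__(self, "cluster_labels", tuple(self.cluster_labels))
        if emb.ndim != 2 or emb.shape[1] < 1:
            raise ValueError("embedding must be a 2-D array with D >= 1")
        if len(self.cell_ids) != emb.shape[0]:
            raise ValueError("cell_ids length must equal embedding row count")
        if len(self.cluster_labels) != emb.shape[0]:
            raise ValueError("cluster_labels length must equal embedding row count")
        if len(set(self.cell_ids)) != len(self.cell_ids):
            raise ValueError("cell_ids must be unique within a timepoint")

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    @property
    def clusters(self) -> list:
        seen: dict = {}
        for c in self.cluster_labels:
            seen.setdefault(c, None)
        return list(seen)


@dataclass(frozen=True)
class AdjacentPair:
    """Two adjacent timepoints embedded in one shared space.

    Time-series integration (e.g. Harmony) is typically run per adjacent
    pair, so a middle timepoint has different coordinates in the two pairs
    it belongs to; its cell ids and cluster labels are stable.
    """

    earlier: TimepointSlice
    later: TimepointSlice

    def __post_init__(self):
        if self.earlier.embedding.shape[1] != self.later.embedding.shape[1]:
            raise ValueError("pair members must share embedding dimensionality")


@dataclass(frozen=True)
class SourceAssignment:
    """Source state assigned to one later-timepoint cell."""

    later_cell_id: object
    assigned_source_cluster: object
    neighbor_ids: tuple
    tie_broken: bool


@dataclass(frozen=True)
class LineageEdge:
    earlier_cluster: object
    earlier_timepoint: object
    later_cluster: object
    later_timepoint: object
    fraction: float
    n_cells: int
    retained: bool


@dataclass
class LineageGraph:
    """Directed graph over (cluster, timepoint) nodes.

    ``edges`` holds every candidate connection with its transition fraction
    (the proportion of the later cluster's cells assigned that earlier
    cluster as source); ``retained`` marks those strictly above the
    threshold. Retained edges are the lineage graph proper; the rest are
    kept for audit.
    """

    nodes: list = field(default_factory=list)  # (cluster, timepoint) pairs
    edges: list = field(default_factory=list)  # LineageEdge
    threshold: float = 0.20

    @property
    def retained_edges(self) -> list:
        return [e for e in self.edges if e.retained]

    def retained_edge_set(self) -> set:
        return {
            (e.earlier_cluster, e.earlier_timepoint, e.later_cluster, e.later_timepoint)
            for e in self.edges
            if e.retained
        }

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "earlier_cluster": e.earlier_cluster,
                    "earlier_tp": e.earlier_timepoint,
                    "later_cluster": e.later_cluster,
                    "later_tp": e.later_timepoint,
                    "fraction": e.fraction,
                    "n_cells": e.n_cells,
                    "retained": e.retained,
                }
                for e in self.edges
            ]
        )

    def to_networkx(self, retained_only: bool = True):
        import networkx as nx

        g = nx.DiGraph(threshold=self.threshold)
        for cluster, tp in self.nodes:
            g.add_node((cluster, tp), cluster=cluster, timepoint=tp)
        for e in self.edges:
            if retained_only and not e.retained:
                continue
            g.add_edge(
                (e.earlier_cluster, e.earlier_timepoint),
                (e.later_cluster, e.later_timepoint),
                fraction=e.fraction,
                n_cells=e.n_cells,
                retained=e.retained,
            )
        return g

    def merge(self, other: "LineageGraph") -> "LineageGraph":
        nodes = list(dict.fromkeys(self.nodes + other.nodes))
        return LineageGraph(nodes=nodes, edges=self.edges + other.edges, threshold=self.threshold)


def _k_nearest(earlier: TimepointSlice, point: np.ndarray, k: int, tree: cKDTree) -> list[int]:
    """Indices of the k nearest earlier cells, distance ties at the k-th
    neighbor broken by ascending cell-id order (deterministic)."""
    n = earlier.n_cells
    k_eff = min(k, n)
    dists, _ = tree.query(point, k=k_eff)
    dists = np.atleast_1d(dists)
    r = dists[-1]
    # All candidates at distance <= r, then lexicographic (distance, id order).
    cand = tree.query_ball_point(point, r * (1 + 1e-12) if r > 0 else 0.0)
    if len(cand) < k_eff:  # numerical guard
        cand = list(range(n))
    cand = np.asarray(cand)
    d = np.linalg.norm(earlier.embedding[cand] - point, axis=1)
    id_rank = np.argsort(np.argsort([str(earlier.cell_ids[i]) for i in cand]))
    order = np.lexsort((id_rank, d))
    return list(cand[order][:k_eff])


def assign_source_states(
    earlier: TimepointSlice, later: TimepointSlice, k: int = 10
) -> list[SourceAssignment]:
    """Assign each later-timepoint cell a source cluster from its k nearest
    earlier-timepoint cells (Euclidean distance in the shared embedding).

    The modal cluster among the k neighbors is assigned; when two or more
    clusters tie at the maximal frequency, the cluster of the single nearest
    neighbor is used and the assignment is flagged ``tie_broken``. If the
    earlier timepoint has fewer than k cells, all of them are used.
    """
    if earlier.n_cells < 1:
        raise ValueError("earlier slice must contain at least one cell")
    if earlier.embedding.shape[1] != later.embedding.shape[1]:
        raise ValueError(
            "embedding dimension mismatch: earlier has "
            f"{earlier.embedding.shape[1]}, later has {later.embedding.shape[1]}"
        )
    if k < 1:
        raise ValueError("k must be >= 1")

    tree = cKDTree(earlier.embedding)
    assignments = []
    for i, cid in enumerate(later.cell_ids):
        nn = _k_nearest(earlier, later.embedding[i], k, tree)
        labels = [earlier.cluster_labels[j] for j in nn]
        counts = Counter(labels)
        top = max(counts.values())
        modal = [c for c, v in counts.items() if v == top]
        if len(modal) == 1:
            cluster, tie = modal[0], False
        else:
            cluster, tie = labels[0], True  # nearest neighbor's cluster
        assignments.append(
            SourceAssignment(
                later_cell_id=cid,
                assigned_source_cluster=cluster,
                neighbor_ids=tuple(earlier.cell_ids[j] for j in nn),
                tie_broken=tie,
            )
        )
    return assignments


def build_lineage_graph(
    assignments: Sequence[SourceAssignment],
    earlier: TimepointSlice,
    later: TimepointSlice,
    threshold: float = 0.20,
) -> LineageGraph:
    """Aggregate per-cell source assignments into cluster-level edges.

    For each (earlier cluster c, later cluster c') pair the transition
    fraction is the number of c' cells assigned source c divided by the full
    size of c'. An edge is retained iff its fraction is strictly greater
    than ``threshold`` ("more than 20%" by default). All candidate fractions
    are kept on the graph for audit.
    """
    if not (0 <= threshold < 1):
        raise ValueError(f"threshold must be in [0, 1), got {threshold}")
    later_ids = set(later.cell_ids)
    cluster_of = dict(zip(later.cell_ids, later.cluster_labels))
    sizes = Counter(later.cluster_labels)

    counts: Counter = Counter()
    for a in assignments:
        if a.later_cell_id not in later_ids:
            raise ValueError(f"assignment references unknown later cell {a.later_cell_id!r}")
        counts[(a.assigned_source_cluster, cluster_of[a.later_cell_id])] += 1

    nodes = [(c, earlier.timepoint_label) for c in earlier.clusters]
    nodes += [(c, later.timepoint_label) for c in later.clusters]
    edges = []
    for (src, dst), n in sorted(counts.items(), key=lambda kv: (str(kv[0][0]), str(kv[0][1]))):
        frac = n / sizes[dst]
        edges.append(
            LineageEdge(
                earlier_cluster=src,
                earlier_timepoint=earlier.timepoint_label,
                later_cluster=dst,
                later_timepoint=later.timepoint_label,
                fraction=frac,
                n_cells=n,
                retained=frac > threshold,
            )
        )
    return LineageGraph(nodes=nodes, edges=edges, threshold=threshold)


def chain_timepoints(
    slices: Sequence[TimepointSlice], k: int = 10, threshold: float = 0.20
) -> LineageGraph:
    """Run the pairwise source-state assignment over every adjacent pair of
    an ordered series and union the resulting graphs.

    ``slices`` are taken in the given order as the stage order and must all
    live in one shared embedding space; the node set covers every
    (cluster, timepoint) observed in the series. When each adjacent pair
    has its own integrated embedding, use :func:`chain_pairs` instead.
    """
    if len(slices) < 2:
        raise ValueError("chain_timepoints requires at least 2 timepoint slices")
    graph = LineageGraph(threshold=threshold)
    for c in slices[0].clusters:
        graph.nodes.append((c, slices[0].timepoint_label))
    for earlier, later in zip(slices[:-1], slices[1:]):
        asg = assign_source_states(earlier, later, k=k)
        graph = graph.merge(build_lineage_graph(asg, earlier, later, threshold=threshold))
    return graph


def chain_pairs(
    pairs: Sequence[AdjacentPair], k: int = 10, threshold: float = 0.20
) -> LineageGraph:
    """Union of per-pair lineage graphs for a series of adjacent-timepoint
    pairs, each pair embedded in its own shared space."""
    if len(pairs) < 1:
        raise ValueError("chain_pairs requires at least 1 adjacent pair")
    graph = LineageGraph(threshold=threshold)
    for p in pairs:
        asg = assign_source_states(p.earlier, p.later, k=k)
        graph = graph.merge(build_lineage_graph(asg, p.earlier, p.later, threshold=threshold))
    return graph
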