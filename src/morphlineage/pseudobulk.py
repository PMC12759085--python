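"""Pseudo-bulk aggregation and marker-gene correlation against a reference.

Cluster-level expression profiles ("pseudo-bulks") are obtained by
averaging the (log-normalized) expression of each cluster's cells. A query
dataset is compared to a reference atlas by computing, over a shared set of
marker genes, the Pearson correlation between every query profile and
every reference profile; the resulting similarity matrix supports
annotation-by-best-match of query clusters. Marker discovery itself is out
of scope — markers are an input, typically from a differential-expression
tool.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import sparse

__all__ = [
    "PseudobulkInput",
    "SimilarityMatrix",
    "aggregate_pseudobulk",
    "marker_correlation",
    "best_match",
]


@dataclass
class PseudobulkInput:
    """Cells × genes expression with per-cell cluster labels.

    ``expression`` is non-negative on a normalized (typically log) scale,
    dense or scipy-sparse. ``markers`` optionally maps cluster -> marker
    gene list.
    """

    expression: object  # (n_cells, n_genes) array or sparse matrix
    cluster_labels: Sequence
    gene_ids: Sequence[str]
    markers: dict | None = None

    def __post_init__(self):
        n_cells, n_genes = self.expression.shape
        if len(self.cluster_labels) != n_cells:
            raise ValueError("cluster_labels length must equal cell count")
        if len(self.gene_ids) != n_genes:
            raise ValueError("gene_ids length must equal gene count")
        if len(set(self.gene_ids)) != n_genes:
            raise ValueError("gene_ids must be unique")

    def marker_union(self) -> list:
        if not self.markers:
            return []
        out: dict = {}
        for genes in self.markers.values():
            for g in genes:
                out.setdefault(g, None)
        return list(out)


@dataclass
class SimilarityMatrix:
    """Query × reference cluster Pearson correlations over marker genes.

    Entries lie in [−1, 1]; a pair involving a zero-variance (constant)
    profile has no defined correlation and is stored as NaN.
    """

    matrix: pd.DataFrame  # rows = query clusters, cols = reference clusters
    markers: tuple
    n_genes: int


def aggregate_pseudobulk(inp: PseudobulkInput, agg: str = "mean") -> pd.DataFrame:
    """Cluster × gene profile matrix (mean per cluster by default).

    The mean is cluster-size-invariant, which keeps profiles comparable
    across datasets with different cell counts; ``agg="sum"`` is available
    for count-style aggregation.
    """
    if agg not in ("mean", "sum"):
        raise ValueError(f"agg must be 'mean' or 'sum', got {agg!r}")
    x = inp.expression
    if sparse.issparse(x):
        x = np.asarray(x.todense())
    else:
        x = np.asarray(x, dtype=float)
    labels = pd.Series(list(inp.cluster_labels))
    clusters = labels.drop_duplicates().tolist()
    rows = []
    for c in clusters:
        mask = (labels == c).to_numpy()
        if mask.sum() == 0:
            raise ValueError(f"cluster {c!r} has no cells")
        block = x[mask]
        rows.append(block.mean(axis=0) if agg == "mean" else block.sum(axis=0))
    return pd.DataFrame(np.vstack(rows), index=clusters, columns=list(inp.gene_ids))


def _pearson_rows(raw_a: np.ndarray, raw_b: np.ndarray) -> np.ndarray:
    """Pearson correlation of every row of a against every row of b,
    NaN where either profile is constant. Identical non-constant profiles
    correlate at exactly 1.0 (round-off is squashed for that case)."""
    a = raw_a - raw_a.mean(axis=1, keepdims=True)
    b = raw_b - raw_b.mean(axis=1, keepdims=True)
    sa = np.sqrt((a**2).sum(axis=1))
    sb = np.sqrt((b**2).sum(axis=1))
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (a @ b.T) / np.outer(sa, sb)
    r[np.outer(sa == 0, np.ones_like(sb, dtype=bool))] = np.nan
    r[np.outer(np.ones_like(sa, dtype=bool), sb == 0)] = np.nan
    np.clip(r, -1.0, 1.0, out=r, where=~np.isnan(r))
    near_one = np.argwhere(np.abs(r - 1.0) < 1e-9)
    for i, j in near_one:
        if sa[i] > 0 and np.array_equal(raw_a[i], raw_b[j]):
            r[i, j] = 1.0
    return r


def marker_correlation(
    query_profiles: pd.DataFrame,
    reference_profiles: pd.DataFrame,
    markers: Sequence[str],
    id_map: dict | None = None,
) -> SimilarityMatrix:
    """Pearson correlation over shared marker genes for every
    query–reference cluster pair.

    ``id_map`` optionally translates query gene ids to reference ids (an
    explicit mapping table, e.g. for cross-species symbol harmonization);
    markers are given in query id space. At least 3 markers must survive
    the intersection with both gene universes.
    """
    if id_map:
        q_to_r = {q: id_map.get(q, q) for q in markers}
    else:
        q_to_r = {q: q for q in markers}
    shared = [
        q
        for q in dict.fromkeys(markers)
        if q in query_profiles.columns and q_to_r[q] in reference_profiles.columns
    ]
    if len(shared) < 3:
        raise ValueError(
            f"only {len(shared)} marker genes are shared between query and "
            f"reference (need >= 3): {shared}"
        )
    q = query_profiles[shared].to_numpy(dtype=float)
    r = reference_profiles[[q_to_r[g] for g in shared]].to_numpy(dtype=float)
    mat = pd.DataFrame(
        _pearson_rows(q, r),
        index=query_profiles.index,
        columns=reference_profiles.index,
    )
    return SimilarityMatrix(matrix=mat, markers=tuple(shared), n_genes=len(shared))


def best_match(sim: SimilarityMatrix) -> pd.DataFrame:
    """Best-correlated reference cluster per query cluster.

    NaN (undefined-correlation) entries are excluded from the argmax; ties
    are broken by reference column order and flagged. Columns: query,
    reference, correlation, tie.
    """
    if sim.matrix.empty:
        raise ValueError("similarity matrix is empty")
    rows = []
    for qc, row in sim.matrix.iterrows():
        valid = row.dropna()
        if valid.empty:
            rows.append({"query": qc, "reference": None, "correlation": np.nan, "tie": False})
            continue
        best = valid.max()
        winners = [c for c in sim.matrix.columns if c in valid.index and valid[c] == best]
        rows.append(
            {
                "query": qc,
                "reference": winners[0],
                "correlation": float(best),
                "tie": len(winners) > 1,
            }
        )
    return pd.DataFrame(rows)
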