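"""Radius-based neighborhoods and neighbor-retention statistics.

A cell's neighbors at a timepoint are all other cells within a fixed
Euclidean radius (default 15 μm, boundary inclusive). Between two
timepoints the *neighbor rate* of a cell is the number of neighbors shared
by identity divided by its neighbor count at the initial timepoint — 1.0
when the neighborhood is perfectly retained (collective movement), falling
toward 0 as cells rearrange (dispersive movement). Rates grouped by
interval length are compared with a one-way ANOVA plus Tukey HSD.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial import cKDTree

__all__ = [
    "PositionFrame",
    "NeighborRateTable",
    "GroupComparison",
    "find_neighbors",
    "neighbor_rate",
    "compare_interval_groups",
    "frames_from_tracks",
]


@dataclass(frozen=True)
class PositionFrame:
    """3D cell positions (μm) at one time index."""

    time_index: int
    cell_ids: tuple
    positions: np.ndarray  # (n, 3)

    def __post_init__(self):
        object.__setattr__(self, "cell_ids", tuple(self.cell_ids))
        p = np.asarray(self.positions, dtype=float)
        object.__setattr__(self, "positions", p)
        if p.ndim != 2 or p.shape[1] != 3:
            raise ValueError("positions must be an (n, 3) array")
        if len(self.cell_ids) != p.shape[0]:
            raise ValueError("cell_ids length must equal position count")
        if len(set(self.cell_ids)) != len(self.cell_ids):
            raise ValueError("cell_ids must be unique within a frame")


@dataclass
class NeighborRateTable:
    """Per-cell shared-neighbor retention rates between two timepoints.

    ``table`` columns: cell_id, t_start, t_end, n_neighbors_start,
    n_shared, rate. Cells isolated at t_start (zero initial neighbors) have
    an undefined rate; they are absent from the table and counted in
    ``n_isolated``.
    """

    table: pd.DataFrame
    n_isolated: int
    radius: float


def find_neighbors(frame: PositionFrame, radius: float = 15.0) -> dict:
    """Per-cell neighbor sets: all *other* cells at distance <= radius.

    The boundary is inclusive ("within a radius"); the relation is
    symmetric and excludes the cell itself.
    """
    if radius <= 0:
        raise ValueError(f"radius must be > 0, got {radius}")
    tree = cKDTree(frame.positions)
    sets: dict = {cid: set() for cid in frame.cell_ids}
    for i, j in tree.query_pairs(r=radius):
        sets[frame.cell_ids[i]].add(frame.cell_ids[j])
        sets[frame.cell_ids[j]].add(frame.cell_ids[i])
    return sets


def neighbor_rate(
    frames: dict, t_start: int, t_end: int, radius: float = 15.0
) -> NeighborRateTable:
    """Shared-neighbor rate per cell between two timepoints.

    ``frames`` maps time_index -> PositionFrame. For each cell present in
    both frames, rate = |N_start ∩ N_end| / |N_start|, with neighbor sets
    recomputed fresh at each timepoint from the cells present in that
    frame. Cells absent at t_end are skipped; cells isolated at t_start are
    tallied separately.
    """
    for t in (t_start, t_end):
        if t not in frames:
            raise ValueError(f"no frame at time index {t}")
    start, end = frames[t_start], frames[t_end]
    n_start = find_neighbors(start, radius)
    n_end = find_neighbors(end, radius)
    rows = []
    n_isolated = 0
    present_both = [c for c in start.cell_ids if c in set(end.cell_ids)]
    for cid in present_both:
        k0 = len(n_start[cid])
        if k0 == 0:
            n_isolated += 1
            continue
        shared = len(n_start[cid] & n_end[cid])
        rows.append(
            {
                "cell_id": cid,
                "t_start": t_start,
                "t_end": t_end,
                "n_neighbors_start": k0,
                "n_shared": shared,
                "rate": shared / k0,
            }
        )
    cols = ["cell_id", "t_start", "t_end", "n_neighbors_start", "n_shared", "rate"]
    return NeighborRateTable(
        table=pd.DataFrame(rows, columns=cols), n_isolated=n_isolated, radius=radius
    )


@dataclass
class GroupComparison:
    """One-way ANOVA across interval groups with Tukey HSD post hoc."""

    group_stats: pd.DataFrame  # group, n, mean, sd
    f_statistic: float
    p_value: float
    tukey: pd.DataFrame  # group1, group2, meandiff, p_adj, lower, upper, reject


def compare_interval_groups(groups: dict) -> GroupComparison:
    """Compare neighbor-rate distributions across interval groups.

    ``groups`` maps a group label (e.g. "T1-T5") to a 1D array of per-cell
    rates. Returns per-group mean ± SD, the omnibus one-way ANOVA F and p,
    and Tukey-HSD-adjusted pairwise p-values.
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    arrays = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    for k, v in arrays.items():
        if v.size < 2:
            raise ValueError(f"group {k!r} has fewer than 2 observations")
    f, p = stats.f_oneway(*arrays.values())
    gs = pd.DataFrame(
        [
            {"group": k, "n": v.size, "mean": v.mean(), "sd": v.std(ddof=1)}
            for k, v in arrays.items()
        ]
    )
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    values = np.concatenate(list(arrays.values()))
    labels = np.concatenate([[k] * v.size for k, v in arrays.items()])
    res = pairwise_tukeyhsd(values, labels)
    tukey = pd.DataFrame(
        res.summary().data[1:],
        columns=[str(c) for c in res.summary().data[0]],
    ).rename(columns={"p-adj": "p_adj"})
    return GroupComparison(
        group_stats=gs, f_statistic=float(f), p_value=float(p), tukey=tukey
    )


def frames_from_tracks(tracks) -> dict:
    """Build per-timepoint PositionFrames from a list of CellTracks."""
    by_time: dict = {}
    for tr in tracks:
        for t, pos in zip(tr.times.tolist(), tr.positions):
            by_time.setdefault(t, []).append((tr.track_id, pos))
    frames = {}
    for t, items in sorted(by_time.items()):
        ids, pos = zip(*items)
        frames[t] = PositionFrame(t, ids, np.stack(pos))
    return frames
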