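"""Decomposition of observed 3D cell trajectories into tissue elongation
and per-cell migration, plus movement-direction statistics.

The observed trajectory (OT) of a cell in an elongating tissue mixes two
motions: bulk tissue elongation and the cell's own migration. Non-migratory
anchor cells (e.g. enveloping-layer epithelial cells, which are coupled by
tight junctions) report the elongation alone: the centroid trajectory of at
least three anchors defines the elongation trajectory (ET). Subtracting the
net ET displacement from each cell's OT yields its migration trajectory
(MT), anchored at the cell's own starting position so that
``OT(t) = MT(t) + (ET(t) - ET(t0))`` holds exactly.

Coordinates are treated as micrometres and time indices as frames (default
cadence 3 min/frame); both are labels only — no unit conversion happens
here.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "CellTrack",
    "Trajectory",
    "TrajectoryDecomposition",
    "DirectionHistogram",
    "compute_elongation_trajectory",
    "compute_migration_trajectory",
    "decompose_tracks",
    "movement_directions",
    "resample_gaps",
    "fit_circle_radius",
    "elongation_plane",
]


@dataclass(frozen=True)
class CellTrack:
    """One cell's time-ordered 3D positions, possibly with frame gaps."""

    track_id: object
    times: np.ndarray  # int frame indices, strictly increasing
    positions: np.ndarray  # (n, 3)
    role: str = "deep"  # "anchor" | "deep"
    interpolated: np.ndarray | None = None  # bool mask over samples

    def __post_init__(self):
        t = np.asarray(self.times, dtype=int)
        p = np.asarray(self.positions, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "positions", p)
        if p.ndim != 2 or p.shape[1] != 3:
            raise ValueError("positions must be an (n, 3) array")
        if t.shape[0] != p.shape[0]:
            raise ValueError("times and positions must have equal length")
        if t.shape[0] < 2:
            raise ValueError("a track needs at least 2 samples")
        if np.any(np.diff(t) <= 0):
            raise ValueError("time_index must be strictly increasing")
        if self.role not in ("anchor", "deep"):
            raise ValueError(f"role must be 'anchor' or 'deep', got {self.role!r}")
        if self.interpolated is None:
            object.__setattr__(self, "interpolated", np.zeros(t.shape[0], dtype=bool))

    def position_at(self, t: int) -> np.ndarray:
        idx = np.searchsorted(self.times, t)
        if idx >= len(self.times) or self.times[idx] != t:
            raise KeyError(f"track {self.track_id!r} has no sample at frame {t}")
        return self.positions[idx]


@dataclass(frozen=True)
class Trajectory:
    """A time-indexed sequence of 3-vectors (used for ET and MT)."""

    times: np.ndarray
    positions: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "times", np.asarray(self.times, dtype=int))
        object.__setattr__(self, "positions", np.asarray(self.positions, dtype=float))

    def displacement(self) -> np.ndarray:
        """Displacement relative to the first sample."""
        return self.positions - self.positions[0]


@dataclass
class TrajectoryDecomposition:
    """ET plus per-track MT for a set of tracks."""

    elongation: Trajectory
    migration: dict  # track_id -> Trajectory
    anchor_ids: tuple


@dataclass
class DirectionHistogram:
    """Binned 2D movement directions (a rose plot's underlying counts).

    Angles are measured counter-clockwise from the +x axis of the
    projection plane, in degrees over [0, 360). Displacements whose in-plane
    projection has zero length carry no direction; they are excluded from
    the bins and tallied in ``n_zero``.
    """

    bin_edges: np.ndarray  # degrees, len = n_bins + 1
    counts: np.ndarray
    window: int
    n_zero: int = 0
    plane_basis: np.ndarray | None = None  # (2, 3) projection used

    @property
    def n_steps(self) -> int:
        return int(self.counts.sum()) + self.n_zero


def resample_gaps(track: CellTrack, max_gap: int = 3) -> list[CellTrack]:
    """Fill frame gaps of at most ``max_gap`` missing frames by linear
    interpolation; longer gaps split the track into separate segments.

    Returns a list of tracks (a single element when no split occurs).
    Interpolated samples are flagged in ``interpolated``. Matches the
    gap-closing behaviour of trackers run with a maximum gap of 3 frames.
    """
    t, p = track.times, track.positions
    gaps = np.diff(t)
    # segment boundaries: after any gap that skips more than max_gap frames
    cut_after = np.where(gaps - 1 > max_gap)[0]
    segments = []
    start = 0
    bounds = list(cut_after) + [len(t) - 1]
    for seg_i, end in enumerate(bounds):
        tt, pp = t[start : end + 1], p[start : end + 1]
        if len(tt) < 2:
            start = end + 1
            continue  # an isolated sample cannot form a track segment
        full_t = np.arange(tt[0], tt[-1] + 1)
        interp = ~np.isin(full_t, tt)
        if interp.any():
            full_p = np.column_stack(
                [np.interp(full_t, tt, pp[:, d]) for d in range(3)]
            )
        else:
            full_t, full_p = tt, pp
            interp = np.zeros(len(tt), dtype=bool)
        tid = track.track_id if len(bounds) == 1 else f"{track.track_id}#{seg_i}"
        segments.append(
            CellTrack(tid, full_t, full_p, role=track.role, interpolated=interp)
        )
        start = end + 1
    return segments


def _common_support(tracks: Sequence[CellTrack]) -> np.ndarray:
    common = set(tracks[0].times.tolist())
    for tr in tracks[1:]:
        common &= set(tr.times.tolist())
    return np.array(sorted(common), dtype=int)


def compute_elongation_trajectory(anchors: Sequence[CellTrack]) -> Trajectory:
    """ET(t) = centroid of anchor positions at t over the common support.

    Requires at least 3 anchor tracks (the minimum used to define the
    tissue frame) overlapping on at least 2 frames; anchors should be
    gap-filled first (see :func:`resample_gaps`).
    """
    if len(anchors) < 3:
        raise ValueError(f"elongation trajectory needs >= 3 anchors, got {len(anchors)}")
    support = _common_support(anchors)
    if len(support) < 2:
        raise ValueError("anchor tracks share fewer than 2 common frames")
    pos = np.mean(
        [np.stack([tr.position_at(t) for t in support]) for tr in anchors], axis=0
    )
    return Trajectory(support, pos)


def compute_migration_trajectory(track: CellTrack, et: Trajectory) -> Trajectory:
    """MT(t) = OT(t) − (ET(t) − ET(t₀)) over the track/ET common support.

    t₀ is the first common frame, so the MT starts at the cell's observed
    position and removes only the net tissue displacement accrued since t₀.
    """
    common = np.array(
        sorted(set(track.times.tolist()) & set(et.times.tolist())), dtype=int
    )
    if len(common) < 2:
        raise ValueError(
            f"track {track.track_id!r} and ET overlap on fewer than 2 frames"
        )
    et_idx = {t: i for i, t in enumerate(et.times.tolist())}
    et_pos = et.positions[[et_idx[t] for t in common]]
    ot_pos = np.stack([track.position_at(t) for t in common])
    mt = ot_pos - (et_pos - et_pos[0])
    return Trajectory(common, mt)


def decompose_tracks(
    tracks: Sequence[CellTrack],
    anchor_ids: Sequence | None = None,
    max_gap: int = 3,
) -> TrajectoryDecomposition:
    """Full decomposition: gap-fill, derive ET from anchors, MT per track.

    Anchors are either the tracks whose ``role`` is ``"anchor"`` or those
    listed explicitly in ``anchor_ids``. MT is computed for every track
    (anchors included — their MT should be near-constant, a useful
    self-consistency check).
    """
    filled: list[CellTrack] = []
    for tr in tracks:
        filled.extend(resample_gaps(tr, max_gap=max_gap))
    if anchor_ids is not None:
        anchor_ids = set(anchor_ids)
        anchors = [tr for tr in filled if tr.track_id in anchor_ids]
    else:
        anchors = [tr for tr in filled if tr.role == "anchor"]
    et = compute_elongation_trajectory(anchors)
    migration = {tr.track_id: compute_migration_trajectory(tr, et) for tr in filled}
    return TrajectoryDecomposition(
        elongation=et,
        migration=migration,
        anchor_ids=tuple(tr.track_id for tr in anchors),
    )


_AXIS = {"x": 0, "y": 1, "z": 2}


def _resolve_plane(plane, tracks: Sequence[CellTrack], window: int) -> np.ndarray:
    """Return a (2, 3) orthonormal projection basis."""
    if isinstance(plane, str):
        if plane == "auto":
            ref = [tr for tr in tracks if tr.role == "anchor"] or list(tracks)
            disps = np.concatenate([np.diff(tr.positions, axis=0) for tr in ref])
            if np.allclose(disps, 0):
                return np.array([[1.0, 0, 0], [0, 1.0, 0]])
            _, _, vt = np.linalg.svd(disps - disps.mean(axis=0), full_matrices=False)
            return vt[:2]
        if len(plane) == 2 and all(a in _AXIS for a in plane):
            basis = np.zeros((2, 3))
            basis[0, _AXIS[plane[0]]] = 1.0
            basis[1, _AXIS[plane[1]]] = 1.0
            return basis
        raise ValueError(f"invalid plane spec {plane!r}")
    basis = np.asarray(plane, dtype=float)
    if basis.shape != (2, 3):
        raise ValueError(f"plane basis must have shape (2, 3), got {basis.shape}")
    return basis


def movement_directions(
    tracks: Sequence[CellTrack],
    window: int = 1,
    plane="auto",
    n_bins: int = 16,
) -> DirectionHistogram:
    """Histogram of per-cell movement directions over ``window``-frame steps.

    Each displacement over ``window`` consecutive observed frames is
    projected onto a 2D plane and converted to an angle in [0°, 360°).
    ``plane`` is ``"auto"`` (the two highest-variance axes of anchor
    displacement, i.e. the elongation plane; falls back to all tracks when
    no anchors are present), a literal axis pair (``"xy"``, ``"xz"``,
    ``"yz"``), or an explicit (2, 3) orthonormal basis.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    basis = _resolve_plane(plane, tracks, window)
    angles = []
    n_zero = 0
    for tr in tracks:
        if len(tr.times) <= window:
            continue
        steps = tr.positions[window:] - tr.positions[:-window]
        proj = steps @ basis.T
        norms = np.linalg.norm(proj, axis=1)
        nz = norms > 0
        n_zero += int((~nz).sum())
        ang = np.degrees(np.arctan2(proj[nz, 1], proj[nz, 0])) % 360.0
        angles.append(ang)
    all_ang = np.concatenate(angles) if angles else np.empty(0)
    edges = np.linspace(0.0, 360.0, n_bins + 1)
    counts, _ = np.histogram(all_ang, bins=edges)
    return DirectionHistogram(
        bin_edges=edges, counts=counts, window=window, n_zero=n_zero, plane_basis=basis
    )


def elongation_plane(et: Trajectory) -> np.ndarray:
    """The two highest-variance axes of an elongation trajectory's
    displacement steps, as a (2, 3) orthonormal basis."""
    disps = np.diff(et.positions, axis=0)
    if np.allclose(disps, 0):
        return np.array([[1.0, 0, 0], [0, 1.0, 0]])
    _, _, vt = np.linalg.svd(disps - disps.mean(axis=0), full_matrices=False)
    return vt[:2]


def fit_circle_radius(points: np.ndarray) -> float:
    """Least-squares circle radius for points on (or near) a circle in 3D.

    The points are first projected onto their best-fit plane (PCA), then an
    algebraic (Kåsa) circle fit is solved in that plane. Used to quantify
    rotational migration of tailbud cells.
    """
    pts = np.asarray(points, dtype=float)
    centered = pts - pts.mean(axis=0)
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    xy = centered @ vt[:2].T
    x, y = xy[:, 0], xy[:, 1]
    a = np.column_stack([2 * x, 2 * y, np.ones_like(x)])
    b = x**2 + y**2
    sol, *_ = np.linalg.lstsq(a, b, rcond=None)
    cx, cy, c = sol
    return float(np.sqrt(c + cx**2 + cy**2))
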