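"""Stage orchestration with shared config, validation and provenance.

A run is described by a :class:`RunConfig` (usually loaded from YAML):
which stages to execute, their parameters, input paths, output directory
and seed. ``run_pipeline`` executes the requested stages in dependency
order and writes a :class:`RunManifest` recording the resolved config,
input checksums, per-stage outputs and wall-clock times. Identical config
plus inputs plus seed reproduces identical analytic outputs.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import io as mio
from .lineage import chain_pairs
from .neighbors import compare_interval_groups, frames_from_tracks, neighbor_rate
from .pseudobulk import aggregate_pseudobulk, best_match, marker_correlation
from .simulate import (
    TimeSeriesSimSpec,
    TrackSimSpec,
    simulate_explant_tracks,
    simulate_expression_pair,
    simulate_timepoint_series,
)
from .tracks import decompose_tracks, movement_directions

__all__ = ["RunConfig", "RunManifest", "run_pipeline", "validate_inputs", "EXIT_CODES"]

STAGES = ("simulate", "lineage", "decompose", "neighbors", "correlate")

# 0 success, 2 config/input validation failure, 3 stage failure
EXIT_CODES = {"ok": 0, "validation": 2, "stage": 3}


@dataclass
class RunConfig:
    """Validated parameters for one pipeline run."""

    stages: tuple = STAGES
    out_dir: str = "morphlineage_out"
    seed: int = 0
    # lineage
    k: int = 10
    threshold: float = 0.20
    # neighbors
    radius: float = 15.0
    interval_pairs: tuple = ((0, 5), (0, 10), (0, 20))
    # decompose
    window: int = 1
    n_bins: int = 16
    max_gap: int = 3
    plane: str = "auto"
    # correlate
    aggregation: str = "mean"
    # inputs (omitted -> the stage consumes simulator output)
    tracks_csv: str | None = None
    anchor_ids: tuple | None = None
    query_dir: str | None = None
    reference_dir: str | None = None
    markers_tsv: str | None = None
    # simulator specs (plain dicts; defaults are the standard study-like setup)
    timepoints_spec: dict = field(default_factory=dict)
    tracks_spec: dict = field(default_factory=dict)
    expression_spec: dict = field(default_factory=dict)
    log_level: str = "INFO"

    def __post_init__(self):
        self.stages = tuple(self.stages)
        for s in self.stages:
            if s not in STAGES:
                raise ValueError(f"stages: unknown stage {s!r} (valid: {STAGES})")
        if not (0 <= self.threshold < 1):
            raise ValueError(f"threshold: must be in [0, 1), got {self.threshold}")
        if self.k < 1:
            raise ValueError(f"k: must be >= 1, got {self.k}")
        if self.radius <= 0:
            raise ValueError(f"radius: must be > 0, got {self.radius}")
        if self.window < 1:
            raise ValueError(f"window: must be >= 1, got {self.window}")
        if self.n_bins < 1:
            raise ValueError(f"n_bins: must be >= 1, got {self.n_bins}")
        if self.aggregation not in ("mean", "sum"):
            raise ValueError(f"aggregation: must be 'mean' or 'sum', got {self.aggregation}")

    @classmethod
    def from_yaml(cls, path: Path | str, **overrides) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)


@dataclass
class RunManifest:
    version: str
    config: dict
    input_checksums: dict
    outputs: dict  # stage -> list of file paths
    wall_clock: dict  # stage -> seconds

    def write(self, path: Path | str) -> Path:
        path = Path(path)
        tmp = path.with_suffix(".tmp")
        tmp.write_text(json.dumps(asdict(self), indent=1, default=str))
        tmp.replace(path)  # atomic on POSIX
        return path


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def validate_inputs(paths: dict) -> list[dict]:
    """Validate declared input files; returns a machine-readable problem
    list (empty when everything checks out). Never raises on bad content.

    ``paths`` maps a format name ("tracks_csv", "expression_dir",
    "markers_tsv", "embedding_tsv") to a filesystem path.
    """
    problems: list[dict] = []

    def flag(name, path, issue):
        problems.append({"input": name, "path": str(path), "problem": issue})

    for name, path in paths.items():
        path = Path(path)
        if not path.exists():
            flag(name, path, "does not exist")
            continue
        try:
            if name == "tracks_csv":
                df = pd.read_csv(path)
                missing = [c for c in mio.TRACK_COLUMNS if c not in df.columns]
                if missing:
                    flag(name, path, f"missing columns: {missing}")
            elif name == "expression_dir":
                from scipy import io as spio

                x = spio.mmread(path / "matrix.mtx")
                genes = pd.read_csv(path / "genes.tsv", sep="\t")
                labels = pd.read_csv(path / "labels.tsv", sep="\t")
                if x.shape[1] != len(genes):
                    flag(name, path, f"matrix has {x.shape[1]} genes, sidecar {len(genes)}")
                if x.shape[0] != len(labels):
                    flag(name, path, f"matrix has {x.shape[0]} cells, sidecar {len(labels)}")
            elif name == "markers_tsv":
                df = pd.read_csv(path, sep="\t")
                for col in ("cluster", "gene"):
                    if col not in df.columns:
                        flag(name, path, f"missing column: {col}")
            elif name == "embedding_tsv":
                df = pd.read_csv(path, sep="\t")
                if "cell_id" not in df.columns:
                    flag(name, path, "missing column: cell_id")
                if not any(c.startswith("dim_") for c in df.columns):
                    flag(name, path, "no dim_* coordinate columns")
        except Exception as exc:  # malformed file: report, never crash
            flag(name, path, f"unreadable: {exc}")
    return problems


def _default_timepoints_spec(seed: int) -> TimeSeriesSimSpec:
    tm = np.array(
        [
            [0.70, 0.30, 0.00, 0.00],
            [0.20, 0.50, 0.30, 0.00],
            [0.00, 0.25, 0.50, 0.25],
            [0.00, 0.00, 0.40, 0.60],
        ]
    )
    return TimeSeriesSimSpec(
        n_timepoints=6,
        clusters_per_timepoint=4,
        cells_per_cluster=100,
        transition_matrix=tm,
        cluster_separation=10.0,
        cluster_sd=1.0,
        seed=seed,
    )


def run_pipeline(config: RunConfig) -> RunManifest:
    """Execute the requested stages in dependency order.

    Stages consume user-supplied inputs when configured, otherwise the
    simulator outputs produced within the same run.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng_seed = int(config.seed)
    outputs: dict = {}
    clocks: dict = {}
    checksums: dict = {}
    for name in ("tracks_csv", "markers_tsv"):
        p = getattr(config, name)
        if p:
            checksums[name] = _sha256(Path(p))

    sim_pairs = None
    sim_tracks = None
    sim_expr = None

    if "simulate" in config.stages:
        t0 = time.perf_counter()
        files = []
        ts_spec = (
            TimeSeriesSimSpec(**config.timepoints_spec)
            if config.timepoints_spec
            else _default_timepoints_spec(rng_seed)
        )
        sim_pairs, truth = simulate_timepoint_series(ts_spec)
        for i, pair in enumerate(sim_pairs):
            files += mio.write_timepoint_slice(pair.earlier, out / f"pair{i}_earlier")
            files += mio.write_timepoint_slice(pair.later, out / f"pair{i}_later")
        files += mio.write_lineage_graph(truth, out, stem="true_lineage").values()

        tr_spec = (
            TrackSimSpec(**config.tracks_spec)
            if config.tracks_spec
            else TrackSimSpec(
                n_anchor=3, n_deep=20, n_frames=120, noise_sd=0.2, seed=rng_seed
            )
        )
        sim_tracks, _, _ = simulate_explant_tracks(tr_spec)
        files.append(mio.write_tracks_csv(sim_tracks, out / "tracks.csv"))

        expr_spec = dict(
            n_clusters=5, n_genes=100, markers_per_cluster=5, noise_sd=0.2
        )
        expr_spec.update(config.expression_spec)
        expr_spec.setdefault("seed", rng_seed)
        sim_expr = simulate_expression_pair(**expr_spec)
        q, r, _ = sim_expr
        files += mio.write_pseudobulk_input(q, out / "query").values()
        files += mio.write_pseudobulk_input(r, out / "reference").values()
        outputs["simulate"] = [str(f) for f in files]
        clocks["simulate"] = time.perf_counter() - t0

    if "lineage" in config.stages:
        t0 = time.perf_counter()
        if sim_pairs is None:
            raise RuntimeError(
                "lineage stage needs simulated pairs (enable the simulate stage "
                "or call the library API on your own slices)"
            )
        graph = chain_pairs(sim_pairs, k=config.k, threshold=config.threshold)
        files = mio.write_lineage_graph(graph, out, stem="lineage").values()
        outputs["lineage"] = [str(f) for f in files]
        clocks["lineage"] = time.perf_counter() - t0

    tracks = None
    if "decompose" in config.stages or "neighbors" in config.stages:
        if config.tracks_csv:
            tracks = mio.read_tracks_csv(config.tracks_csv, anchor_ids=config.anchor_ids)
        elif sim_tracks is not None:
            tracks = sim_tracks
        else:
            raise RuntimeError("decompose/neighbors need tracks_csv or the simulate stage")

    if "decompose" in config.stages:
        t0 = time.perf_counter()
        dec = decompose_tracks(tracks, anchor_ids=config.anchor_ids, max_gap=config.max_gap)
        rows = []
        et_idx = {t: i for i, t in enumerate(dec.elongation.times.tolist())}
        for tid, mt in sorted(dec.migration.items(), key=lambda kv: str(kv[0])):
            for t, pos in zip(mt.times.tolist(), mt.positions):
                e = dec.elongation.positions[et_idx[t]]
                rows.append(
                    {
                        "track_id": tid,
                        "time_index": t,
                        "et_x": e[0], "et_y": e[1], "et_z": e[2],
                        "mt_x": pos[0], "mt_y": pos[1], "mt_z": pos[2],
                    }
                )
        dec_path = out / "decomposition.tsv"
        pd.DataFrame(rows).to_csv(dec_path, sep="\t", index=False)
        hist = movement_directions(
            tracks, window=config.window, plane=config.plane, n_bins=config.n_bins
        )
        hist_path = out / "direction_histogram.tsv"
        pd.DataFrame(
            {
                "bin_start_deg": hist.bin_edges[:-1],
                "bin_end_deg": hist.bin_edges[1:],
                "count": hist.counts,
            }
        ).to_csv(hist_path, sep="\t", index=False)
        outputs["decompose"] = [str(dec_path), str(hist_path)]
        clocks["decompose"] = time.perf_counter() - t0

    if "neighbors" in config.stages:
        t0 = time.perf_counter()
        frames = frames_from_tracks(tracks)
        files = []
        groups = {}
        for t_start, t_end in config.interval_pairs:
            table = neighbor_rate(frames, t_start, t_end, radius=config.radius)
            p = out / f"neighbor_rate_{t_start}_{t_end}.tsv"
            mio.write_neighbor_rate_table(table, p)
            files.append(p)
            groups[f"T{t_start}-T{t_end}"] = table.table["rate"].to_numpy()
        if len(groups) >= 2 and all(len(v) >= 2 for v in groups.values()):
            cmp_res = compare_interval_groups(groups)
            report = {
                "f_statistic": cmp_res.f_statistic,
                "p_value": cmp_res.p_value,
                "groups": cmp_res.group_stats.to_dict(orient="records"),
                "tukey": cmp_res.tukey.to_dict(orient="records"),
            }
            rp = out / "anova_report.json"
            rp.write_text(json.dumps(report, indent=1, default=str))
            files.append(rp)
        outputs["neighbors"] = [str(f) for f in files]
        clocks["neighbors"] = time.perf_counter() - t0

    if "correlate" in config.stages:
        t0 = time.perf_counter()
        if config.query_dir and config.reference_dir:
            q = mio.read_pseudobulk_input(config.query_dir)
            r = mio.read_pseudobulk_input(config.reference_dir)
        elif sim_expr is not None:
            q, r, _ = sim_expr
        else:
            raise RuntimeError("correlate needs query/reference dirs or the simulate stage")
        if config.markers_tsv:
            markers = mio.read_markers_tsv(config.markers_tsv)
            marker_list = [g for genes in markers.values() for g in genes]
        else:
            marker_list = q.marker_union()
        qp = aggregate_pseudobulk(q, agg=config.aggregation)
        rp_ = aggregate_pseudobulk(r, agg=config.aggregation)
        sim = marker_correlation(qp, rp_, marker_list)
        sim_path = out / "similarity.tsv"
        sim.matrix.to_csv(sim_path, sep="\t")
        bm_path = out / "best_match.tsv"
        best_match(sim).to_csv(bm_path, sep="\t", index=False)
        outputs["correlate"] = [str(sim_path), str(bm_path)]
        clocks["correlate"] = time.perf_counter() - t0

    manifest = RunManifest(
        version=__version__,
        config=asdict(config),
        input_checksums=checksums,
        outputs=outputs,
        wall_clock=clocks,
    )
    manifest.write(out / "manifest.json")
    return manifest
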