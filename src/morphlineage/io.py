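"""Readers and writers for the plain-text formats the analyses exchange.

Formats: per-timepoint embedding TSV (cell_id, dim_1..dim_D) and cluster
label TSV (cell_id, cluster); track CSV in an Imaris-spots-export dialect
(track_id, time_index, x, y, z[, role]); expression as Matrix Market with
gene / cell-label TSV sidecars; lineage edge tables as TSV plus JSON and
DOT graph exports.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

from .lineage import LineageGraph, TimepointSlice
from .neighbors import NeighborRateTable
from .pseudobulk import PseudobulkInput
from .tracks import CellTrack

__all__ = [
    "write_timepoint_slice",
    "read_timepoint_slice",
    "write_tracks_csv",
    "read_tracks_csv",
    "write_pseudobulk_input",
    "read_pseudobulk_input",
    "write_markers_tsv",
    "read_markers_tsv",
    "write_lineage_graph",
    "write_neighbor_rate_table",
]

TRACK_COLUMNS = ["track_id", "time_index", "x", "y", "z"]


def write_timepoint_slice(sl: TimepointSlice, prefix: Path | str) -> tuple[Path, Path]:
    """Write one timepoint as `<prefix>.embedding.tsv` + `<prefix>.labels.tsv`."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    dims = [f"dim_{i + 1}" for i in range(sl.embedding.shape[1])]
    emb = pd.DataFrame(sl.embedding, columns=dims)
    emb.insert(0, "cell_id", list(sl.cell_ids))
    emb_path = Path(str(prefix) + ".embedding.tsv")
    emb.to_csv(emb_path, sep="\t", index=False)
    lab = pd.DataFrame({"cell_id": list(sl.cell_ids), "cluster": list(sl.cluster_labels)})
    lab_path = Path(str(prefix) + ".labels.tsv")
    lab.to_csv(lab_path, sep="\t", index=False)
    return emb_path, lab_path


def read_timepoint_slice(
    embedding_tsv: Path | str, labels_tsv: Path | str, timepoint_label
) -> TimepointSlice:
    emb = pd.read_csv(embedding_tsv, sep="\t")
    lab = pd.read_csv(labels_tsv, sep="\t")
    if "cell_id" not in emb.columns or "cell_id" not in lab.columns:
        raise ValueError("embedding and label TSVs must have a cell_id column")
    merged = emb.merge(lab, on="cell_id", how="inner")
    if len(merged) != len(emb):
        raise ValueError("embedding and label TSVs disagree on cell ids")
    dims = [c for c in emb.columns if c.startswith("dim_")]
    return TimepointSlice(
        timepoint_label=timepoint_label,
        cell_ids=merged["cell_id"].tolist(),
        embedding=merged[dims].to_numpy(dtype=float),
        cluster_labels=merged["cluster"].tolist(),
    )


def write_tracks_csv(tracks, path: Path | str) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    rows = []
    for tr in tracks:
        for t, (x, y, z) in zip(tr.times.tolist(), tr.positions):
            rows.append(
                {"track_id": tr.track_id, "time_index": t, "x": x, "y": y, "z": z, "role": tr.role}
            )
    pd.DataFrame(rows).to_csv(path, index=False)
    return path


def read_tracks_csv(path: Path | str, anchor_ids=None) -> list[CellTrack]:
    """Read an Imaris-style spots export. The optional ``role`` column marks
    anchors; alternatively pass ``anchor_ids`` explicitly."""
    df = pd.read_csv(path)
    missing = [c for c in TRACK_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"track CSV is missing required columns: {missing}")
    anchor_ids = set(anchor_ids) if anchor_ids is not None else None
    tracks = []
    for tid, grp in df.groupby("track_id", sort=True):
        grp = grp.sort_values("time_index")
        if anchor_ids is not None:
            role = "anchor" if tid in anchor_ids or str(tid) in anchor_ids else "deep"
        elif "role" in df.columns:
            role = str(grp["role"].iloc[0])
        else:
            role = "deep"
        tracks.append(
            CellTrack(
                track_id=tid,
                times=grp["time_index"].to_numpy(int),
                positions=grp[["x", "y", "z"]].to_numpy(float),
                role=role,
            )
        )
    return tracks


def write_pseudobulk_input(inp: PseudobulkInput, out_dir: Path | str) -> dict:
    """Write expression as `matrix.mtx` + `genes.tsv` + `labels.tsv`."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    x = inp.expression
    if not sparse.issparse(x):
        x = sparse.coo_matrix(np.asarray(x))
    spio.mmwrite(out / "matrix.mtx", x)
    pd.Series(list(inp.gene_ids), name="gene").to_csv(
        out / "genes.tsv", sep="\t", index=False
    )
    pd.DataFrame(
        {"cell_index": range(len(inp.cluster_labels)), "cluster": list(inp.cluster_labels)}
    ).to_csv(out / "labels.tsv", sep="\t", index=False)
    files = {
        "matrix": out / "matrix.mtx",
        "genes": out / "genes.tsv",
        "labels": out / "labels.tsv",
    }
    if inp.markers:
        files["markers"] = write_markers_tsv(inp.markers, out / "markers.tsv")
    return files


def read_pseudobulk_input(in_dir: Path | str) -> PseudobulkInput:
    in_dir = Path(in_dir)
    x = spio.mmread(in_dir / "matrix.mtx").tocsr()
    genes = pd.read_csv(in_dir / "genes.tsv", sep="\t")["gene"].tolist()
    labels = pd.read_csv(in_dir / "labels.tsv", sep="\t")["cluster"].tolist()
    markers_path = in_dir / "markers.tsv"
    markers = read_markers_tsv(markers_path) if markers_path.exists() else None
    return PseudobulkInput(
        expression=x, cluster_labels=labels, gene_ids=genes, markers=markers
    )


def write_markers_tsv(markers: dict, path: Path | str) -> Path:
    path = Path(path)
    rows = [{"cluster": c, "gene": g} for c, genes in markers.items() for g in genes]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
    return path


def read_markers_tsv(path: Path | str) -> dict:
    df = pd.read_csv(path, sep="\t")
    return {c: grp["gene"].tolist() for c, grp in df.groupby("cluster", sort=False)}


def write_lineage_graph(graph: LineageGraph, out_dir: Path | str, stem: str = "lineage") -> dict:
    """Write the edge table TSV plus JSON and DOT renderings of the graph."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    table = out / f"{stem}_edges.tsv"
    graph.to_dataframe().to_csv(table, sep="\t", index=False)

    as_json = {
        "threshold": graph.threshold,
        "nodes": [{"cluster": str(c), "timepoint": tp} for c, tp in graph.nodes],
        "edges": [
            {
                "earlier_cluster": str(e.earlier_cluster),
                "earlier_tp": e.earlier_timepoint,
                "later_cluster": str(e.later_cluster),
                "later_tp": e.later_timepoint,
                "fraction": e.fraction,
                "n_cells": e.n_cells,
                "retained": e.retained,
            }
            for e in graph.edges
        ],
    }
    json_path = out / f"{stem}.json"
    json_path.write_text(json.dumps(as_json, indent=1, default=str))

    def node_name(c, tp):
        return f'"{c}@{tp}"'

    lines = ["digraph lineage {"]
    for c, tp in graph.nodes:
        lines.append(f"  {node_name(c, tp)};")
    for e in graph.retained_edges:
        lines.append(
            f"  {node_name(e.earlier_cluster, e.earlier_timepoint)} -> "
            f"{node_name(e.later_cluster, e.later_timepoint)} "
            f'[label="{e.fraction:.2f}"];'
        )
    lines.append("}")
    dot_path = out / f"{stem}.dot"
    dot_path.write_text("\n".join(lines) + "\n")
    return {"edges": table, "json": json_path, "dot": dot_path}


def write_neighbor_rate_table(table: NeighborRateTable, path: Path | str) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    table.table.to_csv(path, sep="\t", index=False)
    side = path.with_suffix(".meta.json")
    side.write_text(
        json.dumps({"radius": table.radius, "n_isolated": table.n_isolated})
    )
    return path
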