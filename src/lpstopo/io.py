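"""Text readers and writers for all pipeline artifacts.

The canonical dialect is tab-delimited UTF-8 text with LF endings, decimal
point, and ``%.17g`` float formatting (17 significant digits survive a
float64 round trip bit-exactly).  Matrices carry an atlas-labeled header row
and label column; cohort tables use the header ``subject_id,group,crs_r``.

Viewer export follows the BrainNet-style convention: a ``.node`` file with
one row per node (coordinates, a size value and a color value, label) and a
square ``.edge`` matrix.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .atlas import Atlas, default_atlas
from .connectivity import ConnectivityMatrix, RoiSignal
from .graphs import BinaryGraph
from .nbs import NbsResult

__all__ = [
    "write_connectivity", "read_connectivity",
    "write_cohort", "read_cohort",
    "write_signal", "read_signal",
    "write_graph", "export_viewer_files",
]

FLOAT_FMT = "%.17g"
VALID_GROUPS = ("UWS", "MCS")


def _fmt(x: float) -> str:
    return FLOAT_FMT % x


def write_connectivity(matrix: ConnectivityMatrix, path: str | Path) -> Path:
    """Square tab-delimited matrix with a labeled header row and column."""
    path = Path(path)
    labels = matrix.labels or [f"roi{i}" for i in range(matrix.n_rois)]
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("label\t" + "\t".join(labels) + "\n")
        for lab, row in zip(labels, matrix.weights):
            fh.write(lab + "\t" + "\t".join(_fmt(v) for v in row) + "\n")
    return path


def read_connectivity(
    path: str | Path, subject_id: str = "", band: str = "", normalized: bool = False
) -> ConnectivityMatrix:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    w = df.to_numpy(dtype=float)
    if w.ndim != 2 or w.shape[0] != w.shape[1]:
        raise ValueError(f"{path}: expected a square matrix, got shape {w.shape}")
    asym = np.argwhere(w != w.T)
    if len(asym):
        i, j = asym[0]
        raise ValueError(
            f"{path}: matrix not symmetric at ({i}, {j}): {w[i, j]} vs {w[j, i]}"
        )
    if not subject_id:
        stem = path.stem
        subject_id = stem.rsplit("_", 1)[0] if "_" in stem else stem
    if not band and "_" in path.stem:
        band = path.stem.rsplit("_", 1)[1]
    return ConnectivityMatrix(
        subject_id=subject_id, band=band, weights=w, normalized=normalized,
        labels=[str(c) for c in df.columns],
    )


def write_cohort(cohort: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    cohort.to_csv(path, index=False, float_format=FLOAT_FMT, lineterminator="\n")
    return path


def read_cohort(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, float_precision="round_trip")
    required = ["subject_id", "group", "crs_r"]
    if list(df.columns[:3]) != required:
        raise ValueError(f"{path}: expected header {required}, got {list(df.columns)}")
    bad_groups = set(df["group"]) - set(VALID_GROUPS)
    if bad_groups:
        raise ValueError(f"{path}: unknown group labels {sorted(bad_groups)}")
    if df["subject_id"].duplicated().any():
        dups = df.loc[df["subject_id"].duplicated(), "subject_id"].tolist()
        raise ValueError(f"{path}: duplicate subject ids {dups}")
    crs = pd.to_numeric(df["crs_r"], errors="coerce")
    if crs.isna().any():
        bad = df.loc[crs.isna(), "subject_id"].tolist()
        raise ValueError(f"{path}: non-numeric CRS-R for subjects {bad}")
    if (crs < 0).any():
        raise ValueError(f"{path}: negative CRS-R values")
    df["crs_r"] = crs
    return df


def write_signal(signal: RoiSignal, path: str | Path, atlas: Atlas | None = None) -> Path:
    """One delimited matrix per subject: rows = ROIs, labeled first column."""
    atlas = atlas or default_atlas()
    path = Path(path)
    labels = atlas.labels if signal.n_rois == len(atlas) else [
        f"roi{i}" for i in range(signal.n_rois)
    ]
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(f"# subject_id={signal.subject_id} sampling_rate={_fmt(signal.sampling_rate)}\n")
        for lab, row in zip(labels, signal.samples):
            fh.write(lab + "\t" + "\t".join(_fmt(v) for v in row) + "\n")
    return path


def read_signal(path: str | Path) -> RoiSignal:
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().strip()
        meta = dict(
            kv.split("=", 1) for kv in header.lstrip("# ").split() if "=" in kv
        )
        rows = []
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            rows.append([float(v) for v in parts[1:]])
    return RoiSignal(
        subject_id=meta.get("subject_id", path.stem),
        samples=np.asarray(rows),
        sampling_rate=float(meta.get("sampling_rate", 256.0)),
    )


def write_graph(graph: BinaryGraph, prefix: str | Path, atlas: Atlas | None = None) -> tuple[Path, Path]:
    """Adjacency matrix plus labeled edge list (``<prefix>.adj.tsv/.edges.tsv``)."""
    atlas = atlas or default_atlas()
    prefix = Path(prefix)
    labels = [atlas[i].label for i in graph.nodes]
    adj_path = prefix.with_suffix(".adj.tsv")
    with open(adj_path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("label\t" + "\t".join(labels) + "\n")
        for lab, row in zip(labels, graph.adjacency):
            fh.write(lab + "\t" + "\t".join(str(int(v)) for v in row) + "\n")
    edge_path = prefix.with_suffix(".edges.tsv")
    iu, ju = np.nonzero(np.triu(graph.adjacency, k=1))
    with open(edge_path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("source\ttarget\n")
        for i, j in zip(iu, ju):
            fh.write(f"{labels[i]}\t{labels[j]}\n")
    return adj_path, edge_path


def export_viewer_files(
    result: NbsResult,
    prefix: str | Path,
    atlas: Atlas | None = None,
    component: int = 0,
    coordinates: np.ndarray | None = None,
) -> tuple[Path, Path]:
    """BrainNet-style ``.node``/``.edge`` files for one NBS component.

    The node file has one row per ROI of the component (x, y, z, size =
    within-component degree, color = 1, label); coordinates default to 0.
    The edge file is the full square 0/1 matrix over those ROIs.
    """
    atlas = atlas or default_atlas()
    prefix = Path(prefix)
    if not result.components:
        raise ValueError("NBS result has no components to export")
    comp = result.components[component]
    nodes = comp.nodes
    pos = {v: k for k, v in enumerate(nodes)}
    adj = np.zeros((len(nodes), len(nodes)), dtype=int)
    for i, j in comp.edges:
        adj[pos[i], pos[j]] = adj[pos[j], pos[i]] = 1
    if coordinates is None:
        coordinates = np.zeros((len(atlas), 3))
    node_path = prefix.with_suffix(".node")
    with open(node_path, "w", encoding="utf-8", newline="\n") as fh:
        for v in nodes:
            x, y, z = coordinates[v]
            size = int(adj[pos[v]].sum())
            fh.write(f"{_fmt(x)}\t{_fmt(y)}\t{_fmt(z)}\t{size}\t1\t{atlas[v].label}\n")
    edge_path = prefix.with_suffix(".edge")
    np.savetxt(edge_path, adj, fmt="%d", delimiter="\t", newline="\n")
    return node_path, edge_path
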