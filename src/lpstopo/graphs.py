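"""Proportional-threshold binary graphs from weighted connectomes.

A weighted, max-normalized connectome is binarized by keeping the PT%
strongest off-diagonal connections (``k = round(pt/100 * n(n-1)/2)`` edges,
round-half-away-from-zero) and setting them to 1.  Ties at the k-th weight
are broken by ascending (row, col) index after a stable sort, so results are
deterministic even after max-normalization introduces equal weights.  Nodes
left with degree 0 are pruned before topology measures are computed; pruning
removes only zero-degree nodes, so pruned graphs may still consist of several
connected components (handled by the measures downstream, not here).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import networkx as nx
import pandas as pd

from .connectivity import ConnectivityMatrix, overall_fc

__all__ = [
    "BinaryGraph",
    "proportional_threshold",
    "prune_disconnected",
    "overall_fc",
    "threshold_sweep",
    "DEFAULT_PT",
    "DEFAULT_PT_SWEEP",
]

DEFAULT_PT = 20.0
#: 35% down to 1% in steps of 1%.
DEFAULT_PT_SWEEP: tuple[float, ...] = tuple(range(35, 0, -1))


@dataclass
class BinaryGraph:
    """Undirected unweighted graph over retained ROI indices.

    ``nodes[k]`` is the original ROI index of adjacency row/column ``k``;
    ``pruned_nodes`` lists ROI indices removed for having degree 0.
    """

    nodes: list[int]
    adjacency: np.ndarray
    pt: float
    pruned_nodes: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        a = np.asarray(self.adjacency)
        if a.ndim != 2 or a.shape[0] != a.shape[1] or a.shape[0] != len(self.nodes):
            raise ValueError("adjacency shape does not match node list")
        if not np.array_equal(a, a.T):
            raise ValueError("adjacency must be symmetric")
        if np.any(np.diag(a) != 0):
            raise ValueError("self-loops are not allowed")
        if not np.isin(a, (0, 1)).all():
            raise ValueError("adjacency must be 0/1")
        self.adjacency = a.astype(np.int8)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum()) // 2

    def degrees(self) -> np.ndarray:
        return self.adjacency.sum(axis=0).astype(int)

    def to_networkx(self) -> nx.Graph:
        """Graph over positional indices 0..n_nodes-1 (use ``nodes`` to map back)."""
        g = nx.from_numpy_array(self.adjacency)
        g.remove_edges_from(nx.selfloop_edges(g))
        return g


def _round_half_away(x: float) -> int:
    return int(np.floor(x + 0.5)) if x >= 0 else -int(np.floor(-x + 0.5))


def proportional_threshold(matrix: ConnectivityMatrix, pt: float = DEFAULT_PT) -> BinaryGraph:
    """Binarize by keeping the ``pt`` percent strongest connections.

    Returns the un-pruned graph over all ROIs; follow with
    :func:`prune_disconnected` before computing topology measures.
    """
    if not (0 < pt <= 100):
        raise ValueError(f"pt must be in (0, 100], got {pt}")
    w = matrix.weights
    n = w.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    k = _round_half_away(pt / 100.0 * len(iu))
    # stable sort descending by weight, ties by ascending (row, col)
    order = np.argsort(-w[iu, ju], kind="stable")
    keep = order[:k]
    adj = np.zeros((n, n), dtype=np.int8)
    adj[iu[keep], ju[keep]] = 1
    adj += adj.T
    return BinaryGraph(nodes=list(range(n)), adjacency=adj, pt=float(pt))


def prune_disconnected(graph: BinaryGraph) -> BinaryGraph:
    """Remove zero-degree nodes, re-indexing but keeping original ROI indices."""
    if graph.n_edges == 0:
        raise ValueError("graph has no edges; refusing to prune a degenerate graph")
    deg = graph.degrees()
    keep = np.flatnonzero(deg > 0)
    drop = [graph.nodes[k] for k in np.flatnonzero(deg == 0)]
    return BinaryGraph(
        nodes=[graph.nodes[k] for k in keep],
        adjacency=graph.adjacency[np.ix_(keep, keep)],
        pt=graph.pt,
        pruned_nodes=sorted(set(graph.pruned_nodes) | set(drop)),
    )


def threshold_sweep(
    matrix: ConnectivityMatrix,
    pts: tuple[float, ...] = DEFAULT_PT_SWEEP,
    measures: dict | None = None,
) -> pd.DataFrame:
    """Threshold -> prune -> measure at each PT level; long-format result.

    ``measures`` maps measure name to a callable ``f(BinaryGraph) -> float``;
    by default the deterministic whole-brain set is computed.  Degenerate
    graphs at very low PT yield NaN rows tagged with an ``error`` note.
    """
    from . import topology  # deferred; topology imports BinaryGraph from here

    if measures is None:
        measures = topology.WHOLE_BRAIN_MEASURES
    rows = []
    for pt in pts:
        g = proportional_threshold(matrix, pt)
        try:
            g = prune_disconnected(g)
        except ValueError as exc:
            for name in measures:
                rows.append({"pt": float(pt), "n_pruned": np.nan,
                             "n_edges": g.n_edges, "measure": name,
                             "value": np.nan, "error": str(exc)})
            continue
        for name, fn in measures.items():
            try:
                value = float(fn(g))
                err = ""
            except ValueError as exc:
                value, err = np.nan, str(exc)
            rows.append({"pt": float(pt), "n_pruned": len(g.pruned_nodes),
                         "n_edges": g.n_edges, "measure": name,
                         "value": value, "error": err})
    return pd.DataFrame(rows)
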