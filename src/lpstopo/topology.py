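"""Deterministic whole-brain and nodal topology measures.

Conventions, fixed and logged rather than inferred:

* Characteristic path length L averages finite shortest-path lengths only;
  node pairs in different components are excluded from the mean and their
  count is reported alongside the value.
* Global efficiency uses the 1/inf = 0 convention, so disconnected pairs
  contribute 0.
* Local efficiency of a node is the global efficiency of the subgraph induced
  by its neighbors (0 with fewer than 2 neighbors).
* The average clustering coefficient (ACC) averages over all retained nodes,
  counting degree<2 nodes as 0.
* Betweenness is exact shortest-path betweenness with fractional counting
  over equal-length paths; unnormalized values are canonical, a normalized
  variant is available behind a flag.
* LCP-corr is the sample Pearson correlation, across existing edges with at
  least one common neighbor (CN > 0), between the number of common neighbors
  (CN) and the number of links among those common neighbors (LCL, "local
  community links").  It is undefined (NaN) when fewer than 2 edges qualify
  or either vector is constant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import networkx as nx
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path

from .graphs import BinaryGraph

__all__ = [
    "PathLengthResult",
    "NodalMetrics",
    "TopologySummary",
    "characteristic_path_length",
    "global_efficiency",
    "local_efficiency",
    "clustering_coefficient",
    "betweenness_centrality",
    "node_degree",
    "lcp_corr",
    "nodal_metrics",
    "WHOLE_BRAIN_MEASURES",
]


@dataclass(frozen=True)
class PathLengthResult:
    """Characteristic path length plus the disconnected-pair count."""

    value: float
    excluded_pairs: int  # unordered node pairs with no connecting path

    def __float__(self) -> float:
        return self.value


def _distance_matrix(adjacency: np.ndarray) -> np.ndarray:
    """All-pairs unweighted shortest-path distances (inf for disconnected)."""
    return shortest_path(csr_matrix(adjacency), method="D", unweighted=True,
                         directed=False)


def characteristic_path_length(graph: BinaryGraph) -> PathLengthResult:
    """Mean shortest-path length over connected node pairs."""
    n = graph.n_nodes
    if n < 2:
        raise ValueError("characteristic path length needs >= 2 nodes")
    d = _distance_matrix(graph.adjacency)
    iu = np.triu_indices(n, k=1)
    pair_d = d[iu]
    finite = np.isfinite(pair_d)
    if not finite.any():
        raise ValueError("no connected node pair; path length undefined")
    excluded = int(np.count_nonzero(~finite))
    return PathLengthResult(value=float(pair_d[finite].mean()), excluded_pairs=excluded)


def _efficiency_from_adjacency(adjacency: np.ndarray) -> float:
    n = adjacency.shape[0]
    if n < 2:
        return 0.0
    d = _distance_matrix(adjacency)
    iu = np.triu_indices(n, k=1)
    with np.errstate(divide="ignore"):
        inv = 1.0 / d[iu]
    return float(inv.mean())


def global_efficiency(graph: BinaryGraph) -> float:
    """Mean inverse shortest-path length over all pairs (1/inf = 0)."""
    if graph.n_nodes < 2:
        raise ValueError("global efficiency needs >= 2 nodes")
    return _efficiency_from_adjacency(graph.adjacency)


def local_efficiency(graph: BinaryGraph) -> tuple[np.ndarray, float]:
    """Per-node local efficiency and its average over all retained nodes.

    The local efficiency of a node is the global efficiency of the subgraph
    induced by its neighbors (0 with fewer than 2 neighbors).
    """
    a = graph.adjacency
    values = np.zeros(graph.n_nodes)
    for v in range(graph.n_nodes):
        neigh = np.flatnonzero(a[v])
        if len(neigh) < 2:
            continue
        values[v] = _efficiency_from_adjacency(a[np.ix_(neigh, neigh)])
    avg = float(values.mean()) if graph.n_nodes else 0.0
    return values, avg


def clustering_coefficient(graph: BinaryGraph) -> tuple[np.ndarray, float]:
    """Per-node clustering (2T/k(k-1), 0 when k < 2) and ACC."""
    a = graph.adjacency.astype(np.int64)
    deg = a.sum(axis=0)
    triangles = np.einsum("ij,jk,ki->i", a, a, a) // 2
    denom = deg * (deg - 1)
    values = np.where(denom > 0, 2.0 * triangles / np.maximum(denom, 1), 0.0)
    return values, float(values.mean()) if graph.n_nodes else 0.0


def betweenness_centrality(
    graph: BinaryGraph, normalized: bool = False
) -> tuple[np.ndarray, float]:
    """Per-node shortest-path betweenness and its mean (ANBC).

    Unnormalized by default; ``normalized=True`` divides by (n-1)(n-2)/2.
    """
    g = graph.to_networkx()
    bc = nx.betweenness_centrality(g, normalized=normalized)
    values = np.array([bc[v] for v in range(graph.n_nodes)], dtype=float)
    return values, float(values.mean()) if graph.n_nodes else 0.0


def node_degree(graph: BinaryGraph) -> np.ndarray:
    """Adjacency row sums."""
    return graph.degrees()


def lcp_corr(graph: BinaryGraph) -> float:
    """Local-community-paradigm correlation; NaN when undefined."""
    a = graph.adjacency.astype(np.int64)
    iu, ju = np.nonzero(np.triu(a, k=1))
    cns: list[int] = []
    lcls: list[int] = []
    for u, v in zip(iu, ju):
        common = np.flatnonzero(a[u] & a[v])
        cn = len(common)
        if cn == 0:
            continue
        lcl = int(a[np.ix_(common, common)].sum()) // 2
        cns.append(cn)
        lcls.append(lcl)
    if len(cns) < 2:
        return float("nan")
    cn_arr = np.asarray(cns, dtype=float)
    lcl_arr = np.asarray(lcls, dtype=float)
    if cn_arr.std() == 0 or lcl_arr.std() == 0:
        return float("nan")
    return float(np.corrcoef(cn_arr, lcl_arr)[0, 1])


@dataclass
class NodalMetrics:
    """Per-node degree, clustering and betweenness for one subject graph.

    Arrays are aligned with ``roi_indices`` (original atlas indices of the
    retained nodes).
    """

    roi_indices: list[int]
    degree: np.ndarray
    clustering: np.ndarray
    betweenness: np.ndarray


def nodal_metrics(graph: BinaryGraph) -> NodalMetrics:
    deg = node_degree(graph)
    clust, _ = clustering_coefficient(graph)
    btw, _ = betweenness_centrality(graph)
    return NodalMetrics(
        roi_indices=list(graph.nodes), degree=deg, clustering=clust,
        betweenness=btw,
    )


@dataclass
class TopologySummary:
    """Whole-brain measure values for one (subject, band, pt).

    Deterministic fields are filled by :func:`summarize_deterministic`; the
    stochastic fields (sw_omega, sw_omega_eff, q_modularity, sigma_c) by the
    stochastic module.
    """

    subject_id: str
    band: str
    pt: float
    L: float = float("nan")
    excluded_pairs: int = 0
    E_glob: float = float("nan")
    E_loc: float = float("nan")
    ACC: float = float("nan")
    ANBC: float = float("nan")
    LCP_corr: float = float("nan")
    sw_omega: float = float("nan")
    sw_omega_eff: float = float("nan")
    q_modularity: float = float("nan")
    sigma_c: float = float("nan")
    n_pruned: int = 0


def summarize_deterministic(
    graph: BinaryGraph, subject_id: str = "", band: str = "", pt: float | None = None
) -> TopologySummary:
    """All deterministic whole-brain measures of one binary graph."""
    pl = characteristic_path_length(graph)
    _, e_loc = local_efficiency(graph)
    _, acc = clustering_coefficient(graph)
    _, anbc = betweenness_centrality(graph)
    return TopologySummary(
        subject_id=subject_id, band=band,
        pt=graph.pt if pt is None else pt,
        L=pl.value, excluded_pairs=pl.excluded_pairs,
        E_glob=global_efficiency(graph), E_loc=e_loc, ACC=acc, ANBC=anbc,
        LCP_corr=lcp_corr(graph), n_pruned=len(graph.pruned_nodes),
    )


#: name -> callable(BinaryGraph) -> float, for the threshold sweep.
WHOLE_BRAIN_MEASURES = {
    "L": lambda g: characteristic_path_length(g).value,
    "E_glob": global_efficiency,
    "E_loc": lambda g: local_efficiency(g)[1],
    "ACC": lambda g: clustering_coefficient(g)[1],
    "ANBC": lambda g: betweenness_centrality(g)[1],
    "LCP_corr": lcp_corr,
}
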