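"""Network-based statistic (NBS) on weighted connectomes.

Mass-univariate two-sample t-tests are run at every edge of the (weighted,
pre-threshold) connectivity matrices; edges whose t-statistic exceeds a
primary threshold in the configured direction form a suprathreshold graph,
and each connected component is scored by its edge count.  Family-wise-error
corrected p-values come from the permutation null of the maximal component
size under random relabeling of whole subjects:

    corrected_p = (1 + #{perm max size >= observed size}) / (1 + n_perm)

so the observed labeling is always part of the null and corrected_p > 0.

The primary threshold defaults to t = 2.6 with 20,000 permutations.  The
threshold is applied to signed t in one direction per run (A>B keeps t >
threshold, B>A keeps -t > threshold); a reported deficit of group A is
therefore recovered by the B>A contrast.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from math import comb

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components

from .connectivity import ConnectivityMatrix

__all__ = [
    "NbsConfig",
    "NbsComponent",
    "NbsResult",
    "edgewise_tstats",
    "suprathreshold_components",
    "nbs_test",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class NbsConfig:
    t_threshold: float = 2.6
    n_permutations: int = 20_000
    direction: str = "A>B"  # or "B>A"
    seed: int = 0
    alpha: float = 0.05
    component_size: str = "edges"  # or "nodes"

    def __post_init__(self) -> None:
        if self.t_threshold <= 0:
            raise ValueError("t_threshold must be positive")
        if self.n_permutations < 100:
            raise ValueError("need at least 100 permutations")
        if self.direction not in ("A>B", "B>A"):
            raise ValueError("direction must be 'A>B' or 'B>A'")
        if self.component_size not in ("edges", "nodes"):
            raise ValueError("component_size must be 'edges' or 'nodes'")


@dataclass
class NbsComponent:
    edges: list[tuple[int, int]]
    nodes: list[int]
    size: int  # edge count by default; node count behind the config flag
    corrected_p: float = float("nan")


@dataclass
class NbsResult:
    t_matrix: np.ndarray
    components: list[NbsComponent]
    null_max_sizes: np.ndarray
    config: NbsConfig
    labels: list[str] = field(default_factory=list)

    @property
    def significant_components(self) -> list[NbsComponent]:
        return [c for c in self.components if c.corrected_p <= self.config.alpha]


def _stack_upper(matrices: list[ConnectivityMatrix]) -> tuple[np.ndarray, int]:
    n = matrices[0].n_rois
    for m in matrices:
        if m.n_rois != n:
            raise ValueError("all connectomes must share the ROI set")
    iu = np.triu_indices(n, k=1)
    data = np.stack([m.weights[iu] for m in matrices])
    return data, n


def _pooled_t(
    sum_a: np.ndarray, ss_a: np.ndarray, n_a: int,
    sum_b: np.ndarray, ss_b: np.ndarray, n_b: int,
) -> np.ndarray:
    """Pooled-variance two-sample t from per-group sums and sums of squares."""
    mean_a = sum_a / n_a
    mean_b = sum_b / n_b
    var_a = (ss_a - n_a * mean_a**2) / (n_a - 1)
    var_b = (ss_b - n_b * mean_b**2) / (n_b - 1)
    sp2 = ((n_a - 1) * var_a + (n_b - 1) * var_b) / (n_a + n_b - 2)
    denom = np.sqrt(sp2 * (1.0 / n_a + 1.0 / n_b))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (mean_a - mean_b) / denom
    bad = ~np.isfinite(t)
    if bad.any():
        t = np.where(bad, 0.0, t)
    return t


def edgewise_tstats(
    group_a: list[ConnectivityMatrix], group_b: list[ConnectivityMatrix]
) -> np.ndarray:
    """Pooled-variance two-sample t per edge; sign = mean(A) - mean(B).

    Edges with zero pooled variance get t = 0 (logged).
    """
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("need at least 2 subjects per group")
    data_a, n = _stack_upper(group_a)
    data_b, _ = _stack_upper(group_b)
    t_flat = _pooled_t(
        data_a.sum(0), (data_a**2).sum(0), len(group_a),
        data_b.sum(0), (data_b**2).sum(0), len(group_b),
    )
    n_zero = int(np.count_nonzero(t_flat == 0))
    if n_zero:
        logger.debug("%d edges with zero t (incl. zero pooled variance)", n_zero)
    iu = np.triu_indices(n, k=1)
    t = np.zeros((n, n))
    t[iu] = t_flat
    t = t + t.T
    return t


def _components_from_mask(
    mask: np.ndarray, iu: tuple[np.ndarray, np.ndarray], n: int, size_by: str
) -> list[NbsComponent]:
    ei, ej = iu[0][mask], iu[1][mask]
    if len(ei) == 0:
        return []
    adj = coo_matrix((np.ones(len(ei)), (ei, ej)), shape=(n, n))
    n_comp, labels = connected_components(adj, directed=False)
    comps: dict[int, NbsComponent] = {}
    for i, j in zip(ei, ej):
        c = labels[i]
        comp = comps.setdefault(c, NbsComponent(edges=[], nodes=[], size=0))
        comp.edges.append((int(i), int(j)))
    out = []
    for comp in comps.values():
        comp.nodes = sorted({v for e in comp.edges for v in e})
        comp.size = len(comp.edges) if size_by == "edges" else len(comp.nodes)
        out.append(comp)
    out.sort(key=lambda c: -c.size)
    return out


def suprathreshold_components(
    t_matrix: np.ndarray, config: NbsConfig
) -> list[NbsComponent]:
    """Connected components of the edges exceeding the primary threshold."""
    n = t_matrix.shape[0]
    iu = np.triu_indices(n, k=1)
    t_flat = t_matrix[iu]
    signed = t_flat if config.direction == "A>B" else -t_flat
    return _components_from_mask(signed > config.t_threshold, iu, n, config.component_size)


def _max_component_size(
    mask: np.ndarray, iu: tuple[np.ndarray, np.ndarray], n: int, size_by: str
) -> int:
    ei, ej = iu[0][mask], iu[1][mask]
    if len(ei) == 0:
        return 0
    adj = coo_matrix((np.ones(len(ei)), (ei, ej)), shape=(n, n))
    _, labels = connected_components(adj, directed=False)
    if size_by == "edges":
        counts = np.bincount(labels[ei])
    else:
        node_ids = np.unique(np.concatenate([ei, ej]))
        counts = np.bincount(labels[node_ids])
    return int(counts.max())


def nbs_test(
    group_a: list[ConnectivityMatrix],
    group_b: list[ConnectivityMatrix],
    config: NbsConfig = NbsConfig(),
    permutation_block: int = 2000,
) -> NbsResult:
    """Full NBS: edgewise t, suprathreshold components, permutation FWER.

    Permutations relabel whole subjects (connectomes travel as units).  With
    small groups the number of distinct labelings may fall below
    ``n_permutations``; a warning is issued and sampling proceeds with
    replacement, as prescribed for permutation tests on exchangeable units.
    """
    data_a, n = _stack_upper(group_a)
    data_b, _ = _stack_upper(group_b)
    n_a, n_b = len(data_a), len(data_b)
    if n_a < 2 or n_b < 2:
        raise ValueError("need at least 2 subjects per group")
    n_distinct = comb(n_a + n_b, n_a)
    if n_distinct < config.n_permutations:
        warnings.warn(
            f"only {n_distinct} distinct labelings for {config.n_permutations} "
            "permutations; duplicates will occur",
            stacklevel=2,
        )

    t_obs = edgewise_tstats(group_a, group_b)
    observed = suprathreshold_components(t_obs, config)

    x = np.vstack([data_a, data_b])  # (n_subjects, n_edges)
    x2 = x**2
    total = x.sum(0)
    total2 = x2.sum(0)
    iu = np.triu_indices(n, k=1)
    rng = np.random.default_rng(config.seed)

    null_max = np.empty(config.n_permutations, dtype=np.int64)
    done = 0
    while done < config.n_permutations:
        block = min(permutation_block, config.n_permutations - done)
        sel = np.zeros((block, n_a + n_b), dtype=np.float64)
        for r in range(block):
            sel[r, rng.choice(n_a + n_b, size=n_a, replace=False)] = 1.0
        sum_a = sel @ x
        ss_a = sel @ x2
        t_perm = _pooled_t(sum_a, ss_a, n_a, total - sum_a, total2 - ss_a, n_b)
        signed = t_perm if config.direction == "A>B" else -t_perm
        over = signed > config.t_threshold
        for r in range(block):
            null_max[done + r] = _max_component_size(
                over[r], iu, n, config.component_size
            )
        done += block

    for comp in observed:
        exceed = int(np.count_nonzero(null_max >= comp.size))
        comp.corrected_p = (1 + exceed) / (1 + config.n_permutations)

    labels = list(group_a[0].labels) if group_a[0].labels else []
    return NbsResult(t_matrix=t_obs, components=observed,
                     null_max_sizes=null_max, config=config, labels=labels)
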