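import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make tests/oracles.py importable

from lpstopo.connectivity import ConnectivityMatrix, EpochSet
from lpstopo.graphs import BinaryGraph


def make_graph(n: int, edges) -> BinaryGraph:
    """Binary graph from an explicit edge list (nodes 0..n-1)."""
    adj = np.zeros((n, n), dtype=np.int8)
    for i, j in edges:
        adj[i, j] = adj[j, i] = 1
    return BinaryGraph(nodes=list(range(n)), adjacency=adj, pt=100.0)


def random_graph(n: int, p: float, seed: int) -> BinaryGraph:
    rng = np.random.default_rng(seed)
    adj = np.triu((rng.random((n, n)) < p).astype(np.int8), k=1)
    adj += adj.T
    return BinaryGraph(nodes=list(range(n)), adjacency=adj, pt=100.0)


def random_weights(n: int, seed: int, normalized: bool = True) -> ConnectivityMatrix:
    """Random symmetric weight matrix with distinct off-diagonal entries."""
    rng = np.random.default_rng(seed)
    w = np.triu(rng.random((n, n)), k=1)
    w = w + w.T
    if normalized:
        w = w / w.max()
    np.fill_diagonal(w, 0.0)
    return ConnectivityMatrix(subject_id=f"rand{seed}", band="beta1",
                              weights=w, normalized=normalized)


def sinusoid_epochs(
    freqs_hz, phases_rad, n_epochs: int = 8, fs: float = 256.0,
    epoch_seconds: float = 2.0, noise_sd: float = 0.0, seed: int = 0,
    random_epoch_phase: bool = True,
) -> EpochSet:
    """Epoch set of pure sinusoids, one channel per (freq, phase offset) pair.

    All channels share a per-epoch random reference phase so that fixed
    phase *differences* between channels are preserved across epochs.
    """
    rng = np.random.default_rng(seed)
    ns = int(round(epoch_seconds * fs))
    t = np.arange(ns) / fs
    n_ch = len(freqs_hz)
    data = np.zeros((n_epochs, n_ch, ns))
    for e in range(n_epochs):
        ref = rng.uniform(0, 2 * np.pi) if random_epoch_phase else 0.0
        for c, (f, ph) in enumerate(zip(freqs_hz, phases_rad)):
            data[e, c] = np.cos(2 * np.pi * f * t + ref + ph)
    if noise_sd:
        data += noise_sd * rng.standard_normal(data.shape)
    return EpochSet(data=data, sampling_rate=fs, epoch_seconds=epoch_seconds)


@pytest.fixture
def k4_plus_tail() -> BinaryGraph:
    """K4 on nodes 0-3 plus edges 3-4 and 2-4 (the worked LCP-corr example)."""
    return make_graph(5, [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3),
                          (3, 4), (2, 4)])
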