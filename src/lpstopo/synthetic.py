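"""Synthetic cohorts with the statistical structure the analysis assumes.

No patient EEG is shipped with the package; instead this module emulates a
25-subject disorders-of-consciousness cohort (12 UWS, 13 MCS), six frequency
bands, and a planted interhemispheric fronto-parietal connectivity deficit in
the beta1 band of the UWS group, so every downstream stage is testable.

Signal model
------------
Each ROI carries independent white noise plus a weak band-limited oscillation
of its own.  For every coupled ROI pair, both ROIs additionally share a
sinusoidal carrier whose phase is redrawn per epoch and which reaches the
second ROI with a fixed 90-degree lag; the shared-to-noise amplitude ratio is
the coupling strength.  Because a quadrature-lagged shared sinusoid has a
purely imaginary coherency at the carrier bin, expected LPS on a coupled edge
grows monotonically with coupling strength and is near 0 for uncoupled pairs,
giving closed-form anchor points for tests.

Cohort model
------------
CRS-R scores are drawn per subject from group-specific normals truncated at
zero — UWS 5 +/- 1, MCS 13 +/- 4 — matching the clinical summary statistics
the cohort emulates.  Connectivity deficits are planted as a standardized
mean decrease (in units of the between-subject SD) on a configurable edge
set, by default interhemispheric fronto-parietal pairs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .atlas import Atlas, N_ROIS, default_atlas
from .connectivity import (
    BandSpec,
    ConnectivityMatrix,
    DEFAULT_SAMPLING_RATE,
    RoiSignal,
    get_band,
)

__all__ = [
    "EffectSpec",
    "interhemispheric_frontoparietal_edges",
    "generate_coupled_sources",
    "generate_cohort",
    "generate_connectome_cohort",
    "generate_segregation_cohort",
]

logger = logging.getLogger(__name__)

#: Default planted-edge LPS level in the unaffected (MCS) group.
DEFAULT_BASE_LPS = 0.92
#: Default between-subject SD of planted-edge LPS.
DEFAULT_LPS_SD = 0.03
#: ~5 min of 2-s epochs.
DEFAULT_N_EPOCHS = 150

CRS_R_PARAMS = {"UWS": (5.0, 1.0), "MCS": (13.0, 4.0)}


@dataclass(frozen=True)
class EffectSpec:
    """A planted group difference: which edges, which band, how large.

    ``effect_size`` is the standardized mean decrease (in between-subject SD
    units) of connectivity in the affected group; ``direction`` names that
    group.
    """

    edges: frozenset[tuple[int, int]]
    band: str = "beta1"
    effect_size: float = 0.0
    direction: str = "UWS"

    def __post_init__(self) -> None:
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        norm = frozenset(
            (min(i, j), max(i, j)) for i, j in self.edges
        )
        for i, j in norm:
            if not (0 <= i < N_ROIS and 0 <= j < N_ROIS) or i == j:
                raise ValueError(f"invalid ROI pair ({i}, {j})")
        object.__setattr__(self, "edges", norm)
        if not norm and self.effect_size > 0:
            raise ValueError("non-zero effect_size requires a non-empty edge set")


def interhemispheric_frontoparietal_edges(
    atlas: Atlas | None = None, n_edges: int = 20, seed: int | None = None
) -> frozenset[tuple[int, int]]:
    """Cross-hemisphere frontal-parietal ROI pairs for the planted deficit.

    Pairs left-frontal with right-parietal ROIs (and, for larger edge
    counts, right-frontal with left-parietal), emulating a dense
    interhemispheric fronto-parietal subnetwork of reduced connectivity.
    The default 20 edges form the complete bipartite coupling of 4 frontal
    with 5 parietal ROIs, i.e. a compact connected motif rather than
    scattered pairs.  With ``seed`` the candidate pairs are shuffled instead
    of taken in atlas order.
    """
    atlas = atlas or default_atlas()
    frontal_l = atlas.indices_by_lobe("frontal", "L")
    frontal_r = atlas.indices_by_lobe("frontal", "R")
    parietal_l = atlas.indices_by_lobe("parietal", "L")
    parietal_r = atlas.indices_by_lobe("parietal", "R")
    # order candidates so that any prefix is a near-balanced complete
    # bipartite block (growing square blocks), keeping the planted
    # subnetwork compact and connected
    candidates = []
    for hemi_rank, (fr, pa) in enumerate(((frontal_l, parietal_r),
                                          (frontal_r, parietal_l))):
        for k_f, a in enumerate(fr):
            for k_p, b in enumerate(pa):
                key = (hemi_rank, max(k_f, k_p), k_p, k_f)
                candidates.append((key, (min(a, b), max(a, b))))
    candidates = [e for _, e in sorted(candidates)]
    if seed is not None:
        rng = np.random.default_rng(seed)
        order = rng.permutation(len(candidates))
        candidates = [candidates[k] for k in order]
    if n_edges > len(candidates):
        raise ValueError(f"at most {len(candidates)} such edges exist")
    return frozenset(candidates[:n_edges])


def _band_bin_freq(band: BandSpec, epoch_seconds: float,
                   rng: np.random.Generator) -> float:
    """A carrier frequency drawn from the DFT bin grid inside the band.

    Coupled carriers sit on bin centres so that the epoch-length DFT
    concentrates their power in one bin; an off-grid carrier leaks power
    across bins and makes the measured synchronization depend on the
    carrier's alignment with the grid — a quantization artifact that would
    masquerade as between-subject variability.
    """
    df = 1.0 / epoch_seconds
    grid = np.arange(np.ceil(band.lo / df) * df, band.hi + 1e-9, df)
    return float(rng.choice(grid))


def strength_to_lps(strength: float, epoch_samples: int = 512) -> float:
    """Asymptotic LPS of a quadrature-coupled pair at given carrier strength.

    At a bin-centred carrier of amplitude ``s`` against unit-variance white
    noise, the Hann-tapered DFT concentrates carrier power K*s^2 relative to
    the per-bin noise power, with K = N/6 for N-sample epochs; the coherency
    at that bin is purely imaginary with magnitude K s^2 / (K s^2 + 1), so

        LPS = (K s^2 / (K s^2 + 1))^2.
    """
    k = epoch_samples / 6.0
    ratio = k * strength**2 / (k * strength**2 + 1.0)
    return ratio**2


def lps_to_strength(lps: float, epoch_samples: int = 512) -> float:
    """Carrier strength that yields the target asymptotic LPS (inverse map)."""
    if not (0.0 <= lps < 1.0):
        raise ValueError("target LPS must be in [0, 1)")
    if lps == 0.0:
        return 0.0
    k = epoch_samples / 6.0
    ratio = float(np.sqrt(lps))
    return float(np.sqrt(ratio / (1.0 - ratio) / k))


@dataclass(frozen=True)
class CommonDrive:
    """A coherent oscillatory source shared by a subnetwork.

    All ``nodes_zero`` receive the carrier at zero phase, all
    ``nodes_lagged`` at ``lag_degrees``.  Lagged synchronization therefore
    appears exactly on the cross pairs (one node from each set), while
    within-set pairs share the carrier at zero lag and contribute no LPS —
    the same insensitivity to instantaneous mixing that makes the measure
    robust to volume conduction.
    """

    nodes_zero: tuple[int, ...]
    nodes_lagged: tuple[int, ...]
    strength: float
    lag_degrees: float = 90.0

    def __post_init__(self) -> None:
        if set(self.nodes_zero) & set(self.nodes_lagged):
            raise ValueError("drive node sets must be disjoint")
        if not (0.0 <= self.strength <= 1.0):
            raise ValueError("drive strength must be in [0, 1]")

    @property
    def cross_pairs(self) -> frozenset[tuple[int, int]]:
        return frozenset(
            (min(a, b), max(a, b))
            for a in self.nodes_zero for b in self.nodes_lagged
        )


def _bipartition_of(edges: frozenset[tuple[int, int]]) -> tuple[tuple, tuple] | None:
    """(side_a, side_b) if ``edges`` is a complete bipartite graph, else None."""
    import networkx as nx

    g = nx.Graph(list(edges))
    if not nx.is_connected(g) or not nx.is_bipartite(g):
        return None
    side_a, side_b = nx.bipartite.sets(g)
    if len(side_a) * len(side_b) != len(edges):
        return None
    return tuple(sorted(side_a)), tuple(sorted(side_b))


def generate_coupled_sources(
    atlas: Atlas,
    coupling: dict[tuple[int, int], float],
    band: str | BandSpec,
    n_epochs: int = DEFAULT_N_EPOCHS,
    sampling_rate: float = DEFAULT_SAMPLING_RATE,
    epoch_seconds: float = 2.0,
    lag_degrees: float = 90.0,
    own_oscillation_amplitude: float = 0.3,
    own_oscillation_range: tuple[float, float] = (2.0, 30.0),
    drives: tuple[CommonDrive, ...] = (),
    seed: int = 0,
    subject_id: str = "sim",
) -> RoiSignal:
    """Simulate one subject's ROI signals with lag-coupled edges in one band.

    ``coupling`` maps unordered ROI index pairs to strengths in [0, 1]; each
    coupled pair shares a band-limited carrier with a fixed phase lag
    (default 90 degrees, which maximizes the imaginary coherency and hence
    LPS sensitivity).  ``drives`` add coherent subnetwork sources (one
    carrier per drive) on top of the pairwise couplings.

    Each ROI's independent background oscillation is drawn from the broad
    EEG range ``own_oscillation_range`` rather than from the coupling band,
    as background rhythms span the spectrum; this also keeps incidental
    spectral collisions with coupled carriers rare.
    """
    if n_epochs < 1:
        raise ValueError("n_epochs must be >= 1")
    if sampling_rate <= 0:
        raise ValueError("sampling rate must be positive")
    spec = get_band(band)
    for pair, s in coupling.items():
        if not (0.0 <= s <= 1.0):
            raise ValueError(f"coupling strength {s} for {pair} outside [0, 1]")
    rng = np.random.default_rng(seed)
    n = len(atlas)
    epoch_samples = int(round(epoch_seconds * sampling_rate))
    t = np.arange(epoch_samples) / sampling_rate
    lag = np.deg2rad(lag_degrees)

    data = rng.standard_normal((n_epochs, n, epoch_samples))
    # independent background oscillation per ROI, phase redrawn per epoch
    lo, hi = own_oscillation_range
    own_freqs = rng.uniform(lo, hi, size=n)
    own_phases = rng.uniform(0, 2 * np.pi, size=(n_epochs, n))
    data += own_oscillation_amplitude * np.cos(
        2 * np.pi * own_freqs[None, :, None] * t[None, None, :]
        + own_phases[:, :, None]
    )
    # shared lagged carrier per coupled edge
    for (i, j), s in sorted(coupling.items()):
        if s == 0.0:
            continue
        f = _band_bin_freq(spec, epoch_seconds, rng)
        phases = rng.uniform(0, 2 * np.pi, size=n_epochs)
        arg = 2 * np.pi * f * t[None, :] + phases[:, None]
        data[:, i, :] += s * np.cos(arg)
        data[:, j, :] += s * np.cos(arg - lag)
    # one coherent carrier per subnetwork drive
    for drive in drives:
        if drive.strength == 0.0:
            continue
        f = _band_bin_freq(spec, epoch_seconds, rng)
        phases = rng.uniform(0, 2 * np.pi, size=n_epochs)
        arg = 2 * np.pi * f * t[None, :] + phases[:, None]
        drive_lag = np.deg2rad(drive.lag_degrees)
        for i in drive.nodes_zero:
            data[:, i, :] += drive.strength * np.cos(arg)
        for j in drive.nodes_lagged:
            data[:, j, :] += drive.strength * np.cos(arg - drive_lag)

    samples = data.transpose(1, 0, 2).reshape(n, n_epochs * epoch_samples)
    return RoiSignal(subject_id=subject_id, samples=samples,
                     sampling_rate=sampling_rate)


def _draw_crs_r(group: str, rng: np.random.Generator) -> float:
    mean, sd = CRS_R_PARAMS[group]
    value = rng.normal(mean, sd)
    if value < 0:
        logger.info("CRS-R draw %.2f truncated to 0 for group %s", value, group)
        value = 0.0
    return float(value)


def _cohort_table(groups: list[str], rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    counters = {"UWS": 0, "MCS": 0}
    for g in groups:
        counters[g] += 1
        rows.append(
            {"subject_id": f"{g.lower()}{counters[g]:02d}", "group": g,
             "crs_r": _draw_crs_r(g, rng)}
        )
    return pd.DataFrame(rows, columns=["subject_id", "group", "crs_r"])


def generate_cohort(
    n_uws: int = 12,
    n_mcs: int = 13,
    effect: EffectSpec | None = None,
    base_lps: float = DEFAULT_BASE_LPS,
    lps_sd: float = DEFAULT_LPS_SD,
    n_baseline_edges: int = 40,
    baseline_lps: float = 0.97,
    n_background_edges: int = 300,
    background_lps: float = 0.2,
    background_subject_sd: float = 0.05,
    n_epochs: int = DEFAULT_N_EPOCHS,
    sampling_rate: float = DEFAULT_SAMPLING_RATE,
    epoch_seconds: float = 2.0,
    seed: int = 0,
    atlas: Atlas | None = None,
) -> tuple[list[RoiSignal], pd.DataFrame]:
    """Simulate a full cohort of ROI signal sets plus its cohort table.

    The planted contrast is specified on the scale the analysis measures:
    MCS subjects get a per-subject planted-edge LPS level drawn from
    ``N(base_lps, lps_sd)``, UWS subjects from a mean shifted down by
    ``effect.effect_size * lps_sd`` (a standardized decrease of LPS
    weight).  Targets are converted to carrier strengths through the
    closed-form response :func:`lps_to_strength` — the coupling-to-LPS map
    is compressive, so planting in coupling space would deliver a smaller,
    skewed contrast.  Only ``effect.band`` carries coupling; all other
    bands are null.

    When the effect edge set is a complete bipartite subnetwork (the default
    planted motif is), the effect is realized as a single coherent drive
    (:class:`CommonDrive`) with one per-subject strength: source nodes
    receive the carrier at zero phase and target nodes at 90 degrees, so
    LPS appears exactly on the planted cross pairs.  For arbitrary edge
    sets the effect falls back to independent per-edge carriers, which is
    noisier for ROIs participating in many planted edges.

    In addition, every subject shares two group-independent layers drawn
    once per cohort on pairs away from the effect subnetwork:

    * a backbone of ``n_baseline_edges`` strongly coupled edges (LPS level
      ``N(baseline_lps, lps_sd/3)``), which keeps the matrix maximum used
      for normalization on edges unaffected by the group contrast; and
    * a broad weak background of ``n_background_edges`` edges whose
      subject-level mean varies (``N(background_lps,
      background_subject_sd)``), giving overall functional connectivity a
      realistic between-subject spread dominated by group-independent
      variation — as in the emulated study, where overall FC did not
      differ between groups while a specific subnetwork did.
    """
    if n_uws < 2 or n_mcs < 2:
        raise ValueError("need at least 2 subjects per group")
    atlas = atlas or default_atlas()
    if effect is None:
        # the emulated study condition: a clearly significant
        # interhemispheric fronto-parietal deficit in the UWS group
        effect = EffectSpec(edges=interhemispheric_frontoparietal_edges(atlas),
                            effect_size=2.5)
    rng = np.random.default_rng(seed)
    groups = ["UWS"] * n_uws + ["MCS"] * n_mcs
    cohort = _cohort_table(groups, rng)

    n = len(atlas)
    effect_rois = {v for e in effect.edges for v in e}
    all_pairs = [(i, j) for i in range(n) for j in range(i + 1, n)
                 if i not in effect_rois and j not in effect_rois]
    chosen = rng.choice(len(all_pairs), size=n_baseline_edges + n_background_edges,
                        replace=False)
    baseline_edges = [all_pairs[k] for k in sorted(chosen[:n_baseline_edges])]
    background_edges = [all_pairs[k] for k in sorted(chosen[n_baseline_edges:])]

    bipartition = _bipartition_of(effect.edges) if effect.edges else None
    epoch_samples = int(round(epoch_seconds * sampling_rate))

    def draw_strength(lps_mean: float, sd: float) -> float:
        target = float(np.clip(rng.normal(lps_mean, sd), 0.0, 0.995))
        return float(np.clip(lps_to_strength(target, epoch_samples), 0.0, 1.0))

    signals = []
    for _, row in cohort.iterrows():
        mean = base_lps
        if row["group"] == effect.direction:
            mean = base_lps - effect.effect_size * lps_sd
        coupling = {}
        drives: tuple[CommonDrive, ...] = ()
        if bipartition is not None:
            drives = (CommonDrive(nodes_zero=bipartition[0],
                                  nodes_lagged=bipartition[1],
                                  strength=draw_strength(mean, lps_sd)),)
        else:
            for pair in sorted(effect.edges):
                coupling[pair] = draw_strength(mean, lps_sd)
        for pair in baseline_edges:
            coupling[pair] = draw_strength(baseline_lps, lps_sd / 3)
        subject_background = rng.normal(background_lps, background_subject_sd)
        for pair in background_edges:
            target = np.clip(rng.normal(subject_background, background_subject_sd),
                             0.0, 0.6)
            coupling[pair] = float(np.clip(
                lps_to_strength(float(target), epoch_samples), 0.0, 1.0))
        signals.append(
            generate_coupled_sources(
                atlas, coupling, effect.band, n_epochs=n_epochs,
                sampling_rate=sampling_rate, epoch_seconds=epoch_seconds,
                drives=drives,
                seed=int(rng.integers(2**31)), subject_id=row["subject_id"],
            )
        )
    return signals, cohort


def _base_weight_matrix(
    n: int, edge_profile: np.ndarray, subject_sd: float, rng: np.random.Generator
) -> np.ndarray:
    noise = rng.normal(0.0, subject_sd, size=(n, n))
    noise = np.triu(noise, k=1)
    w = edge_profile + noise + noise.T
    np.fill_diagonal(w, 0.0)
    return w


def _clip_weights(w: np.ndarray) -> np.ndarray:
    n_out = int(np.count_nonzero((w < 0) | (w > 1)))
    if n_out:
        # a handful of tail draws per matrix is expected; a large fraction
        # means the requested shift pushes the weight distribution out of range
        level = logging.WARNING if n_out > 0.01 * w.size else logging.DEBUG
        logger.log(level, "%d weights outside [0, 1] clipped", n_out)
    w = np.clip(w, 0.0, 1.0)
    np.fill_diagonal(w, 0.0)
    return w


def generate_connectome_cohort(
    n_uws: int = 12,
    n_mcs: int = 13,
    effect: EffectSpec | None = None,
    base_mean: float = 0.3,
    edge_sd: float = 0.08,
    subject_sd: float = 0.05,
    seed: int = 0,
    atlas: Atlas | None = None,
) -> tuple[list[ConnectivityMatrix], pd.DataFrame]:
    """Fast path: draw weighted connectomes directly, bypassing signals.

    Every subject shares a fixed edge profile (edge-wise means drawn once
    from ``N(base_mean, edge_sd)``) plus independent subject noise of SD
    ``subject_sd``; UWS subjects have ``effect.effect_size * subject_sd``
    subtracted on the planted edges, i.e. a standardized mean shift of
    ``effect_size``.  Weights falling outside [0, 1] are clipped and logged.
    """
    if n_uws < 2 or n_mcs < 2:
        raise ValueError("need at least 2 subjects per group")
    atlas = atlas or default_atlas()
    n = len(atlas)
    if effect is None:
        effect = EffectSpec(edges=interhemispheric_frontoparietal_edges(atlas))
    rng = np.random.default_rng(seed)
    groups = ["UWS"] * n_uws + ["MCS"] * n_mcs
    cohort = _cohort_table(groups, rng)

    profile_tri = rng.normal(base_mean, edge_sd, size=(n, n))
    edge_profile = np.triu(profile_tri, k=1)
    edge_profile = edge_profile + edge_profile.T

    shift = np.zeros((n, n))
    for i, j in effect.edges:
        shift[i, j] = shift[j, i] = effect.effect_size * subject_sd

    matrices = []
    for _, row in cohort.iterrows():
        w = _base_weight_matrix(n, edge_profile, subject_sd, rng)
        if row["group"] == effect.direction:
            w = w - shift
        matrices.append(
            ConnectivityMatrix(
                subject_id=row["subject_id"], band=effect.band,
                weights=_clip_weights(w), normalized=False,
                labels=atlas.labels,
            )
        )
    return matrices, cohort


def generate_segregation_cohort(
    n_uws: int = 12,
    n_mcs: int = 13,
    n_modules: int = 6,
    base_mean: float = 0.3,
    subject_sd: float = 0.04,
    mcs_boost: float = 0.06,
    uws_boost: float = 0.16,
    band: str = "beta1",
    seed: int = 0,
    atlas: Atlas | None = None,
) -> tuple[list[ConnectivityMatrix], pd.DataFrame]:
    """Cohort with extra local cliquishness in the UWS-like group.

    Within-module edge weights are boosted in both groups, more strongly for
    UWS, so that UWS binary graphs at a fixed density form denser local
    cliques: higher clustering, local efficiency and LCP-corr, lower
    small-worldness omega — the segregation-over-integration profile the
    analysis is designed to detect.
    """
    if n_uws < 2 or n_mcs < 2:
        raise ValueError("need at least 2 subjects per group")
    atlas = atlas or default_atlas()
    n = len(atlas)
    rng = np.random.default_rng(seed)
    groups = ["UWS"] * n_uws + ["MCS"] * n_mcs
    cohort = _cohort_table(groups, rng)

    module = rng.integers(0, n_modules, size=n)
    same_module = (module[:, None] == module[None, :]).astype(float)
    np.fill_diagonal(same_module, 0.0)

    matrices = []
    for _, row in cohort.iterrows():
        boost = uws_boost if row["group"] == "UWS" else mcs_boost
        noise = np.triu(rng.normal(0.0, subject_sd, size=(n, n)), k=1)
        w = base_mean + boost * same_module + noise + noise.T
        np.fill_diagonal(w, 0.0)
        matrices.append(
            ConnectivityMatrix(
                subject_id=row["subject_id"], band=band,
                weights=_clip_weights(w), normalized=False,
                labels=atlas.labels,
            )
        )
    return matrices, cohort
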