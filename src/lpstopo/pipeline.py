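"""End-to-end pipeline: simulate -> connectivity -> graphs -> topology -> NBS -> stats.

Every run writes its artifacts into a run directory with full provenance
(config hash, seeds, library versions); the same config and seed reproduce
byte-identical numeric outputs.  Stages can be run in one call
(:func:`run_pipeline`) or individually through the CLI subcommands, which
compose to the same results because each stage reads exactly what the
previous stage wrote.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .atlas import default_atlas
from .connectivity import (
    BANDS,
    ConnectivityMatrix,
    lps_all_bands,
    normalize_by_max,
    overall_fc,
    segment_epochs,
)
from .graphs import (
    DEFAULT_PT,
    proportional_threshold,
    prune_disconnected,
    threshold_sweep,
)
from .io import (
    export_viewer_files,
    read_cohort,
    read_connectivity,
    read_signal,
    write_cohort,
    write_connectivity,
    write_signal,
)
from .nbs import NbsConfig, nbs_test
from .stats import mann_whitney, nodal_contrast, whole_brain_comparison
from .stochastic import (
    modularity,
    small_worldness_both,
    structural_consistency,
)
from .synthetic import EffectSpec, generate_cohort, interhemispheric_frontoparietal_edges
from .topology import nodal_metrics, summarize_deterministic

__all__ = ["PipelineConfig", "run_pipeline", "load_config"]

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    out_dir: str = "run"
    seed: int = 0
    bands: tuple[str, ...] = tuple(BANDS)
    pt_default: float = DEFAULT_PT
    pt_sweep: tuple[float, ...] = (30.0, 20.0, 10.0)
    epoch_seconds: float = 2.0
    # synthetic stage (disable to read signals/cohort from input paths)
    simulate: bool = True
    n_uws: int = 12
    n_mcs: int = 13
    effect_band: str = "beta1"
    effect_size: float = 2.5
    n_effect_edges: int = 20
    n_epochs: int = 150
    # stage inputs when simulate is off
    cohort_file: str | None = None
    signals_dir: str | None = None
    # stochastic measure settings (focus band only, for tractable runtimes)
    stochastic_band: str = "beta1"
    n_null: int = 20
    n_restarts: int = 20
    n_rep: int = 10
    swaps_per_edge: int = 10
    perturb_fraction: float = 0.1
    # NBS settings
    nbs_t_threshold: float = 2.6
    nbs_n_permutations: int = 500
    nbs_direction: str = "B>A"  # MCS>UWS recovers a planted UWS deficit
    nbs_alpha: float = 0.05

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def load_config(path: str | Path) -> PipelineConfig:
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    for key in ("bands", "pt_sweep"):
        if key in raw:
            raw[key] = tuple(raw[key])
    return PipelineConfig(**raw)


def _stage_simulate(config: PipelineConfig, out: Path) -> tuple[list, pd.DataFrame]:
    atlas = default_atlas()
    effect = EffectSpec(
        edges=interhemispheric_frontoparietal_edges(atlas, config.n_effect_edges),
        band=config.effect_band, effect_size=config.effect_size, direction="UWS",
    )
    signals, cohort = generate_cohort(
        config.n_uws, config.n_mcs, effect=effect, n_epochs=config.n_epochs,
        seed=config.seed, atlas=atlas,
    )
    sig_dir = out / "signals"
    sig_dir.mkdir(parents=True, exist_ok=True)
    for s in signals:
        write_signal(s, sig_dir / f"{s.subject_id}.tsv", atlas)
    write_cohort(cohort, out / "cohort.csv")
    return signals, cohort


def _stage_connectivity(
    config: PipelineConfig, out: Path, signals: list, cohort: pd.DataFrame
) -> dict[str, dict[str, ConnectivityMatrix]]:
    atlas = default_atlas()
    conn_dir = out / "connectivity"
    conn_dir.mkdir(parents=True, exist_ok=True)
    matrices: dict[str, dict[str, ConnectivityMatrix]] = {b: {} for b in config.bands}
    band_specs = {b: BANDS[b] for b in config.bands}
    for signal in signals:
        epochs = segment_epochs(signal, config.epoch_seconds)
        for band, m in lps_all_bands(epochs, band_specs).items():
            m.subject_id = signal.subject_id
            m.labels = atlas.labels
            m = normalize_by_max(m)
            write_connectivity(m, conn_dir / f"{signal.subject_id}_{band}.tsv")
            matrices[band][signal.subject_id] = m
    return matrices


def _load_connectivity(config: PipelineConfig, out: Path, cohort: pd.DataFrame):
    conn_dir = out / "connectivity"
    matrices: dict[str, dict[str, ConnectivityMatrix]] = {b: {} for b in config.bands}
    for band in config.bands:
        for sid in cohort["subject_id"]:
            path = conn_dir / f"{sid}_{band}.tsv"
            if not path.exists():
                raise FileNotFoundError(f"missing connectivity file {path}")
            matrices[band][sid] = read_connectivity(path, subject_id=sid, band=band,
                                                    normalized=True)
    return matrices


def _stage_graphs(config: PipelineConfig, out: Path, matrices) -> pd.DataFrame:
    rows = []
    for band, per_subject in matrices.items():
        for sid, matrix in per_subject.items():
            sweep = threshold_sweep(matrix, config.pt_sweep)
            sweep.insert(0, "band", band)
            sweep.insert(0, "subject_id", sid)
            rows.append(sweep)
    table = pd.concat(rows, ignore_index=True)
    table.to_csv(out / "threshold_sweep.csv", index=False,
                 float_format="%.17g", lineterminator="\n")
    return table


def _stage_topology(config: PipelineConfig, out: Path, matrices, cohort):
    summaries = {band: [] for band in config.bands}
    nodal = {}
    seed_rng = np.random.default_rng(config.seed + 1)
    stochastic_seeds = {
        sid: int(seed_rng.integers(2**31)) for sid in cohort["subject_id"]
    }
    for band in config.bands:
        for sid in cohort["subject_id"]:
            graph = prune_disconnected(
                proportional_threshold(matrices[band][sid], config.pt_default)
            )
            summary = summarize_deterministic(graph, subject_id=sid, band=band)
            if band == config.stochastic_band:
                s = stochastic_seeds[sid]
                omega, omega_eff = small_worldness_both(
                    graph, config.n_null, config.swaps_per_edge, seed=s
                )
                summary.sw_omega = omega.value
                summary.sw_omega_eff = omega_eff.value
                summary.q_modularity = modularity(
                    graph, n_restarts=config.n_restarts, seed=s + 2
                ).q
                summary.sigma_c = structural_consistency(
                    graph, config.perturb_fraction, config.n_rep, seed=s + 3
                ).mean
                nodal[sid] = nodal_metrics(graph)
            summaries[band].append(summary)
    long_rows = []
    for band, items in summaries.items():
        for s in items:
            for measure in ("L", "E_glob", "E_loc", "ACC", "ANBC", "LCP_corr",
                            "sw_omega", "sw_omega_eff", "q_modularity", "sigma_c"):
                long_rows.append({
                    "subject_id": s.subject_id, "band": band, "pt": s.pt,
                    "measure": measure, "value": getattr(s, measure),
                    "n_pruned": s.n_pruned,
                })
    pd.DataFrame(long_rows).to_csv(out / "topology.csv", index=False,
                                   float_format="%.17g", lineterminator="\n")
    return summaries, nodal


def _stage_nbs(config: PipelineConfig, out: Path, matrices, cohort):
    band = config.effect_band
    uws = [matrices[band][s] for s in cohort.loc[cohort["group"] == "UWS", "subject_id"]]
    mcs = [matrices[band][s] for s in cohort.loc[cohort["group"] == "MCS", "subject_id"]]
    nbs_config = NbsConfig(
        t_threshold=config.nbs_t_threshold,
        n_permutations=config.nbs_n_permutations,
        direction=config.nbs_direction, seed=config.seed + 2,
        alpha=config.nbs_alpha,
    )
    result = nbs_test(uws, mcs, nbs_config)
    atlas = default_atlas()
    rows = [
        {"component": k, "size_edges": len(c.edges), "size_nodes": len(c.nodes),
         "corrected_p": c.corrected_p,
         "edges": ";".join(f"{atlas[i].label}-{atlas[j].label}" for i, j in c.edges)}
        for k, c in enumerate(result.components)
    ]
    pd.DataFrame(rows, columns=["component", "size_edges", "size_nodes",
                                "corrected_p", "edges"]).to_csv(
        out / "nbs_components.csv", index=False, float_format="%.17g",
        lineterminator="\n")
    if result.components:
        export_viewer_files(result, out / "nbs_component0", atlas)
    return result


def _stage_stats(config: PipelineConfig, out: Path, matrices, cohort, summaries, nodal):
    focus = summaries[config.stochastic_band]
    comparison = whole_brain_comparison(focus, cohort)
    comparison.to_csv(out / "whole_brain_comparison.csv", index=False,
                      float_format="%.17g", lineterminator="\n")

    atlas = default_atlas()
    uws_ids = cohort.loc[cohort["group"] == "UWS", "subject_id"]
    mcs_ids = cohort.loc[cohort["group"] == "MCS", "subject_id"]
    nodal_tables = []
    for metric in ("degree", "clustering", "betweenness"):
        table = nodal_contrast(
            [nodal[s] for s in uws_ids], [nodal[s] for s in mcs_ids],
            metric=metric, n_rois=len(atlas), labels=atlas.labels,
        )
        table.insert(0, "metric", metric)
        nodal_tables.append(table)
    pd.concat(nodal_tables, ignore_index=True).to_csv(
        out / "nodal_contrast.csv", index=False, float_format="%.17g",
        lineterminator="\n")

    # overall-FC bias check, per band
    fc_rows = []
    for band in config.bands:
        fc = {sid: overall_fc(m) for sid, m in matrices[band].items()}
        a = [fc[s] for s in uws_ids]
        b = [fc[s] for s in mcs_ids]
        u, p = mann_whitney(a, b)
        fc_rows.append({"band": band, "uws_mean": np.mean(a), "mcs_mean": np.mean(b),
                        "mw_u": u, "mw_p": p})
    pd.DataFrame(fc_rows).to_csv(out / "overall_fc.csv", index=False,
                                 float_format="%.17g", lineterminator="\n")
    return comparison


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute all stages; returns the run directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    if config.simulate:
        signals, cohort = _stage_simulate(config, out)
    else:
        if not config.cohort_file or not config.signals_dir:
            raise FileNotFoundError(
                "simulate is off and no cohort_file/signals_dir configured"
            )
        cohort = read_cohort(config.cohort_file)
        signals = [
            read_signal(Path(config.signals_dir) / f"{sid}.tsv")
            for sid in cohort["subject_id"]
        ]
    logger.info("cohort: %d subjects", len(cohort))

    matrices = _stage_connectivity(config, out, signals, cohort)
    _stage_graphs(config, out, matrices)
    summaries, nodal = _stage_topology(config, out, matrices, cohort)
    _stage_nbs(config, out, matrices, cohort)
    _stage_stats(config, out, matrices, cohort, summaries, nodal)

    provenance = {
        "config": dataclasses.asdict(config),
        "config_hash": config.config_hash(),
        "versions": {
            "lpstopo": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
    }
    with open(out / "provenance.json", "w", encoding="utf-8") as fh:
        json.dump(provenance, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
    return out
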