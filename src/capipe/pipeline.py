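"""Pipeline orchestration: behaviour -> ensembles -> bursts -> spatial ->
network -> statistics, over a study directory tree, writing tidy CSVs.

Every stage is deterministic given the analysis configuration's seed; stage
failures abort with an error naming the stage and session.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from . import behavior, bursts, ensembles, network, spatial
from .core import (
    SESSION_LABELS,
    AnalysisConfig,
    RegistrationMap,
    SessionDataset,
    compute_speed,
    read_registration,
    read_session,
)

log = logging.getLogger("capipe")

_FLOAT_FMT = "%.8g"


class PipelineError(RuntimeError):
    def __init__(self, stage: str, session: str | None, cause: Exception):
        self.stage, self.session = stage, session
        where = f"stage={stage}" + (f", session={session}" if session else "")
        super().__init__(f"[{where}] {cause}")


def read_study(study_dir: str | Path) -> tuple[dict[str, SessionDataset], RegistrationMap]:
    """Read a study tree written by the simulator (study.yaml + session dirs)."""
    study_dir = Path(study_dir)
    manifest_path = study_dir / "study.yaml"
    if not manifest_path.exists():
        raise FileNotFoundError(manifest_path)
    with open(manifest_path) as fh:
        manifest = yaml.safe_load(fh)
    sessions = {}
    for label in SESSION_LABELS:
        if label not in manifest["sessions"]:
            raise PipelineError("read", label, FileNotFoundError(f"session {label} missing"))
        sessions[label] = read_session(study_dir / manifest["sessions"][label])
    regmap = read_registration(study_dir / manifest["registration"])
    return sessions, regmap


def _write(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def run_pipeline(
    study_dir: str | Path,
    out_dir: str | Path,
    config: AnalysisConfig | None = None,
) -> dict[str, pd.DataFrame]:
    """Run every analysis stage on one animal's study tree.

    Writes per-stage CSVs under ``out_dir`` and returns them keyed by name.
    """
    config = config or AnalysisConfig()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    sessions, regmap = read_study(study_dir)
    animal = next(iter(sessions.values())).meta.animal_id
    group = next(iter(sessions.values())).meta.group_label
    tables: dict[str, pd.DataFrame] = {}
    metric_rows: list[dict] = []

    def add_metric(session: str, name: str, value: float) -> None:
        metric_rows.append(
            {"animal_id": animal, "group": group, "session": session,
             "metric_name": name, "value": value}
        )

    # ---- behaviour ----
    try:
        summaries = {}
        for label, ds in sessions.items():
            if ds.arena.object_positions:
                summaries[label] = behavior.score_object_exploration(
                    ds.trajectory, ds.arena, session_label=label
                )
        if summaries:
            tables["behavior"] = behavior.exploration_table(summaries, animal)
            for label, summary in summaries.items():
                for obj, pct in summary.percent_of_total.items():
                    add_metric(label, f"exploration_percent_obj{obj}", pct)
        log.info("behaviour scored for %d session(s)", len(summaries))
    except Exception as exc:  # noqa: BLE001 - stage-tagged abort
        raise PipelineError("behavior", None, exc) from exc

    # ---- ensembles ----
    try:
        events_by_session = {label: ds.events for label, ds in sessions.items()}
        tables["ensembles"] = ensembles.ensemble_table(
            regmap, animal, events_by_session, config.min_active_events
        )
        for _, row in tables["ensembles"].iterrows():
            add_metric(row["session"], row["metric"], row["value"])
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("ensembles", None, exc) from exc

    # ---- bursts ----
    burst_rows, burst_session_rows = [], []
    for label, ds in sessions.items():
        try:
            popz = bursts.population_zscore(ds.traces)
            detected = bursts.detect_bursts(popz, ds.meta.fps, config.burst)
            bursts.burst_participation(ds.events, detected)
            metrics = bursts.burst_session_metrics(detected)
            traj = compute_speed(ds.trajectory)
            frame_speed = np.interp(
                np.arange(ds.traces.n_frames) / ds.meta.fps, traj.t, traj.speed
            )
            corr = bursts.activity_speed_correlation(popz, frame_speed, ds.meta.fps, detected)
            burst_rows.append(bursts.burst_table(detected, animal, label))
            row = {"animal_id": animal, "session": label, **metrics,
                   "speed_rho": corr["rho"], "speed_rho_burst": corr.get("rho_burst", np.nan)}
            burst_session_rows.append(row)
            add_metric(label, "burst_count", metrics["count"])
            add_metric(label, "burst_mean_duration_s", metrics["mean_duration_s"])
            add_metric(label, "burst_mean_magnitude", metrics["mean_magnitude"])
            log.info("%s: %d burst(s)", label, metrics["count"])
        except Exception as exc:  # noqa: BLE001
            raise PipelineError("bursts", label, exc) from exc
    tables["bursts"] = pd.concat(burst_rows, ignore_index=True)
    tables["burst_sessions"] = pd.DataFrame(burst_session_rows)

    # ---- spatial ----
    spatial_rows = []
    ss_root = np.random.SeedSequence(config.seed)
    session_seeds = dict(zip(SESSION_LABELS, ss_root.spawn(len(SESSION_LABELS))))
    for label, ds in sessions.items():
        try:
            results = spatial.analyze_session_cells(
                ds.trajectory, ds.events, ds.arena, config.spatial, session_seeds[label]
            )
            table = spatial.spatial_table(results, animal, label)
            spatial_rows.append(table)
            placey = table[table["is_place_cell_like"]]
            add_metric(label, "place_cell_fraction",
                       float(table["is_place_cell_like"].mean()))
            add_metric(label, "mean_info_bits_per_event",
                       float(placey["info_bits_per_event"].mean()) if len(placey) else np.nan)
            add_metric(label, "mean_object_score",
                       float(placey["object_score"].mean()) if len(placey) else np.nan)
            log.info("%s: %d/%d place-cell-like", label, len(placey), len(table))
        except Exception as exc:  # noqa: BLE001
            raise PipelineError("spatial", label, exc) from exc
    tables["spatial_cells"] = pd.concat(spatial_rows, ignore_index=True)

    # ---- network ----
    summaries = {}
    node_rows, edge_rows = [], []
    for label, ds in sessions.items():
        try:
            net = network.build_network(ds.traces, config.network)
            nodes = network.node_table(net, config.network)
            nodes.insert(0, "session", label)
            nodes.insert(0, "animal_id", animal)
            node_rows.append(nodes)
            edges = net.edge_table.copy()
            edges.insert(0, "session", label)
            edges.insert(0, "animal_id", animal)
            edge_rows.append(edges)
            summaries[label] = network.session_summary(net, config.network)
            log.info("%s: network %d nodes / %d edges", label, net.n_nodes, net.n_edges)
        except Exception as exc:  # noqa: BLE001
            raise PipelineError("network", label, exc) from exc
    tables["network_nodes"] = pd.concat(node_rows, ignore_index=True)
    tables["network_edges"] = pd.concat(edge_rows, ignore_index=True)
    try:
        summary = network.normalize_to_habituation(summaries)
        summary.insert(0, "animal_id", animal)
        tables["network_summary"] = summary
        for _, row in summary.iterrows():
            add_metric(row["session"], row["metric"], row["value"])
            add_metric(row["session"], row["metric"] + "_percent_of_HA", row["percent_of_HA"])
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("network", "HA", exc) from exc

    tables["metrics"] = pd.DataFrame(metric_rows)

    # ---- cell-level session statistics (single-animal scope) ----
    try:
        cells = tables["spatial_cells"]
        usable = cells.dropna(subset=["info_bits_per_event"])
        if usable["session"].nunique() >= 2 and len(usable) >= 8:
            report = _info_across_sessions(usable)
            tables["stats_spatial_info"] = report
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("stats", None, exc) from exc

    for name, df in tables.items():
        _write(df, out_dir / f"{name}.csv")
    config.to_yaml(out_dir / "config_used.yaml")
    return tables


def _info_across_sessions(cells: pd.DataFrame) -> pd.DataFrame:
    from .stats import compare_sessions_within

    tidy = cells.rename(columns={"info_bits_per_event": "value"})[
        ["animal_id", "session", "value"]
    ].assign(animal_id=lambda d: d["animal_id"] + "/" + cells["cell_id"])
    report = compare_sessions_within(tidy, paired=False)
    out = report.pairwise.copy()
    out.insert(0, "omnibus_p", report.p_value)
    out.insert(0, "omnibus_statistic", report.statistic)
    out.insert(0, "omnibus", report.omnibus_test)
    return out


def write_report(out_dir: str | Path, report_dir: str | Path | None = None) -> dict[str, pd.DataFrame]:
    """Pivot the metric table into per-figure-style CSVs.

    fig2c/fig2d: recruitment and reactivation; fig3b-e: place-cell metrics;
    fig4b-d: burst metrics; fig5d-f: network centralities vs habituation.
    """
    out_dir = Path(out_dir)
    report_dir = Path(report_dir) if report_dir else out_dir / "report"
    report_dir.mkdir(parents=True, exist_ok=True)
    metrics = pd.read_csv(out_dir / "metrics.csv")
    views = {
        "fig2c_recruitment": ["active_percent_of_HA"],
        "fig2d_reactivation": ["reactivation_percent"],
        "fig3b_place_fraction": ["place_cell_fraction"],
        "fig3c_spatial_info": ["mean_info_bits_per_event"],
        "fig3e_object_score": ["mean_object_score"],
        "fig4b_burst_count": ["burst_count"],
        "fig4c_burst_duration": ["burst_mean_duration_s"],
        "fig4d_burst_magnitude": ["burst_mean_magnitude"],
        "fig5d_degree": ["mean_degree_percent_of_HA"],
        "fig5e_clustering": ["mean_clustering_percent_of_HA"],
        "fig5f_closeness": ["mean_closeness_percent_of_HA"],
    }
    out = {}
    for name, wanted in views.items():
        view = metrics[metrics["metric_name"].isin(wanted)]
        if not view.empty:
            _write(view, report_dir / f"{name}.csv")
            out[name] = view
    return out


def _collect_metrics(per_animal: Mapping[str, pd.DataFrame]) -> pd.DataFrame:
    """Stack per-animal metric tables for group-level statistics."""
    return pd.concat(list(per_animal.values()), ignore_index=True)
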