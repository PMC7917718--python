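"""End-to-end orchestration: simulate/load -> preprocess -> detect ->
reconstruct -> metrics -> report.

A run is fully described by a :class:`RunConfig` (inputs or a simulation
block, all stage tunables, seed); every stage writes its artifact to the
output directory so any later stage can be re-run from disk, and the
manifest records the seed and a hash of the configuration, which makes
runs byte-reproducible.
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

from . import io as cio
from .network import (
    DEFAULT_THRESHOLD,
    build_network,
    correlation_vs_distance,
    lag_matrix,
    network_metrics,
    pairwise_correlation,
)
from .synthetic import CellMap, SimConfig, apply_preset, simulate
from .traces import TraceMatrix, detect_events, preprocess, summarize_activity

__all__ = ["RunConfig", "RunReport", "run", "render_report"]

log = logging.getLogger("caldynet")


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one analysis run.

    Either ``traces_path`` (+ ``cells_path``) point at existing artifacts,
    or ``sim`` provides a simulation block; ``groups`` optionally maps
    group labels to condition presets, in which case one simulated
    recording is analysed per group.
    """

    out_dir: str = "caldynet_run"
    seed: int = 0
    traces_path: str | None = None
    cells_path: str | None = None
    sim: SimConfig | None = None
    groups: dict[str, str] = field(default_factory=dict)  # label -> preset

    # stage tunables
    baseline_window_s: float = 60.0
    baseline_percentile: float = 20.0
    k_mad: float = 3.0
    min_duration_s: float = 1.5
    offset_fraction: float = 0.5
    threshold: float = DEFAULT_THRESHOLD
    max_lag_s: float = 10.0
    contact_margin_um: float = 2.0
    min_abs_lag_s: float = 0.5

    def validate(self) -> None:
        if self.traces_path is None and self.sim is None:
            raise ValueError(
                "RunConfig needs either traces_path or a sim block"
            )
        if not 0.0 < self.threshold < 1.0:
            raise ValueError("threshold must lie in (0, 1)")

    def config_hash(self) -> str:
        payload = dataclasses.asdict(self)
        payload.pop("out_dir", None)  # where a run lands is not what it is
        if self.sim is not None:
            payload["sim"] = dataclasses.asdict(self.sim)
        blob = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim_block = raw.pop("sim", None)
        sim = SimConfig(**sim_block) if sim_block is not None else None
        return cls(sim=sim, **raw)


@dataclass
class RunReport:
    """Paths and tables produced by one run."""

    out_dir: Path
    activity: pd.DataFrame       # one row per group
    metrics: pd.DataFrame        # one row per group
    manifest: dict


def _analyse_one(
    label: str,
    cell_map: CellMap | None,
    traces: TraceMatrix,
    config: RunConfig,
    out: Path,
) -> tuple[dict, dict]:
    out.mkdir(parents=True, exist_ok=True)
    cio.write_trace_matrix(traces, out / "traces.csv")
    if cell_map is not None:
        cio.write_cell_map(cell_map, out / "cells.csv")

    log.info("[%s] preprocessing (%d cells, %d frames)", label,
             traces.n_cells, traces.values.shape[1])
    fluct = preprocess(
        traces, config.baseline_window_s, config.baseline_percentile
    )
    cio.write_trace_matrix(fluct, out / "fluctuations.csv")

    events = detect_events(
        fluct, k_mad=config.k_mad, min_duration_s=config.min_duration_s,
        offset_fraction=config.offset_fraction,
    )
    cio.write_events(events, out / "events.tsv")
    summary = summarize_activity(
        events, traces.n_cells, traces.recording_length_s
    )
    cio.write_key_values(summary.to_dict(), out / "activity.txt")

    metrics_row: dict = {}
    if cell_map is not None:
        corr = pairwise_correlation(fluct)
        lags = lag_matrix(fluct, max_lag_s=config.max_lag_s)
        cio.write_matrix(corr, cell_map.cell_ids, out / "correlation.csv")
        cio.write_matrix(lags, cell_map.cell_ids, out / "lags.csv")
        net = build_network(
            corr, lags, cell_map, threshold=config.threshold,
            contact_margin_um=config.contact_margin_um,
        )
        cio.write_edge_list(net, out / "edges.tsv")
        cio.write_graphml(net, out / "network.graphml")
        scatter = correlation_vs_distance(
            corr, cell_map, config.contact_margin_um
        )
        scatter.to_csv(out / "correlation_vs_distance.tsv", sep="\t", index=False)
        m = network_metrics(
            net, corr, cell_map,
            contact_margin_um=config.contact_margin_um,
            min_abs_lag_s=config.min_abs_lag_s,
        )
        metrics_row = m.to_dict()
        cio.write_key_values(metrics_row, out / "network_metrics.txt")
    return summary.to_dict(), metrics_row


def run(config: RunConfig) -> RunReport:
    """Execute the configured pipeline; idempotent for fixed seed+config."""
    config.validate()
    out_root = Path(config.out_dir)
    out_root.mkdir(parents=True, exist_ok=True)

    jobs: list[tuple[str, SimConfig | None]] = []
    if config.sim is not None:
        if config.groups:
            for label, preset in config.groups.items():
                jobs.append((label, apply_preset(config.sim, preset)))
        else:
            jobs.append(("run", config.sim))
    else:
        jobs.append(("run", None))

    activity_rows, metric_rows = [], []
    for k, (label, sim_cfg) in enumerate(jobs):
        try:
            if sim_cfg is not None:
                sim_cfg = sim_cfg.replace(seed=config.seed + k)
                cell_map, truth, traces = simulate(sim_cfg)
                (out_root / label).mkdir(parents=True, exist_ok=True)
                cio.write_ground_truth(
                    truth, out_root / label / "ground_truth.json"
                )
            else:
                traces = cio.read_trace_matrix(config.traces_path)
                cell_map = (
                    cio.read_cell_map(config.cells_path)
                    if config.cells_path else None
                )
            act, met = _analyse_one(
                label, cell_map, traces, config, out_root / label
            )
        except Exception as exc:
            raise RuntimeError(
                f"pipeline stage failed for group {label!r}: {exc}"
            ) from exc
        activity_rows.append({"group": label, **act})
        metric_rows.append({"group": label, **met})

    activity = pd.DataFrame(activity_rows)
    metrics = pd.DataFrame(metric_rows)
    activity.to_csv(out_root / "activity_by_group.tsv", sep="\t", index=False)
    metrics.to_csv(out_root / "metrics_by_group.tsv", sep="\t", index=False)

    manifest = {
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "groups": [label for label, _ in jobs],
        "artifacts": sorted(
            str(p.relative_to(out_root)) for p in out_root.rglob("*") if p.is_file()
        ),
    }
    (out_root / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return RunReport(out_root, activity, metrics, manifest)


# ---------------------------------------------------------------------------
# figures
# ---------------------------------------------------------------------------

def render_report(out_dir) -> list[Path]:
    """Render figures from the saved run artifacts (never from memory):
    correlation-vs-distance scatter, network graph, and the four-measure
    panel across groups.  Deterministic given fixed inputs."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out_root = Path(out_dir)
    manifest = json.loads((out_root / "manifest.json").read_text())
    figures: list[Path] = []

    for label in manifest["groups"]:
        gdir = out_root / label
        scatter_path = gdir / "correlation_vs_distance.tsv"
        if scatter_path.exists():
            df = pd.read_csv(scatter_path, sep="\t")
            fig, ax = plt.subplots(figsize=(5, 4))
            for cls, color in [("neighboring", "red"), ("distant", "blue")]:
                sub = df[df["adjacency"] == cls]
                ax.scatter(sub["distance_um"], sub["rho"], s=12, c=color,
                           label=cls, alpha=0.7)
            ax.set_xlabel("inter-soma distance (um)")
            ax.set_ylabel("correlation")
            ax.set_title(f"{label}: correlation vs distance")
            ax.legend(frameon=False)
            fig.tight_layout()
            p = gdir / "correlation_vs_distance.png"
            fig.savefig(p, dpi=120)
            plt.close(fig)
            figures.append(p)

        cells_path = gdir / "cells.csv"
        edges_path = gdir / "edges.tsv"
        if cells_path.exists() and edges_path.exists():
            cells = pd.read_csv(cells_path)
            edges = pd.read_csv(edges_path, sep="\t")
            pos = {int(r.cell_id): (r.x_um, r.y_um) for r in cells.itertuples()}
            fig, ax = plt.subplots(figsize=(5, 5))
            for r in edges.itertuples():
                x0, y0 = pos[int(r.cell_i)]
                x1, y1 = pos[int(r.cell_j)]
                ax.plot([x0, x1], [y0, y1], "-", color="gray", lw=0.8, zorder=1)
            ax.scatter(cells["x_um"], cells["y_um"], s=30, c="tab:green", zorder=2)
            ax.set_aspect("equal")
            ax.set_xlabel("x (um)")
            ax.set_ylabel("y (um)")
            ax.set_title(f"{label}: functional network (rho > threshold)")
            fig.tight_layout()
            p = gdir / "network_graph.png"
            fig.savefig(p, dpi=120)
            plt.close(fig)
            figures.append(p)

    metrics_path = out_root / "metrics_by_group.tsv"
    metrics = pd.read_csv(metrics_path, sep="\t")
    if len(metrics) and "mean_adjacent_correlation" in metrics:
        panels = [
            ("mean_adjacent_correlation", "mean adjacent-cell correlation"),
            ("mean_propagation_speed_um_s", "propagation speed (um/s)"),
            ("mean_connections_per_cell", "connections per cell"),
            ("pct_correlated_connections", "% correlated connections"),
        ]
        fig, axes = plt.subplots(2, 2, figsize=(8, 6))
        for ax, (col, title) in zip(axes.ravel(), panels):
            ax.bar(metrics["group"], metrics[col], color="tab:blue")
            ax.set_title(title, fontsize=9)
            ax.tick_params(axis="x", rotation=30, labelsize=8)
        fig.tight_layout()
        p = out_root / "metrics_panel.png"
        fig.savefig(p, dpi=120)
        plt.close(fig)
        figures.append(p)
    return figures
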