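"""Readers and writers for the delimited-text artifact schemas.

All artifacts are plain text: cell maps and trace matrices as CSV, event
tables and edge lists as TSV, ground truth as JSON, networks additionally
as GraphML, metric panels as key=value files, image stacks as multi-frame
TIFF.
"""

from __future__ import annotations

import json
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .synthetic import CellMap, GroundTruth
from .traces import TraceMatrix

__all__ = [
    "write_cell_map", "read_cell_map",
    "write_trace_matrix", "read_trace_matrix",
    "write_ground_truth", "read_ground_truth",
    "write_events", "read_events",
    "write_matrix", "read_matrix",
    "write_edge_list", "write_graphml",
    "write_key_values", "read_key_values",
    "write_stack", "read_stack",
]


def write_cell_map(cell_map: CellMap, path) -> None:
    pd.DataFrame(
        {
            "cell_id": cell_map.cell_ids,
            "x_um": cell_map.x_um,
            "y_um": cell_map.y_um,
            "radius_um": cell_map.radius_um,
        }
    ).to_csv(path, index=False)


def read_cell_map(path) -> CellMap:
    df = pd.read_csv(path)
    return CellMap(
        cell_ids=df["cell_id"].to_numpy(int),
        x_um=df["x_um"].to_numpy(float),
        y_um=df["y_um"].to_numpy(float),
        radius_um=df["radius_um"].to_numpy(float),
    )


def write_trace_matrix(tm: TraceMatrix, path) -> None:
    """First column cell_id, then one column per frame; the header row
    carries frame times in seconds."""
    cols = [f"{t:.6f}" for t in tm.times_s]
    df = pd.DataFrame(tm.values, columns=cols)
    df.insert(0, "cell_id", tm.cell_ids)
    df.to_csv(path, index=False)


def read_trace_matrix(path) -> TraceMatrix:
    df = pd.read_csv(path)
    times = np.array([float(c) for c in df.columns[1:]])
    return TraceMatrix(
        cell_ids=df["cell_id"].to_numpy(int),
        times_s=times,
        values=df.iloc[:, 1:].to_numpy(float),
    )


def write_ground_truth(gt: GroundTruth, path) -> None:
    payload = {
        "wave_speed_um_s": gt.wave_speed_um_s,
        "active_fraction": gt.active_fraction,
        "seed": gt.seed,
        "active_cells": [int(c) for c in gt.active_cells],
        "true_edges": sorted([int(i), int(j)] for i, j in gt.true_edges),
        "event_trains": {
            str(c): np.asarray(tr).tolist() for c, tr in gt.event_trains.items()
        },
        "initiations": np.asarray(gt.initiations).tolist(),
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_ground_truth(path) -> GroundTruth:
    payload = json.loads(Path(path).read_text())
    return GroundTruth(
        true_edges={(int(i), int(j)) for i, j in payload["true_edges"]},
        event_trains={
            int(c): np.asarray(tr).reshape(-1, 3)
            for c, tr in payload["event_trains"].items()
        },
        wave_speed_um_s=payload["wave_speed_um_s"],
        active_fraction=payload["active_fraction"],
        seed=payload["seed"],
        active_cells=np.asarray(payload["active_cells"], int),
        initiations=np.asarray(payload["initiations"]).reshape(-1, 2),
    )


def write_events(events: pd.DataFrame, path) -> None:
    events.to_csv(path, sep="\t", index=False)


def read_events(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_matrix(matrix: np.ndarray, cell_ids, path) -> None:
    """Square matrix (correlation or lag) as CSV with cell_id labels."""
    df = pd.DataFrame(matrix, index=cell_ids, columns=cell_ids)
    df.to_csv(path, index_label="cell_id")


def read_matrix(path) -> tuple[np.ndarray, np.ndarray]:
    df = pd.read_csv(path, index_col="cell_id")
    return df.to_numpy(float), df.index.to_numpy(int)


def write_edge_list(net: nx.Graph, path) -> None:
    rows = [
        (u, v, d["rho"], d["tau_s"], d["distance_um"], d["adjacency"])
        for u, v, d in net.edges(data=True)
    ]
    pd.DataFrame(
        rows, columns=["cell_i", "cell_j", "rho", "tau_s", "distance_um", "adjacency"]
    ).to_csv(path, sep="\t", index=False)


def write_graphml(net: nx.Graph, path) -> None:
    nx.write_graphml(net, path)


def write_key_values(values: dict, path) -> None:
    with open(path, "w") as fh:
        for k, v in values.items():
            fh.write(f"{k}={v}\n")


def read_key_values(path) -> dict:
    out = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        k, v = line.split("=", 1)
        try:
            out[k] = float(v)
        except ValueError:
            out[k] = v
    return out


def write_stack(stack: np.ndarray, path) -> None:
    import tifffile

    tifffile.imwrite(
        path, np.asarray(stack, dtype=np.float32), photometric="minisblack"
    )


def read_stack(path) -> np.ndarray:
    import tifffile

    return tifffile.imread(path)
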