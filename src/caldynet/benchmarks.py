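"""Frozen synthetic study scenarios and recovery measurements.

Each scenario fixes one question about the pipeline:

* :func:`edge_recovery` — can the correlation threshold recover the
  ground-truth functional network (precision/recall)?
* :func:`dynamics_recovery` — are the programmed activity statistics
  (active %, oscillation frequency, mean duration) recovered by event
  detection?
* :func:`wave_speed_recovery` — is the programmed wave speed recovered
  by cross-correlation delays on a chain culture?
* :func:`mann_whitney_type_i` — is the Mann-Whitney wrapper calibrated
  (type-I error at nominal alpha)?
* :func:`preset_contrast` — do the damaged-condition presets come out
  below the intact preset in activity and connectivity?

The scenario parameters are part of the package's experimental design
and are deliberately not exposed as knobs.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .network import (
    DEFAULT_THRESHOLD,
    build_network,
    lag_matrix,
    network_metrics,
    pairwise_correlation,
    propagation_speed,
)
from .synthetic import (
    CellMap,
    SimConfig,
    apply_preset,
    generate_event_trains,
    render_traces,
    simulate,
)
from .traces import detect_events, preprocess, summarize_activity

__all__ = [
    "network_recovery_config",
    "dynamics_config",
    "edge_recovery",
    "dynamics_recovery",
    "wave_speed_recovery",
    "mann_whitney_type_i",
    "preset_contrast",
]


def network_recovery_config(seed: int) -> SimConfig:
    """Well-connected fully active culture with strong shared events.

    All events have amplitude >= 5x the noise sd; propagated transients
    attenuate per hop (0.6), which keeps directly coupled pairs clearly
    above the 0.3 correlation cutoff while second-order (common
    neighbour) pairs stay below it.
    """
    return SimConfig(
        n_cells=20,
        field_width_um=450.0,
        field_height_um=450.0,
        conn_decay_um=50.0,
        conn_base_prob=0.9,
        active_fraction=1.0,
        event_rate_per_min=0.6,
        duration_s=1800.0,
        wave_speed_um_s=100.0,
        propagation_attenuation=0.6,
        amplitude_dff=0.85,
        noise_sd_dff=0.1,
        seed=seed,
    )


def dynamics_config(seed: int) -> SimConfig:
    """Sparser activity for event-statistics recovery (SNR 5)."""
    return SimConfig(
        n_cells=20,
        field_width_um=450.0,
        field_height_um=450.0,
        conn_decay_um=50.0,
        conn_base_prob=0.9,
        active_fraction=0.6,
        event_rate_per_min=0.15,
        duration_s=900.0,
        wave_speed_um_s=40.0,
        amplitude_dff=0.5,
        noise_sd_dff=0.1,
        seed=seed,
    )


def edge_recovery(
    seeds: range | list[int], threshold: float = DEFAULT_THRESHOLD
) -> dict[str, float]:
    """Pooled precision/recall of recovered edges vs ground truth."""
    tp = fp = fn = 0
    for seed in seeds:
        cfg = network_recovery_config(int(seed))
        cell_map, truth, traces = simulate(cfg)
        fluct = preprocess(traces)
        corr = pairwise_correlation(fluct)
        n = len(cell_map)
        recovered = set()
        for a in range(n):
            for b in range(a + 1, n):
                if np.isfinite(corr[a, b]) and corr[a, b] > threshold:
                    i = int(cell_map.cell_ids[a])
                    j = int(cell_map.cell_ids[b])
                    recovered.add((i, j) if i < j else (j, i))
        tp += len(recovered & truth.true_edges)
        fp += len(recovered - truth.true_edges)
        fn += len(truth.true_edges - recovered)
    return {
        "precision": tp / (tp + fp) if tp + fp else float("nan"),
        "recall": tp / (tp + fn) if tp + fn else float("nan"),
        "n_true_edges": tp + fn,
        "n_recovered_edges": tp + fp,
    }


def dynamics_recovery(seeds: range | list[int]) -> dict[str, float]:
    """Detected vs programmed activity statistics, averaged over seeds.

    The reference values come from the ground-truth event trains (which
    include propagated events), so the comparison isolates detection
    error from simulation stochasticity.
    """
    det = {"active_cells_pct": [], "frequency_per_min": [], "mean_duration_s": []}
    tru = {k: [] for k in det}
    for seed in seeds:
        cfg = dynamics_config(int(seed))
        cell_map, truth, traces = simulate(cfg)
        fluct = preprocess(traces)
        events = detect_events(fluct)
        summary = summarize_activity(events, len(cell_map), cfg.duration_s)
        truth_stats = truth.activity_stats(cfg.duration_s)
        for key in det:
            det[key].append(getattr(summary, key))
            tru[key].append(truth_stats[key])
    out: dict[str, float] = {}
    for key in det:
        d = float(np.nanmean(det[key]))
        t = float(np.nanmean(tru[key]))
        out[f"detected_{key}"] = d
        out[f"true_{key}"] = t
        out[f"rel_err_{key}"] = abs(d - t) / t
    return out


def _chain_culture(
    n_cells: int, spacing_um: float, jitter_um: float, rng: np.random.Generator
) -> tuple[CellMap, set[tuple[int, int]]]:
    """Quasi-linear culture wired as a nearest-neighbour chain — the
    canonical geometry for a travelling calcium wave."""
    x = spacing_um * np.arange(n_cells) + rng.uniform(
        -jitter_um, jitter_um, n_cells
    )
    y = 20.0 + rng.uniform(-jitter_um, jitter_um, n_cells)
    cell_map = CellMap(
        cell_ids=np.arange(n_cells),
        x_um=x - x.min() + 10.0,
        y_um=y,
        radius_um=np.full(n_cells, 5.0),
    )
    edges = {(i, i + 1) for i in range(n_cells - 1)}
    return cell_map, edges


def wave_speed_recovery(
    seeds: range | list[int], wave_speed_um_s: float = 40.0
) -> dict[str, float]:
    """Recover a programmed wave speed on chain cultures.

    A pacemaker cell at one end initiates every event; the wave
    propagates down the chain at ``wave_speed_um_s``.  The estimate is
    the propagation-speed measure of the reconstructed network (mean of
    distance / |cross-correlation delay| over supra-threshold pairs).
    """
    estimates = []
    for seed in seeds:
        cfg = SimConfig(
            n_cells=15,
            field_width_um=600.0,
            field_height_um=40.0,
            active_fraction=1.0,
            event_rate_per_min=0.6,
            duration_s=600.0,
            wave_speed_um_s=wave_speed_um_s,
            max_hops=None,
            n_pacemakers=1,
            pacemaker_mode="edge",
            amplitude_dff=0.5,
            noise_sd_dff=0.02,
            seed=int(seed),
        )
        rng = np.random.default_rng(int(seed))
        cell_map, edges = _chain_culture(cfg.n_cells, 40.0, 5.0, rng)
        truth = generate_event_trains(edges, cell_map, cfg, rng=rng)
        traces = render_traces(truth, cfg, rng=rng)
        fluct = preprocess(traces)
        corr = pairwise_correlation(fluct)
        lags = lag_matrix(fluct, max_lag_s=10.0)
        net = build_network(corr, lags, cell_map)
        speed, _ = propagation_speed(net)
        estimates.append(speed)
    est = float(np.nanmean(estimates))
    return {
        "wave_speed_estimate_um_s": est,
        "wave_speed_true_um_s": wave_speed_um_s,
        "rel_err": abs(est - wave_speed_um_s) / wave_speed_um_s,
    }


def mann_whitney_type_i(
    n_sim: int = 2000, n_per_group: int = 10, seed: int = 0,
    alpha: float = 0.05,
) -> float:
    """Empirical type-I error of the two-sided Mann-Whitney comparison
    at nominal *alpha*, under the null of identical normal populations."""
    rng = np.random.default_rng(seed)
    rejections = 0
    for _ in range(n_sim):
        a = rng.normal(size=n_per_group)
        b = rng.normal(size=n_per_group)
        p = stats.mannwhitneyu(a, b, alternative="two-sided").pvalue
        if p < alpha:
            rejections += 1
    return rejections / n_sim


def preset_contrast(
    n_seeds: int = 10, presets: tuple[str, ...] = ("intact", "gd", "hypoxia"),
    base_seed: int = 0,
) -> pd.DataFrame:
    """Run the full pipeline under each condition preset and tabulate
    per-seed activity and connectivity summaries."""
    rows = []
    for k in range(n_seeds):
        for preset in presets:
            cfg = apply_preset(SimConfig(seed=base_seed + k), preset)
            cell_map, truth, traces = simulate(cfg)
            fluct = preprocess(traces)
            events = detect_events(fluct)
            summary = summarize_activity(events, len(cell_map), cfg.duration_s)
            corr = pairwise_correlation(fluct)
            lags = lag_matrix(fluct, max_lag_s=10.0)
            net = build_network(corr, lags, cell_map)
            metrics = network_metrics(net, corr, cell_map)
            iu = np.triu_indices(len(cell_map), k=1)
            rows.append(
                {
                    "preset": preset,
                    "seed": base_seed + k,
                    "active_cells_pct": summary.active_cells_pct,
                    "frequency_per_min": summary.frequency_per_min,
                    "mean_duration_s": summary.mean_duration_s,
                    "correlation_mean": float(np.nanmean(corr[iu])),
                    "correlation_median": metrics.correlation_median,
                    "mean_connections_per_cell": metrics.mean_connections_per_cell,
                    "pct_correlated_connections": metrics.pct_correlated_connections,
                }
            )
    return pd.DataFrame(rows)
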