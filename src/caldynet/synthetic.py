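"""Synthetic calcium-activity generator.

Forward model for a cultured neuron-glial network imaged with a
calcium-sensitive dye: somas placed in a 2-D field of view, a
distance-decaying ground-truth functional network, network calcium events
initiated as a Poisson process and propagated along true edges with
finite wave speed, and fluorescence traces rendered with realistic
transient kinetics, baseline drift and shot-like Gaussian noise.

Every generator is driven by :class:`SimConfig` and a single integer
seed, and is bit-reproducible for a fixed seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import networkx as nx
import numpy as np

__all__ = [
    "SimConfig",
    "CellMap",
    "GroundTruth",
    "CONDITION_PRESETS",
    "apply_preset",
    "generate_cell_map",
    "generate_true_network",
    "generate_event_trains",
    "render_traces",
    "render_stack",
    "simulate",
]


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SimConfig:
    """Parameters of one simulated recording.

    Geometry is in micrometres, time in seconds.  ``event_rate_per_min`` is
    the *initiation* rate per initiator cell; because events propagate to
    network neighbours, the per-cell rate observed in the rendered traces
    is higher in well-connected cultures.
    """

    n_cells: int = 50
    field_width_um: float = 450.0
    field_height_um: float = 450.0
    soma_radius_um: float = 5.0
    duration_s: float = 600.0
    sampling_rate_hz: float = 2.0          # confocal time series at 2 frames/s

    # ground-truth connectivity: P(edge) = base_prob * exp(-d / decay)
    conn_decay_um: float = 50.0
    conn_base_prob: float = 0.6

    # event statistics
    active_fraction: float = 0.61
    event_rate_per_min: float = 0.40
    event_duration_mean_s: float = 12.0
    event_duration_sd_s: float = 3.0

    # wave propagation
    wave_speed_um_s: float = 40.0
    max_hops: int | None = 1
    transmission_prob: float = 1.0
    propagation_attenuation: float = 1.0   # amplitude factor per hop
    n_pacemakers: int | None = None        # None: every active cell initiates
    pacemaker_mode: str = "random"         # "random" | "edge" (lowest x)

    # fluorescence rendering
    rise_tau_s: float = 0.5
    decay_tau_s: float = 3.0
    amplitude_dff: float = 0.5             # transient peak as dF/F0
    baseline: float = 100.0                # arbitrary fluorescence units
    noise_sd_dff: float = 0.1              # Gaussian noise sd as dF/F0
    drift_per_min: float = 0.005           # fractional baseline drift / min

    preset: str | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sampling_rate_hz <= 0:
            raise ValueError("sampling_rate_hz must be > 0")
        if self.duration_s < 10 * self.event_duration_mean_s:
            raise ValueError(
                "duration_s must be at least 10x the mean event duration"
            )
        if self.noise_sd_dff < 0:
            raise ValueError("noise_sd_dff must be >= 0")
        if not 0.0 <= self.active_fraction <= 1.0:
            raise ValueError("active_fraction must lie in [0, 1]")

    @property
    def n_frames(self) -> int:
        return int(round(self.duration_s * self.sampling_rate_hz))

    def replace(self, **kw) -> "SimConfig":
        return dataclasses.replace(self, **kw)


#: Condition presets mirror the *ordering* of the experimental groups
#: (intact culture, glucose deprivation, acute hypoxia): damaged cultures
#: have a lower active fraction and a lower event-initiation rate.  The
#: active fractions follow the reported group means; initiation rates are
#: scaled proportionally to the reported per-cell oscillation frequencies.
CONDITION_PRESETS: dict[str, dict[str, float]] = {
    "intact": {
        "active_fraction": 0.61,
        "event_rate_per_min": 0.40,
        "event_duration_mean_s": 11.8,
    },
    "gd": {
        "active_fraction": 0.47,
        "event_rate_per_min": 0.29,
        "event_duration_mean_s": 11.8,
    },
    "hypoxia": {
        "active_fraction": 0.36,
        "event_rate_per_min": 0.13,
        "event_duration_mean_s": 12.0,
    },
}


def apply_preset(config: SimConfig, preset: str) -> SimConfig:
    """Return a copy of *config* with the named condition preset applied."""
    try:
        overrides = CONDITION_PRESETS[preset]
    except KeyError:
        raise ValueError(
            f"unknown preset {preset!r}; available: {sorted(CONDITION_PRESETS)}"
        ) from None
    return config.replace(preset=preset, **overrides)


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CellMap:
    """Soma centroids and radii in the field of view (micrometres)."""

    cell_ids: np.ndarray          # (n,) int
    x_um: np.ndarray              # (n,) float
    y_um: np.ndarray              # (n,) float
    radius_um: np.ndarray         # (n,) float

    def __post_init__(self) -> None:
        n = len(self.cell_ids)
        if len(np.unique(self.cell_ids)) != n:
            raise ValueError("cell_ids must be unique")
        if not (len(self.x_um) == len(self.y_um) == len(self.radius_um) == n):
            raise ValueError("coordinate arrays must match cell_ids length")
        if np.any(self.radius_um <= 0):
            raise ValueError("soma radii must be positive")

    def __len__(self) -> int:
        return len(self.cell_ids)

    def distance_matrix(self) -> np.ndarray:
        """Pairwise Euclidean centroid distances (n x n, micrometres)."""
        dx = self.x_um[:, None] - self.x_um[None, :]
        dy = self.y_um[:, None] - self.y_um[None, :]
        return np.hypot(dx, dy)

    def index_of(self, cell_id: int) -> int:
        idx = np.flatnonzero(self.cell_ids == cell_id)
        if idx.size == 0:
            raise KeyError(f"unknown cell_id {cell_id}")
        return int(idx[0])


@dataclass
class GroundTruth:
    """Simulator-side truth used by recovery tests.

    ``event_trains`` maps cell_id to an (n_events, 3) array with columns
    onset (s), duration (s), amplitude (dF/F0); overlapping deliveries to
    one cell are merged into a single oscillation, so trains are
    time-ordered and non-overlapping.
    """

    true_edges: set[tuple[int, int]]
    event_trains: dict[int, np.ndarray]
    wave_speed_um_s: float
    active_fraction: float
    seed: int
    active_cells: np.ndarray = field(default_factory=lambda: np.array([], int))
    initiations: np.ndarray = field(
        default_factory=lambda: np.empty((0, 2))
    )  # rows: (time_s, initiator_cell_id)

    def n_events(self, cell_id: int) -> int:
        return len(self.event_trains.get(cell_id, ()))

    def activity_stats(self, recording_length_s: float) -> dict[str, float]:
        """True active %, per-active-cell frequency (osc/min) and mean
        duration (s), computed directly from the truth trains."""
        n_cells = len(self.event_trains)
        counts = {c: len(tr) for c, tr in self.event_trains.items()}
        active = [c for c, k in counts.items() if k > 0]
        durations = np.concatenate(
            [self.event_trains[c][:, 1] for c in active]
        ) if active else np.array([])
        minutes = recording_length_s / 60.0
        return {
            "active_cells_pct": 100.0 * len(active) / n_cells if n_cells else np.nan,
            "frequency_per_min": (
                float(np.mean([counts[c] for c in active]) / minutes)
                if active else np.nan
            ),
            "mean_duration_s": float(durations.mean()) if durations.size else np.nan,
        }


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------

def _as_rng(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


def generate_cell_map(config: SimConfig, rng=None) -> CellMap:
    """Place ``n_cells`` non-overlapping somas uniformly at random.

    Somas are sampled by rejection: a candidate centroid is kept only if
    its distance to every accepted soma exceeds the sum of radii.  Raises
    ``RuntimeError`` if the field cannot accommodate the requested count.
    """
    if config.n_cells < 2:
        raise ValueError("n_cells must be >= 2")
    rng = _as_rng(config.seed if rng is None else rng)
    r = config.soma_radius_um
    lo, hi_x = r, config.field_width_um - r
    hi_y = config.field_height_um - r
    if hi_x <= lo or hi_y <= lo:
        raise RuntimeError("field of view too small for the soma radius")

    xs: list[float] = []
    ys: list[float] = []
    max_attempts = 10_000 * config.n_cells
    attempts = 0
    while len(xs) < config.n_cells:
        if attempts >= max_attempts:
            raise RuntimeError(
                f"could not place {config.n_cells} non-overlapping somas "
                f"in a {config.field_width_um}x{config.field_height_um} um field"
            )
        attempts += 1
        x = rng.uniform(lo, hi_x)
        y = rng.uniform(lo, hi_y)
        if xs:
            d = np.hypot(np.asarray(xs) - x, np.asarray(ys) - y)
            if np.any(d <= 2 * r):
                continue
        xs.append(x)
        ys.append(y)

    n = config.n_cells
    return CellMap(
        cell_ids=np.arange(n, dtype=int),
        x_um=np.asarray(xs),
        y_um=np.asarray(ys),
        radius_um=np.full(n, r, dtype=float),
    )


def generate_true_network(
    cell_map: CellMap,
    decay_length_um: float,
    base_prob: float,
    seed_or_rng=0,
) -> set[tuple[int, int]]:
    """Draw a ground-truth undirected network with distance-decaying
    connection probability ``base_prob * exp(-d / decay_length)``.

    Returns unordered pairs as ``(cell_i, cell_j)`` tuples with i < j.
    """
    if not 0.0 <= base_prob <= 1.0:
        raise ValueError("base_prob must lie in [0, 1]")
    if decay_length_um <= 0:
        raise ValueError("decay_length_um must be > 0")
    rng = _as_rng(seed_or_rng)
    ids = cell_map.cell_ids
    dist = cell_map.distance_matrix()
    edges: set[tuple[int, int]] = set()
    n = len(ids)
    for a in range(n):
        for b in range(a + 1, n):
            p = base_prob * np.exp(-dist[a, b] / decay_length_um)
            if rng.random() < p:
                i, j = int(ids[a]), int(ids[b])
                edges.add((i, j) if i < j else (j, i))
    return edges


def _truth_graph(cell_map: CellMap, edges: Iterable[tuple[int, int]]) -> nx.Graph:
    g = nx.Graph()
    g.add_nodes_from(int(c) for c in cell_map.cell_ids)
    dist = cell_map.distance_matrix()
    for i, j in edges:
        a, b = cell_map.index_of(i), cell_map.index_of(j)
        g.add_edge(i, j, length=float(dist[a, b]))
    return g


def _merge_train(events: list[tuple[float, float, float]]) -> np.ndarray:
    """Sort events and merge overlapping ones into single oscillations."""
    if not events:
        return np.empty((0, 3))
    events = sorted(events)
    merged: list[list[float]] = [list(events[0])]
    for onset, dur, amp in events[1:]:
        cur = merged[-1]
        if onset < cur[0] + cur[1]:           # overlaps the running event
            cur[1] = max(cur[1], onset + dur - cur[0])
            cur[2] = max(cur[2], amp)
        else:
            merged.append([onset, dur, amp])
    return np.asarray(merged)


def generate_event_trains(
    true_edges: set[tuple[int, int]],
    cell_map: CellMap,
    config: SimConfig,
    rng=None,
) -> GroundTruth:
    """Simulate network calcium events and their propagation.

    A subset of exactly ``round(active_fraction * n_cells)`` cells is
    active; inactive cells receive no events.  Initiator cells fire as
    independent Poisson processes at ``event_rate_per_min``; each event
    propagates along ground-truth edges (shortest path by physical edge
    length) with per-hop delay = edge length / wave speed, optionally
    limited to ``max_hops`` hops and thinned per hop by
    ``transmission_prob``.
    """
    if config.event_rate_per_min <= 0:
        raise ValueError("event_rate_per_min must be > 0")
    if config.wave_speed_um_s <= 0:
        raise ValueError("wave_speed_um_s must be > 0")
    if not 0.0 <= config.active_fraction <= 1.0:
        raise ValueError("active_fraction must lie in [0, 1]")
    rng = _as_rng(config.seed if rng is None else rng)

    ids = [int(c) for c in cell_map.cell_ids]
    n = len(ids)
    n_active = int(round(config.active_fraction * n))
    active = sorted(rng.choice(ids, size=n_active, replace=False).tolist())
    active_set = set(active)

    trains: dict[int, list[tuple[float, float, float]]] = {c: [] for c in ids}
    initiations: list[tuple[float, int]] = []

    if n_active > 0:
        graph = _truth_graph(cell_map, true_edges)
        if config.n_pacemakers is not None:
            k = min(config.n_pacemakers, n_active)
            if config.pacemaker_mode == "edge":
                # wave enters from one side: lowest-x active cells of the
                # giant component initiate, so the wave can actually spread
                giant = max(nx.connected_components(graph), key=len)
                pool = sorted(active_set & giant) or active
                xs = {c: cell_map.x_um[cell_map.index_of(c)] for c in pool}
                initiators = sorted(pool, key=xs.get)[: min(k, len(pool))]
            else:
                initiators = sorted(
                    rng.choice(active, size=k, replace=False).tolist()
                )
        else:
            initiators = active
        rate_hz = config.event_rate_per_min / 60.0
        n_events = rng.poisson(rate_hz * config.duration_s * len(initiators))
        times = np.sort(rng.uniform(0.0, config.duration_s, size=n_events))
        sources = rng.choice(initiators, size=n_events) if n_events else []

        for t0, src in zip(times, sources):
            src = int(src)
            initiations.append((float(t0), src))
            duration = float(
                np.clip(
                    rng.normal(config.event_duration_mean_s,
                               config.event_duration_sd_s),
                    2.0 / config.sampling_rate_hz,
                    None,
                )
            )
            amp = config.amplitude_dff
            if config.transmission_prob < 1.0:
                # percolate: each edge relays this event independently
                g_ev = nx.Graph()
                g_ev.add_nodes_from(graph.nodes)
                for u, v, d in graph.edges(data=True):
                    if rng.random() < config.transmission_prob:
                        g_ev.add_edge(u, v, length=d["length"])
            else:
                g_ev = graph
            delays = _propagation_delays(
                g_ev, src, config.wave_speed_um_s, config.max_hops
            )
            for cell, (delay, hops) in delays.items():
                if cell not in active_set:
                    continue
                onset = t0 + delay
                if onset >= config.duration_s:
                    continue
                dur = min(duration, config.duration_s - onset)
                if dur < 1.0 / config.sampling_rate_hz:
                    continue
                trains[cell].append(
                    (onset, dur, amp * config.propagation_attenuation**hops)
                )

    merged = {c: _merge_train(tr) for c, tr in trains.items()}
    return GroundTruth(
        true_edges=set(true_edges),
        event_trains=merged,
        wave_speed_um_s=config.wave_speed_um_s,
        active_fraction=config.active_fraction,
        seed=config.seed,
        active_cells=np.asarray(active, dtype=int),
        initiations=np.asarray(initiations) if initiations else np.empty((0, 2)),
    )


def _propagation_delays(
    graph: nx.Graph, source: int, wave_speed: float, max_hops: int | None
) -> dict[int, tuple[float, int]]:
    """Map cell -> (delay s, hop count) from *source* along shortest
    physical paths, delay additive per hop; hop count optionally bounded."""
    if max_hops is not None:
        reachable = nx.single_source_shortest_path_length(
            graph, source, cutoff=max_hops
        )
        sub = graph.subgraph(reachable.keys())
    else:
        sub = graph
    lengths, paths = nx.single_source_dijkstra(sub, source, weight="length")
    return {
        int(c): (d / wave_speed, len(paths[c]) - 1) for c, d in lengths.items()
    }


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def _transient(t: np.ndarray, onset: float, duration: float, peak: float,
               rise_tau: float, decay_tau: float) -> np.ndarray:
    """Fluorescence transient: saturating-exponential rise toward *peak*
    during the event plateau, exponential decay after offset."""
    out = np.zeros_like(t)
    offset = onset + duration
    rising = (t >= onset) & (t < offset)
    out[rising] = peak * (1.0 - np.exp(-(t[rising] - onset) / rise_tau))
    level_at_offset = peak * (1.0 - np.exp(-duration / rise_tau))
    decaying = t >= offset
    out[decaying] = level_at_offset * np.exp(-(t[decaying] - offset) / decay_tau)
    return out


def render_traces(
    ground_truth: GroundTruth, config: SimConfig, rng=None
):
    """Render fluorescence traces: baseline + linear drift + transients +
    i.i.d. Gaussian noise.  Returns a :class:`caldynet.traces.TraceMatrix`."""
    from .traces import TraceMatrix

    rng = _as_rng(config.seed + 1 if rng is None else rng)
    cell_ids = np.asarray(sorted(ground_truth.event_trains), dtype=int)
    n_frames = config.n_frames
    t = np.arange(n_frames) / config.sampling_rate_hz

    values = np.empty((len(cell_ids), n_frames))
    drift = config.baseline * config.drift_per_min * (t / 60.0)
    for row, cell in enumerate(cell_ids):
        trace = config.baseline + drift.copy()
        for onset, dur, amp in ground_truth.event_trains[int(cell)]:
            if onset > config.duration_s:
                raise ValueError("event train extends beyond recording length")
            trace += config.baseline * _transient(
                t, onset, dur, amp, config.rise_tau_s, config.decay_tau_s
            )
        values[row] = trace
    if config.noise_sd_dff > 0:
        values += rng.normal(
            0.0, config.noise_sd_dff * config.baseline, size=values.shape
        )
    return TraceMatrix(cell_ids=cell_ids, times_s=t, values=values)


def render_stack(
    traces, cell_map: CellMap, pixel_size_um: float = 1.0,
    background: float = 0.0,
) -> np.ndarray:
    """Rasterize traces into a (frames, H, W) grayscale stack: each soma
    is a uniform disk whose intensity tracks the cell's trace."""
    from skimage.draw import disk as draw_disk

    if len(cell_map) == 0:
        raise ValueError("cell_map is empty")
    if len(cell_map) != len(traces.cell_ids):
        raise ValueError("traces and cell_map are inconsistent")

    # infer field extent from the map (cells were placed within the field)
    width = int(np.ceil((cell_map.x_um + cell_map.radius_um).max() / pixel_size_um)) + 1
    height = int(np.ceil((cell_map.y_um + cell_map.radius_um).max() / pixel_size_um)) + 1
    masks = []
    for k in range(len(cell_map)):
        rr, cc = draw_disk(
            (cell_map.y_um[k] / pixel_size_um, cell_map.x_um[k] / pixel_size_um),
            cell_map.radius_um[k] / pixel_size_um,
            shape=(height, width),
        )
        r_px = cell_map.radius_um[k] / pixel_size_um
        expected = np.pi * r_px**2
        if rr.size < 0.5 * expected:
            raise ValueError(
                f"soma {int(cell_map.cell_ids[k])} falls outside image bounds"
            )
        masks.append((rr, cc))

    order = {int(c): i for i, c in enumerate(traces.cell_ids)}
    n_frames = traces.values.shape[1]
    stack = np.full((n_frames, height, width), background, dtype=np.float32)
    for k, (rr, cc) in enumerate(masks):
        row = order[int(cell_map.cell_ids[k])]
        stack[:, rr, cc] = traces.values[row][:, None]
    return stack


# ---------------------------------------------------------------------------
# one-call convenience
# ---------------------------------------------------------------------------

def simulate(config: SimConfig):
    """Run the full generator: cell map, true network, event trains and
    rendered traces, all derived from ``config.seed``.

    Returns ``(cell_map, ground_truth, trace_matrix)``.
    """
    ss = np.random.SeedSequence(config.seed)
    r_map, r_net, r_ev, r_tr = [np.random.default_rng(s) for s in ss.spawn(4)]
    cell_map = generate_cell_map(config, rng=r_map)
    edges = generate_true_network(
        cell_map, config.conn_decay_um, config.conn_base_prob, r_net
    )
    truth = generate_event_trains(edges, cell_map, config, rng=r_ev)
    traces = render_traces(truth, config, rng=r_tr)
    return cell_map, truth, traces
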