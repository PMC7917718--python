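"""Functional network reconstruction and connectivity metrics.

The network is reconstructed in two steps: pairwise product-moment
correlation of the preprocessed dF/F0 fluctuations, then a hard cutoff
rho > threshold (default 0.3, the upper bound of the correlation level
observed in pure astrocyte cultures) to declare significant functional
connections.  Four measures summarize the network state:

* mean correlation between adjacent (soma-contact) cell pairs,
* mean number of functional connections per cell (mean degree),
* percentage of correlated connections out of all possible pairs,
* mean propagation speed of delays, i.e. the average over connected
  pairs of inter-soma distance / |cross-correlation time delay|.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .synthetic import CellMap
from .traces import TraceMatrix

__all__ = [
    "DEFAULT_THRESHOLD",
    "NetworkMetrics",
    "pairwise_correlation",
    "cross_correlation_delay",
    "lag_matrix",
    "classify_adjacent",
    "build_network",
    "mean_adjacent_correlation",
    "connections_per_cell",
    "pct_correlated_connections",
    "propagation_speed",
    "correlation_vs_distance",
    "network_metrics",
]

#: Correlation cutoff for significant functional connections.
DEFAULT_THRESHOLD = 0.3


@dataclass(frozen=True)
class NetworkMetrics:
    """The four-measure connectivity panel plus distribution summaries.

    ``correlation_median``/quartiles are computed over all defined cell
    pairs; the ``edge_``-prefixed variants restrict to supra-threshold
    pairs (both are reported because summaries of either kind appear in
    the literature).  Undefined quantities are NaN.
    """

    mean_adjacent_correlation: float
    mean_connections_per_cell: float
    pct_correlated_connections: float
    mean_propagation_speed_um_s: float
    n_speed_excluded: int
    adjacent_correlation_median: float
    adjacent_correlation_q1: float
    adjacent_correlation_q3: float
    correlation_median: float
    correlation_q1: float
    correlation_q3: float
    edge_correlation_median: float
    edge_correlation_q1: float
    edge_correlation_q3: float

    def to_dict(self) -> dict:
        return dict(self.__dict__)


# ---------------------------------------------------------------------------
# correlation and lag
# ---------------------------------------------------------------------------

def pairwise_correlation(fluct: TraceMatrix) -> np.ndarray:
    """Product-moment correlation matrix of the fluctuation traces.

    Constant traces have no defined correlation; their rows/columns are
    NaN (excluded downstream).  The diagonal is 1 by convention.
    """
    if fluct.n_cells < 2:
        raise ValueError("need at least 2 cells")
    if fluct.values.shape[1] < 10:
        raise ValueError("need at least 10 frames")
    if not np.all(np.isfinite(fluct.values)):
        raise ValueError("fluctuation matrix contains non-finite values")

    x = fluct.values
    sd = x.std(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(x)
    corr = np.asarray(corr, dtype=float)
    bad = sd == 0
    corr[bad, :] = np.nan
    corr[:, bad] = np.nan
    np.fill_diagonal(corr, 1.0)
    corr = np.clip(corr, -1.0, 1.0)
    # enforce exact symmetry against floating-point asymmetries
    return (corr + corr.T) / 2.0


def cross_correlation_delay(
    x: np.ndarray, y: np.ndarray, sampling_rate_hz: float,
    max_lag_s: float = 10.0, interpolate: bool = True,
) -> float:
    """Cross-correlation time delay tau between two fluctuation traces.

    tau is the lag maximizing the normalized cross-correlation over
    [-max_lag, +max_lag]; tau > 0 means *y* follows *x*.  Ties are broken
    toward the smallest |tau|.  With ``interpolate`` a parabolic fit
    through the peak and its two neighbours refines tau below the frame
    interval (the refinement is zero for a symmetric peak, so exact
    frame shifts stay exact).  NaN for constant traces.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    max_lag = int(round(max_lag_s * sampling_rate_hz))
    if max_lag < 1:
        raise ValueError("max_lag_s must span at least 1 frame")
    if x.std() == 0 or y.std() == 0:
        return float("nan")
    xz = (x - x.mean()) / x.std()
    yz = (y - y.mean()) / y.std()
    n = len(x)
    lags = np.arange(-max_lag, max_lag + 1)
    c = np.empty(len(lags))
    for k, lag in enumerate(lags):
        if lag >= 0:
            c[k] = np.dot(xz[: n - lag], yz[lag:]) / n
        else:
            c[k] = np.dot(xz[-lag:], yz[: n + lag]) / n
    best = c.max()
    candidates = lags[c >= best - 1e-12]
    tau_frames = float(candidates[np.argmin(np.abs(candidates))])
    if interpolate:
        k = int(tau_frames) + max_lag
        if 0 < k < len(lags) - 1:
            denom = c[k - 1] - 2 * c[k] + c[k + 1]
            if denom < -1e-15:
                delta = 0.5 * (c[k - 1] - c[k + 1]) / denom
                tau_frames += float(np.clip(delta, -0.5, 0.5))
    return tau_frames / sampling_rate_hz


def lag_matrix(
    fluct: TraceMatrix, max_lag_s: float = 10.0,
    pairs: list[tuple[int, int]] | None = None,
) -> np.ndarray:
    """Antisymmetric matrix of cross-correlation delays tau_ij (s).

    tau_ij > 0 means cell j follows cell i; tau_ji = -tau_ij.  When
    *pairs* (index pairs) is given only those entries are computed and
    the rest are NaN.
    """
    n = fluct.n_cells
    fs = fluct.sampling_rate_hz
    tau = np.full((n, n), np.nan)
    np.fill_diagonal(tau, 0.0)
    if pairs is None:
        pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    for i, j in pairs:
        t = cross_correlation_delay(
            fluct.values[i], fluct.values[j], fs, max_lag_s
        )
        tau[i, j] = t
        tau[j, i] = -t
    return tau


# ---------------------------------------------------------------------------
# adjacency and network construction
# ---------------------------------------------------------------------------

def classify_adjacent(cell_map: CellMap, contact_margin_um: float = 2.0) -> np.ndarray:
    """Boolean matrix marking neighboring pairs: somas in direct contact,
    i.e. centroid distance <= r_i + r_j + margin.  Diagonal is False."""
    if contact_margin_um < 0:
        raise ValueError("contact_margin_um must be >= 0")
    dist = cell_map.distance_matrix()
    rsum = cell_map.radius_um[:, None] + cell_map.radius_um[None, :]
    adj = dist <= rsum + contact_margin_um
    np.fill_diagonal(adj, False)
    return adj


def build_network(
    corr: np.ndarray,
    lags: np.ndarray,
    cell_map: CellMap,
    threshold: float = DEFAULT_THRESHOLD,
    contact_margin_um: float = 2.0,
) -> nx.Graph:
    """Thresholded functional network.

    An edge joins cells i and j iff rho_ij > threshold (strict, signed);
    each edge carries rho, tau (s), centroid distance (um) and the
    neighboring/distant classification.  NaN correlations (constant
    traces) never form edges.
    """
    n = len(cell_map)
    if corr.shape != (n, n) or lags.shape != (n, n):
        raise ValueError("matrix shapes inconsistent with cell_map")
    dist = cell_map.distance_matrix()
    adjacent = classify_adjacent(cell_map, contact_margin_um)

    g = nx.Graph(threshold=float(threshold))
    for k, cid in enumerate(cell_map.cell_ids):
        g.add_node(
            int(cid),
            x_um=float(cell_map.x_um[k]),
            y_um=float(cell_map.y_um[k]),
            radius_um=float(cell_map.radius_um[k]),
        )
    for a in range(n):
        for b in range(a + 1, n):
            rho = corr[a, b]
            if np.isfinite(rho) and rho > threshold:
                g.add_edge(
                    int(cell_map.cell_ids[a]),
                    int(cell_map.cell_ids[b]),
                    rho=float(rho),
                    tau_s=float(lags[a, b]),
                    distance_um=float(dist[a, b]),
                    adjacency="neighboring" if adjacent[a, b] else "distant",
                )
    return g


# ---------------------------------------------------------------------------
# the four connectivity measures
# ---------------------------------------------------------------------------

def mean_adjacent_correlation(
    corr: np.ndarray, adjacent: np.ndarray
) -> tuple[float, float, float, float]:
    """Mean (and median [Q1; Q3]) correlation over *all* neighboring
    pairs, supra-threshold or not.

    Returns ``(mean, median, q1, q3)``; all NaN when there is no
    neighboring pair with a defined correlation.
    """
    mask = np.triu(adjacent, k=1)
    vals = corr[mask]
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        warnings.warn("no neighboring pairs with defined correlation")
        return (float("nan"),) * 4
    q1, med, q3 = np.percentile(vals, [25, 50, 75])
    return float(vals.mean()), float(med), float(q1), float(q3)


def connections_per_cell(net: nx.Graph) -> float:
    """Mean number of functional connections per cell: 2E / N."""
    n = net.number_of_nodes()
    if n < 1:
        raise ValueError("network has no nodes")
    return 2.0 * net.number_of_edges() / n


def pct_correlated_connections(net: nx.Graph) -> float:
    """Percentage of correlated connections out of all possible pairs:
    100 x E / (N(N-1)/2).  0% means no significant correlative
    interactions; 100% the maximum possible."""
    n = net.number_of_nodes()
    if n < 2:
        raise ValueError("need at least 2 cells")
    return 100.0 * net.number_of_edges() / (n * (n - 1) / 2.0)


def propagation_speed(
    net: nx.Graph, min_abs_lag_s: float = 0.5
) -> tuple[float, int]:
    """Mean propagation speed of delays: average of d_ij / |tau_ij| over
    edges with |tau| >= ``min_abs_lag_s``.

    Pairs with smaller (including zero) delay carry no usable timing
    information and are excluded; the count of excluded edges is
    returned alongside.  NaN when no edge qualifies.
    """
    ratios = []
    excluded = 0
    for _, _, data in net.edges(data=True):
        tau = abs(data["tau_s"])
        if np.isfinite(tau) and tau >= min_abs_lag_s:
            ratios.append(data["distance_um"] / tau)
        else:
            excluded += 1
    if not ratios:
        warnings.warn("no edge with |tau| above min_abs_lag_s; speed undefined")
        return float("nan"), excluded
    return float(np.mean(ratios)), excluded


def correlation_vs_distance(
    corr: np.ndarray, cell_map: CellMap, contact_margin_um: float = 2.0
) -> pd.DataFrame:
    """One row per unordered cell pair: distance, correlation and the
    neighboring/distant classification (the scatter decomposition)."""
    n = len(cell_map)
    if corr.shape != (n, n):
        raise ValueError("corr shape inconsistent with cell_map")
    dist = cell_map.distance_matrix()
    adjacent = classify_adjacent(cell_map, contact_margin_um)
    rows = []
    for a in range(n):
        for b in range(a + 1, n):
            rows.append(
                (
                    int(cell_map.cell_ids[a]),
                    int(cell_map.cell_ids[b]),
                    float(dist[a, b]),
                    float(corr[a, b]),
                    "neighboring" if adjacent[a, b] else "distant",
                )
            )
    return pd.DataFrame(
        rows, columns=["cell_i", "cell_j", "distance_um", "rho", "adjacency"]
    )


def network_metrics(
    net: nx.Graph,
    corr: np.ndarray,
    cell_map: CellMap,
    contact_margin_um: float = 2.0,
    min_abs_lag_s: float = 0.5,
) -> NetworkMetrics:
    """Assemble the four-measure panel for one reconstructed network."""
    adjacent = classify_adjacent(cell_map, contact_margin_um)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        adj_mean, adj_med, adj_q1, adj_q3 = mean_adjacent_correlation(corr, adjacent)
        speed, n_excl = propagation_speed(net, min_abs_lag_s)

    mask = np.triu(np.ones_like(corr, dtype=bool), k=1)
    all_vals = corr[mask]
    all_vals = all_vals[np.isfinite(all_vals)]
    if all_vals.size:
        q1, med, q3 = np.percentile(all_vals, [25, 50, 75])
    else:
        q1 = med = q3 = float("nan")
    edge_vals = np.array([d["rho"] for _, _, d in net.edges(data=True)])
    if edge_vals.size:
        eq1, emed, eq3 = np.percentile(edge_vals, [25, 50, 75])
    else:
        eq1 = emed = eq3 = float("nan")

    return NetworkMetrics(
        mean_adjacent_correlation=adj_mean,
        mean_connections_per_cell=connections_per_cell(net),
        pct_correlated_connections=pct_correlated_connections(net),
        mean_propagation_speed_um_s=speed,
        n_speed_excluded=n_excl,
        adjacent_correlation_median=adj_med,
        adjacent_correlation_q1=adj_q1,
        adjacent_correlation_q3=adj_q3,
        correlation_median=float(med),
        correlation_q1=float(q1),
        correlation_q3=float(q3),
        edge_correlation_median=float(emed),
        edge_correlation_q1=float(eq1),
        edge_correlation_q3=float(eq3),
    )
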