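"""Correlation, lags, thresholded network construction and the four
connectivity measures, each checked against brute-force recomputation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from caldynet import (
    CellMap,
    build_network,
    classify_adjacent,
    connections_per_cell,
    correlation_vs_distance,
    cross_correlation_delay,
    lag_matrix,
    mean_adjacent_correlation,
    network_metrics,
    pairwise_correlation,
    pct_correlated_connections,
    propagation_speed,
)
from caldynet.traces import TraceMatrix


def tm_from(values, fs=2.0):
    values = np.atleast_2d(np.asarray(values, float))
    return TraceMatrix(
        cell_ids=np.arange(len(values)),
        times_s=np.arange(values.shape[1]) / fs,
        values=values,
    )


def grid_map(n, spacing=30.0, radius=5.0):
    side = int(np.ceil(np.sqrt(n)))
    xy = [(10 + spacing * (k % side), 10 + spacing * (k // side))
          for k in range(n)]
    return CellMap(
        cell_ids=np.arange(n),
        x_um=np.array([p[0] for p in xy]),
        y_um=np.array([p[1] for p in xy]),
        radius_um=np.full(n, radius),
    )


class TestPairwiseCorrelation:
    def test_identical_traces_give_one(self, rng):
        x = rng.normal(size=300)
        corr = pairwise_correlation(tm_from([x, x.copy()]))
        assert corr[0, 1] == pytest.approx(1.0, abs=1e-12)

    def test_negated_trace_gives_minus_one(self, rng):
        x = rng.normal(size=300)
        corr = pairwise_correlation(tm_from([x, -x]))
        assert corr[0, 1] == pytest.approx(-1.0, abs=1e-12)

    def test_matches_bruteforce_double_loop(self, rng):
        x = rng.normal(size=(5, 200))
        corr = pairwise_correlation(tm_from(x))
        for i in range(5):
            for j in range(5):
                xi, xj = x[i] - x[i].mean(), x[j] - x[j].mean()
                expected = (xi * xj).sum() / np.sqrt(
                    (xi**2).sum() * (xj**2).sum()
                )
                assert corr[i, j] == pytest.approx(expected, abs=1e-12)

    def test_constant_trace_yields_nan_entries(self, rng):
        x = np.vstack([rng.normal(size=100), np.full(100, 3.0)])
        corr = pairwise_correlation(tm_from(x))
        assert np.isnan(corr[0, 1])
        assert corr[0, 0] == 1.0

    def test_symmetry_is_exact(self, rng):
        corr = pairwise_correlation(tm_from(rng.normal(size=(8, 150))))
        np.testing.assert_array_equal(corr, corr.T)


class TestCrossCorrelationDelay:
    def test_pure_shift_recovered_exactly(self):
        t = np.arange(400) / 2.0
        s = np.sin(2 * np.pi * t / 40.0)
        y = np.concatenate([np.zeros(3), s[:-3]])
        tau = cross_correlation_delay(s, y, 2.0, max_lag_s=10.0,
                                      interpolate=False)
        assert tau == pytest.approx(1.5)
        tau_i = cross_correlation_delay(s, y, 2.0, max_lag_s=10.0)
        assert tau_i == pytest.approx(1.5, abs=0.25)

    def test_identical_traces_zero_lag_tiebreak(self, rng):
        x = rng.normal(size=200)
        assert cross_correlation_delay(x, x, 2.0) == 0.0

    def test_sign_convention_follower_positive(self):
        t = np.arange(400) / 2.0
        s = np.exp(-((t - 100) ** 2) / 20.0)
        follower = np.concatenate([np.zeros(4), s[:-4]])
        tau = cross_correlation_delay(s, follower, 2.0)
        assert tau > 0
        assert cross_correlation_delay(follower, s, 2.0) == pytest.approx(-tau)

    def test_constant_trace_gives_nan(self):
        assert np.isnan(cross_correlation_delay(
            np.ones(50), np.arange(50.0), 2.0))

    def test_rendered_pair_with_programmed_delay(self):
        """Generator pair with a 2 s propagation delay: tau = 2.0 within
        one frame, noise-free."""
        from caldynet import (SimConfig, generate_event_trains, preprocess,
                              render_traces)

        m = CellMap(cell_ids=np.array([0, 1]),
                    x_um=np.array([10.0, 110.0]),
                    y_um=np.array([50.0, 50.0]),
                    radius_um=np.array([5.0, 5.0]))
        cfg = SimConfig(n_cells=2, wave_speed_um_s=50.0, noise_sd_dff=0.0,
                        drift_per_min=0.0, event_rate_per_min=0.5,
                        duration_s=300.0, event_duration_mean_s=8.0,
                        event_duration_sd_s=1.0, n_pacemakers=1,
                        pacemaker_mode="edge", active_fraction=1.0, seed=9)
        gt = generate_event_trains({(0, 1)}, m, cfg)
        fluct = preprocess(render_traces(gt, cfg))
        tau = cross_correlation_delay(fluct.values[0], fluct.values[1], 2.0)
        assert tau == pytest.approx(2.0, abs=0.5)

    def test_lag_matrix_antisymmetric(self, rng):
        x = rng.normal(size=(4, 120)).cumsum(axis=1)
        lm = lag_matrix(tm_from(x), max_lag_s=5.0)
        np.testing.assert_allclose(lm, -lm.T, atol=1e-12)


class TestClassifyAdjacent:
    def test_contact_pair_is_neighboring(self):
        m = CellMap(cell_ids=np.array([0, 1]), x_um=np.array([0.0, 9.0]),
                    y_um=np.zeros(2), radius_um=np.full(2, 5.0))
        assert classify_adjacent(m, 0.0)[0, 1]

    def test_distant_pair_is_not(self):
        m = CellMap(cell_ids=np.array([0, 1]), x_um=np.array([0.0, 30.0]),
                    y_um=np.zeros(2), radius_um=np.full(2, 5.0))
        assert not classify_adjacent(m, 0.0)[0, 1]

    def test_huge_margin_makes_all_neighboring(self):
        m = grid_map(6)
        adj = classify_adjacent(m, 1e9)
        iu = np.triu_indices(6, k=1)
        assert adj[iu].all()


class TestBuildNetwork:
    def test_threshold_is_strict_and_applied_per_pair(self):
        m = grid_map(3)
        corr = np.eye(3)
        corr[0, 1] = corr[1, 0] = 0.5
        corr[0, 2] = corr[2, 0] = 0.2
        corr[1, 2] = corr[2, 1] = 0.3  # exactly at cutoff: excluded
        lags = np.zeros((3, 3))
        net = build_network(corr, lags, m, threshold=0.3)
        assert set(map(frozenset, net.edges)) == {frozenset((0, 1))}

    def test_threshold_one_gives_empty_network(self, rng):
        m = grid_map(5)
        x = rng.normal(size=(5, 100))
        corr = pairwise_correlation(tm_from(x))
        net = build_network(corr, np.zeros((5, 5)), m, threshold=1.0)
        assert net.number_of_edges() == 0
        assert net.number_of_nodes() == 5

    def test_edge_attributes_carry_distance_and_class(self):
        m = CellMap(cell_ids=np.array([0, 1]), x_um=np.array([0.0, 9.0]),
                    y_um=np.zeros(2), radius_um=np.full(2, 5.0))
        corr = np.array([[1.0, 0.8], [0.8, 1.0]])
        lags = np.array([[0.0, 1.0], [-1.0, 0.0]])
        net = build_network(corr, lags, m)
        d = net.edges[0, 1]
        assert d["distance_um"] == pytest.approx(9.0)
        assert d["adjacency"] == "neighboring"
        assert d["rho"] == pytest.approx(0.8)
        assert d["tau_s"] == pytest.approx(1.0)


def brute_edges(corr, threshold):
    n = corr.shape[0]
    return {(i, j) for i in range(n) for j in range(i + 1, n)
            if np.isfinite(corr[i, j]) and corr[i, j] > threshold}


class TestMetrics:
    def test_mean_adjacent_correlation_values(self):
        corr = np.eye(3)
        corr[0, 1] = corr[1, 0] = 0.4
        corr[0, 2] = corr[2, 0] = 0.6
        corr[1, 2] = corr[2, 1] = 0.9
        adj = np.zeros((3, 3), bool)
        adj[0, 1] = adj[1, 0] = adj[0, 2] = adj[2, 0] = True
        mean, med, q1, q3 = mean_adjacent_correlation(corr, adj)
        assert mean == pytest.approx(0.5)
        assert med == pytest.approx(0.5)

    def test_no_neighbors_is_undefined(self):
        out = mean_adjacent_correlation(np.eye(2), np.zeros((2, 2), bool))
        assert all(np.isnan(v) for v in out)

    def test_connections_per_cell_small_cases(self):
        m = grid_map(3)
        corr = np.eye(3)
        corr[0, 1] = corr[1, 0] = 0.9
        net = build_network(corr, np.zeros((3, 3)), m)
        assert connections_per_cell(net) == pytest.approx(2.0 / 3.0)

    def test_complete_graph_degree(self):
        m = grid_map(4)
        corr = np.full((4, 4), 0.9)
        np.fill_diagonal(corr, 1.0)
        net = build_network(corr, np.zeros((4, 4)), m)
        assert connections_per_cell(net) == pytest.approx(3.0)
        assert pct_correlated_connections(net) == pytest.approx(100.0)

    def test_pct_connections_small_case(self):
        m = grid_map(3)
        corr = np.eye(3)
        corr[0, 1] = corr[1, 0] = 0.9
        net = build_network(corr, np.zeros((3, 3)), m)
        assert pct_correlated_connections(net) == pytest.approx(100.0 / 3.0)

    def test_propagation_speed_ratio_and_exclusion(self):
        m = CellMap(cell_ids=np.arange(3),
                    x_um=np.array([0.0, 100.0, 150.0]),
                    y_um=np.zeros(3), radius_um=np.full(3, 5.0))
        corr = np.full((3, 3), 0.9)
        np.fill_diagonal(corr, 1.0)
        lags = np.array([[0.0, 2.0, 0.1],
                         [-2.0, 0.0, 1.0],
                         [-0.1, -1.0, 0.0]])
        net = build_network(corr, lags, m)
        speed, excluded = propagation_speed(net, min_abs_lag_s=0.5)
        # edges (0,1): 100/2=50 and (1,2): 50/1=50; (0,2) excluded
        assert speed == pytest.approx(50.0)
        assert excluded == 1

    def test_propagation_speed_undefined_when_all_zero_lag(self):
        m = grid_map(3)
        corr = np.full((3, 3), 0.9)
        np.fill_diagonal(corr, 1.0)
        with pytest.warns(UserWarning):
            speed, excluded = propagation_speed(
                build_network(corr, np.zeros((3, 3)), m))
        assert np.isnan(speed)
        assert excluded == 3

    def test_correlation_vs_distance_table(self, rng):
        m = grid_map(3)
        corr = pairwise_correlation(tm_from(rng.normal(size=(3, 100))))
        table = correlation_vs_distance(corr, m)
        assert len(table) == 3
        for row in table.itertuples():
            a = m.index_of(row.cell_i)
            b = m.index_of(row.cell_j)
            d = np.hypot(m.x_um[a] - m.x_um[b], m.y_um[a] - m.y_um[b])
            assert row.distance_um == pytest.approx(d, abs=1e-9)
        adj = classify_adjacent(m)
        for row in table.itertuples():
            expected = "neighboring" if adj[m.index_of(row.cell_i),
                                            m.index_of(row.cell_j)] else "distant"
            assert row.adjacency == expected

    @settings(derandomize=True, max_examples=15, deadline=None)
    @given(seed=st.integers(min_value=0, max_value=10_000))
    def test_metrics_invariant_under_relabeling(self, seed):
        """Permuting cell ids permutes the network but leaves every
        scalar metric unchanged."""
        rng = np.random.default_rng(seed)
        n = 8
        x = rng.normal(size=(n, 150)) + rng.normal(size=150) * 0.8
        m = grid_map(n)
        corr = pairwise_correlation(tm_from(x))
        lags = lag_matrix(tm_from(x), max_lag_s=5.0)
        net = build_network(corr, lags, m)
        base = network_metrics(net, corr, m)

        perm = rng.permutation(n)
        m2 = CellMap(cell_ids=m.cell_ids.copy(),
                     x_um=m.x_um[perm], y_um=m.y_um[perm],
                     radius_um=m.radius_um[perm])
        corr2 = corr[np.ix_(perm, perm)]
        lags2 = lags[np.ix_(perm, perm)]
        net2 = build_network(corr2, lags2, m2)
        out = network_metrics(net2, corr2, m2)
        for key, val in base.to_dict().items():
            other = out.to_dict()[key]
            if isinstance(val, float) and np.isnan(val):
                assert np.isnan(other)
            else:
                assert other == pytest.approx(val, abs=1e-12), key

    @settings(derandomize=True, max_examples=15, deadline=None)
    @given(seed=st.integers(min_value=0, max_value=10_000))
    def test_edges_match_bruteforce(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(3, 12)
        x = rng.normal(size=(n, 80)) + rng.normal(size=80)
        m = grid_map(int(n))
        corr = pairwise_correlation(tm_from(x))
        net = build_network(corr, np.zeros((n, n)), m)
        assert {tuple(sorted(e)) for e in net.edges} == brute_edges(corr, 0.3)
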