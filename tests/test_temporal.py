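"""Temporal integration, infection states and the synthetic generators."""

import networkx as nx
import numpy as np
import pytest

from percolearn import make_square_lattice
from percolearn.temporal import (
    CaseCountTable,
    TemporalEdgeList,
    aggregate_window,
    cumulative_interval_accuracy,
    epidemic_cluster_sizes,
    estimate_Tc,
    infection_state_matrix,
    integration_state_matrix,
    synth_epidemic,
    synth_temporal,
)


@pytest.fixture
def three_events():
    return TemporalEdgeList((("a", "b", 5.0), ("b", "c", 20.0)))


class TestAggregation:
    def test_zero_window_keeps_only_t0_events(self):
        tel = TemporalEdgeList((("a", "b", 0.0), ("b", "c", 1.0)))
        g = aggregate_window(tel, 0.0, 0.0)
        assert set(map(frozenset, g.edges())) == {frozenset(("a", "b"))}

    def test_full_window_recovers_whole_graph(self, three_events):
        g = aggregate_window(three_events, 0.0, 100.0)
        assert g.number_of_edges() == 2

    def test_partial_window(self, three_events):
        g = aggregate_window(three_events, 0.0, 10.0)
        assert set(map(frozenset, g.edges())) == {frozenset(("a", "b"))}

    def test_window_monotonicity(self, three_events):
        e1 = set(aggregate_window(three_events, 0.0, 6.0).edges())
        e2 = set(aggregate_window(three_events, 0.0, 25.0).edges())
        assert e1 <= e2

    def test_self_contact_rejected(self):
        with pytest.raises(ValueError):
            TemporalEdgeList((("a", "a", 1.0),))


class TestIntegrationMatrix:
    def test_row_count_and_saturation(self, three_events):
        sm = integration_state_matrix(three_events, t0=0.0, dT=1.0, n_steps=30)
        assert sm.M == 30
        # last row = largest window: temporally connected system, all ones
        assert sm.X[-1].all()

    def test_single_event_switches_once(self):
        tel = TemporalEdgeList((("a", "b", 3.0),))
        sm = integration_state_matrix(tel, dT=1.0, n_steps=6)
        col_b = sm.X[:, sm.node_order.index("b")]  # rows ascend in T
        assert col_b.tolist() == [0, 0, 1, 1, 1, 1]


class TestTc:
    def test_two_halves_merging_late(self):
        # two 3-cliques wired internally at t=0, bridged by one event at t=50
        events = [(0, 1, 0.0), (1, 2, 0.0), (0, 2, 0.0),
                  (3, 4, 0.0), (4, 5, 0.0), (3, 5, 0.0),
                  (2, 3, 50.0)]
        tel = TemporalEdgeList(tuple(events))
        assert estimate_Tc(tel, dT=1.0, n_steps=100) == pytest.approx(1.0)
        # before the bridge the second component has size 3 (max), tie -> smallest T

    def test_all_events_at_zero(self):
        tel = TemporalEdgeList(((0, 1, 0.0), (1, 2, 0.0)))
        assert estimate_Tc(tel, dT=1.0, n_steps=10) == pytest.approx(1.0)

    def test_empty_event_list_low_confidence(self):
        assert estimate_Tc(TemporalEdgeList(()), n_steps=10) is None

    def test_recovery_on_synthetic_fixtures(self):
        g = make_square_lattice(6)
        hits = []
        for seed in range(20):
            tel, true_tc = synth_temporal(g, max_time=600.0, seed=seed)
            est = estimate_Tc(tel, dT=1.0, n_steps=650)
            hits.append(abs(est - true_tc) <= 2.0)
        assert np.mean(hits) >= 0.9

    def test_synth_temporal_deterministic(self):
        g = make_square_lattice(4)
        a, ta = synth_temporal(g, seed=5)
        b, tb = synth_temporal(g, seed=5)
        assert a.events == b.events and ta == tb

    def test_constant_activation_times(self):
        g = make_square_lattice(3)
        tel, tc = synth_temporal(g, seed=0, activation_times=np.full(g.number_of_edges(), 42.0))
        assert tc == 42.0


class TestInfectionStates:
    def test_zero_cases_all_zero(self):
        cct = CaseCountTable(("a",), (0, 1), np.zeros((1, 2), dtype=int), {"a": 1000})
        assert infection_state_matrix(cct).sum() == 0

    def test_threshold_is_strict(self):
        cases = np.array([[10, 11]])
        cct = CaseCountTable(("a",), (0, 1), cases, {"a": 100_000})
        Xinf = infection_state_matrix(cct)
        assert Xinf[0, 0] == 0  # 10 / 1e5 == 1e-4 exactly: not above
        assert Xinf[1, 0] == 1  # 11 / 1e5 > 1e-4

    def test_missing_population_names_region(self):
        cct = CaseCountTable(("a", "b"), (0,), np.zeros((2, 1), dtype=int), {"a": 10})
        with pytest.raises(ValueError, match="b"):
            infection_state_matrix(cct)

    def test_cumulative_rows_monotone(self):
        g = nx.path_graph(8)
        cct, _ = synth_epidemic(g, beta=0.7, seed=1, days=40, start_day=0)
        Xinf = infection_state_matrix(cct)
        assert (np.diff(Xinf.astype(int), axis=0) >= 0).all()


class TestSynthEpidemic:
    def test_beta_one_on_path_advances_one_node_per_day(self):
        g = nx.path_graph(6)
        cct, emergence = synth_epidemic(g, beta=1.0, seed=3, days=12, start_day=0)
        Xinf = infection_state_matrix(cct)
        n_inf = Xinf.sum(axis=1)
        # front grows by at most 2/day (both directions), at least 1 until saturation
        growth = np.diff(n_inf[: int(np.argmax(n_inf == 6)) + 1])
        assert (growth >= 1).all() and (growth <= 2).all()
        assert emergence is not None

    def test_beta_zero_never_emerges(self):
        g = nx.path_graph(20)
        _, emergence = synth_epidemic(g, beta=0.0, seed=0, days=30, start_day=0)
        assert emergence is None

    def test_deterministic(self):
        g = make_square_lattice(4)
        a, ea = synth_epidemic(g, beta=0.5, seed=9, days=20, start_day=0)
        b, eb = synth_epidemic(g, beta=0.5, seed=9, days=20, start_day=0)
        assert (a.cases == b.cases).all() and ea == eb


class TestCumulativeIntervals:
    def test_accuracy_rises_after_emergence(self):
        g = make_square_lattice(6)
        cct, emergence = synth_epidemic(g, beta=0.35, seed=4, days=120, start_day=40)
        assert emergence is not None and emergence >= 40
        Xinf = infection_state_matrix(cct)
        from percolearn.phase_clustering import SampleBin

        # sample regions guaranteed to become infected (the seed's neighborhood)
        n_inf, largest = epidemic_cluster_sizes(Xinf, g, cct.regions)
        infected_final = [r for r, x in zip(cct.regions, Xinf[-1]) if x]
        sample = SampleBin(tuple(infected_final[:10]), "high-fidelity", 0)
        ends, alphas = cumulative_interval_accuracy(Xinf, g, cct.regions, sample, seed=2)
        pre = alphas[ends <= emergence]
        post = alphas[ends >= emergence + 20]
        assert post.max() > pre.mean()
        assert post.max() >= 0.8
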