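"""Temporal-network integration and epidemic-state applications.

Two time-varying settings reuse the percolation machinery by swapping the
control parameter:

* **Integration.**  Time-stamped contacts are aggregated over a growing
  window [t0, t0 + T]; the window length T plays the role of phi and the
  critical integration time ``T_c`` — where the aggregated network forms a
  spanning temporal cluster — is located by the same
  second-largest-component criterion used for phi_c.
* **Epidemics.**  Regions are marked infected once per-capita cumulative
  cases exceed a threshold (default 1e-4, strict inequality); days play the
  role of configurations, and the emergence of a connected cluster of
  infected regions on the mobility network is the phase transition.

Synthetic generators with known ground truth (activation times with a
known T_c; an SI epidemic with a known emergence day) stand in for the
real flight-schedule and case-count feeds, which are out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .percolation import StateMatrix, gcc_membership
from .phase_clustering import SampleBin, add_noise, align_and_score, cluster_two, embed_2d

__all__ = [
    "TemporalEdgeList",
    "CaseCountTable",
    "aggregate_window",
    "integration_state_matrix",
    "integration_times",
    "estimate_Tc",
    "infection_state_matrix",
    "epidemic_cluster_sizes",
    "epidemic_day_labels",
    "cumulative_interval_accuracy",
    "synth_temporal",
    "synth_epidemic",
]


@dataclass(frozen=True)
class TemporalEdgeList:
    """Time-stamped contacts (u, v, minutes); nodes may also be declared
    explicitly so isolated nodes survive aggregation."""

    events: tuple
    nodes: tuple = ()

    def __post_init__(self) -> None:
        for u, v, ts in self.events:
            if u == v:
                raise ValueError(f"self-contact {u!r} at t={ts}")
            if ts < 0:
                raise ValueError(f"negative timestamp {ts}")

    def all_nodes(self) -> list:
        declared = set(self.nodes)
        for u, v, _ in self.events:
            declared.add(u)
            declared.add(v)
        return sorted(declared)

    def to_tsv(self, path) -> None:
        pd.DataFrame(self.events, columns=["u", "v", "minutes"]).to_csv(
            path, sep="\t", index=False
        )

    @classmethod
    def from_tsv(cls, path) -> "TemporalEdgeList":
        df = pd.read_csv(path, sep="\t")
        return cls(tuple(df.itertuples(index=False, name=None)))


@dataclass(frozen=True)
class CaseCountTable:
    """Cumulative detected cases per region per day, with populations."""

    regions: tuple
    days: tuple
    cases: np.ndarray  # regions x days
    population: dict

    def __post_init__(self) -> None:
        cases = np.asarray(self.cases)
        if cases.shape != (len(self.regions), len(self.days)):
            raise ValueError("cases shape inconsistent with regions/days")
        if (cases < 0).any():
            raise ValueError("case counts must be non-negative")

    def to_csv(self, cases_path, population_path=None) -> None:
        rows = [
            {"region": r, "day": d, "cases": int(self.cases[i, j])}
            for i, r in enumerate(self.regions)
            for j, d in enumerate(self.days)
        ]
        pd.DataFrame(rows).to_csv(cases_path, index=False)
        if population_path is not None:
            pd.DataFrame(
                {"region": list(self.population), "population": list(self.population.values())}
            ).to_csv(population_path, index=False)


def aggregate_window(tel: TemporalEdgeList, t0: float, T: float) -> nx.Graph:
    """Simple graph with an edge iff at least one event falls in [t0, t0+T]."""
    if T < 0:
        raise ValueError("window length T must be non-negative")
    g = nx.Graph()
    g.add_nodes_from(tel.all_nodes())
    g.add_edges_from((u, v) for u, v, ts in tel.events if t0 <= ts <= t0 + T)
    return g


def _window_stats(tel: TemporalEdgeList, t0: float, Ts: np.ndarray, want_rows: bool):
    """Second-largest sizes (and optionally membership rows) per window length."""
    nodes = tel.all_nodes()
    n = len(nodes)
    seconds = np.empty(len(Ts))
    rows = np.empty((len(Ts), n), dtype=np.uint8) if want_rows else None
    g = nx.Graph()
    g.add_nodes_from(nodes)
    events = sorted(
        ((ts, u, v) for u, v, ts in tel.events if ts >= t0), key=lambda e: e[0]
    )
    ei = 0
    for k, T in enumerate(Ts):
        while ei < len(events) and events[ei][0] <= t0 + T:
            g.add_edge(events[ei][1], events[ei][2])
            ei += 1
        sizes = sorted((len(c) for c in nx.connected_components(g)), reverse=True)
        seconds[k] = sizes[1] if len(sizes) > 1 else 0
        if want_rows:
            rows[k] = gcc_membership(g, nodes)
    return nodes, seconds, rows


def integration_state_matrix(
    tel: TemporalEdgeList, t0: float = 0.0, dT: float = 1.0, n_steps: int = 1100
) -> StateMatrix:
    """Rows = largest-component membership of the [t0, t0+k*dT] aggregate.

    Rows are indexed by T ascending; the StateMatrix stores its control
    parameter descending, so the T grid is negated internally and exposed
    through ``integration_times``.
    """
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    Ts = np.arange(1, n_steps + 1) * dT
    nodes, _, rows = _window_stats(tel, t0, Ts, want_rows=True)
    # StateMatrix requires a strictly decreasing control grid; store -T so
    # row k still corresponds to window length (k+1)*dT.
    return StateMatrix(rows, -Ts, nodes)


def integration_times(sm: StateMatrix) -> np.ndarray:
    """Ascending window lengths of an integration state matrix."""
    return -sm.phis


def estimate_Tc(
    tel: TemporalEdgeList, t0: float = 0.0, dT: float = 1.0, n_steps: int = 1100
) -> float | None:
    """Critical integration time: T maximizing the second-largest component.

    Mirrors the phi_c criterion; ties break toward the smallest T.  Returns
    None (low confidence) for an event-free list.
    """
    if not tel.events:
        return None
    Ts = np.arange(1, n_steps + 1) * dT
    _, seconds, _ = _window_stats(tel, t0, Ts, want_rows=False)
    best = np.flatnonzero(seconds == seconds.max())
    return float(Ts[best].min())


def infection_state_matrix(
    cct: CaseCountTable, threshold: float = 1e-4
) -> np.ndarray:
    """Binary days x regions matrix: 1 iff cases per capita exceed threshold
    (strict inequality)."""
    missing = [r for r in cct.regions if r not in cct.population]
    if missing:
        raise ValueError(f"missing population for region(s): {missing}")
    pops = np.array([cct.population[r] for r in cct.regions], dtype=float)
    if (pops <= 0).any():
        raise ValueError("populations must be positive")
    per_capita = np.asarray(cct.cases, dtype=float) / pops[:, None]
    return (per_capita.T > threshold).astype(np.uint8)


def epidemic_cluster_sizes(Xinf: np.ndarray, mobility_g: nx.Graph, regions) -> tuple[np.ndarray, np.ndarray]:
    """Per day: (number of infected regions, size of the largest connected
    infected component on the mobility network)."""
    Xinf = np.asarray(Xinf)
    n_inf = Xinf.sum(axis=1)
    largest = np.zeros(Xinf.shape[0], dtype=int)
    for d in range(Xinf.shape[0]):
        infected = [r for r, x in zip(regions, Xinf[d]) if x]
        if infected:
            sub = mobility_g.subgraph(infected)
            largest[d] = max((len(c) for c in nx.connected_components(sub)), default=0)
    return n_inf.astype(int), largest


def epidemic_day_labels(
    Xinf: np.ndarray, mobility_g: nx.Graph, regions, emergence_frac: float = 0.1
) -> np.ndarray:
    """Per-day phase label: 1 once the largest infected cluster exceeds
    ``emergence_frac`` of the regions."""
    _, largest = epidemic_cluster_sizes(Xinf, mobility_g, regions)
    return (largest > emergence_frac * len(list(regions))).astype(np.uint8)


def cumulative_interval_accuracy(
    Xinf: np.ndarray,
    mobility_g: nx.Graph,
    regions,
    sample: SampleBin,
    interval: int = 20,
    seed: int | None = 0,
    sigma2: float = 0.01,
    emergence_frac: float = 0.1,
) -> tuple[np.ndarray, np.ndarray]:
    """Clustering accuracy on growing day windows [0,20], [0,40], ...

    Each window runs the noise -> t-SNE -> 2-means pipeline on the sampled
    regions' infection trajectories and scores the day labels against the
    epidemic-cluster ground truth.  Before emergence both phases collapse
    and the score hovers at the 0.5 guessing level; it rises as the
    epidemic cluster grows.  Windows too short to embed are scored NaN.
    """
    Xinf = np.asarray(Xinf)
    y_days = epidemic_day_labels(Xinf, mobility_g, regions, emergence_frac)
    ridx = {r: j for j, r in enumerate(regions)}
    cols = [ridx[r] for r in sample.nodes]
    ends = np.arange(interval, Xinf.shape[0] + 1, interval)
    seeds = np.random.SeedSequence(seed).spawn(len(ends))
    alphas = np.empty(len(ends))
    for i, (end, s) in enumerate(zip(ends, seeds)):
        sub = Xinf[:end, cols].astype(float)
        children = s.spawn(3)
        if end < 4:
            alphas[i] = float("nan")
            continue
        noisy = add_noise(sub, sigma2=sigma2, seed=children[0])
        perp = min(30.0, max(2.0, (end - 1) / 3.0))
        emb = embed_2d(noisy, perplexity=perp, seed=int(children[1].generate_state(1)[0] % 2**31))
        yhat = cluster_two(emb, seed=int(children[2].generate_state(1)[0] % 2**31))
        alphas[i] = align_and_score(yhat, y_days[:end])
    return ends, alphas


def synth_temporal(
    g: nx.Graph,
    max_time: float = 600.0,
    seed: int | None = 0,
    activation_times: np.ndarray | None = None,
) -> tuple[TemporalEdgeList, float]:
    """Assign each edge one activation time; return the list and its true T_c.

    Times default to uniform(0, max_time).  The ground-truth T_c is found
    by brute force: rebuild the aggregate graph at every activation time
    and locate the maximum of the second-largest component size (smallest
    such window on ties) — an independent path from :func:`estimate_Tc`'s
    incremental sweep.
    """
    if not nx.is_connected(g):
        raise ValueError("the underlying graph must be connected")
    edges = list(g.edges())
    rng = np.random.default_rng(seed)
    if activation_times is None:
        activation_times = rng.uniform(0.0, max_time, size=len(edges))
    times = np.asarray(activation_times, dtype=float)
    tel = TemporalEdgeList(
        tuple((u, v, float(t)) for (u, v), t in zip(edges, times)),
        nodes=tuple(sorted(g.nodes())),
    )
    # brute-force ground truth at the event times themselves
    uniq = np.unique(times)
    best_T, best_s2 = None, -1.0
    for T in uniq:
        sub = nx.Graph()
        sub.add_nodes_from(g.nodes())
        sub.add_edges_from(e for e, t in zip(edges, times) if t <= T)
        sizes = sorted((len(c) for c in nx.connected_components(sub)), reverse=True)
        s2 = sizes[1] if len(sizes) > 1 else 0
        if s2 > best_s2:
            best_T, best_s2 = float(T), s2
    return tel, best_T


def synth_epidemic(
    g: nx.Graph,
    beta: float,
    seed: int | None = 0,
    days: int = 120,
    start_day: int = 40,
    populations: dict | None = None,
    emergence_frac: float = 0.1,
    case_rate: float = 2e-4,
) -> tuple[CaseCountTable, int | None]:
    """SI epidemic on the mobility graph with known emergence day.

    The outbreak starts at one uniformly chosen seed region on
    ``start_day`` (the table covers a quiet pre-epidemic stretch first,
    emulating empirical case feeds in which the cluster emerges well into
    the observation window); each subsequent day every infected region
    infects each susceptible neighbor independently with probability
    ``beta``.  An infected region reports cumulative cases growing by
    ``case_rate * population`` per day (at least 1), so its per-capita
    count crosses the 1e-4 reporting threshold on its infection day.  The
    true emergence day is the first day the largest infected cluster
    exceeds ``emergence_frac`` of the regions (None if never).
    """
    if not 0 <= beta <= 1:
        raise ValueError("beta must lie in [0, 1]")
    if not 0 <= start_day < days:
        raise ValueError("start_day must lie in [0, days)")
    rng = np.random.default_rng(seed)
    regions = sorted(g.nodes())
    n = len(regions)
    if populations is None:
        populations = {r: 100_000 for r in regions}
    infected_day = {r: None for r in regions}
    seed_region = regions[int(rng.integers(n))]
    infected_day[seed_region] = start_day
    for day in range(start_day + 1, days):
        newly = []
        for r in regions:
            if infected_day[r] is not None and infected_day[r] < day:
                for nb in g.neighbors(r):
                    if infected_day[nb] is None and rng.random() < beta:
                        newly.append(nb)
        for nb in newly:
            if infected_day[nb] is None:
                infected_day[nb] = day
    cases = np.zeros((n, days), dtype=int)
    for i, r in enumerate(regions):
        d0 = infected_day[r]
        if d0 is not None:
            daily = max(1, int(np.ceil(case_rate * populations[r])))
            cases[i, d0:] = daily * np.arange(1, days - d0 + 1)
    cct = CaseCountTable(tuple(regions), tuple(range(days)), cases, dict(populations))
    # ground-truth emergence from the infection days directly
    emergence = None
    for day in range(days):
        infected = [r for r in regions if infected_day[r] is not None and infected_day[r] <= day]
        if infected:
            sub = g.subgraph(infected)
            if max((len(c) for c in nx.connected_components(sub)), default=0) > emergence_frac * n:
                emergence = day
                break
    return cct, emergence
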