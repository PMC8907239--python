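"""Bond percolation: state matrices, second-largest-cluster curves, phi_c.

The control parameter is the bond-occupation probability ``phi``.  The
default representation is the *coupled* (monotone) process: every edge gets
one fixed uniform(0,1) weight and the occupied edge set at ``phi`` keeps
exactly the edges with weight <= phi.  Occupied sets are then nested across
phi, so each node's giant-component membership traces a step-like
trajectory as phi decreases — the raw material for the phase-clustering
stage.  An *independent* mode (fresh Bernoulli draw per phi) is available
for comparison.

The critical occupation probability is located, as is standard in finite
systems, at the maximum of the mean second-largest component size.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "StateMatrix",
    "LabelVector",
    "PercolationRun",
    "make_run",
    "occupied_subgraph",
    "gcc_membership",
    "build_state_matrix",
    "second_largest_curve",
    "estimate_phic_ground_truth",
    "make_labels",
    "phi_grid",
]


@dataclass
class StateMatrix:
    """M x N binary matrix of giant-component membership.

    Row ``m`` is the configuration at control-parameter value ``phis[m]``
    (strictly decreasing); column ``j`` is node ``node_order[j]``.

    ``second_largest``, when present, is this realization's second-largest
    component size per row, and ``realization_phic`` its argmax — the
    transition of *this* realization, which is what the phase labels must
    be paired with when scoring clusterings of these trajectories (the
    ensemble-averaged estimator can sit a few hundredths away).
    """

    X: np.ndarray
    phis: np.ndarray
    node_order: list
    second_largest: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=np.uint8)
        self.phis = np.asarray(self.phis, dtype=float)
        if self.X.shape != (len(self.phis), len(self.node_order)):
            raise ValueError("X shape inconsistent with phis/node_order")
        if np.any(np.diff(self.phis) >= 0):
            raise ValueError("phis must be strictly decreasing")

    @property
    def realization_phic(self) -> float:
        """Second-largest-cluster argmax of this realization (ties: smallest phi)."""
        if self.second_largest is None:
            raise ValueError("this StateMatrix carries no second-largest curve")
        best = np.flatnonzero(self.second_largest == self.second_largest.max())
        return float(self.phis[best].min())

    @property
    def M(self) -> int:
        return self.X.shape[0]

    @property
    def N(self) -> int:
        return self.X.shape[1]

    def columns(self, nodes) -> np.ndarray:
        """Float submatrix of the given nodes, in the given order."""
        idx = {v: j for j, v in enumerate(self.node_order)}
        return self.X[:, [idx[v] for v in nodes]].astype(float)

    def to_csv(self, path) -> None:
        df = pd.DataFrame(self.X, columns=[str(v) for v in self.node_order])
        df.insert(0, "phi", self.phis)
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "StateMatrix":
        df = pd.read_csv(path)
        phis = df.pop("phi").to_numpy()

        def coerce(c):
            try:
                return int(c)
            except ValueError:
                return c

        return cls(df.to_numpy(dtype=np.uint8), phis, [coerce(c) for c in df.columns])


@dataclass
class LabelVector:
    """Ground-truth phase labels: 0 before the transition (phi >= phic), 1 after."""

    y: np.ndarray
    phic: float

    def to_csv(self, path, phis=None) -> None:
        df = pd.DataFrame({"y": self.y.astype(int)})
        if phis is not None:
            df.insert(0, "phi", phis)
        df.to_csv(path, index=False)


@dataclass(frozen=True)
class PercolationRun:
    """One realization of edge randomness.

    ``edges``/``weights`` define the coupled process; in independent mode
    the weights are ignored and each phi gets its own Bernoulli substream
    derived from ``seed``.
    """

    edges: tuple
    weights: np.ndarray
    mode: str = "coupled"
    seed: int | None = None


def make_run(g: nx.Graph, seed: int | None = 0, mode: str = "coupled") -> PercolationRun:
    if mode not in ("coupled", "independent"):
        raise ValueError(f"unknown mode {mode!r}")
    rng = np.random.default_rng(seed)
    edges = tuple(g.edges())
    weights = rng.random(len(edges))
    return PercolationRun(edges=edges, weights=weights, mode=mode, seed=seed)


def occupied_subgraph(g: nx.Graph, run: PercolationRun, phi: float) -> nx.Graph:
    """Subgraph of occupied edges at ``phi`` (all nodes retained)."""
    if not 0 <= phi <= 1:
        raise ValueError(f"phi must lie in [0, 1], got {phi}")
    sub = nx.Graph()
    sub.add_nodes_from(g.nodes())
    if run.mode == "coupled":
        keep = run.weights <= phi
    else:
        row_key = int(round(phi / 1e-9))  # phi-specific substream
        rng = np.random.default_rng([0 if run.seed is None else run.seed, row_key])
        keep = rng.random(len(run.edges)) < phi
    sub.add_edges_from(e for e, k in zip(run.edges, keep) if k)
    return sub


def gcc_membership(g: nx.Graph, all_nodes) -> np.ndarray:
    """Indicator of membership in the largest connected component.

    Ties between equal-size components are broken toward the component
    containing the smallest node id (with isolated nodes this makes the
    answer deterministic: at phi=0 exactly one node is flagged).
    """
    comps = list(nx.connected_components(g))
    if comps:
        top = max(len(c) for c in comps)
        best = min((c for c in comps if len(c) == top), key=min)
    else:
        best = set()
    return np.fromiter((1 if v in best else 0 for v in all_nodes), dtype=np.uint8)


def phi_grid(dphi: float = 0.001) -> np.ndarray:
    """Descending grid (1.0, 1-dphi, ..., dphi); phi=0 excluded so that
    dphi = 0.001 yields exactly M = 1000 rows."""
    if not 0 < dphi < 1:
        raise ValueError("dphi must lie in (0, 1)")
    M = round(1.0 / dphi)
    if abs(M * dphi - 1.0) > 1e-9:
        raise ValueError(f"dphi={dphi} does not divide 1")
    return np.arange(M, 0, -1) * dphi


def _flatten(parent: np.ndarray) -> np.ndarray:
    """Full path compression of a union-find parent array, vectorized."""
    while True:
        pp = parent[parent]
        if np.array_equal(pp, parent):
            return parent
        parent = pp


class _UnionFind:
    """Array union-find with union by size (hot loop for the phi sweep)."""

    def __init__(self, n: int):
        self.parent = np.arange(n, dtype=np.int64)
        self.size = np.ones(n, dtype=np.int64)

    def find(self, a: int) -> int:
        p = self.parent
        while p[a] != a:
            p[a] = p[p[a]]
            a = p[a]
        return a

    def union(self, a: int, b: int) -> tuple[int, int, int] | None:
        """Merge; return (size_a, size_b, merged_size) or None if same root."""
        ra, rb = self.find(a), self.find(b)
        if ra == rb:
            return None
        if self.size[ra] < self.size[rb]:
            ra, rb = rb, ra
        sa, sb = int(self.size[ra]), int(self.size[rb])
        self.parent[rb] = ra
        self.size[ra] = sa + sb
        return sa, sb, sa + sb


def _coupled_sweep(
    g: nx.Graph,
    weights: np.ndarray,
    phis_desc: np.ndarray,
    node_index: dict,
    want_rows: bool,
):
    """Single coupled run: add edges in weight order, report per grid phi.

    Returns (largest, second, rows) with rows=None unless requested; all
    indexed ascending in phi and flipped by the caller.
    """
    n = len(node_index)
    edges = np.array(
        [(node_index[u], node_index[v]) for u, v in g.edges()], dtype=np.int64
    ).reshape(-1, 2)
    order = np.argsort(weights, kind="stable")
    w_sorted = weights[order]
    e_sorted = edges[order]

    phis_asc = phis_desc[::-1]
    uf = _UnionFind(n)
    largest = np.empty(len(phis_asc))
    second = np.empty(len(phis_asc))
    rows = np.empty((len(phis_asc), n), dtype=np.uint8) if want_rows else None

    # lazy max-heap of component sizes; cnt[s] = number of live components of size s
    cnt = np.zeros(n + 1, dtype=np.int64)
    cnt[1] = n
    heap = [-1]
    ei = 0
    for k, phi in enumerate(phis_asc):
        while ei < len(w_sorted) and w_sorted[ei] <= phi:
            res = uf.union(e_sorted[ei, 0], e_sorted[ei, 1])
            if res is not None:
                sa, sb, s = res
                cnt[sa] -= 1
                cnt[sb] -= 1
                cnt[s] += 1
                heapq.heappush(heap, -s)
            ei += 1
        while heap and cnt[-heap[0]] <= 0:
            heapq.heappop(heap)
        l1 = -heap[0] if heap else 0
        if cnt[l1] >= 2:
            l2 = l1
        else:
            nz = np.flatnonzero(cnt[:l1])
            l2 = int(nz[-1]) if len(nz) else 0
        largest[k] = l1
        second[k] = l2 if l1 > 0 else 0
        if want_rows:
            parent = _flatten(uf.parent.copy())
            sizes = np.bincount(parent, minlength=n)
            max_roots = np.flatnonzero(sizes == sizes.max())
            # tie-break: component containing the smallest node id
            winner = parent[np.flatnonzero(np.isin(parent, max_roots))[0]] if len(
                max_roots
            ) > 1 else max_roots[0]
            rows[k] = (parent == winner).astype(np.uint8)
    return largest, second, rows


def build_state_matrix(
    g: nx.Graph,
    dphi: float = 0.001,
    seed: int | None = 0,
    mode: str = "coupled",
) -> StateMatrix:
    """Simulate one percolation realization over the full phi grid.

    Row ``m`` is the largest-component membership indicator at ``phis[m]``;
    columns follow ``sorted(g.nodes())``.  With ``dphi = 0.001`` the matrix
    has M = 1000 rows.
    """
    phis = phi_grid(dphi)
    nodes = sorted(g.nodes())
    node_index = {v: i for i, v in enumerate(nodes)}
    if mode == "coupled":
        run = make_run(g, seed=seed, mode="coupled")
        _, second, rows = _coupled_sweep(
            g, run.weights, phis, node_index, want_rows=True
        )
        X, s2 = rows[::-1], second[::-1].copy()
    elif mode == "independent":
        run = make_run(g, seed=seed, mode="independent")
        X = np.empty((len(phis), len(nodes)), dtype=np.uint8)
        s2 = np.empty(len(phis))
        for m, phi in enumerate(phis):
            sub = occupied_subgraph(g, run, phi)
            X[m] = gcc_membership(sub, nodes)
            sizes = sorted((len(c) for c in nx.connected_components(sub)), reverse=True)
            s2[m] = sizes[1] if len(sizes) > 1 else 0
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return StateMatrix(X, phis, nodes, second_largest=s2)


def second_largest_curve(
    g: nx.Graph,
    dphi: float = 0.001,
    n_runs: int = 100,
    seed: int | None = 0,
    mode: str = "coupled",
) -> tuple[np.ndarray, np.ndarray]:
    """Mean second-largest component size on the phi grid over ``n_runs``."""
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    phis = phi_grid(dphi)
    nodes = sorted(g.nodes())
    node_index = {v: i for i, v in enumerate(nodes)}
    acc = np.zeros(len(phis))
    child_seeds = np.random.SeedSequence(seed).spawn(n_runs)
    for cs in child_seeds:
        run_seed = int(cs.generate_state(1)[0] % 2**31)
        if mode == "coupled":
            run = make_run(g, seed=run_seed, mode="coupled")
            _, second, _ = _coupled_sweep(
                g, run.weights, phis, node_index, want_rows=False
            )
            acc += second[::-1]
        else:
            run = make_run(g, seed=run_seed, mode="independent")
            for m, phi in enumerate(phis):
                sub = occupied_subgraph(g, run, phi)
                sizes = sorted((len(c) for c in nx.connected_components(sub)), reverse=True)
                acc[m] += sizes[1] if len(sizes) > 1 else 0
    return phis, acc / n_runs


def estimate_phic_ground_truth(
    g: nx.Graph,
    dphi: float = 0.001,
    n_runs: int = 100,
    seed: int | None = 0,
    mode: str = "coupled",
) -> float:
    """phi at the maximum of the mean second-largest-cluster curve.

    Ties are broken toward the smallest phi on the grid.
    """
    phis, curve = second_largest_curve(g, dphi=dphi, n_runs=n_runs, seed=seed, mode=mode)
    best = np.flatnonzero(curve == curve.max())
    return float(phis[best].min())


def make_labels(phis, phic: float) -> LabelVector:
    """Phase labels on the grid: y = 0 where phi >= phic, else 1."""
    if not 0 <= phic <= 1:
        raise ValueError(f"phic must lie in [0, 1], got {phic}")
    phis = np.asarray(phis, dtype=float)
    return LabelVector((phis < phic).astype(np.uint8), float(phic))
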