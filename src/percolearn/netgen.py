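"""Synthetic network topologies and plain-text graph IO.

Two reference topologies span the structural spectrum studied by the
percolation pipeline: an open-boundary square lattice (uniform, tightly
peaked degree distribution) and a configuration-model network with a
power-law degree distribution ``p_k ~ k**-gamma`` (heavy-tailed).  Graphs
are plain :class:`networkx.Graph` objects with integer node ids.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

__all__ = [
    "DegreeSequence",
    "make_square_lattice",
    "sample_powerlaw_degrees",
    "configuration_model_graph",
    "read_edge_list",
    "write_edge_list",
]


@dataclass(frozen=True)
class DegreeSequence:
    """A degree sequence together with the exponent that generated it.

    ``sum(degrees)`` must be even for a stub-matching realization to exist;
    the sampler guarantees this by redrawing the last entry.
    """

    degrees: tuple[int, ...]
    gamma: float | None = None
    kmin: int | None = None

    def __post_init__(self) -> None:
        if any(d < 0 for d in self.degrees):
            raise ValueError("degrees must be non-negative")

    @property
    def n(self) -> int:
        return len(self.degrees)

    def moments(self) -> tuple[float, float]:
        """Empirical first and second moments ``<k>, <k^2>``."""
        arr = np.asarray(self.degrees, dtype=float)
        return float(arr.mean()), float((arr**2).mean())


def make_square_lattice(L: int) -> nx.Graph:
    """Build the ``L x L`` square lattice with open boundaries.

    Nodes are labeled row-major ``0 .. L*L-1`` so downstream tie-breaks are
    reproducible.  Interior nodes have degree 4, border nodes 3, corners 2;
    ``|E| = 2 L (L - 1)``.
    """
    if not isinstance(L, (int, np.integer)) or L < 1:
        raise ValueError(f"L must be a positive integer, got {L!r}")
    g = nx.Graph()
    g.add_nodes_from(range(L * L))
    for r in range(L):
        for c in range(L):
            v = r * L + c
            if c + 1 < L:
                g.add_edge(v, v + 1)
            if r + 1 < L:
                g.add_edge(v, v + L)
    return g


def truncated_powerlaw_pmf(gamma: float, kmin: int, kmax: int) -> np.ndarray:
    """Normalized pmf ``p_k ∝ k**-gamma`` on the integers ``kmin..kmax``."""
    ks = np.arange(kmin, kmax + 1, dtype=float)
    w = ks**-gamma
    return w / w.sum()


def sample_powerlaw_degrees(
    N: int, gamma: float, kmin: int = 2, seed: int | None = 0
) -> DegreeSequence:
    """Draw ``N`` i.i.d. degrees from the truncated discrete power law.

    Support is ``[kmin, N-1]`` (degrees are capped at ``N-1`` so a simple
    graph can realize them).  If the total is odd the last degree is redrawn
    until the handshake parity holds.  Bit-reproducible for a fixed seed.
    """
    if N < 1:
        raise ValueError("N must be positive")
    if gamma <= 1:
        raise ValueError("gamma must exceed 1 for a normalizable pmf")
    if kmin < 1:
        raise ValueError("kmin must be >= 1")
    if kmin >= N:
        raise ValueError(f"kmin={kmin} must be smaller than N={N}")
    rng = np.random.default_rng(seed)
    kmax = N - 1
    pmf = truncated_powerlaw_pmf(gamma, kmin, kmax)
    support = np.arange(kmin, kmax + 1)
    degrees = rng.choice(support, size=N, p=pmf)
    while degrees.sum() % 2 != 0:
        degrees[-1] = rng.choice(support, p=pmf)
    return DegreeSequence(tuple(int(d) for d in degrees), gamma=gamma, kmin=kmin)


def configuration_model_graph(deg: DegreeSequence | list[int], seed: int | None = 0) -> nx.Graph:
    """Random stub-matching realization of ``deg``, simplified.

    Self-loops are deleted and parallel edges collapsed after matching, so
    realized degrees never exceed the requested ones and the graph is
    simple.  For ``gamma > 3`` the distortion is O(1/N).
    """
    degrees = list(deg.degrees) if isinstance(deg, DegreeSequence) else list(deg)
    if sum(degrees) % 2 != 0:
        raise ValueError("degree sum must be even for stub matching")
    rng = np.random.default_rng(seed)
    multi = nx.configuration_model(degrees, seed=rng)
    g = nx.Graph()
    g.add_nodes_from(range(len(degrees)))
    g.add_edges_from((u, v) for u, v in multi.edges() if u != v)
    return g


def write_edge_list(g: nx.Graph, path) -> None:
    """Write ``u v`` pairs, one edge per line, ``#`` comments allowed."""
    with open(path, "w") as fh:
        fh.write(f"# nodes: {' '.join(str(v) for v in g.nodes())}\n")
        for u, v in g.edges():
            fh.write(f"{u} {v}\n")


def read_edge_list(path) -> nx.Graph:
    """Read a whitespace-separated edge list written by :func:`write_edge_list`.

    Node ids that parse as integers are stored as ``int``; a declared-node
    header comment (``# nodes: ...``) restores isolated nodes.  A malformed
    line raises :class:`ValueError` naming its line number.
    """

    def coerce(tok: str):
        try:
            return int(tok)
        except ValueError:
            return tok

    g = nx.Graph()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped:
                continue
            if stripped.startswith("#"):
                body = stripped.lstrip("#").strip()
                if body.startswith("nodes:"):
                    g.add_nodes_from(coerce(t) for t in body[len("nodes:"):].split())
                continue
            toks = stripped.split()
            if len(toks) != 2:
                raise ValueError(
                    f"{path}:{lineno}: expected two tokens per edge line, got {len(toks)}"
                )
            u, v = (coerce(t) for t in toks)
            g.add_edge(u, v)
    return g
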