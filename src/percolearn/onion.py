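"""Onion decomposition: layered refinement of the k-core.

The k-core index (coreness) groups nodes into shells; the onion
decomposition refines each shell by recording the peeling pass (*layer*) at
which a node is removed, exposing the internal core-periphery organization
that plain coreness misses.  Layer 1 is the outermost periphery; the
highest layer is the innermost core.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import pandas as pd

__all__ = [
    "OnionResult",
    "OnionSpectrum",
    "kcore_decomposition",
    "onion_decomposition",
    "onion_spectrum",
    "order_nodes_core_to_periphery",
]


@dataclass(frozen=True)
class OnionResult:
    coreness: dict
    layer: dict

    @property
    def n_layers(self) -> int:
        return len(set(self.layer.values()))

    def to_csv(self, path) -> None:
        nodes = sorted(self.layer)
        pd.DataFrame(
            {
                "node": nodes,
                "coreness": [self.coreness[v] for v in nodes],
                "layer": [self.layer[v] for v in nodes],
            }
        ).to_csv(path, index=False)


@dataclass(frozen=True)
class OnionSpectrum:
    layers: tuple[int, ...]
    counts: tuple[int, ...]
    fractions: tuple[float, ...]

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {"layer": self.layers, "count": self.counts, "fraction": self.fractions}
        ).to_csv(path, index=False)


def kcore_decomposition(g: nx.Graph) -> dict:
    """Standard repeated-pruning coreness for every node."""
    return dict(nx.core_number(g)) if g.number_of_nodes() else {}


def onion_decomposition(g: nx.Graph) -> OnionResult:
    """Peel the graph layer by layer.

    In each pass every remaining node whose residual degree is at most the
    current core value is removed simultaneously and assigned the current
    layer and core value.  When the residual minimum degree exceeds the
    core value, the core value is raised to it — so recorded core values
    coincide with the standard k-core index.
    """
    if g.number_of_nodes() == 0:
        return OnionResult({}, {})
    deg = dict(g.degree())
    remaining = set(g.nodes())
    coreness: dict = {}
    layer: dict = {}
    core = min(deg.values())
    current_layer = 0
    while remaining:
        current_layer += 1
        peel = {v for v in remaining if deg[v] <= core}
        for v in peel:
            layer[v] = current_layer
            coreness[v] = core
        for v in peel:
            for u in g.neighbors(v):
                if u in remaining and u not in peel:
                    deg[u] -= 1
        remaining -= peel
        if remaining:
            mindeg = min(deg[v] for v in remaining)
            if mindeg > core:
                core = mindeg
    return OnionResult(coreness, layer)


def onion_spectrum(res: OnionResult, N: int | None = None) -> OnionSpectrum:
    """Per-layer node counts and fractions (layers ascending)."""
    if N is None:
        N = len(res.layer)
    vals = sorted(set(res.layer.values()))
    counts = [sum(1 for l in res.layer.values() if l == v) for v in vals]
    return OnionSpectrum(tuple(vals), tuple(counts), tuple(c / N for c in counts))


def order_nodes_core_to_periphery(res: OnionResult) -> list:
    """Nodes by descending layer (inner core first), ties by ascending id."""
    return sorted(res.layer, key=lambda v: (-res.layer[v], v))
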