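"""Unsupervised phase classification of percolation configurations.

A subset ("bin") of 20 nodes is extracted from the state matrix, spread
with small Gaussian noise, embedded to two dimensions with t-SNE and split
into two clusters with k-means.  The cluster labels are aligned to the
ground-truth phase labels (cluster ids are arbitrary) and scored by the
mean Kronecker agreement

    alpha = (1 / n_states) * sum_i delta(yhat_i, y_i).

Bins taken from coherent onion layers — nodes that attach to the giant
component at comparable phi — cluster far better than bins straddling
layers, which is the point of the layer-guided sampling strategy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.cluster import KMeans
from sklearn.manifold import TSNE

from .percolation import LabelVector, StateMatrix

__all__ = [
    "SampleBin",
    "ClusterResult",
    "bin_nodes",
    "random_bins",
    "add_noise",
    "embed_2d",
    "cluster_two",
    "accuracy",
    "align_and_score",
    "trajectory_coherence",
    "cluster_bin",
    "layer_accuracy_scan",
    "select_high_fidelity_bins",
]


@dataclass(frozen=True)
class SampleBin:
    """An ordered node subset with its provenance ("layers ..." or "random")."""

    nodes: tuple
    provenance: str
    bin_index: int

    def __post_init__(self) -> None:
        if len(self.nodes) < 1:
            raise ValueError("a bin must contain at least one node")
        if len(set(self.nodes)) != len(self.nodes):
            raise ValueError("bin node ids must be unique")


@dataclass
class ClusterResult:
    embedding: np.ndarray
    yhat: np.ndarray
    alpha: float


def bin_nodes(ordered, bin_size: int = 20, provenance: str = "layers") -> list[SampleBin]:
    """Consecutive disjoint bins (1-20, 21-40, ...) covering every node.

    The last bin may be smaller; order within bins is preserved so bins of
    a core-to-periphery ordering inherit the layer structure.
    """
    if bin_size < 1:
        raise ValueError("bin_size must be >= 1")
    ordered = list(ordered)
    bins = []
    for i in range(0, len(ordered), bin_size):
        chunk = tuple(ordered[i : i + bin_size])
        bins.append(
            SampleBin(chunk, f"{provenance}[{i}:{i + len(chunk)}]", len(bins))
        )
    return bins


def random_bins(nodes, size: int, n_bins: int, seed: int | None = 0) -> list[SampleBin]:
    """``n_bins`` independent uniform samples of ``size`` nodes (no replacement
    within a bin), irrespective of layer position."""
    nodes = list(nodes)
    if size > len(nodes):
        raise ValueError(f"bin size {size} exceeds number of nodes {len(nodes)}")
    rng = np.random.default_rng(seed)
    return [
        SampleBin(
            tuple(nodes[j] for j in rng.choice(len(nodes), size=size, replace=False)),
            "random",
            i,
        )
        for i in range(n_bins)
    ]


def add_noise(Xsub: np.ndarray, sigma2: float = 0.01, seed: int | None = 0) -> np.ndarray:
    """Add i.i.d. N(0, sigma2) noise to spread the binary points."""
    if sigma2 < 0:
        raise ValueError("sigma2 must be non-negative")
    Xsub = np.asarray(Xsub, dtype=float)
    if sigma2 == 0:
        return Xsub
    rng = np.random.default_rng(seed)
    return Xsub + rng.normal(0.0, np.sqrt(sigma2), size=Xsub.shape)


def embed_2d(
    Xnoisy: np.ndarray,
    perplexity: float = 30,
    seed: int | None = 0,
    max_iter: int = 500,
    init: str = "random",
    learning_rate: float = 200.0,
) -> np.ndarray:
    """2-D t-SNE embedding of the configurations (rows).

    The classical t-SNE setting (random initialization, learning rate 200)
    is the default: deliberately stochastic, it fragments incoherent bins
    into multiple islands, which is precisely the failure mode the
    layer-guided sampling is designed to avoid.  500 iterations is ample
    for ~1000 points; PCA initialization is available via ``init`` and
    yields more reproducible but systematically easier embeddings.
    """
    Xnoisy = np.asarray(Xnoisy, dtype=float)
    M = Xnoisy.shape[0]
    if M < 4:
        raise ValueError(f"need at least 4 configurations, got {M}")
    if perplexity >= M:
        raise ValueError(f"perplexity {perplexity} must be smaller than M={M}")
    tsne = TSNE(
        n_components=2,
        perplexity=perplexity,
        random_state=seed,
        init=init,
        learning_rate=learning_rate,
        max_iter=max_iter,
    )
    return tsne.fit_transform(Xnoisy)


def cluster_two(points: np.ndarray, seed: int | None = 0) -> np.ndarray:
    """2-means partition of the embedded configurations; labels in {0,1}."""
    points = np.asarray(points, dtype=float)
    if points.shape[0] < 2:
        raise ValueError("need at least 2 points to split into two clusters")
    km = KMeans(n_clusters=2, n_init=10, random_state=seed)
    return km.fit_predict(points).astype(np.uint8)


def accuracy(yhat, y) -> float:
    yhat = np.asarray(yhat)
    y = np.asarray(y)
    if yhat.shape != y.shape:
        raise ValueError(f"length mismatch: {yhat.shape} vs {y.shape}")
    return float(np.mean(yhat == y))


def align_and_score(yhat, y) -> float:
    """Accuracy after the best of the two cluster-to-phase assignments.

    Cluster ids carry no phase meaning, so the score is the maximum of
    alpha(yhat, y) and alpha(1 - yhat, y); it is therefore always >= 0.5.
    """
    yhat = np.asarray(yhat)
    return max(accuracy(yhat, y), accuracy(1 - yhat, y))


def trajectory_coherence(Xsub: np.ndarray) -> float:
    """Mean pairwise row-agreement between columns, in [0, 1].

    Columns (node trajectories) that attach/detach from the giant component
    at similar phi agree on most rows; 1 means identical trajectories.
    """
    Xsub = np.asarray(Xsub)
    M, n = Xsub.shape
    if n < 2:
        raise ValueError("need at least two columns")
    # agreement counts via Gram matrices of X and its complement
    X = Xsub.astype(float)
    agree = X.T @ X + (1 - X).T @ (1 - X)
    iu = np.triu_indices(n, k=1)
    return float(agree[iu].mean() / M)


def cluster_bin(
    X: StateMatrix,
    bin_: SampleBin,
    y: np.ndarray | None = None,
    sigma2: float = 0.01,
    perplexity: float = 30,
    seed: int | None = 0,
) -> ClusterResult:
    """noise -> t-SNE -> 2-means for one bin; alpha is NaN without labels."""
    ss = np.random.SeedSequence(seed).spawn(3)
    sub = X.columns(bin_.nodes)
    noisy = add_noise(sub, sigma2=sigma2, seed=ss[0])
    emb = embed_2d(noisy, perplexity=perplexity, seed=int(ss[1].generate_state(1)[0] % 2**31))
    yhat = cluster_two(emb, seed=int(ss[2].generate_state(1)[0] % 2**31))
    alpha = align_and_score(yhat, y) if y is not None else float("nan")
    return ClusterResult(emb, yhat, alpha)


def layer_accuracy_scan(
    X: StateMatrix,
    y: LabelVector | np.ndarray,
    bins: list[SampleBin],
    seed: int | None = 0,
    sigma2: float = 0.01,
    perplexity: float = 30,
) -> list[float]:
    """Per-bin clustering accuracy, bins in the given (core-to-periphery) order."""
    yv = y.y if isinstance(y, LabelVector) else np.asarray(y)
    seeds = np.random.SeedSequence(seed).spawn(len(bins))
    return [
        cluster_bin(
            X, b, yv, sigma2=sigma2, perplexity=perplexity,
            seed=int(s.generate_state(1)[0] % 2**31),
        ).alpha
        for b, s in zip(bins, seeds)
    ]


def refine_by_coherence(
    X: StateMatrix,
    bins: list[SampleBin],
    accs,
    tol: float = 0.01,
) -> tuple[SampleBin, float, float]:
    """Among bins whose accuracy ties the best within ``tol``, pick the most
    trajectory-coherent one; returns (bin, accuracy, coherence).

    Clustering accuracy saturates for every bin whose nodes mostly switch
    near the transition, so it cannot distinguish a tight step bundle from
    a bin carrying stragglers that detach far from it.  Downstream
    consumers that assume a single common step — the confusion sweep in
    particular — are unstable on straggler bins; coherence breaks the tie
    toward the bundle.
    """
    accs = np.asarray(accs, dtype=float)
    if len(accs) != len(bins):
        raise ValueError("accs must align with bins")
    near = np.flatnonzero(accs >= accs.max() - tol)
    coh = np.array(
        [
            trajectory_coherence(X.columns(bins[i].nodes)) if len(bins[i].nodes) >= 2 else 1.0
            for i in near
        ]
    )
    best = near[int(np.argmax(coh))]
    return bins[best], float(accs[best]), float(coh.max())


def select_high_fidelity_bins(
    X: StateMatrix,
    bins: list[SampleBin],
    mode: str = "coherence",
    y: LabelVector | np.ndarray | None = None,
    seed: int | None = 0,
) -> list[tuple[SampleBin, float]]:
    """Rank bins by expected clustering quality, best first.

    ``supervised`` ranks by the clustering accuracy against the ground-truth
    labels; ``coherence`` ranks by label-free trajectory coherence, which is
    what a practitioner without ground truth would use.  Ties keep the
    original bin order.
    """
    if mode == "supervised":
        if y is None:
            raise ValueError("supervised mode requires ground-truth labels y")
        scores = layer_accuracy_scan(X, y, bins, seed=seed)
    elif mode == "coherence":
        scores = [
            trajectory_coherence(X.columns(b.nodes)) if len(b.nodes) >= 2 else 1.0
            for b in bins
        ]
    else:
        raise ValueError(f"unknown mode {mode!r}")
    ranked = sorted(zip(bins, scores), key=lambda t: -t[1])
    return [(b, float(s)) for b, s in ranked]
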