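"""Confusion-scheme estimation of the critical occupation probability.

A synthetic label boundary is swept across the control-parameter range: at
each trial threshold the configurations are labeled 0 (phi >= threshold)
or 1 (phi < threshold) and a small feed-forward classifier is trained to
reproduce those labels from a high-fidelity node sample.  Test accuracy is
high at both sweep endpoints (labels nearly constant) and at the true
transition (labels match the data's real structure), producing a W-shaped
accuracy curve whose middle peak estimates phi_c.

Classifier: input layer of width = sample size, one hidden layer of 128
ReLU units with dropout 0.1, single sigmoid output, binary cross-entropy
loss, Adam with learning rate 1e-3.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ClassifierConfig",
    "ConfusionCurve",
    "PeakResult",
    "synthetic_labels",
    "train_eval_classifier",
    "confusion_sweep",
    "find_middle_peak",
]


@dataclass(frozen=True)
class ClassifierConfig:
    hidden_units: int = 128
    dropout_p: float = 0.1
    learning_rate: float = 1e-3
    epochs: int = 100
    batch_size: int = 32
    test_fraction: float = 0.2

    def __post_init__(self) -> None:
        if not 0 < self.test_fraction < 1:
            raise ValueError("test_fraction must lie in (0, 1)")
        if not 0 <= self.dropout_p < 1:
            raise ValueError("dropout_p must lie in [0, 1)")


@dataclass
class ConfusionCurve:
    """Threshold grid (ascending, constant step) with test accuracies."""

    thresholds: np.ndarray
    test_accuracy: np.ndarray
    phic_hat: float = float("nan")
    low_confidence: bool = False

    @property
    def n_steps(self) -> int:
        """Number of increments in the sweep (grid points minus one)."""
        return len(self.thresholds) - 1

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {"threshold": self.thresholds, "test_accuracy": self.test_accuracy}
        ).to_csv(path, index=False)


@dataclass(frozen=True)
class PeakResult:
    phic_hat: float
    low_confidence: bool


def synthetic_labels(phis, threshold: float) -> np.ndarray:
    """Trial labels: 0 where phi >= threshold, 1 where phi < threshold."""
    if not 0 <= threshold <= 1:
        raise ValueError(f"threshold must lie in [0, 1], got {threshold}")
    return (np.asarray(phis, dtype=float) < threshold).astype(np.uint8)


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def train_eval_classifier(
    Xsub: np.ndarray,
    labels: np.ndarray,
    cfg: ClassifierConfig | None = None,
    seed: int | None = 0,
) -> float:
    """Train the feed-forward classifier, return held-out accuracy.

    Random train/test split of the configurations (rows); fresh parameter
    initialization every call; decision threshold 0.5 on the sigmoid
    output.  Deterministic given the seed.
    """
    cfg = cfg or ClassifierConfig()
    X = np.asarray(Xsub, dtype=float)
    y = np.asarray(labels, dtype=float).ravel()
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValueError(f"shape mismatch: X {X.shape} vs labels {y.shape}")
    if X.shape[0] < 10:
        raise ValueError("need at least 10 configurations to train")

    rng = np.random.default_rng(seed)
    n, d = X.shape
    h = cfg.hidden_units
    perm = rng.permutation(n)
    n_test = max(1, int(round(cfg.test_fraction * n)))
    test_idx, train_idx = perm[:n_test], perm[n_test:]
    Xtr, ytr = X[train_idx], y[train_idx]
    Xte, yte = X[test_idx], y[test_idx]

    # He initialization
    W1 = rng.normal(0.0, np.sqrt(2.0 / d), size=(d, h))
    b1 = np.zeros(h)
    W2 = rng.normal(0.0, np.sqrt(2.0 / h), size=(h, 1))
    b2 = np.zeros(1)

    params = [W1, b1, W2, b2]
    m_adam = [np.zeros_like(p) for p in params]
    v_adam = [np.zeros_like(p) for p in params]
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    lr, p_drop = cfg.learning_rate, cfg.dropout_p
    step = 0
    n_train = len(train_idx)
    for _ in range(cfg.epochs):
        order = rng.permutation(n_train)
        for start in range(0, n_train, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            xb, yb = Xtr[idx], ytr[idx]
            B = len(idx)
            # forward
            a1 = xb @ W1 + b1
            h1 = np.maximum(a1, 0.0)
            if p_drop > 0:
                mask = (rng.random(h1.shape) >= p_drop) / (1.0 - p_drop)
                h1d = h1 * mask
            else:
                h1d = h1
            z = (h1d @ W2 + b2).ravel()
            p = _sigmoid(z)
            # backward (BCE): dL/dz = (p - y)/B
            dz = ((p - yb) / B)[:, None]
            gW2 = h1d.T @ dz
            gb2 = dz.sum(axis=0)
            dh = dz @ W2.T
            if p_drop > 0:
                dh = dh * mask
            da1 = dh * (a1 > 0)
            gW1 = xb.T @ da1
            gb1 = da1.sum(axis=0)
            step += 1
            for pth, g, mm, vv in zip(params, [gW1, gb1, gW2, gb2], m_adam, v_adam):
                mm *= beta1
                mm += (1 - beta1) * g
                vv *= beta2
                vv += (1 - beta2) * g * g
                mhat = mm / (1 - beta1**step)
                vhat = vv / (1 - beta2**step)
                pth -= lr * mhat / (np.sqrt(vhat) + eps)

    p_test = _sigmoid((np.maximum(Xte @ W1 + b1, 0.0) @ W2 + b2).ravel())
    return float(np.mean((p_test >= 0.5) == (yte >= 0.5)))


def confusion_sweep(
    Xsub: np.ndarray,
    phis,
    delta: float = 0.005,
    cfg: ClassifierConfig | None = None,
    seed: int | None = 0,
) -> ConfusionCurve:
    """Sweep the label boundary over [0, 1] in steps of ``delta``.

    With delta = 0.005 the sweep makes 200 increments (201 thresholds).
    Each threshold trains a freshly initialized classifier with its own
    sub-seed derived from the master seed.
    """
    n_steps = round(1.0 / delta)
    if abs(n_steps * delta - 1.0) > 1e-9:
        raise ValueError(f"delta={delta} does not divide 1")
    thresholds = np.linspace(0.0, 1.0, n_steps + 1)
    seeds = np.random.SeedSequence(seed).spawn(len(thresholds))
    accs = np.empty(len(thresholds))
    for i, (t, s) in enumerate(zip(thresholds, seeds)):
        labels = synthetic_labels(phis, t)
        accs[i] = train_eval_classifier(
            Xsub, labels, cfg=cfg, seed=int(s.generate_state(1)[0] % 2**31)
        )
    curve = ConfusionCurve(thresholds, accs)
    peak = find_middle_peak(curve)
    curve.phic_hat = peak.phic_hat
    curve.low_confidence = peak.low_confidence
    return curve


def find_middle_peak(
    curve: ConfusionCurve,
    boundary_exclusion: float = 0.05,
    smooth_window: int = 5,
) -> PeakResult:
    """Locate the interior (middle) peak of the W-shaped accuracy curve.

    The curve is smoothed by a centered moving average, a
    ``boundary_exclusion`` fraction of the grid is discarded at each end
    (the endpoint peaks are artifacts of near-constant labels), and the
    highest interior *local* maximum of the smoothed curve is returned,
    ties toward the smallest threshold.  Requiring a local maximum stops
    the tall endpoint arms, which decay monotonically into the interior,
    from capturing the estimate.  A flat or peak-free interior falls back
    to the plain interior argmax and is flagged low-confidence.
    """
    from scipy.signal import find_peaks

    t = np.asarray(curve.thresholds, dtype=float)
    a = np.asarray(curve.test_accuracy, dtype=float)
    if len(t) == 0:
        raise ValueError("empty curve")
    smooth = (
        pd.Series(a).rolling(smooth_window, center=True, min_periods=1).mean().to_numpy()
    )
    lo, hi = boundary_exclusion, 1.0 - boundary_exclusion
    interior = (t >= lo) & (t <= hi)
    if not interior.any():
        interior = np.ones_like(t, dtype=bool)
    ti, ai = t[interior], smooth[interior]
    if ai.max() - ai.min() < 1e-9:
        return PeakResult(float(ti[0]), True)
    # pad so a maximum at the interior edge still counts as a peak
    padded = np.r_[-np.inf, ai, -np.inf]
    peaks, _ = find_peaks(padded, plateau_size=1)
    peaks -= 1
    # the edge-padding trick can report the decaying boundary arms; keep
    # only genuine interior peaks unless nothing else exists
    genuine = [p for p in peaks if 0 < p < len(ai) - 1]
    if not genuine:
        best = np.flatnonzero(ai == ai.max())
        return PeakResult(float(ti[best].min()), True)
    heights = ai[genuine]
    top = np.flatnonzero(heights == heights.max())
    return PeakResult(float(min(ti[genuine[i]] for i in top)), False)
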