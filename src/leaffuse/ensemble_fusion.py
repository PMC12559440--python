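"""Fusing member-classifier probability outputs into one prediction.

Three fusion modes, in increasing order of adaptivity:

* **average** — elementwise mean of the member outputs O_1..O_N;
* **global** — fixed convex weights, Ô = Σ w_i · O_i with w on the
  N-simplex (these scalar weights are what the hyperparameter search in
  :mod:`leaffuse.nas_search` optimizes);
* **attention** — input-dependent weights α = softmax(W · concat(O_1..O_N))
  with a trainable matrix W ∈ R^{N×(N·K)}, so the better member can be
  emphasized per sample.  W is trained by minimizing categorical
  cross-entropy with Adagrad.

Every fused output is a convex combination of simplex points and therefore
stays on the K-simplex.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .synthetic_data import MemberOutputTable

__all__ = [
    "AttentionParams",
    "ScalarWeights",
    "attention_alpha",
    "attention_fuse",
    "average_fuse",
    "categorical_cross_entropy",
    "fit_attention",
    "fuse_table",
    "scalar_fuse",
]

PROB_CLIP = 1e-12  # floor applied to probabilities before taking logs


def _as_outputs(outputs) -> np.ndarray:
    """Stack member outputs into an (N, K) or (n, N, K) float array."""
    arr = np.asarray(outputs, dtype=float)
    if arr.ndim not in (2, 3):
        raise ValueError("expected a list of probability vectors")
    return arr


@dataclass(frozen=True)
class ScalarWeights:
    """Fixed per-model fusion weights on the N-simplex."""

    w: tuple[float, ...]

    def __post_init__(self) -> None:
        w = np.asarray(self.w, dtype=float)
        if np.any(w < -1e-12):
            raise ValueError("weights must be non-negative")
        if abs(w.sum() - 1.0) > 1e-9:
            raise ValueError("weights must sum to 1")

    @classmethod
    def from_w1(cls, w1: float) -> "ScalarWeights":
        """Two-model weights (w1, 1 - w1)."""
        return cls(w=(float(w1), float(1.0 - w1)))

    def as_array(self) -> np.ndarray:
        return np.asarray(self.w, dtype=float)


@dataclass
class AttentionParams:
    """Trainable attention matrix mapping concat(O_1..O_N) to N logits."""

    W: np.ndarray  # (N, N*K)

    def __post_init__(self) -> None:
        self.W = np.asarray(self.W, dtype=float)
        if self.W.ndim != 2 or not np.all(np.isfinite(self.W)):
            raise ValueError("W must be a finite 2-D matrix")

    @classmethod
    def zeros(cls, n_models: int, n_classes: int) -> "AttentionParams":
        return cls(W=np.zeros((n_models, n_models * n_classes)))

    @property
    def n_models(self) -> int:
        return self.W.shape[0]


def average_fuse(outputs) -> np.ndarray:
    """Averaging ensemble: elementwise mean of the member outputs."""
    arr = _as_outputs(outputs)
    return arr.mean(axis=-2)


def scalar_fuse(outputs, w: ScalarWeights) -> np.ndarray:
    """Fixed-weight ensemble Ô = Σ w_i · O_i (convex combination)."""
    arr = _as_outputs(outputs)
    wv = w.as_array()
    if arr.shape[-2] != len(wv):
        raise ValueError("number of weights must match number of members")
    return np.einsum("...nk,n->...k", arr, wv)


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def attention_alpha(params: AttentionParams, outputs) -> np.ndarray:
    """Input-dependent weights α = softmax(W · concat(O_1..O_N))."""
    arr = _as_outputs(outputs)
    concat = arr.reshape(*arr.shape[:-2], -1)  # (..., N*K)
    if concat.shape[-1] != params.W.shape[1]:
        raise ValueError(
            f"concatenated output length {concat.shape[-1]} does not match "
            f"attention matrix width {params.W.shape[1]}"
        )
    logits = concat @ params.W.T  # (..., N)
    return _softmax(logits)


def attention_fuse(params: AttentionParams, outputs) -> np.ndarray:
    """Attention ensemble Ô = Σ α_i · O_i with α from attention_alpha."""
    arr = _as_outputs(outputs)
    alpha = attention_alpha(params, arr)
    return np.einsum("...nk,...n->...k", arr, alpha)


def categorical_cross_entropy(y_onehot: np.ndarray, o_hat: np.ndarray) -> float:
    """L = −Σ_k Y_k log(Ô_k), probabilities floored at 1e-12 before the log."""
    y = np.asarray(y_onehot, dtype=float)
    o = np.clip(np.asarray(o_hat, dtype=float), PROB_CLIP, None)
    return float(-(y * np.log(o)).sum(axis=-1).mean())


@dataclass(frozen=True)
class AdagradConfig:
    lr: float = 0.01857
    initial_accumulator: float = 0.1
    eps: float = 1e-7


def fit_attention(
    params: AttentionParams,
    table: MemberOutputTable,
    optimizer: AdagradConfig = AdagradConfig(),
    epochs: int = 10,
    batch_size: int = 64,
    seed: int = 0,
) -> tuple[AttentionParams, list[float]]:
    """Train the attention matrix by cross-entropy minimization (Adagrad).

    Returns the parameters of the best-loss epoch and the per-epoch mean
    training loss.  With ``epochs=0`` the input parameters are returned
    unchanged.  Deterministic under ``seed``.
    """
    if table.n_samples == 0:
        raise ValueError("empty member-output table")
    W = params.W.copy()
    n_models, width = W.shape
    if width != table.n_models * table.n_classes:
        raise ValueError("attention matrix width does not match the table")
    probs = table.probs  # (n, N, K)
    concat = probs.reshape(table.n_samples, -1)
    y = table.true_class
    rng = np.random.default_rng(seed)
    acc = np.full_like(W, optimizer.initial_accumulator)
    losses: list[float] = []
    best_loss = np.inf
    best_W = W.copy()

    def epoch_loss(Wm: np.ndarray) -> float:
        alpha = _softmax(concat @ Wm.T)
        fused = np.einsum("nik,ni->nk", probs, alpha)
        p_true = np.clip(fused[np.arange(len(y)), y], PROB_CLIP, None)
        return float(-np.log(p_true).mean())

    for _ in range(epochs):
        order = rng.permutation(table.n_samples)
        for start in range(0, table.n_samples, batch_size):
            idx = order[start : start + batch_size]
            c = concat[idx]  # (b, N*K)
            p = probs[idx]  # (b, N, K)
            alpha = _softmax(c @ W.T)  # (b, N)
            fused = np.einsum("bik,bi->bk", p, alpha)
            p_true = np.clip(fused[np.arange(len(idx)), y[idx]], PROB_CLIP, None)
            # dL/dalpha_i = -O_i[y] / fused[y]; softmax jacobian to logits
            g_alpha = -p[np.arange(len(idx)), :, y[idx]] / p_true[:, None]
            inner = (alpha * g_alpha).sum(axis=1, keepdims=True)
            g_logits = alpha * (g_alpha - inner)  # (b, N)
            grad = g_logits.T @ c / len(idx)  # (N, N*K)
            acc += grad * grad
            W -= optimizer.lr * grad / (np.sqrt(acc) + optimizer.eps)
        loss = epoch_loss(W)
        losses.append(loss)
        if loss < best_loss:
            best_loss = loss
            best_W = W.copy()

    return AttentionParams(W=best_W), losses


def fuse_table(
    table: MemberOutputTable,
    mode: str = "average",
    weights: ScalarWeights | None = None,
    params: AttentionParams | None = None,
) -> np.ndarray:
    """Fuse every row of a member-output table; returns (n, K) probabilities."""
    if mode == "average":
        return average_fuse(table.probs)
    if mode == "global":
        if weights is None:
            raise ValueError("global mode requires scalar weights")
        return scalar_fuse(table.probs, weights)
    if mode == "attention":
        if params is None:
            raise ValueError("attention mode requires attention parameters")
        return attention_fuse(params, table.probs)
    raise ValueError(f"unknown fusion mode {mode!r}")


def fused_accuracy(table: MemberOutputTable, fused: np.ndarray) -> float:
    """Top-1 accuracy of fused outputs (lowest class index wins ties)."""
    pred = fused.argmax(axis=1)
    return float((pred == table.true_class).mean())
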