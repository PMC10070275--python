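"""A small feed-forward network with Adam, implemented on numpy.

The classifiers in this package are deliberately tiny (two hidden layers,
64 and 16 ReLU units, dropout only on the input layer), so a vectorized
numpy implementation is fast, dependency-free and bit-reproducible: every
random draw (weight init, batch shuffling, dropout masks) comes from one
``numpy.random.Generator``.
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np

Array = np.ndarray


def softmax_rows(Z: Array, T: float = 1.0) -> Array:
    """Row-wise tempered softmax, exp((z - max)/T) normalized per row."""
    if T <= 0:
        raise ValueError("temperature must be > 0")
    S = Z / T
    S = S - S.max(axis=1, keepdims=True)
    E = np.exp(S)
    return E / E.sum(axis=1, keepdims=True)


class MLPCore:
    """Weights + forward/backward for an input-dropout ReLU MLP.

    Layers: input -> (dropout p) -> [hidden_i, ReLU]* -> linear logits.
    He-normal initialization. ``backward`` expects the gradient of the loss
    with respect to the logits, already averaged over the batch.
    """

    def __init__(self, n_in: int, hidden: Sequence[int], n_out: int, rng: np.random.Generator):
        sizes = [n_in, *hidden, n_out]
        self.W = [
            rng.normal(0.0, np.sqrt(2.0 / sizes[i]), size=(sizes[i], sizes[i + 1]))
            for i in range(len(sizes) - 1)
        ]
        self.b = [np.zeros(sizes[i + 1]) for i in range(len(sizes) - 1)]
        # Adam state
        self._mW = [np.zeros_like(w) for w in self.W]
        self._vW = [np.zeros_like(w) for w in self.W]
        self._mb = [np.zeros_like(b) for b in self.b]
        self._vb = [np.zeros_like(b) for b in self.b]
        self._t = 0

    @property
    def n_in(self) -> int:
        return self.W[0].shape[0]

    @property
    def n_out(self) -> int:
        return self.W[-1].shape[1]

    def forward(
        self,
        X: Array,
        dropout: float = 0.0,
        rng: np.random.Generator | None = None,
    ) -> tuple[Array, list[Array]]:
        """Return (logits, activation cache). Dropout applies only when
        ``dropout > 0`` and an ``rng`` is supplied (training mode)."""
        if dropout > 0 and rng is not None:
            mask = (rng.random(X.shape) >= dropout) / (1.0 - dropout)
            A = X * mask
        else:
            A = X
        cache = [A]
        for i, (W, b) in enumerate(zip(self.W, self.b)):
            Z = A @ W + b
            if i < len(self.W) - 1:
                A = np.maximum(Z, 0.0)
                cache.append(A)
            else:
                A = Z
        return A, cache

    def backward(self, cache: list[Array], dlogits: Array) -> tuple[list[Array], list[Array]]:
        gW = [np.empty(0)] * len(self.W)
        gb = [np.empty(0)] * len(self.b)
        delta = dlogits
        for i in range(len(self.W) - 1, -1, -1):
            A_prev = cache[i]
            gW[i] = A_prev.T @ delta
            gb[i] = delta.sum(axis=0)
            if i > 0:
                delta = (delta @ self.W[i].T) * (cache[i] > 0)
        return gW, gb

    def adam_step(
        self,
        gW: list[Array],
        gb: list[Array],
        lr: float,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
    ) -> None:
        self._t += 1
        c1 = 1.0 - beta1**self._t
        c2 = 1.0 - beta2**self._t
        for i in range(len(self.W)):
            for g, w, m, v in (
                (gW[i], self.W[i], self._mW[i], self._vW[i]),
                (gb[i], self.b[i], self._mb[i], self._vb[i]),
            ):
                m *= beta1
                m += (1 - beta1) * g
                v *= beta2
                v += (1 - beta2) * g * g
                w -= lr * (m / c1) / (np.sqrt(v / c2) + eps)

    def get_weights(self) -> dict[str, Array]:
        out: dict[str, Array] = {}
        for i, (W, b) in enumerate(zip(self.W, self.b)):
            out[f"W{i}"] = W.copy()
            out[f"b{i}"] = b.copy()
        return out

    def set_weights(self, weights: dict[str, Array]) -> None:
        for i in range(len(self.W)):
            self.W[i] = np.array(weights[f"W{i}"], dtype=float)
            self.b[i] = np.array(weights[f"b{i}"], dtype=float)


GradFn = Callable[[Array, Array], tuple[Array, float]]
# (batch logits, batch row indices) -> (dL/dlogits averaged over batch, batch loss)


def train_loop(
    core: MLPCore,
    X: Array,
    grad_fn: GradFn,
    *,
    epochs: int,
    batch_size: int,
    learning_rate: float,
    dropout: float,
    rng: np.random.Generator,
    patience: int | None = None,
    tol: float = 1e-4,
) -> list[float]:
    """Mini-batch training driven by a pluggable logit-gradient callback.

    The callback receives batch logits and the batch's row indices into
    ``X`` and returns the mean-over-batch gradient on the logits plus the
    batch loss; cross-entropy and knowledge-distillation training differ
    only in this callback, so both consume the generator identically (one
    permutation per epoch, one dropout mask per batch).

    Early stopping (optional): stop when the epoch mean loss has not
    improved by more than ``tol`` for ``patience`` consecutive epochs.
    Returns the per-epoch mean loss trajectory.
    """
    n = X.shape[0]
    losses: list[float] = []
    best = np.inf
    stale = 0
    for epoch in range(epochs):
        order = rng.permutation(n)
        total = 0.0
        for start in range(0, n, batch_size):
            idx = order[start : start + batch_size]
            logits, cache = core.forward(X[idx], dropout=dropout, rng=rng)
            dlogits, loss = grad_fn(logits, idx)
            if not np.isfinite(loss):
                raise FloatingPointError(f"non-finite training loss at epoch {epoch}")
            gW, gb = core.backward(cache, dlogits)
            core.adam_step(gW, gb, lr=learning_rate)
            total += loss * len(idx)
        losses.append(total / n)
        if patience is not None:
            if losses[-1] < best - tol:
                best = losses[-1]
                stale = 0
            else:
                stale += 1
                if stale >= patience:
                    break
    return losses
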