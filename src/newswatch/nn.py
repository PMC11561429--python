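"""Minimal feed-forward machinery for the two trainable heads.

Both trainable components in the package are the same shape: a fixed encoder
produces feature vectors, and a two-layer head (affine -> ReLU -> affine ->
element-wise sigmoid) maps them to independent per-output probabilities,
trained with (optionally masked) binary cross-entropy under Adam with a
linear-warmup/linear-decay learning-rate schedule.  Everything here is plain
numpy with analytic gradients; with fixed seeds all of it is bit-reproducible
on one machine.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np


def linear_warmup_linear_decay(step: int, total_steps: int, warmup_fraction: float) -> float:
    """LR multiplier in [0, 1]: linear ramp to 1 at the warmup boundary, then linear decay to 0.

    *step* is 1-based (the step about to be taken); the multiplier is exactly 1
    at ``ceil(warmup_fraction * total_steps)`` and exactly 0 at the final step
    when ``total_steps`` is reached.
    """
    if total_steps <= 0:
        return 0.0
    warmup_steps = max(1, int(np.ceil(warmup_fraction * total_steps)))
    if step <= warmup_steps:
        return step / warmup_steps
    if total_steps == warmup_steps:
        return 1.0
    return max(0.0, (total_steps - step) / (total_steps - warmup_steps))


@dataclass
class SigmoidMLP:
    """Affine(d_in -> hidden) -> ReLU -> Affine(hidden -> d_out) -> sigmoid."""

    W1: np.ndarray
    b1: np.ndarray
    W2: np.ndarray
    b2: np.ndarray

    @classmethod
    def init(cls, d_in: int, hidden: int, d_out: int, seed: int = 0) -> "SigmoidMLP":
        rng = np.random.default_rng(seed)
        return cls(
            W1=rng.normal(0.0, np.sqrt(2.0 / d_in), size=(d_in, hidden)),
            b1=np.zeros(hidden),
            W2=rng.normal(0.0, np.sqrt(2.0 / hidden), size=(hidden, d_out)),
            b2=np.zeros(d_out),
        )

    def forward(self, X: np.ndarray) -> np.ndarray:
        """Probabilities in (0, 1), shape (n, d_out)."""
        H = np.maximum(X @ self.W1 + self.b1, 0.0)
        z = H @ self.W2 + self.b2
        return _sigmoid(z)

    def loss_and_grads(
        self, X: np.ndarray, Y: np.ndarray, mask: np.ndarray | None = None
    ) -> tuple[float, dict[str, np.ndarray]]:
        """Masked mean BCE and its gradients.

        *mask* (same shape as Y) selects which (example, output) cells carry a
        label; masked-out cells contribute exactly zero loss and gradient.
        """
        H_pre = X @ self.W1 + self.b1
        H = np.maximum(H_pre, 0.0)
        P = _sigmoid(H @ self.W2 + self.b2)
        if mask is None:
            mask = np.ones_like(P)
        n_obs = float(mask.sum())
        if n_obs == 0:
            zero = {k: np.zeros_like(v) for k, v in self.params().items()}
            return 0.0, zero
        eps = 1e-12
        bce = -(Y * np.log(P + eps) + (1.0 - Y) * np.log(1.0 - P + eps))
        loss = float((bce * mask).sum() / n_obs)
        dZ = (P - Y) * mask / n_obs  # d loss / d logits
        gW2 = H.T @ dZ
        gb2 = dZ.sum(axis=0)
        dH = dZ @ self.W2.T
        dH_pre = dH * (H_pre > 0.0)
        gW1 = X.T @ dH_pre
        gb1 = dH_pre.sum(axis=0)
        return loss, {"W1": gW1, "b1": gb1, "W2": gW2, "b2": gb2}

    def params(self) -> dict[str, np.ndarray]:
        return {"W1": self.W1, "b1": self.b1, "W2": self.W2, "b2": self.b2}

    def copy(self) -> "SigmoidMLP":
        return SigmoidMLP(self.W1.copy(), self.b1.copy(), self.W2.copy(), self.b2.copy())

    def load(self, other: "SigmoidMLP") -> None:
        self.W1, self.b1 = other.W1.copy(), other.b1.copy()
        self.W2, self.b2 = other.W2.copy(), other.b2.copy()


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


@dataclass
class Adam:
    """Adam optimizer over a named parameter dict."""

    lr: float = 1e-3
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8
    _m: dict = field(default_factory=dict)
    _v: dict = field(default_factory=dict)
    _t: int = 0

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray], lr_scale: float = 1.0) -> None:
        self._t += 1
        for name, p in params.items():
            g = grads[name]
            m = self._m.setdefault(name, np.zeros_like(p))
            v = self._v.setdefault(name, np.zeros_like(p))
            m += (1 - self.beta1) * (g - m)
            v += (1 - self.beta2) * (g * g - v)
            m_hat = m / (1 - self.beta1**self._t)
            v_hat = v / (1 - self.beta2**self._t)
            p -= self.lr * lr_scale * m_hat / (np.sqrt(v_hat) + self.eps)


def train_mlp(
    model: SigmoidMLP,
    X: np.ndarray,
    Y: np.ndarray,
    mask: np.ndarray | None,
    *,
    epochs: int,
    learning_rate: float,
    batch_size: int,
    warmup_fraction: float,
    seed: int,
    eval_fn: Callable[[SigmoidMLP], float] | None = None,
    eval_every_steps: int | None = None,
) -> list[dict]:
    """Mini-batch Adam training with early stopping on ``eval_fn`` (higher = better).

    Evaluates every *eval_every_steps* optimization steps (and at the end of
    every epoch); whenever the score improves, the parameters are
    checkpointed, and the best checkpoint is restored into *model* at the end.
    Returns the history of ``{"step", "epoch", "loss", "score"}`` records.
    """
    n = X.shape[0]
    if n == 0:
        raise ValueError("empty training set")
    rng = np.random.default_rng(seed)
    steps_per_epoch = int(np.ceil(n / batch_size))
    total_steps = epochs * steps_per_epoch
    optimizer = Adam(lr=learning_rate)
    history: list[dict] = []
    best_score = -np.inf
    best_params: SigmoidMLP | None = None
    step = 0
    last_loss = float("nan")

    def evaluate(loss: float, epoch: int) -> None:
        nonlocal best_score, best_params
        if eval_fn is None:
            return
        score = eval_fn(model)
        history.append({"step": step, "epoch": epoch, "loss": loss, "score": score})
        if score > best_score:
            best_score = score
            best_params = model.copy()

    for epoch in range(epochs):
        order = rng.permutation(n)
        for start in range(0, n, batch_size):
            batch = order[start : start + batch_size]
            loss, grads = model.loss_and_grads(
                X[batch], Y[batch], None if mask is None else mask[batch]
            )
            if not np.isfinite(loss):
                raise FloatingPointError(f"non-finite training loss at step {step}: {loss}")
            step += 1
            last_loss = loss
            lr_scale = linear_warmup_linear_decay(step, total_steps, warmup_fraction)
            optimizer.step(model.params(), grads, lr_scale)
            if eval_every_steps and step % eval_every_steps == 0:
                evaluate(loss, epoch)
            elif eval_fn is None:
                history.append({"step": step, "epoch": epoch, "loss": loss, "score": None})
        if steps_per_epoch:
            evaluate(last_loss, epoch)
    if best_params is not None:
        model.load(best_params)
    return history
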