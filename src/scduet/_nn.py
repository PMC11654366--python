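"""Minimal feed-forward network engine used by the doublet decomposer.

Implements exactly the components the decomposition networks need, on
numpy in single precision: dense layers with rectified-linear hidden
activations and a softmax output, categorical cross-entropy loss, and the
Adam optimizer.  The engine is deterministic given a seed: weight
initialization and mini-batch shuffling both come from one
``numpy.random.Generator``.

Weights are initialized uniformly on ``[-sqrt(1/fan_in), +sqrt(1/fan_in)]``
(fan-in scaling keeps pre-activation variance bounded at any width);
biases start at zero.
"""

from __future__ import annotations

import numpy as np

__all__ = ["relu", "softmax", "MLPClassifier"]


def relu(z: np.ndarray) -> np.ndarray:
    """Rectified linear unit, max(0, z)."""
    return np.maximum(z, 0.0)


def softmax(z: np.ndarray) -> np.ndarray:
    """Row-wise softmax, numerically stabilized by max subtraction."""
    z = np.asarray(z, dtype=np.float64)
    shifted = z - z.max(axis=-1, keepdims=True)
    e = np.exp(shifted)
    return e / e.sum(axis=-1, keepdims=True)


class MLPClassifier:
    """Fully connected softmax classifier trained with Adam.

    Parameters
    ----------
    input_dim, hidden_sizes, output_dim
        Layer widths; ``hidden_sizes`` may be any length >= 1.
    seed
        Seeds weight initialization and epoch shuffling.
    """

    def __init__(
        self,
        input_dim: int,
        hidden_sizes: tuple[int, ...],
        output_dim: int,
        seed: int = 0,
    ) -> None:
        if input_dim < 1 or output_dim < 1 or any(h < 1 for h in hidden_sizes):
            raise ValueError("all layer sizes must be >= 1")
        self.input_dim = int(input_dim)
        self.hidden_sizes = tuple(int(h) for h in hidden_sizes)
        self.output_dim = int(output_dim)
        self.seed = int(seed)
        self._rng = np.random.default_rng(seed)
        sizes = (self.input_dim, *self.hidden_sizes, self.output_dim)
        self.weights: list[np.ndarray] = []
        self.biases: list[np.ndarray] = []
        for fan_in, fan_out in zip(sizes[:-1], sizes[1:]):
            limit = np.sqrt(1.0 / fan_in)
            w = self._rng.uniform(-limit, limit, size=(fan_in, fan_out))
            self.weights.append(w.astype(np.float32))
            self.biases.append(np.zeros(fan_out, dtype=np.float32))
        self.loss_history_: list[float] = []
        self.val_loss_history_: list[float] = []

    # -- inference ---------------------------------------------------------

    def _forward(self, x: np.ndarray) -> tuple[list[np.ndarray], np.ndarray]:
        """Return per-layer post-ReLU activations and output probabilities."""
        acts = [x]
        h = x
        for w, b in zip(self.weights[:-1], self.biases[:-1]):
            h = relu(h @ w + b)
            acts.append(h)
        logits = h @ self.weights[-1] + self.biases[-1]
        return acts, softmax(logits)

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        """Class probabilities for a batch (or single vector)."""
        x = np.asarray(x, dtype=np.float32)
        single = x.ndim == 1
        if single:
            x = x[None, :]
        if x.shape[1] != self.input_dim:
            raise ValueError(
                f"expected {self.input_dim} features, got {x.shape[1]}"
            )
        _, proba = self._forward(x)
        return proba[0] if single else proba

    # -- training ----------------------------------------------------------

    def fit(
        self,
        x: np.ndarray,
        y: np.ndarray,
        *,
        epochs: int = 20,
        batch_size: int = 256,
        learning_rate: float = 1e-3,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
        x_val: np.ndarray | None = None,
        y_val: np.ndarray | None = None,
    ) -> "MLPClassifier":
        """Minimize categorical cross-entropy by mini-batch Adam.

        ``y`` holds integer class labels.  Mean training loss per epoch is
        recorded in ``loss_history_``; if a validation split is given, its
        per-epoch cross-entropy goes to ``val_loss_history_``.
        """
        x = np.ascontiguousarray(x, dtype=np.float32)
        y = np.asarray(y, dtype=np.int64)
        n = x.shape[0]
        if n < batch_size:
            raise ValueError(
                f"need at least batch_size={batch_size} samples, got {n}"
            )
        if y.max() >= self.output_dim:
            raise ValueError("label exceeds output dimension")

        params = self.weights + self.biases
        m = [np.zeros_like(p) for p in params]
        v = [np.zeros_like(p) for p in params]
        t = 0
        for _ in range(epochs):
            order = self._rng.permutation(n)
            epoch_loss = 0.0
            for start in range(0, n, batch_size):
                batch = order[start : start + batch_size]
                xb, yb = x[batch], y[batch]
                acts, proba = self._forward(xb)
                bsz = len(batch)
                eps_p = 1e-12
                epoch_loss += -np.log(proba[np.arange(bsz), yb] + eps_p).sum()

                # backprop: softmax + cross-entropy gives (p - onehot)/bsz
                delta = proba.astype(np.float32)
                delta[np.arange(bsz), yb] -= 1.0
                delta /= bsz
                grads_w: list[np.ndarray] = [None] * len(self.weights)
                grads_b: list[np.ndarray] = [None] * len(self.biases)
                for layer in range(len(self.weights) - 1, -1, -1):
                    grads_w[layer] = acts[layer].T @ delta
                    grads_b[layer] = delta.sum(axis=0)
                    if layer > 0:
                        delta = delta @ self.weights[layer].T
                        delta[acts[layer] <= 0] = 0.0

                t += 1
                grads = grads_w + grads_b
                lr_t = learning_rate * np.sqrt(1 - beta2**t) / (1 - beta1**t)
                for p, g, mi, vi in zip(params, grads, m, v):
                    mi *= beta1
                    mi += (1 - beta1) * g
                    vi *= beta2
                    vi += (1 - beta2) * np.square(g)
                    p -= lr_t * mi / (np.sqrt(vi) + eps)
            self.loss_history_.append(epoch_loss / n)
            if x_val is not None and y_val is not None and len(y_val):
                proba_val = self.predict_proba(np.asarray(x_val, dtype=np.float32))
                self.val_loss_history_.append(
                    float(
                        -np.log(
                            proba_val[np.arange(len(y_val)), y_val] + 1e-12
                        ).mean()
                    )
                )
        return self

    # -- persistence -------------------------------------------------------

    def state_dict(self) -> dict:
        state = {"hidden_sizes": list(self.hidden_sizes), "seed": self.seed}
        for i, (w, b) in enumerate(zip(self.weights, self.biases)):
            state[f"w{i}"] = w
            state[f"b{i}"] = b
        return state

    @classmethod
    def from_state_dict(cls, state: dict) -> "MLPClassifier":
        hidden = tuple(int(h) for h in state["hidden_sizes"])
        w0 = np.asarray(state["w0"])
        n_layers = len(hidden) + 1
        last_w = np.asarray(state[f"w{n_layers - 1}"])
        net = cls(w0.shape[0], hidden, last_w.shape[1], seed=int(state["seed"]))
        for i in range(n_layers):
            net.weights[i] = np.asarray(state[f"w{i}"], dtype=np.float32)
            net.biases[i] = np.asarray(state[f"b{i}"], dtype=np.float32)
        return net
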