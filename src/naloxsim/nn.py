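"""Minimal numpy neural-network engine: dense and LSTM layers with exact
backpropagation (through time) and an Adam optimizer.

Conventions: batches are leading axes; an LSTM consumes (B, T, D) and emits
(B, T, H).  Gate order in the packed weight matrices is input, forget, cell,
output.  All parameters live in flat ``{name: array}`` dicts so optimizers
and checkpoints stay trivial.  float64 throughout: these networks are small
and exact reproducibility across runs matters more than speed here.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Dense", "LSTM", "Adam", "sigmoid", "glorot"]


def sigmoid(x: np.ndarray) -> np.ndarray:
    # overflow in exp(-x) for very negative x harmlessly saturates to 0
    with np.errstate(over="ignore"):
        return 1.0 / (1.0 + np.exp(-x))


def glorot(rng: np.random.Generator, fan_in: int, fan_out: int,
           shape: tuple[int, ...] | None = None) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape or (fan_in, fan_out))


class Dense:
    """Affine layer with optional activation ('tanh', 'sigmoid', or None)."""

    def __init__(self, name: str, d_in: int, d_out: int,
                 rng: np.random.Generator, activation: str | None = "tanh"):
        self.name = name
        self.activation = activation
        self.params = {
            f"{name}.W": glorot(rng, d_in, d_out),
            f"{name}.b": np.zeros(d_out),
        }

    def forward(self, x: np.ndarray, params: dict) -> tuple[np.ndarray, tuple]:
        z = x @ params[f"{self.name}.W"] + params[f"{self.name}.b"]
        if self.activation == "tanh":
            y = np.tanh(z)
        elif self.activation == "sigmoid":
            y = sigmoid(z)
        else:
            y = z
        return y, (x, y)

    def backward(self, dy: np.ndarray, cache: tuple, params: dict,
                 grads: dict) -> np.ndarray:
        x, y = cache
        if self.activation == "tanh":
            dz = dy * (1.0 - y * y)
        elif self.activation == "sigmoid":
            dz = dy * y * (1.0 - y)
        else:
            dz = dy
        W = params[f"{self.name}.W"]
        flat_x = x.reshape(-1, x.shape[-1])
        flat_dz = dz.reshape(-1, dz.shape[-1])
        grads[f"{self.name}.W"] = grads.get(f"{self.name}.W", 0.0) + flat_x.T @ flat_dz
        grads[f"{self.name}.b"] = grads.get(f"{self.name}.b", 0.0) + flat_dz.sum(0)
        return dz @ W.T


class LSTM:
    """Single-layer LSTM unrolled over a fixed number of steps.

    Gate columns are packed [input, forget, output, cell] so the three
    logistic gates activate in one vectorized call.  Initial hidden/cell
    states are zero; the forget-gate bias starts at 1, a standard choice
    that keeps early gradients alive.
    """

    def __init__(self, name: str, d_in: int, hidden: int,
                 rng: np.random.Generator):
        self.name = name
        self.d_in = d_in
        self.hidden = hidden
        b = np.zeros(4 * hidden)
        b[hidden:2 * hidden] = 1.0  # forget gate
        self.params = {
            f"{name}.W": glorot(rng, d_in, 4 * hidden, (d_in, 4 * hidden)),
            f"{name}.U": glorot(rng, hidden, 4 * hidden, (hidden, 4 * hidden)),
            f"{name}.b": b,
        }

    def forward(self, x_seq: np.ndarray, params: dict) -> tuple[np.ndarray, tuple]:
        """x_seq: (B, T, D) -> h_seq: (B, T, H)."""
        name, H = self.name, self.hidden
        W, U, b = params[f"{name}.W"], params[f"{name}.U"], params[f"{name}.b"]
        B, T, _ = x_seq.shape
        xWb = x_seq @ W + b  # (B, T, 4H), precomputed for every step
        h = np.zeros((B, H))
        c = np.zeros((B, H))
        hs = np.empty((B, T, H))
        cache_steps = []
        for t in range(T):
            z = xWb[:, t] + h @ U
            gates = sigmoid(z[:, :3 * H])
            i = gates[:, :H]
            f = gates[:, H:2 * H]
            o = gates[:, 2 * H:]
            g = np.tanh(z[:, 3 * H:])
            c_new = f * c + i * g
            tanh_c = np.tanh(c_new)
            h_new = o * tanh_c
            cache_steps.append((h, c, gates, g, tanh_c))
            h, c = h_new, c_new
            hs[:, t] = h
        return hs, (x_seq, cache_steps)

    def backward(self, dh_seq: np.ndarray, cache: tuple, params: dict,
                 grads: dict) -> np.ndarray:
        """dh_seq: upstream gradient on every step's hidden output."""
        name, H = self.name, self.hidden
        W, U = params[f"{name}.W"], params[f"{name}.U"]
        x_seq, cache_steps = cache
        B, T, _ = x_seq.shape
        dW = np.zeros_like(W)
        dU = np.zeros_like(U)
        db = np.zeros(4 * H)
        dx_flat = np.empty((B * T, x_seq.shape[2]))
        dz_flat = np.empty((B * T, 4 * H))  # per-step gate grads, stacked
        dh_next = np.zeros((B, H))
        dc_next = np.zeros((B, H))
        for t in range(T - 1, -1, -1):
            h_prev, c_prev, gates, g, tanh_c = cache_steps[t]
            i = gates[:, :H]
            f = gates[:, H:2 * H]
            o = gates[:, 2 * H:]
            dh = dh_seq[:, t] + dh_next
            dc = dh * o * (1.0 - tanh_c * tanh_c) + dc_next
            dz = dz_flat[t * B:(t + 1) * B]
            dz[:, :H] = dc * g * i * (1 - i)
            dz[:, H:2 * H] = dc * c_prev * f * (1 - f)
            dz[:, 2 * H:3 * H] = dh * tanh_c * o * (1 - o)
            dz[:, 3 * H:] = dc * i * (1 - g * g)
            dU += h_prev.T @ dz
            dh_next = dz @ U.T
            dc_next = dc * f
        # batched accumulation over all steps at once
        x_flat = np.swapaxes(x_seq, 0, 1).reshape(B * T, -1)
        dW += x_flat.T @ dz_flat
        db += dz_flat.sum(0)
        np.matmul(dz_flat, W.T, out=dx_flat)
        dx_seq = np.swapaxes(dx_flat.reshape(T, B, -1), 0, 1)
        grads[f"{name}.W"] = grads.get(f"{name}.W", 0.0) + dW
        grads[f"{name}.U"] = grads.get(f"{name}.U", 0.0) + dU
        grads[f"{name}.b"] = grads.get(f"{name}.b", 0.0) + db
        return dx_seq


class Adam:
    """Adaptive-moment gradient descent over a parameter dict."""

    def __init__(self, params: dict, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, params: dict, grads: dict, clip_norm: float | None = 5.0) -> None:
        if clip_norm is not None:
            total = np.sqrt(sum(float(np.sum(g * g)) for g in grads.values()))
            if total > clip_norm:
                scale = clip_norm / total
                grads = {k: g * scale for k, g in grads.items()}
        self.t += 1
        b1t = 1.0 - self.beta1 ** self.t
        b2t = 1.0 - self.beta2 ** self.t
        for k, g in grads.items():
            self.m[k] = self.beta1 * self.m[k] + (1 - self.beta1) * g
            self.v[k] = self.beta2 * self.v[k] + (1 - self.beta2) * (g * g)
            params[k] -= self.lr * (self.m[k] / b1t) / (
                np.sqrt(self.v[k] / b2t) + self.eps)

    def state(self) -> dict:
        return {"t": self.t, "m": self.m, "v": self.v, "lr": self.lr}

    def load_state(self, state: dict) -> None:
        self.t = state["t"]
        self.m = state["m"]
        self.v = state["v"]
        self.lr = state.get("lr", self.lr)
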