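"""Minimal trainable layer stack for operational networks.

Forward and backward passes are written directly in numpy; every layer
caches what its backward pass needs.  Gradients are exact (verified against
central finite differences in the test suite).  The stack is deliberately
small: the networks built here have tens of thousands of parameters and run
comfortably on a single CPU.
"""

from __future__ import annotations

import io
import json
import zipfile
from typing import Sequence

import numpy as np

from .ops import _conv2d_backward, _conv2d_forward, _im2col, _pad_same

__all__ = [
    "Layer",
    "OperationalConv2d",
    "Tanh",
    "MaxPool2d",
    "Flatten",
    "Dense",
    "Sequential",
    "Adam",
    "softmax",
    "softmax_cross_entropy",
    "save_checkpoint",
    "load_checkpoint",
]


class Layer:
    """Base layer: parameter dict ``p`` mirrored by gradient dict ``g``."""

    def __init__(self):
        self.p: dict[str, np.ndarray] = {}
        self.g: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def zero_grad(self):
        for k, v in self.p.items():
            self.g[k] = np.zeros_like(v)


class OperationalConv2d(Layer):
    """Q-order operational convolution layer (same-padding, stride 1).

    Weights: (C_out, C_in, Q, k, k); output channel k is
    bias_k + sum_{i,q} corr((x_i - a)^q, W[k, i, q]).  Q = 1 reduces exactly
    to a standard convolution layer.

    Initialization is symmetric uniform with fan-in scaling, the same bound
    1/sqrt(C_in * k_h * k_w) applied independently to each q-slice, so the
    Q = 1 layer is initialized exactly like a standard convolution.
    """

    def __init__(self, c_in, c_out, kernel=3, q_order=3, shift=0.0, rng=None,
                 dtype=np.float32):
        super().__init__()
        if q_order < 1:
            raise ValueError(f"q_order must be >= 1, got {q_order}")
        rng = np.random.default_rng(rng)
        self.c_in, self.c_out = int(c_in), int(c_out)
        self.kh = self.kw = int(kernel)
        self.q_order = int(q_order)
        self.shift = float(shift)
        bound = 1.0 / np.sqrt(c_in * self.kh * self.kw)
        shape = (c_out, c_in, q_order, self.kh, self.kw)
        self.p["W"] = rng.uniform(-bound, bound, size=shape).astype(dtype)
        self.p["b"] = np.zeros(c_out, dtype=dtype)
        self.zero_grad()
        self._cache = None
        # the stack's first layer never needs a gradient wrt its input
        self.need_input_grad = True

    def forward(self, x):
        if x.ndim != 4 or x.shape[1] != self.c_in:
            raise ValueError(
                f"expected (N, {self.c_in}, H, W) input, got shape {x.shape}"
            )
        x = x.astype(self.p["W"].dtype, copy=False)
        n, _, h, w = x.shape
        base = x - self.shift
        powers = np.empty((n, self.c_in, self.q_order, h, w), dtype=base.dtype)
        powers[:, :, 0] = base
        for q in range(1, self.q_order):
            powers[:, :, q] = powers[:, :, q - 1] * base
        z = powers.reshape(n, self.c_in * self.q_order, h, w)
        zp = _pad_same(z, self.kh, self.kw)
        w2 = self.p["W"].reshape(self.c_out, -1)
        out, cols = _conv2d_forward(zp, w2, self.p["b"], self.kh, self.kw)
        self._cache = (base, powers, cols, zp.shape)
        return out

    def backward(self, grad):
        base, powers, cols, zp_shape = self._cache
        w2 = self.p["W"].reshape(self.c_out, -1)
        grad_zp, grad_w2, grad_b = _conv2d_backward(
            grad, cols, w2, zp_shape, self.kh, self.kw,
            need_input_grad=self.need_input_grad,
        )
        self.g["W"] += grad_w2.reshape(self.p["W"].shape)
        self.g["b"] += grad_b
        if not self.need_input_grad:
            return None
        ph, pw = (self.kh - 1) // 2, (self.kw - 1) // 2
        hp, wp = zp_shape[2], zp_shape[3]
        grad_z = grad_zp[:, :, ph : hp - ph, pw : wp - pw]
        n, _, h, w = base.shape
        grad_zq = grad_z.reshape(n, self.c_in, self.q_order, h, w)
        # d(x - a)^q / dx = q (x - a)^(q-1); powers[:, :, q-2] holds (x-a)^(q-1)
        grad_x = grad_zq[:, :, 0].copy()
        for q in range(2, self.q_order + 1):
            grad_x += q * grad_zq[:, :, q - 1] * powers[:, :, q - 2]
        return grad_x

    def spec(self):
        return {
            "kind": "opconv",
            "c_in": self.c_in,
            "c_out": self.c_out,
            "kernel": self.kh,
            "q_order": self.q_order,
            "shift": self.shift,
        }


class Tanh(Layer):
    def forward(self, x):
        out = np.tanh(x)
        self._out = out
        return out

    def backward(self, grad):
        return grad * (1.0 - self._out * self._out)

    def spec(self):
        return {"kind": "tanh"}


class MaxPool2d(Layer):
    """Max pooling with floor (non-ceil) output arithmetic."""

    def __init__(self, pool_size=2, stride=None):
        super().__init__()
        self.ph = self.pw = int(pool_size)
        self.stride = int(stride) if stride is not None else int(pool_size)

    def out_size(self, h, w):
        s = self.stride
        return (h - self.ph) // s + 1, (w - self.pw) // s + 1

    def forward(self, x):
        n, c, h, w = x.shape
        ho, wo = self.out_size(h, w)
        if ho < 1 or wo < 1:
            raise ValueError(
                f"pool {self.ph}x{self.pw}/{self.stride} collapses {h}x{w} input"
            )
        s = self.stride
        windows = np.lib.stride_tricks.sliding_window_view(
            x, (self.ph, self.pw), axis=(2, 3)
        )[:, :, ::s, ::s]
        flat = windows.reshape(n, c, ho, wo, self.ph * self.pw)
        idx = flat.argmax(axis=-1)
        out = np.take_along_axis(flat, idx[..., None], axis=-1)[..., 0]
        self._cache = (x.shape, idx, ho, wo)
        return out

    def backward(self, grad):
        x_shape, idx, ho, wo = self._cache
        n, c = x_shape[:2]
        grad_x = np.zeros(x_shape, dtype=grad.dtype)
        hi = (np.arange(ho) * self.stride)[None, None, :, None] + idx // self.pw
        wi = (np.arange(wo) * self.stride)[None, None, None, :] + idx % self.pw
        ni = np.arange(n)[:, None, None, None]
        ci = np.arange(c)[None, :, None, None]
        np.add.at(grad_x, (ni, ci, hi, wi), grad)
        return grad_x

    def spec(self):
        return {"kind": "maxpool", "pool_size": self.ph, "stride": self.stride}


class Flatten(Layer):
    def forward(self, x):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._shape)

    def spec(self):
        return {"kind": "flatten"}


class Dense(Layer):
    def __init__(self, n_in, n_out, rng=None, dtype=np.float32):
        super().__init__()
        rng = np.random.default_rng(rng)
        self.n_in, self.n_out = int(n_in), int(n_out)
        bound = 1.0 / np.sqrt(n_in)
        self.p["W"] = rng.uniform(-bound, bound, size=(n_out, n_in)).astype(dtype)
        self.p["b"] = np.zeros(n_out, dtype=dtype)
        self.zero_grad()

    def forward(self, x):
        x = x.astype(self.p["W"].dtype, copy=False)
        self._x = x
        return x @ self.p["W"].T + self.p["b"]

    def backward(self, grad):
        self.g["W"] += grad.T @ self._x
        self.g["b"] += grad.sum(axis=0)
        return grad @ self.p["W"]

    def spec(self):
        return {"kind": "dense", "n_in": self.n_in, "n_out": self.n_out}


class Sequential:
    """Ordered layer stack producing class logits."""

    def __init__(self, layers: Sequence[Layer], name: str = "model"):
        self.layers = list(layers)
        self.name = name
        if self.layers and isinstance(self.layers[0], OperationalConv2d):
            self.layers[0].need_input_grad = False

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    __call__ = forward

    def backward(self, grad: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    def predict_proba(self, x: np.ndarray, batch_size: int = 64) -> np.ndarray:
        out = [
            softmax(self.forward(x[i : i + batch_size]))
            for i in range(0, len(x), batch_size)
        ]
        return np.concatenate(out, axis=0)

    def zero_grad(self):
        for layer in self.layers:
            layer.zero_grad()

    def parameters(self):
        for i, layer in enumerate(self.layers):
            for key in layer.p:
                yield f"{i}.{key}", layer.p, key

    def num_parameters(self) -> int:
        return sum(p[k].size for _, p, k in self.parameters())

    def state_dict(self) -> dict[str, np.ndarray]:
        return {name: p[k].copy() for name, p, k in self.parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]):
        for name, p, k in self.parameters():
            if name not in state:
                raise KeyError(f"checkpoint missing parameter {name}")
            if state[name].shape != p[k].shape:
                raise ValueError(
                    f"shape mismatch for {name}: {state[name].shape} vs {p[k].shape}"
                )
            p[k] = state[name].astype(p[k].dtype, copy=True)

    def layer_specs(self):
        return [layer.spec() for layer in self.layers]


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, labels: np.ndarray):
    """Mean categorical cross-entropy of a SoftMax head.

    Returns (loss, grad wrt logits, probabilities); labels are integer class
    indices.
    """
    probs = softmax(logits.astype(np.float64))
    n = logits.shape[0]
    eps = 1e-12
    loss = -np.mean(np.log(probs[np.arange(n), labels] + eps))
    grad = probs.copy()
    grad[np.arange(n), labels] -= 1.0
    grad /= n
    return float(loss), grad.astype(logits.dtype), probs


class Adam:
    """Adaptive-moment optimizer (the training method used throughout)."""

    def __init__(self, model: Sequential, lr=5e-4, beta1=0.9, beta2=0.999, eps=1e-8):
        self.model = model
        self.lr = float(lr)
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = {name: np.zeros_like(p[k]) for name, p, k in model.parameters()}
        self.v = {name: np.zeros_like(p[k]) for name, p, k in model.parameters()}

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for i, layer in enumerate(self.model.layers):
            for key in layer.p:
                name = f"{i}.{key}"
                g = layer.g[key]
                self.m[name] = b1 * self.m[name] + (1 - b1) * g
                self.v[name] = b2 * self.v[name] + (1 - b2) * g * g
                mhat = self.m[name] / (1 - b1 ** self.t)
                vhat = self.v[name] / (1 - b2 ** self.t)
                layer.p[key] -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(
                    layer.p[key].dtype
                )


# ---------------------------------------------------------------------------
# checkpoint container
# ---------------------------------------------------------------------------


def save_checkpoint(model: Sequential, path, meta: dict | None = None):
    """Serialize a model: layer ordering/specs as JSON plus raw arrays.

    The container is a zip holding ``meta.json`` (layer specs, model name,
    extra metadata) and one ``.npy`` entry per parameter, keyed by layer
    index and parameter name.  Round-trip is exact.
    """
    header = {
        "name": model.name,
        "layers": model.layer_specs(),
        "meta": meta or {},
    }
    with zipfile.ZipFile(path, "w") as zf:
        zf.writestr("meta.json", json.dumps(header, indent=1))
        for name, p, k in model.parameters():
            buf = io.BytesIO()
            np.save(buf, p[k])
            zf.writestr(f"params/{name}.npy", buf.getvalue())


def load_checkpoint(path):
    """Load a checkpoint; returns (header dict, state dict of arrays)."""
    with zipfile.ZipFile(path, "r") as zf:
        header = json.loads(zf.read("meta.json"))
        state = {}
        for entry in zf.namelist():
            if entry.startswith("params/") and entry.endswith(".npy"):
                name = entry[len("params/") : -len(".npy")]
                state[name] = np.load(io.BytesIO(zf.read(entry)), allow_pickle=False)
    return header, state
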