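"""Generative-neuron primitives: Taylor-polynomial nodal operators and the
Q-order operational convolution.

A generative neuron replaces the fixed linear kernel product of a
convolutional neuron with a learned polynomial nodal operator

    Psi(w, y) = sum_{q=1..Q} w_q (y - a)^q

applied per connection before summation.  A standard convolution is the
Q = 1 special case.  The constant term of the polynomial is absorbed into
the per-channel layer bias (a per-connection constant is unidentifiable
next to the bias).  The shift ``a`` is zero when the surrounding activation
is tanh, which centres activations at the origin; it is kept as a field for
generality.

Convolution orientation is cross-correlation (no kernel flip), the
convention of every mainstream deep-learning framework; serialized weights
are unambiguous under this convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "NodalWeights",
    "OperationalLayerParams",
    "raise_to_powers",
    "nodal_transform",
    "operational_conv2d",
    "tanh_activate",
]


@dataclass
class NodalWeights:
    """Coefficients w_1..w_Q of one polynomial nodal operator plus shift a."""

    coeffs: np.ndarray
    shift: float = 0.0

    def __post_init__(self):
        self.coeffs = np.atleast_1d(np.asarray(self.coeffs, dtype=float))
        if self.coeffs.ndim != 1 or self.coeffs.size < 1:
            raise ValueError("coeffs must be a non-empty 1-D vector (w_1..w_Q)")

    @property
    def q_order(self) -> int:
        return int(self.coeffs.size)


@dataclass
class OperationalLayerParams:
    """Parameter bank of one operational layer.

    weights has shape (C_out, C_in, Q, k_h, k_w): one polynomial coefficient
    per output channel, input channel, polynomial order and kernel tap.
    """

    weights: np.ndarray
    bias: np.ndarray
    q_order: int
    shift: float = 0.0

    def __post_init__(self):
        self.weights = np.asarray(self.weights)
        self.bias = np.asarray(self.bias)
        if self.weights.ndim != 5:
            raise ValueError(
                f"weights must be rank-5 (C_out, C_in, Q, k_h, k_w); got rank {self.weights.ndim}"
            )
        if self.q_order < 1:
            raise ValueError(f"q_order must be >= 1, got {self.q_order}")
        if self.weights.shape[2] != self.q_order:
            raise ValueError(
                f"weights Q axis ({self.weights.shape[2]}) disagrees with q_order ({self.q_order})"
            )
        if self.bias.shape != (self.weights.shape[0],):
            raise ValueError(
                f"bias must have length C_out={self.weights.shape[0]}, got shape {self.bias.shape}"
            )
        if not (np.all(np.isfinite(self.weights)) and np.all(np.isfinite(self.bias))):
            raise ValueError("weights and bias must be finite")


def raise_to_powers(x: np.ndarray, q_order: int, shift: float = 0.0) -> np.ndarray:
    """Stack (x - shift)^q for q = 1..Q along a new leading axis.

    Slice q (1-based) is the element-wise q-th power of the shifted input;
    slice 1 is exactly ``x - shift``.
    """
    if not isinstance(q_order, (int, np.integer)) or q_order < 1:
        raise ValueError(f"q_order must be an integer >= 1, got {q_order!r}")
    x = np.asarray(x)
    if not np.all(np.isfinite(x)):
        raise ValueError("input contains non-finite values")
    base = x - shift
    out = np.empty((q_order,) + base.shape, dtype=base.dtype)
    out[0] = base
    for q in range(1, q_order):
        out[q] = out[q - 1] * base
    return out


def nodal_transform(y, w: NodalWeights):
    """Evaluate the nodal operator Psi(w, y) = sum_q w_q (y - a)^q.

    Accepts scalar or array ``y``; broadcasts element-wise.
    """
    if not isinstance(w, NodalWeights):
        w = NodalWeights(np.asarray(w))
    y = np.asarray(y, dtype=float)
    base = y - w.shift
    acc = np.zeros_like(base)
    power = np.ones_like(base)
    for coeff in w.coeffs:
        power = power * base
        acc = acc + coeff * power
    return acc if acc.ndim else float(acc)


def tanh_activate(x: np.ndarray) -> np.ndarray:
    """Element-wise hyperbolic tangent; the canonical Self-ONN activation.

    tanh maps into [-1, 1], which keeps the polynomial powers of the next
    operational layer bounded and justifies the shift a = 0.
    """
    x = np.asarray(x)
    if not np.all(np.isfinite(x)):
        raise ValueError("input contains non-finite values")
    return np.tanh(x)


# ---------------------------------------------------------------------------
# low-level cross-correlation machinery (im2col), shared with the nn layers
# ---------------------------------------------------------------------------


def _pad_same(x: np.ndarray, kh: int, kw: int) -> np.ndarray:
    """Zero-pad the two trailing spatial axes for size-preserving 'same' output.

    Requires odd kernel sizes (all layers here use 3x3).
    """
    ph, pw = (kh - 1) // 2, (kw - 1) // 2
    pad = [(0, 0)] * (x.ndim - 2) + [(ph, ph), (pw, pw)]
    return np.pad(x, pad, mode="constant")


def _im2col(x: np.ndarray, kh: int, kw: int) -> np.ndarray:
    """(N, C, H, W) -> (N, H_out*W_out, C*kh*kw) patch matrix, stride 1."""
    n, c, h, w = x.shape
    windows = np.lib.stride_tricks.sliding_window_view(x, (kh, kw), axis=(2, 3))
    # (N, C, Ho, Wo, kh, kw) -> (N, Ho, Wo, C, kh, kw) -> (N, Ho*Wo, C*kh*kw)
    ho, wo = windows.shape[2], windows.shape[3]
    cols = windows.transpose(0, 2, 3, 1, 4, 5).reshape(n, ho * wo, c * kh * kw)
    return np.ascontiguousarray(cols)


def _conv2d_forward(xp: np.ndarray, w2: np.ndarray, bias: np.ndarray, kh: int, kw: int):
    """Stride-1 valid cross-correlation on a pre-padded input.

    xp: (N, C, Hp, Wp) padded input; w2: (C_out, C*kh*kw) flattened kernels.
    Returns (out (N, C_out, Ho, Wo), cols) with cols cached for backward.
    """
    c_out = w2.shape[0]
    cols = _im2col(xp, kh, kw)
    n = xp.shape[0]
    ho = xp.shape[2] - kh + 1
    wo = xp.shape[3] - kw + 1
    # one flat GEMM over (N*L, K) rather than a strided batch of matmuls
    out = cols.reshape(n * ho * wo, -1) @ w2.T + bias
    out = out.reshape(n, ho, wo, c_out).transpose(0, 3, 1, 2)
    return out, cols


def _conv2d_backward(grad_out, cols, w2, xp_shape, kh, kw, need_input_grad=True):
    """Gradients of the stride-1 cross-correlation.

    grad_out: (N, C_out, Ho, Wo).  Returns (grad_xp, grad_w2, grad_bias);
    grad_xp on the padded input, or None when not requested.
    """
    n, c_out, ho, wo = grad_out.shape
    g2 = np.ascontiguousarray(grad_out.transpose(0, 2, 3, 1)).reshape(
        n * ho * wo, c_out
    )
    cols2 = cols.reshape(n * ho * wo, -1)
    grad_w2 = g2.T @ cols2
    grad_bias = g2.sum(axis=0)
    if not need_input_grad:
        return None, grad_w2, grad_bias
    grad_cols = (g2 @ w2).reshape(n, ho * wo, -1)  # (N, L, C*kh*kw)
    c = xp_shape[1]
    grad_cols = grad_cols.reshape(n, ho, wo, c, kh, kw)
    grad_xp = np.zeros(xp_shape, dtype=grad_out.dtype)
    for i in range(kh):
        for j in range(kw):
            grad_xp[:, :, i : i + ho, j : j + wo] += grad_cols[:, :, :, :, i, j].transpose(
                0, 3, 1, 2
            )
    return grad_xp, grad_w2, grad_bias


def operational_conv2d(
    x: np.ndarray, params: OperationalLayerParams, padding: str = "same"
) -> np.ndarray:
    """Q-order operational cross-correlation of a (C, H, W) feature map.

    Output channel k is  bias_k + sum_{i, q} corr((x_i - a)^q, weights[k, i, q])
    over input channels i and polynomial orders q.  With Q = 1 this is a
    standard convolution layer.
    """
    x = np.asarray(x)
    if x.ndim != 3:
        raise ValueError(f"expected a (C, H, W) feature map, got shape {x.shape}")
    c_out, c_in, q, kh, kw = params.weights.shape
    if x.shape[0] != c_in:
        raise ValueError(f"input has {x.shape[0]} channels, weights expect {c_in}")
    if padding not in ("same", "valid"):
        raise ValueError(f"unknown padding {padding!r}")
    powers = raise_to_powers(x, params.q_order, params.shift)  # (Q, C, H, W)
    z = powers.transpose(1, 0, 2, 3).reshape(1, c_in * q, x.shape[1], x.shape[2])
    if padding == "same":
        z = _pad_same(z, kh, kw)
    w2 = params.weights.reshape(c_out, c_in * q * kh * kw)
    out, _ = _conv2d_forward(
        z.astype(float), w2.astype(float), params.bias.astype(float), kh, kw
    )
    return out[0]
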