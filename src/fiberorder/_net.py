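"""Minimal feed-forward conv-net engine (numpy, CPU, single scalar output).

Supports the layer kinds the regression model needs — valid-mode strided
convolution, 2x2 average pooling, dense layers — with ReLU activations and
a logistic output unit, trained by Adam on mean squared error.  Everything
is float32 and deterministic for a fixed numpy Generator.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["ConvNet", "adam_step"]


def _gabor_bank(k: int, f: int, rng: np.random.Generator, wavelength: float = 4.0) -> np.ndarray:
    """Oriented Gabor filters (zero-mean, unit-norm) as a (k, k, f) stack.

    Filter j is tuned to fibers running along angle j*pi/f; alternating
    filters use the odd (sine) phase.  A small random perturbation breaks
    exact symmetry so training can differentiate the bank.
    """
    half = (k - 1) / 2.0
    yy, xx = np.mgrid[-half : half + 1, -half : half + 1]
    sigma = k / 4.0
    envelope = np.exp(-(xx**2 + yy**2) / (2 * sigma**2))
    bank = np.empty((k, k, f))
    for j in range(f):
        phi = j * np.pi / f  # fiber direction
        u = -np.sin(phi) * xx + np.cos(phi) * yy  # coordinate across the fiber
        carrier = np.cos if j % 2 == 0 else np.sin
        g = envelope * carrier(2 * np.pi * u / wavelength)
        g -= g.mean()
        g /= np.linalg.norm(g) + 1e-12
        bank[:, :, j] = g
    bank += 0.01 * rng.standard_normal(bank.shape)
    return bank


def _im2col(x: np.ndarray, k: int, stride: int) -> np.ndarray:
    """(N, C, H, W) -> (N, oh, ow, C*k*k) patches for valid convolution."""
    windows = sliding_window_view(x, (k, k), axis=(2, 3))[:, :, ::stride, ::stride]
    # (N, C, oh, ow, k, k) -> (N, oh, ow, C, k, k)
    windows = windows.transpose(0, 2, 3, 1, 4, 5)
    n, oh, ow = windows.shape[:3]
    return np.ascontiguousarray(windows).reshape(n, oh, ow, -1)


class ConvNet:
    """Small convolutional regression network with a logistic output.

    ``layers`` is an ordered list of descriptors::

        {"kind": "conv", "filters": F, "kernel": k, "stride": s}
        {"kind": "pool", "size": 2}
        {"kind": "dense", "width": W}

    The last dense layer must have width 1; its logistic squash bounds the
    prediction to (0, 1).
    """

    def __init__(self, input_size: int, layers: list[dict], rng: np.random.Generator):
        if layers[-1]["kind"] != "dense" or layers[-1]["width"] != 1:
            raise ValueError("last layer must be a dense layer of width 1")
        self.input_size = int(input_size)
        self.layers = [dict(l) for l in layers]
        self.params: dict[str, np.ndarray] = {}
        shape = (1, input_size, input_size)  # (C, H, W)
        flat = None
        for i, layer in enumerate(self.layers):
            kind = layer["kind"]
            if kind == "conv":
                c, h, w = shape
                k, s, f = layer["kernel"], layer.get("stride", 1), layer["filters"]
                fan_in = c * k * k
                if layer.get("init") == "gabor" and c == 1:
                    W = _gabor_bank(k, f, rng).reshape(fan_in, f)
                else:
                    W = rng.standard_normal((fan_in, f)) * np.sqrt(2.0 / fan_in)
                self.params[f"W{i}"] = W.astype(np.float32)
                self.params[f"b{i}"] = np.zeros(f, dtype=np.float32)
                oh = (h - k) // s + 1
                ow = (w - k) // s + 1
                if oh < 1 or ow < 1:
                    raise ValueError("feature map shrank below 1x1")
                shape = (f, oh, ow)
            elif kind == "pool":
                c, h, w = shape
                p = layer.get("size", 2)
                shape = (c, h // p, w // p)
            elif kind == "dense":
                if flat is None:
                    flat = int(np.prod(shape))
                width = layer["width"]
                scale = np.sqrt(2.0 / flat) if width > 1 else np.sqrt(1.0 / flat)
                self.params[f"W{i}"] = (
                    rng.standard_normal((flat, width)) * scale
                ).astype(np.float32)
                self.params[f"b{i}"] = np.zeros(width, dtype=np.float32)
                flat = width
            else:
                raise ValueError(f"unknown layer kind {kind!r}")

    # -- forward -----------------------------------------------------------

    def forward(self, x: np.ndarray, want_cache: bool = False):
        """Predictions in (0, 1) for a batch ``x`` of shape (N, H, W)."""
        a = np.asarray(x, dtype=np.float32)[:, None, :, :]  # (N, 1, H, W)
        cache = {"inputs": []}
        flat = None
        n_layers = len(self.layers)
        for i, layer in enumerate(self.layers):
            kind = layer["kind"]
            if kind == "conv":
                k, s = layer["kernel"], layer.get("stride", 1)
                in_shape = a.shape
                cols = _im2col(a, k, s)
                z = cols @ self.params[f"W{i}"] + self.params[f"b{i}"]
                if layer.get("activation", "relu") == "abs":
                    act, dact = np.abs(z), np.sign(z).astype(np.float32)
                else:
                    act, dact = np.maximum(z, 0.0), (z > 0)
                a = act.transpose(0, 3, 1, 2)
                if want_cache:
                    cache["inputs"].append((cols, in_shape, a.shape, dact))
            elif kind == "pool":
                p = layer.get("size", 2)
                n, c, h, w = a.shape
                h2, w2 = h // p, w // p
                trimmed = a[:, :, : h2 * p, : w2 * p]
                a = trimmed.reshape(n, c, h2, p, w2, p).mean(axis=(3, 5))
                if want_cache:
                    cache["inputs"].append(((n, c, h, w), p))
            elif kind == "dense":
                if flat is None:
                    cache["pre_flatten"] = a.shape
                    a = a.reshape(a.shape[0], -1)
                    flat = a.shape[1]
                z = a @ self.params[f"W{i}"] + self.params[f"b{i}"]
                if i == n_layers - 1:
                    pred = 1.0 / (1.0 + np.exp(-z[:, 0]))
                    if want_cache:
                        cache["inputs"].append((a, pred))
                    return (pred, cache) if want_cache else pred
                a_new = np.maximum(z, 0.0)
                if want_cache:
                    cache["inputs"].append((a, z > 0))
                a = a_new
                flat = a.shape[1]
        raise AssertionError("unreachable: last layer returns")

    # -- backward ----------------------------------------------------------

    def backward(self, cache: dict, dpred: np.ndarray) -> dict[str, np.ndarray]:
        """Gradients of the loss w.r.t. parameters, given d(loss)/d(pred)."""
        grads: dict[str, np.ndarray] = {}
        da = None
        for i in range(len(self.layers) - 1, -1, -1):
            layer = self.layers[i]
            kind = layer["kind"]
            stored = cache["inputs"][i]
            if kind == "dense":
                if i == len(self.layers) - 1:
                    a_in, pred = stored
                    dz = (dpred * pred * (1.0 - pred)).astype(np.float32)[:, None]
                else:
                    a_in, relu_mask = stored
                    dz = da * relu_mask
                grads[f"W{i}"] = a_in.T @ dz
                grads[f"b{i}"] = dz.sum(axis=0)
                da = dz @ self.params[f"W{i}"].T
                if i > 0 and self.layers[i - 1]["kind"] != "dense":
                    da = da.reshape(cache["pre_flatten"])
            elif kind == "pool":
                (n, c, h, w), p = stored
                h2, w2 = da.shape[2], da.shape[3]
                up = np.repeat(np.repeat(da, p, axis=2), p, axis=3) / (p * p)
                full = np.zeros((n, c, h, w), dtype=np.float32)
                full[:, :, : h2 * p, : w2 * p] = up
                da = full
            elif kind == "conv":
                cols, in_shape, out_shape, dact = stored
                k, s = layer["kernel"], layer.get("stride", 1)
                n, f, oh, ow = out_shape
                # dact has shape (N, oh, ow, F), matching z before transpose
                dz = (da.transpose(0, 2, 3, 1) * dact).reshape(-1, f)
                cols_mat = cols.reshape(-1, cols.shape[-1])
                grads[f"W{i}"] = cols_mat.T @ dz
                grads[f"b{i}"] = dz.sum(axis=0)
                if i > 0:  # no gradient needed w.r.t. the raw image
                    dcols = (dz @ self.params[f"W{i}"].T).reshape(n, oh, ow, -1)
                    prev_c = cols.shape[-1] // (k * k)
                    dcols = dcols.reshape(n, oh, ow, prev_c, k, k).transpose(0, 3, 1, 2, 4, 5)
                    dx = np.zeros(in_shape, dtype=np.float32)
                    for ki in range(k):
                        for kj in range(k):
                            dx[:, :, ki : ki + s * oh : s, kj : kj + s * ow : s] += dcols[
                                :, :, :, :, ki, kj
                            ]
                    da = dx
        return grads


def adam_step(
    params: dict[str, np.ndarray],
    grads: dict[str, np.ndarray],
    state: dict,
    lr: float,
    beta1: float = 0.9,
    beta2: float = 0.999,
    eps: float = 1e-8,
) -> None:
    """One in-place Adam update; ``state`` holds first/second moments and t."""
    state["t"] = state.get("t", 0) + 1
    t = state["t"]
    for key, g in grads.items():
        m = state.setdefault(f"m_{key}", np.zeros_like(params[key]))
        v = state.setdefault(f"v_{key}", np.zeros_like(params[key]))
        m += (1.0 - beta1) * (g - m)
        v += (1.0 - beta2) * (g * g - v)
        m_hat = m / (1.0 - beta1**t)
        v_hat = v / (1.0 - beta2**t)
        params[key] -= (lr * m_hat / (np.sqrt(v_hat) + eps)).astype(params[key].dtype)
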