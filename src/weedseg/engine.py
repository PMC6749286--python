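"""Numeric execution of a :class:`~weedseg.netgraph.NetworkGraph`.

Forward evaluation and reverse-mode gradients for every node kind, on float32
numpy arrays in ``(batch, height, width, channels)`` layout.  Convolutions are
evaluated through im2col views (``numpy.lib.stride_tricks.sliding_window_view``)
so the heavy lifting stays inside BLAS/einsum; gradients with respect to the
input are scattered tap-by-tap (a k*k loop), which is exact and cheap for the
3x3 kernels used throughout.

Padding follows the TensorFlow "same" convention: for stride 1 the spatial
dims are preserved; for stride 2 (even dims enforced upstream) one row/column
of zeros is appended at the bottom/right.

Batch normalisation keeps running mean/variance buffers (momentum 0.9) that
are updated during training-mode forwards and used verbatim in inference mode.
"""

from __future__ import annotations

from typing import Dict, Iterable, Optional, Tuple

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .netgraph import INPUT_ID, GraphNode, NetworkGraph

__all__ = ["init_weights", "forward", "backward", "Adam"]

BN_EPS = 1e-5
BN_MOMENTUM = 0.9

Arrays = Dict[str, np.ndarray]


# ---------------------------------------------------------------------------
# Initialisation
# ---------------------------------------------------------------------------

def init_weights(graph: NetworkGraph, seed: int) -> Tuple[Arrays, Arrays]:
    """Fan-in-scaled (He) random init; deterministic given ``seed``.

    Returns ``(weights, buffers)``: trainable arrays keyed ``"<node>.W"`` /
    ``".b"`` / ``".gamma"`` / ``".beta"`` and batch-norm running statistics
    keyed ``"<node>.mean"`` / ``".var"``.
    """
    rng = np.random.default_rng(seed)
    weights: Arrays = {}
    buffers: Arrays = {}
    for n in graph.nodes:
        if n.kind == "conv2d":
            fan_in = n.kernel ** 2 * n.in_channels
            weights[f"{n.id}.W"] = rng.normal(
                0.0, np.sqrt(2.0 / fan_in), (n.kernel, n.kernel, n.in_channels, n.out_channels)
            ).astype(np.float32)
            weights[f"{n.id}.b"] = np.zeros(n.out_channels, np.float32)
        elif n.kind == "depthwise_conv2d":
            # no bias: depthwise nodes feed BN or a pointwise conv, and a bias
            # here would defeat exact kernel tying across block stages
            fan_in = n.kernel ** 2
            weights[f"{n.id}.W"] = rng.normal(
                0.0, np.sqrt(2.0 / fan_in), (n.kernel, n.kernel, n.in_channels, n.depth_multiplier)
            ).astype(np.float32)
        elif n.kind == "pointwise_conv2d":
            weights[f"{n.id}.W"] = rng.normal(
                0.0, np.sqrt(2.0 / n.in_channels), (n.in_channels, n.out_channels)
            ).astype(np.float32)
            weights[f"{n.id}.b"] = np.zeros(n.out_channels, np.float32)
        elif n.kind == "batch_norm":
            c = n.out_channels or n.in_channels
            weights[f"{n.id}.gamma"] = np.ones(c, np.float32)
            weights[f"{n.id}.beta"] = np.zeros(c, np.float32)
            buffers[f"{n.id}.mean"] = np.zeros(c, np.float32)
            buffers[f"{n.id}.var"] = np.ones(c, np.float32)
    return weights, buffers


# ---------------------------------------------------------------------------
# Convolution helpers
# ---------------------------------------------------------------------------

def _pad_same(x: np.ndarray, k: int, stride: int) -> np.ndarray:
    if stride == 1:
        p = (k - 1) // 2
        pads = ((0, 0), (p, p), (p, p), (0, 0))
    else:  # stride 2, even dims: TF pads 0 at top/left, k-2 at bottom/right
        p = k - 2
        pads = ((0, 0), (0, p), (0, p), (0, 0))
    if all(a == 0 and b == 0 for a, b in pads):
        return x
    return np.pad(x, pads)


def _cols(xp: np.ndarray, k: int, stride: int) -> np.ndarray:
    # (N, Ho, Wo, C, k, k) strided view over the padded input
    v = sliding_window_view(xp, (k, k), axis=(1, 2))
    return v[:, ::stride, ::stride]


def _effective_dw_kernel(node: GraphNode, weights: Arrays) -> np.ndarray:
    W = weights[f"{node.id}.W"]
    if node.kernel_sources is None:
        return W
    slices = [
        weights[f"{src}.W"][:, :, sc, :] for src, sc in node.kernel_sources
    ]
    return np.stack(slices, axis=2)


# ---------------------------------------------------------------------------
# Forward
# ---------------------------------------------------------------------------

def forward(
    graph: NetworkGraph,
    weights: Arrays,
    buffers: Arrays,
    x: np.ndarray,
    training: bool = False,
    keep: bool = True,
) -> Tuple[Arrays, Dict[str, tuple]]:
    """Evaluate every node on batch ``x`` (N,H,W,C float32).

    Returns ``(activations, saved)`` where ``activations`` maps node id to its
    output and ``saved`` holds per-node tensors needed by :func:`backward`.
    In training mode batch-norm uses batch statistics and updates the running
    buffers in place.
    """
    acts: Arrays = {INPUT_ID: np.ascontiguousarray(x, dtype=np.float32)}
    saved: Dict[str, tuple] = {}
    for n in graph.nodes:
        ins = [acts[i] for i in n.inputs]
        if n.kind == "conv2d":
            xp = _pad_same(ins[0], n.kernel, n.stride)
            cols = _cols(xp, n.kernel, n.stride)
            W = weights[f"{n.id}.W"]
            y = np.einsum("nhwcij,ijco->nhwo", cols, W, optimize=True)
            y += weights[f"{n.id}.b"]
            saved[n.id] = (xp,)
            acts[n.id] = y
        elif n.kind == "depthwise_conv2d":
            xp = _pad_same(ins[0], n.kernel, n.stride)
            cols = _cols(xp, n.kernel, n.stride)
            W = _effective_dw_kernel(n, weights)
            y = np.einsum("nhwcij,ijcm->nhwcm", cols, W, optimize=True)
            y = y.reshape(y.shape[:3] + (n.out_channels,))
            saved[n.id] = (xp,)
            acts[n.id] = y
        elif n.kind == "pointwise_conv2d":
            xs = ins[0]
            if n.stride == 2:
                xs = xs[:, ::2, ::2]
            y = xs @ weights[f"{n.id}.W"] + weights[f"{n.id}.b"]
            saved[n.id] = (xs,)
            acts[n.id] = y
        elif n.kind == "avg_pool2x2":
            a = ins[0]
            N, H, W_, C = a.shape
            acts[n.id] = a.reshape(N, H // 2, 2, W_ // 2, 2, C).mean(axis=(2, 4))
        elif n.kind == "upscale2x":
            acts[n.id] = np.repeat(np.repeat(ins[0], 2, axis=1), 2, axis=2)
        elif n.kind == "concat":
            acts[n.id] = np.concatenate(ins, axis=3)
            saved[n.id] = tuple(a.shape[3] for a in ins)
        elif n.kind == "add":
            acts[n.id] = sum(ins[1:], start=ins[0].copy())
        elif n.kind == "batch_norm":
            a = ins[0]
            gamma = weights[f"{n.id}.gamma"]
            beta = weights[f"{n.id}.beta"]
            if training:
                mu = a.mean(axis=(0, 1, 2))
                var = a.var(axis=(0, 1, 2))
                buffers[f"{n.id}.mean"] = (
                    BN_MOMENTUM * buffers[f"{n.id}.mean"] + (1 - BN_MOMENTUM) * mu
                ).astype(np.float32)
                buffers[f"{n.id}.var"] = (
                    BN_MOMENTUM * buffers[f"{n.id}.var"] + (1 - BN_MOMENTUM) * var
                ).astype(np.float32)
            else:
                mu = buffers[f"{n.id}.mean"]
                var = buffers[f"{n.id}.var"]
            ivar = 1.0 / np.sqrt(var + BN_EPS)
            xhat = (a - mu) * ivar
            acts[n.id] = gamma * xhat + beta
            saved[n.id] = (xhat, ivar, training)
        elif n.kind == "relu":
            acts[n.id] = np.maximum(ins[0], 0.0)
        elif n.kind == "softmax":
            a = ins[0]
            e = np.exp(a - a.max(axis=3, keepdims=True))
            acts[n.id] = e / e.sum(axis=3, keepdims=True)
    if not keep:
        saved = {}
    return acts, saved


# ---------------------------------------------------------------------------
# Backward
# ---------------------------------------------------------------------------

def _unpad(dxp: np.ndarray, like: Tuple[int, ...], k: int, stride: int) -> np.ndarray:
    if stride == 1:
        p = (k - 1) // 2
        return dxp[:, p : p + like[1], p : p + like[2], :]
    return dxp[:, : like[1], : like[2], :]


def backward(
    graph: NetworkGraph,
    weights: Arrays,
    acts: Arrays,
    saved: Dict[str, tuple],
    seed_grads: Arrays,
) -> Arrays:
    """Reverse-mode sweep from ``seed_grads`` (node id -> dL/d(output)).

    Returns gradients for every trainable array reached by the sweep.  Nodes
    whose output never receives a gradient (dead branches, nodes after the
    seeding point) are skipped.
    """
    node_grads: Arrays = {k: v.astype(np.float32) for k, v in seed_grads.items()}
    param_grads: Arrays = {}

    def send(nid: str, g: np.ndarray) -> None:
        if nid in node_grads:
            node_grads[nid] = node_grads[nid] + g
        else:
            node_grads[nid] = g

    def addp(key: str, g: np.ndarray) -> None:
        if key in param_grads:
            param_grads[key] += g
        else:
            param_grads[key] = g

    for n in reversed(graph.nodes):
        g = node_grads.pop(n.id, None)
        if g is None:
            continue
        if n.kind == "conv2d":
            (xp,) = saved[n.id]
            k, s = n.kernel, n.stride
            cols = _cols(xp, k, s)
            W = weights[f"{n.id}.W"]
            addp(f"{n.id}.W", np.einsum("nhwcij,nhwo->ijco", cols, g, optimize=True))
            addp(f"{n.id}.b", g.sum(axis=(0, 1, 2)))
            Ho, Wo = g.shape[1], g.shape[2]
            dxp = np.zeros_like(xp)
            for i in range(k):
                for j in range(k):
                    dxp[:, i : i + s * Ho : s, j : j + s * Wo : s, :] += np.einsum(
                        "nhwo,co->nhwc", g, W[i, j], optimize=True
                    )
            send(n.inputs[0], _unpad(dxp, acts[n.inputs[0]].shape, k, s))
        elif n.kind == "depthwise_conv2d":
            (xp,) = saved[n.id]
            k, s, m = n.kernel, n.stride, n.depth_multiplier
            cols = _cols(xp, k, s)
            gr = g.reshape(g.shape[:3] + (n.in_channels, m))
            dW = np.einsum("nhwcij,nhwcm->ijcm", cols, gr, optimize=True)
            if n.kernel_sources is None:
                addp(f"{n.id}.W", dW)
            else:
                for c, (src, sc) in enumerate(n.kernel_sources):
                    key = f"{src}.W"
                    if key not in param_grads:
                        param_grads[key] = np.zeros_like(weights[key])
                    param_grads[key][:, :, sc, :] += dW[:, :, c, :]
            W = _effective_dw_kernel(n, weights)
            Ho, Wo = g.shape[1], g.shape[2]
            dxp = np.zeros_like(xp)
            for i in range(k):
                for j in range(k):
                    dxp[:, i : i + s * Ho : s, j : j + s * Wo : s, :] += np.einsum(
                        "nhwcm,cm->nhwc", gr, W[i, j], optimize=True
                    )
            send(n.inputs[0], _unpad(dxp, acts[n.inputs[0]].shape, k, s))
        elif n.kind == "pointwise_conv2d":
            (xs,) = saved[n.id]
            W = weights[f"{n.id}.W"]
            addp(f"{n.id}.W", np.einsum("nhwc,nhwo->co", xs, g, optimize=True))
            addp(f"{n.id}.b", g.sum(axis=(0, 1, 2)))
            dxs = g @ W.T
            if n.stride == 2:
                full = np.zeros_like(acts[n.inputs[0]])
                full[:, ::2, ::2] = dxs
                dxs = full
            send(n.inputs[0], dxs)
        elif n.kind == "avg_pool2x2":
            d = np.repeat(np.repeat(g, 2, axis=1), 2, axis=2) * 0.25
            send(n.inputs[0], d)
        elif n.kind == "upscale2x":
            N, H2, W2, C = g.shape
            send(n.inputs[0], g.reshape(N, H2 // 2, 2, W2 // 2, 2, C).sum(axis=(2, 4)))
        elif n.kind == "concat":
            sizes = saved[n.id]
            off = 0
            for inp, c in zip(n.inputs, sizes):
                send(inp, g[..., off : off + c])
                off += c
        elif n.kind == "add":
            for inp in n.inputs:
                send(inp, g)
        elif n.kind == "batch_norm":
            xhat, ivar, was_training = saved[n.id]
            gamma = weights[f"{n.id}.gamma"]
            addp(f"{n.id}.gamma", (g * xhat).sum(axis=(0, 1, 2)))
            addp(f"{n.id}.beta", g.sum(axis=(0, 1, 2)))
            dxhat = g * gamma
            if was_training:
                M = xhat.shape[0] * xhat.shape[1] * xhat.shape[2]
                dx = (
                    ivar
                    / M
                    * (
                        M * dxhat
                        - dxhat.sum(axis=(0, 1, 2))
                        - xhat * (dxhat * xhat).sum(axis=(0, 1, 2))
                    )
                )
            else:
                dx = dxhat * ivar
            send(n.inputs[0], dx.astype(np.float32))
        elif n.kind == "relu":
            send(n.inputs[0], g * (acts[n.id] > 0))
        elif n.kind == "softmax":
            p = acts[n.id]
            send(n.inputs[0], p * (g - (g * p).sum(axis=3, keepdims=True)))
    return param_grads


# ---------------------------------------------------------------------------
# Optimiser
# ---------------------------------------------------------------------------

class Adam:
    """Adaptive moment estimation over a dict of named arrays."""

    def __init__(self, lr: float = 1e-3, beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-8):
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.t = 0
        self.m: Arrays = {}
        self.v: Arrays = {}

    def step(self, weights: Arrays, grads: Arrays) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        corr1 = 1 - b1 ** self.t
        corr2 = 1 - b2 ** self.t
        for key, g in grads.items():
            m = self.m.get(key)
            if m is None:
                m = np.zeros_like(g)
                self.v[key] = np.zeros_like(g)
            v = self.v[key]
            m = b1 * m + (1 - b1) * g
            v = b2 * v + (1 - b2) * g * g
            self.m[key] = m
            self.v[key] = v
            weights[key] = weights[key] - self.lr * (m / corr1) / (
                np.sqrt(v / corr2) + self.eps
            )
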