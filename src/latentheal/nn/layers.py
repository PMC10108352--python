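"""Neural-network building blocks on top of the autodiff engine.

Convolutions are N-dimensional (the same code path serves 2D images and 3D
volumes): the forward pass extracts strided patches with
``sliding_window_view`` and reduces them with a single matmul; the backward
pass recomputes the patch matrix for the weight gradient and scatters the
column gradient back onto the (padded) input with one batched ``bincount``.
"""

from __future__ import annotations

import math

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .tensor import Tensor

__all__ = [
    "Module",
    "Linear",
    "ConvNd",
    "Embedding",
    "LayerNorm",
    "upsample_nearest",
    "depth_to_space",
    "layer_norm",
]

# cache of col2im flat-index maps keyed by geometry
_COL2IM_CACHE: dict[tuple, np.ndarray] = {}


def _conv_geometry(spatial, kernel, stride, padding):
    out = []
    for s_in, k in zip(spatial, kernel):
        span = s_in + 2 * padding - k
        if span % stride != 0:
            raise ValueError(
                f"conv geometry not exact: size {s_in}, kernel {k}, "
                f"stride {stride}, padding {padding}"
            )
        out.append(span // stride + 1)
    return tuple(out)


def _im2col(xp: np.ndarray, kernel, stride):
    """(N, C, *Spad) -> (N*P, C*prod(kernel)) patch matrix, P = prod(Sout)."""
    nd = len(kernel)
    win = sliding_window_view(xp, kernel, axis=tuple(range(2, 2 + nd)))
    sl = (slice(None), slice(None)) + tuple(slice(None, None, stride) for _ in range(nd))
    win = win[sl]  # (N, C, *Sout, *kernel)
    n, c = win.shape[0], win.shape[1]
    sout = win.shape[2 : 2 + nd]
    perm = (0,) + tuple(range(2, 2 + nd)) + (1,) + tuple(range(2 + nd, 2 + 2 * nd))
    cols = win.transpose(perm).reshape(n * int(np.prod(sout)), c * int(np.prod(kernel)))
    return np.ascontiguousarray(cols), sout


def _col2im_indices(c, spad, sout, kernel, stride):
    key = (c, spad, sout, kernel, stride)
    cached = _COL2IM_CACHE.get(key)
    if cached is not None:
        return cached
    nd = len(spad)
    base = [np.arange(so) * stride for so in sout]
    grids = np.meshgrid(*base, indexing="ij")  # spatial origin of each patch
    koffs = np.meshgrid(*[np.arange(k) for k in kernel], indexing="ij")
    p = int(np.prod(sout))
    kk = int(np.prod(kernel))
    per_dim = [
        grids[d].reshape(p, 1) + koffs[d].reshape(1, kk) for d in range(nd)
    ]
    flat_spatial = np.ravel_multi_index(tuple(per_dim), spad)  # (P, K)
    spad_size = int(np.prod(spad))
    idx = (np.arange(c)[:, None, None] * spad_size + flat_spatial[None]).transpose(1, 0, 2)
    idx = np.ascontiguousarray(idx.reshape(p, c * kk))
    _COL2IM_CACHE[key] = idx
    return idx


def convnd(x: Tensor, weight: Tensor, bias: Tensor, stride: int = 1, padding: int = 0) -> Tensor:
    """N-d cross-correlation of `x` (N, C, *S) with `weight` (O, C, *K)."""
    nd = weight.data.ndim - 2
    kernel = weight.data.shape[2:]
    n, c = x.data.shape[:2]
    spatial = x.data.shape[2:]
    if len(spatial) != nd or c != weight.data.shape[1]:
        raise ValueError(f"conv input {x.data.shape} incompatible with weight {weight.data.shape}")
    sout = _conv_geometry(spatial, kernel, stride, padding)
    o = weight.data.shape[0]
    pad_width = [(0, 0), (0, 0)] + [(padding, padding)] * nd
    xp = np.pad(x.data, pad_width) if padding else x.data
    cols, _ = _im2col(xp, kernel, stride)
    wmat = weight.data.reshape(o, -1).T  # (C*K, O)
    y = cols @ wmat + bias.data
    p = int(np.prod(sout))
    y = y.reshape((n,) + sout + (o,))
    y = np.moveaxis(y, -1, 1)
    spad = xp.shape[2:]

    def backward(g):
        gt = np.moveaxis(g, 1, -1).reshape(n * p, o)
        cols_b, _ = _im2col(xp, kernel, stride)  # recompute: cheaper than retaining
        gw = (cols_b.T @ gt).T.reshape(weight.data.shape)
        gb = gt.sum(axis=0)
        dcols = gt @ wmat.T  # (N*P, C*K)
        idx = _col2im_indices(c, spad, sout, kernel, stride)
        spad_size = c * int(np.prod(spad))
        offsets = (np.arange(n) * spad_size)[:, None]
        flat = (idx[None].reshape(1, p * idx.shape[1]) + offsets).ravel()
        acc = np.bincount(flat, weights=dcols.ravel(), minlength=n * spad_size)
        dxp = acc.reshape((n, c) + spad)
        if padding:
            sl = (slice(None), slice(None)) + tuple(
                slice(padding, padding + s) for s in spatial
            )
            dxp = dxp[sl]
        return dxp, gw, gb

    return Tensor._node(np.ascontiguousarray(y), (x, weight, bias), backward)


def upsample_nearest(x: Tensor, factor: int) -> Tensor:
    """Repeat each spatial cell `factor` times along every spatial axis."""
    nd = x.data.ndim - 2
    d = x.data
    for ax in range(2, 2 + nd):
        d = np.repeat(d, factor, axis=ax)
    n, c = x.data.shape[:2]
    spatial = x.data.shape[2:]

    def backward(g):
        shape = [n, c]
        for s in spatial:
            shape.extend([s, factor])
        g = g.reshape(shape)
        return (g.sum(axis=tuple(range(3, 2 + 2 * nd + 1, 2))),)

    return Tensor._node(d, (x,), backward)


def depth_to_space(x: Tensor, r: int) -> Tensor:
    """(N, c*r^nd, *S) -> (N, c, *S*r): move channel blocks into space.

    Composite of reshape/transpose, so the backward pass is free of
    scatter operations — the cheap way to upsample inside a decoder.
    """
    nd = x.ndim - 2
    n, c_full = x.shape[:2]
    spatial = x.shape[2:]
    c = c_full // (r**nd)
    if c * r**nd != c_full:
        raise ValueError(f"channels {c_full} not divisible by r^nd = {r**nd}")
    x = x.reshape((n, c) + (r,) * nd + spatial)
    perm = [0, 1]
    for d in range(nd):
        perm += [2 + nd + d, 2 + d]
    x = x.transpose(*perm)
    return x.reshape((n, c) + tuple(s * r for s in spatial))


def layer_norm(x: Tensor, gamma: Tensor, beta: Tensor, eps: float = 1e-5) -> Tensor:
    """Layer normalization over the last axis."""
    mu = x.data.mean(axis=-1, keepdims=True)
    xc = x.data - mu
    var = (xc * xc).mean(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    yhat = xc * inv
    out = yhat * gamma.data + beta.data
    m = x.data.shape[-1]

    def backward(g):
        gy = g * gamma.data
        dx = inv * (
            gy
            - gy.mean(axis=-1, keepdims=True)
            - yhat * (gy * yhat).mean(axis=-1, keepdims=True)
        )
        axes = tuple(range(g.ndim - 1))
        return dx, (g * yhat).sum(axis=axes), g.sum(axis=axes)

    return Tensor._node(out, (x, gamma, beta), backward)


class Module:
    """Container with recursive parameter discovery and flat state dicts."""

    def parameters(self) -> list[Tensor]:
        out: list[Tensor] = []
        for v in vars(self).values():
            if isinstance(v, Tensor) and v.requires_grad:
                out.append(v)
            elif isinstance(v, Module):
                out.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        out.extend(item.parameters())
                    elif isinstance(item, Tensor) and item.requires_grad:
                        out.append(item)
        return out

    def state_dict(self, prefix: str = "") -> dict[str, np.ndarray]:
        out: dict[str, np.ndarray] = {}
        for k, v in vars(self).items():
            if isinstance(v, Tensor) and v.requires_grad:
                out[prefix + k] = v.data
            elif isinstance(v, Module):
                out.update(v.state_dict(prefix + k + "."))
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Module):
                        out.update(item.state_dict(f"{prefix}{k}.{i}."))
                    elif isinstance(item, Tensor) and item.requires_grad:
                        out[f"{prefix}{k}.{i}"] = item.data
        return out

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        own = self._named_parameters("")
        missing = set(own) - set(state)
        if missing:
            raise KeyError(f"missing parameters in checkpoint: {sorted(missing)}")
        for name, tensor in own.items():
            arr = np.asarray(state[name], dtype=np.float64)
            if arr.shape != tensor.data.shape:
                raise ValueError(f"shape mismatch for {name}: {arr.shape} vs {tensor.data.shape}")
            tensor.data = arr.copy()

    def _named_parameters(self, prefix: str) -> dict[str, Tensor]:
        out: dict[str, Tensor] = {}
        for k, v in vars(self).items():
            if isinstance(v, Tensor) and v.requires_grad:
                out[prefix + k] = v
            elif isinstance(v, Module):
                out.update(v._named_parameters(prefix + k + "."))
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Module):
                        out.update(item._named_parameters(f"{prefix}{k}.{i}."))
                    elif isinstance(item, Tensor) and item.requires_grad:
                        out[f"{prefix}{k}.{i}"] = item
        return out


class Linear(Module):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator, zero_init: bool = False):
        if zero_init:
            w = np.zeros((d_in, d_out))
        else:
            w = rng.normal(0.0, math.sqrt(2.0 / d_in), size=(d_in, d_out))
        self.weight = Tensor(w, requires_grad=True)
        self.bias = Tensor(np.zeros(d_out), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class ConvNd(Module):
    def __init__(
        self,
        c_in: int,
        c_out: int,
        kernel: int,
        rng: np.random.Generator,
        stride: int = 1,
        padding: int = 0,
        ndim: int = 2,
    ):
        fan_in = c_in * kernel**ndim
        w = rng.normal(0.0, math.sqrt(2.0 / fan_in), size=(c_out, c_in) + (kernel,) * ndim)
        self.weight = Tensor(w, requires_grad=True)
        self.bias = Tensor(np.zeros(c_out), requires_grad=True)
        self.stride = stride
        self.padding = padding

    def __call__(self, x: Tensor) -> Tensor:
        return convnd(x, self.weight, self.bias, stride=self.stride, padding=self.padding)


class Embedding(Module):
    def __init__(self, vocab: int, dim: int, rng: np.random.Generator):
        self.weight = Tensor(rng.normal(0.0, 0.02, size=(vocab, dim)), requires_grad=True)

    def __call__(self, idx: np.ndarray) -> Tensor:
        from .tensor import embedding

        return embedding(self.weight, idx)


class LayerNorm(Module):
    def __init__(self, dim: int):
        self.gamma = Tensor(np.ones(dim), requires_grad=True)
        self.beta = Tensor(np.zeros(dim), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return layer_norm(x, self.gamma, self.beta)
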