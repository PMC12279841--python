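"""Neural-network building blocks on top of the autodiff engine.

Layout convention is NCHW throughout.  Convolutions are evaluated by an
im2col rearrangement followed by a single BLAS matmul; depthwise
convolutions and average pooling use a vectorised shift-and-accumulate
scheme, which is faster than im2col at their small kernel counts.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import as_strided

from . import tensor as T
from .tensor import Tensor

__all__ = [
    "Module",
    "ModuleList",
    "Sequential",
    "Conv2d",
    "DepthwiseConv2d",
    "BatchNorm2d",
    "ConvBNAct",
    "Linear",
    "conv2d",
    "depthwise_conv2d",
    "avg_pool2d",
    "global_avg_pool",
    "global_max_pool",
    "upsample_nearest",
]


# --------------------------------------------------------------------------- #
# functional convolutions
# --------------------------------------------------------------------------- #

def _im2col(xp: np.ndarray, k: int, stride: int, dilation: int):
    n, c, hp, wp = xp.shape
    ext = (k - 1) * dilation + 1
    ho = (hp - ext) // stride + 1
    wo = (wp - ext) // stride + 1
    sn, sc, sh, sw = xp.strides
    view = as_strided(
        xp,
        shape=(n, c, k, k, ho, wo),
        strides=(sn, sc, sh * dilation, sw * dilation, sh * stride, sw * stride),
    )
    return np.ascontiguousarray(view).reshape(n, c * k * k, ho * wo), ho, wo


def conv2d(x, w, b=None, stride: int = 1, padding: int = 0, dilation: int = 1):
    """2D cross-correlation.  ``w``: (Cout, Cin, k, k), ``b``: (Cout,)."""
    x = T.as_tensor(x)
    w = T.as_tensor(w)
    cout, cin, k, _ = w.shape
    xd = x.data
    if padding:
        xd = np.pad(xd, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    cols, ho, wo = _im2col(xd, k, stride, dilation)
    w2 = w.data.reshape(cout, cin * k * k)
    out = np.matmul(w2, cols)                       # (N, Cout, L)
    n = x.data.shape[0]
    out = out.reshape(n, cout, ho, wo)
    if b is not None:
        b = T.as_tensor(b)
        out = out + b.data.reshape(1, cout, 1, 1)

    parents = (x, w) if b is None else (x, w, b)

    def backward(g):
        gl = g.reshape(n, cout, ho * wo)
        if b is not None and b.requires_grad:
            b._accum(gl.sum(axis=(0, 2)))
        if w.requires_grad:
            dw2 = np.tensordot(gl, cols, axes=([0, 2], [0, 2]))
            w._accum(dw2.reshape(w.data.shape))
        if x.requires_grad:
            dcols = np.matmul(w2.T, gl)            # (N, Cin*k*k, L)
            dcols = dcols.reshape(n, cin, k, k, ho, wo)
            dxp = np.zeros_like(xd)
            for ki in range(k):
                hi = ki * dilation
                for kj in range(k):
                    wi = kj * dilation
                    dxp[:, :, hi:hi + ho * stride:stride, wi:wi + wo * stride:stride] += dcols[:, :, ki, kj]
            if padding:
                dxp = dxp[:, :, padding:-padding, padding:-padding]
            x._accum(dxp)

    return Tensor._make(out, parents, backward)


def depthwise_conv2d(x, w, b=None, padding: int = 0, dilation: int = 1):
    """Per-channel (depth-multiplier 1) convolution.  ``w``: (C, k, k)."""
    x = T.as_tensor(x)
    w = T.as_tensor(w)
    c, k, _ = w.shape
    xd = x.data
    if padding:
        xd = np.pad(xd, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    n, _, hp, wp = xd.shape
    ext = (k - 1) * dilation + 1
    ho, wo = hp - ext + 1, wp - ext + 1
    out = np.zeros((n, c, ho, wo), dtype=xd.dtype)
    for ki in range(k):
        for kj in range(k):
            out += w.data[:, ki, kj][None, :, None, None] * xd[
                :, :, ki * dilation:ki * dilation + ho, kj * dilation:kj * dilation + wo
            ]
    if b is not None:
        b = T.as_tensor(b)
        out = out + b.data.reshape(1, c, 1, 1)
    parents = (x, w) if b is None else (x, w, b)

    def backward(g):
        if b is not None and b.requires_grad:
            b._accum(g.sum(axis=(0, 2, 3)))
        if w.requires_grad:
            dw = np.empty_like(w.data)
            for ki in range(k):
                for kj in range(k):
                    patch = xd[:, :, ki * dilation:ki * dilation + ho, kj * dilation:kj * dilation + wo]
                    dw[:, ki, kj] = (g * patch).sum(axis=(0, 2, 3))
            w._accum(dw)
        if x.requires_grad:
            dxp = np.zeros_like(xd)
            for ki in range(k):
                for kj in range(k):
                    dxp[:, :, ki * dilation:ki * dilation + ho, kj * dilation:kj * dilation + wo] += (
                        w.data[:, ki, kj][None, :, None, None] * g
                    )
            if padding:
                dxp = dxp[:, :, padding:-padding, padding:-padding]
            x._accum(dxp)

    return Tensor._make(out, parents, backward)


def avg_pool2d(x, k: int):
    """k×k average pooling, stride 1, same spatial size.

    The divisor is the number of in-bounds cells of each window (padding is
    excluded from the average), so pooling a constant map returns that
    constant everywhere, borders included.
    """
    x = T.as_tensor(x)
    pad = k // 2
    xd = np.pad(x.data, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    n, c, hp, wp = xd.shape
    ho, wo = hp - k + 1, wp - k + 1
    ones = np.pad(np.ones((ho, wo), dtype=xd.dtype), ((pad, pad), (pad, pad)))
    counts = np.zeros((ho, wo), dtype=xd.dtype)
    out = np.zeros((n, c, ho, wo), dtype=xd.dtype)
    for ki in range(k):
        for kj in range(k):
            out += xd[:, :, ki:ki + ho, kj:kj + wo]
            counts += ones[ki:ki + ho, kj:kj + wo]
    out /= counts

    def backward(g):
        gk = g / counts
        dxp = np.zeros_like(xd)
        for ki in range(k):
            for kj in range(k):
                dxp[:, :, ki:ki + ho, kj:kj + wo] += gk
        x._accum(dxp[:, :, pad:-pad, pad:-pad] if pad else dxp)

    return Tensor._make(out, (x,), backward)


def global_avg_pool(x):
    return T.as_tensor(x).mean(axis=(2, 3), keepdims=True)


def global_max_pool(x):
    return T.as_tensor(x).max(axis=(2, 3), keepdims=True)


def upsample_nearest(x, scale: int):
    x = T.as_tensor(x)
    out = np.repeat(np.repeat(x.data, scale, axis=2), scale, axis=3)
    n, c, h, w = x.data.shape

    def backward(g):
        x._accum(g.reshape(n, c, h, scale, w, scale).sum(axis=(3, 5)))

    return Tensor._make(out, (x,), backward)


# --------------------------------------------------------------------------- #
# module system
# --------------------------------------------------------------------------- #

class Module:
    """Minimal container with parameter traversal and train/eval state."""

    def __init__(self):
        self.training = True

    def forward(self, *args, **kwargs):  # pragma: no cover - abstract
        raise NotImplementedError

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    def _children(self):
        for name, val in vars(self).items():
            if isinstance(val, Module):
                yield name, val
            elif isinstance(val, (list, tuple)):
                for i, item in enumerate(val):
                    if isinstance(item, Module):
                        yield f"{name}.{i}", item

    def named_parameters(self, prefix: str = ""):
        for name, val in vars(self).items():
            if isinstance(val, Tensor) and val.requires_grad:
                yield prefix + name, val
        for cname, child in self._children():
            yield from child.named_parameters(prefix + cname + ".")

    def parameters(self):
        for _, p in self.named_parameters():
            yield p

    def named_buffers(self, prefix: str = ""):
        for name, val in vars(self).items():
            if isinstance(val, np.ndarray):
                yield prefix + name, val
        for cname, child in self._children():
            yield from child.named_buffers(prefix + cname + ".")

    def modules(self):
        yield self
        for _, child in self._children():
            yield from child.modules()

    def train(self, mode: bool = True):
        for m in self.modules():
            m.training = mode
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def num_parameters(self) -> int:
        return int(sum(p.size for p in self.parameters()))

    def state_dict(self) -> dict:
        out = {name: p.data.copy() for name, p in self.named_parameters()}
        out.update({name: b.copy() for name, b in self.named_buffers()})
        return out

    def load_state_dict(self, state: dict):
        for name, p in self.named_parameters():
            p.data = np.asarray(state[name], dtype=p.data.dtype).reshape(p.data.shape)
        for name, b in self.named_buffers():
            b[...] = np.asarray(state[name]).reshape(b.shape)


class ModuleList(Module):
    def __init__(self, mods=()):
        super().__init__()
        self.items = list(mods)

    def append(self, m):
        self.items.append(m)

    def __iter__(self):
        return iter(self.items)

    def __getitem__(self, i):
        return self.items[i]

    def __len__(self):
        return len(self.items)


class Sequential(Module):
    def __init__(self, *mods):
        super().__init__()
        self.items = list(mods)

    def forward(self, x):
        for m in self.items:
            x = m(x)
        return x

    def __iter__(self):
        return iter(self.items)


def _he_init(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    std = np.sqrt(2.0 / fan_in)
    return rng.normal(0.0, std, size=shape).astype(np.float32)


class Conv2d(Module):
    def __init__(self, cin, cout, k=3, stride=1, padding=None, dilation=1, bias=True, rng=None):
        super().__init__()
        rng = rng or np.random.default_rng()
        self.stride = stride
        self.dilation = dilation
        self.padding = (k // 2) * dilation if padding is None else padding
        self.weight = Tensor(_he_init(rng, (cout, cin, k, k), cin * k * k), requires_grad=True)
        self.bias = Tensor(np.zeros(cout, dtype=np.float32), requires_grad=True) if bias else None

    def forward(self, x):
        return conv2d(x, self.weight, self.bias, self.stride, self.padding, self.dilation)


class DepthwiseConv2d(Module):
    def __init__(self, c, k=3, padding=None, dilation=1, bias=True, rng=None):
        super().__init__()
        rng = rng or np.random.default_rng()
        self.dilation = dilation
        self.padding = (k // 2) * dilation if padding is None else padding
        self.weight = Tensor(_he_init(rng, (c, k, k), k * k), requires_grad=True)
        self.bias = Tensor(np.zeros(c, dtype=np.float32), requires_grad=True) if bias else None

    def forward(self, x):
        return depthwise_conv2d(x, self.weight, self.bias, self.padding, self.dilation)


class BatchNorm2d(Module):
    def __init__(self, c, eps=1e-5, momentum=0.1):
        super().__init__()
        self.eps = eps
        self.momentum = momentum
        self.gamma = Tensor(np.ones(c, dtype=np.float32), requires_grad=True)
        self.beta = Tensor(np.zeros(c, dtype=np.float32), requires_grad=True)
        self.running_mean = np.zeros(c, dtype=np.float32)
        self.running_var = np.ones(c, dtype=np.float32)

    def forward(self, x):
        x = T.as_tensor(x)
        gamma, beta = self.gamma, self.beta
        if not self.training:
            scale = self.gamma.data / np.sqrt(self.running_var + self.eps)
            shift = self.beta.data - scale * self.running_mean
            out = x.data * scale.reshape(1, -1, 1, 1) + shift.reshape(1, -1, 1, 1)

            def backward_eval(g):
                if x.requires_grad:
                    x._accum(g * scale.reshape(1, -1, 1, 1))
                if gamma.requires_grad:
                    xhat = (x.data - self.running_mean.reshape(1, -1, 1, 1)) / np.sqrt(
                        self.running_var.reshape(1, -1, 1, 1) + self.eps)
                    gamma._accum((g * xhat).sum(axis=(0, 2, 3)))
                if beta.requires_grad:
                    beta._accum(g.sum(axis=(0, 2, 3)))

            return T.Tensor._make(out, (x, gamma, beta), backward_eval)

        # training mode: fused batch statistics with a hand-written backward
        axes = (0, 2, 3)
        m = x.data.shape[0] * x.data.shape[2] * x.data.shape[3]
        mu = x.data.mean(axis=axes, keepdims=True)
        var = ((x.data - mu) ** 2).mean(axis=axes, keepdims=True)
        self.running_mean += self.momentum * (mu.ravel() - self.running_mean)
        self.running_var += self.momentum * (var.ravel() - self.running_var)
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x.data - mu) * inv_std
        out = xhat * gamma.data.reshape(1, -1, 1, 1) + beta.data.reshape(1, -1, 1, 1)

        def backward_train(g):
            if gamma.requires_grad:
                gamma._accum((g * xhat).sum(axis=axes))
            if beta.requires_grad:
                beta._accum(g.sum(axis=axes))
            if x.requires_grad:
                gg = g * gamma.data.reshape(1, -1, 1, 1)
                gmean = gg.mean(axis=axes, keepdims=True)
                xdot = (gg * xhat).mean(axis=axes, keepdims=True)
                x._accum(inv_std * (gg - gmean - xhat * xdot))

        return T.Tensor._make(out, (x, gamma, beta), backward_train)


class ConvBNAct(Module):
    """Convolution + batch normalization + SiLU (the host detector's conv unit)."""

    def __init__(self, cin, cout, k=3, stride=1, padding=None, dilation=1, act=True, rng=None):
        super().__init__()
        self.conv = Conv2d(cin, cout, k, stride, padding, dilation, bias=False, rng=rng)
        self.bn = BatchNorm2d(cout)
        self.act = act

    def forward(self, x):
        y = self.bn(self.conv(x))
        return T.silu(y) if self.act else y


class Linear(Module):
    def __init__(self, fin, fout, bias=True, rng=None):
        super().__init__()
        rng = rng or np.random.default_rng()
        self.weight = Tensor(_he_init(rng, (fout, fin), fin), requires_grad=True)
        self.bias = Tensor(np.zeros(fout, dtype=np.float32), requires_grad=True) if bias else None

    def forward(self, x):
        y = x @ self.weight.swapaxes(0, 1) if isinstance(x, Tensor) else Tensor(x) @ self.weight.swapaxes(0, 1)
        if self.bias is not None:
            y = y + self.bias
        return y
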