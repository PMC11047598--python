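"""Minimal numpy layer library used by the detector graphs.

Every layer implements forward (with an optional training flag), an exact
backward pass, parameter/gradient dictionaries, and static shape / MAC
accounting so that whole graphs can be profiled without running them.

Conventions
-----------
* activations are ``(N, C, H, W)`` float64 arrays;
* convolution MACs are counted as ``k_h * k_w * C_in * C_out * H_out * W_out``
  (transposed convolutions at *output* resolution, the convention of the
  common profilers under which single-stage detectors report their GFLOPs);
* a parameter is any array the optimizer may update; BN running statistics
  are buffers, not parameters.
"""
from __future__ import annotations

import numpy as np

# Default BN epsilon for the whole package (common detection-framework value).
BN_EPS = 1e-3


def sigmoid(x):
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def silu(x):
    return x * sigmoid(x)


def _he_init(rng, shape, fan_in):
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)


def im2col(x, kh, kw, stride, ph, pw):
    """Unfold ``x`` into columns; returns (cols, H_out, W_out).

    cols has shape (N, C*kh*kw, H_out*W_out).
    """
    n, c, h, w = x.shape
    ho = (h + 2 * ph - kh) // stride + 1
    wo = (w + 2 * pw - kw) // stride + 1
    xp = np.pad(x, ((0, 0), (0, 0), (ph, ph), (pw, pw)))
    cols = np.empty((n, c, kh, kw, ho, wo), dtype=x.dtype)
    for i in range(kh):
        for j in range(kw):
            cols[:, :, i, j] = xp[:, :, i:i + stride * ho:stride, j:j + stride * wo:stride]
    return cols.reshape(n, c * kh * kw, ho * wo), ho, wo


def col2im(cols, x_shape, kh, kw, stride, ph, pw, ho, wo):
    """Adjoint of :func:`im2col` (scatter-add back into image layout)."""
    n, c, h, w = x_shape
    cols = cols.reshape(n, c, kh, kw, ho, wo)
    xp = np.zeros((n, c, h + 2 * ph, w + 2 * pw), dtype=cols.dtype)
    for i in range(kh):
        for j in range(kw):
            xp[:, :, i:i + stride * ho:stride, j:j + stride * wo:stride] += cols[:, :, i, j]
    return xp[:, :, ph:ph + h, pw:pw + w]


class Layer:
    """Base class; subclasses may override any of these."""

    multi_input = False

    def params(self):
        return {}

    def grads(self):
        return {}

    def buffers(self):
        return {}

    def zero_grad(self):
        for g in self.grads().values():
            g[...] = 0.0

    def forward(self, x, train=False):  # pragma: no cover - abstract
        raise NotImplementedError

    def backward(self, dy):  # pragma: no cover - abstract
        raise NotImplementedError(f"{type(self).__name__} has no backward")

    def out_shape(self, in_shape):
        return in_shape

    def macs(self, in_shape):
        return 0


class Conv2d(Layer):
    def __init__(self, cin, cout, kernel_size, stride=1, padding=None,
                 bias=True, rng=None):
        kh, kw = (kernel_size, kernel_size) if np.isscalar(kernel_size) else kernel_size
        if padding is None:
            padding = (kh // 2, kw // 2)
        ph, pw = (padding, padding) if np.isscalar(padding) else padding
        self.cin, self.cout, self.kh, self.kw = cin, cout, kh, kw
        self.stride, self.ph, self.pw = stride, ph, pw
        rng = rng or np.random.default_rng(0)
        self.weight = _he_init(rng, (cout, cin, kh, kw), cin * kh * kw)
        self.bias = np.zeros(cout) if bias else None
        self.g_weight = np.zeros_like(self.weight)
        self.g_bias = np.zeros(cout) if bias else None
        self._cache = None

    def params(self):
        p = {"weight": self.weight}
        if self.bias is not None:
            p["bias"] = self.bias
        return p

    def grads(self):
        g = {"weight": self.g_weight}
        if self.bias is not None:
            g["bias"] = self.g_bias
        return g

    def forward(self, x, train=False):
        cols, ho, wo = im2col(x, self.kh, self.kw, self.stride, self.ph, self.pw)
        w2 = self.weight.reshape(self.cout, -1)
        y = np.einsum("ok,nkl->nol", w2, cols, optimize=True)
        if self.bias is not None:
            y += self.bias[None, :, None]
        if train:
            self._cache = (x.shape, cols, ho, wo)
        return y.reshape(x.shape[0], self.cout, ho, wo)

    def backward(self, dy):
        x_shape, cols, ho, wo = self._cache
        n = dy.shape[0]
        dyf = dy.reshape(n, self.cout, -1)
        self.g_weight += np.einsum("nol,nkl->ok", dyf, cols, optimize=True).reshape(self.weight.shape)
        if self.bias is not None:
            self.g_bias += dyf.sum(axis=(0, 2))
        dcols = np.einsum("ok,nol->nkl", self.weight.reshape(self.cout, -1), dyf, optimize=True)
        self._cache = None
        return col2im(dcols, x_shape, self.kh, self.kw, self.stride, self.ph, self.pw, ho, wo)

    def out_shape(self, in_shape):
        c, h, w = in_shape
        ho = (h + 2 * self.ph - self.kh) // self.stride + 1
        wo = (w + 2 * self.pw - self.kw) // self.stride + 1
        return (self.cout, ho, wo)

    def macs(self, in_shape):
        _, ho, wo = self.out_shape(in_shape)
        return self.kh * self.kw * self.cin * self.cout * ho * wo


class ConvTranspose2d(Layer):
    """Transposed convolution restricted to kernel == stride (tile upsampling)."""

    def __init__(self, cin, cout, kernel_size=2, stride=2, bias=True, rng=None):
        if kernel_size != stride:
            raise ValueError("only kernel_size == stride supported")
        self.cin, self.cout, self.k = cin, cout, kernel_size
        rng = rng or np.random.default_rng(0)
        self.weight = _he_init(rng, (cin, cout, self.k, self.k), cin)
        self.bias = np.zeros(cout) if bias else None
        self.g_weight = np.zeros_like(self.weight)
        self.g_bias = np.zeros(cout) if bias else None
        self._cache = None

    def params(self):
        p = {"weight": self.weight}
        if self.bias is not None:
            p["bias"] = self.bias
        return p

    def grads(self):
        g = {"weight": self.g_weight}
        if self.bias is not None:
            g["bias"] = self.g_bias
        return g

    def forward(self, x, train=False):
        n, c, h, w = x.shape
        k = self.k
        y = np.zeros((n, self.cout, h * k, w * k), dtype=x.dtype)
        for i in range(k):
            for j in range(k):
                y[:, :, i::k, j::k] = np.einsum("nchw,co->nohw", x, self.weight[:, :, i, j],
                                                optimize=True)
        if self.bias is not None:
            y += self.bias[None, :, None, None]
        if train:
            self._cache = x
        return y

    def backward(self, dy):
        x = self._cache
        k = self.k
        dx = np.zeros_like(x)
        for i in range(k):
            for j in range(k):
                sub = dy[:, :, i::k, j::k]
                self.g_weight[:, :, i, j] += np.einsum("nchw,nohw->co", x, sub, optimize=True)
                dx += np.einsum("nohw,co->nchw", sub, self.weight[:, :, i, j], optimize=True)
        if self.bias is not None:
            self.g_bias += dy.sum(axis=(0, 2, 3))
        self._cache = None
        return dx

    def out_shape(self, in_shape):
        c, h, w = in_shape
        return (self.cout, h * self.k, w * self.k)

    def macs(self, in_shape):
        # output-resolution convention (matches common profilers)
        _, ho, wo = self.out_shape(in_shape)
        return self.k * self.k * self.cin * self.cout * ho * wo


class BatchNorm2d(Layer):
    def __init__(self, c, eps=BN_EPS, momentum=0.03):
        self.c, self.eps, self.momentum = c, eps, momentum
        self.gamma = np.ones(c)
        self.beta = np.zeros(c)
        self.running_mean = np.zeros(c)
        self.running_var = np.ones(c)
        self.g_gamma = np.zeros(c)
        self.g_beta = np.zeros(c)
        self._cache = None

    def params(self):
        return {"gamma": self.gamma, "beta": self.beta}

    def grads(self):
        return {"gamma": self.g_gamma, "beta": self.g_beta}

    def buffers(self):
        return {"running_mean": self.running_mean, "running_var": self.running_var}

    def forward(self, x, train=False):
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * inv[None, :, None, None]
        if train:
            self._cache = (xhat, inv, x.shape)
        return self.gamma[None, :, None, None] * xhat + self.beta[None, :, None, None]

    def backward(self, dy):
        xhat, inv, shape = self._cache
        n_elem = shape[0] * shape[2] * shape[3]
        self.g_gamma += (dy * xhat).sum(axis=(0, 2, 3))
        self.g_beta += dy.sum(axis=(0, 2, 3))
        dxhat = dy * self.gamma[None, :, None, None]
        t1 = dxhat.sum(axis=(0, 2, 3))[None, :, None, None]
        t2 = (dxhat * xhat).sum(axis=(0, 2, 3))[None, :, None, None]
        dx = inv[None, :, None, None] * (dxhat - t1 / n_elem - xhat * t2 / n_elem)
        self._cache = None
        return dx


class ChannelScale(Layer):
    """Per-channel multiplicative scale; trainable when used in Hyper-Search."""

    def __init__(self, c, init=1.0, trainable=False):
        self.scale = np.full(c, float(init)) if np.isscalar(init) else np.asarray(init, float).copy()
        self.trainable = trainable
        self.g_scale = np.zeros_like(self.scale)
        self._cache = None

    def params(self):
        return {"scale": self.scale} if self.trainable else {}

    def grads(self):
        return {"scale": self.g_scale} if self.trainable else {}

    def forward(self, x, train=False):
        if train:
            self._cache = x
        return x * self.scale[None, :, None, None]

    def backward(self, dy):
        x = self._cache
        if self.trainable:
            self.g_scale += (dy * x).sum(axis=(0, 2, 3))
        self._cache = None
        return dy * self.scale[None, :, None, None]


class SiLU(Layer):
    def forward(self, x, train=False):
        if train:
            self._cache = x
        return silu(x)

    def backward(self, dy):
        x = self._cache
        s = sigmoid(x)
        self._cache = None
        return dy * (s * (1.0 + x * (1.0 - s)))


class ReLU(Layer):
    def forward(self, x, train=False):
        if train:
            self._cache = x
        return np.maximum(x, 0.0)

    def backward(self, dy):
        x = self._cache
        self._cache = None
        return dy * (x > 0)


class Identity(Layer):
    def forward(self, x, train=False):
        return x

    def backward(self, dy):
        return dy


ACTIVATIONS = {"silu": SiLU, "relu": ReLU, "none": Identity}


class MaxPool2d(Layer):
    def __init__(self, kernel_size, stride=1, padding=None):
        self.k = kernel_size
        self.stride = stride
        self.pad = kernel_size // 2 if padding is None else padding
        self._cache = None

    def forward(self, x, train=False):
        n, c, h, w = x.shape
        xp = np.pad(x, ((0, 0), (0, 0), (self.pad,) * 2, (self.pad,) * 2),
                    constant_values=-np.inf)
        cols, ho, wo = im2col(xp, self.k, self.k, self.stride, 0, 0)
        cols = cols.reshape(n, c, self.k * self.k, ho * wo)
        arg = cols.argmax(axis=2)
        y = np.take_along_axis(cols, arg[:, :, None], axis=2)[:, :, 0]
        if train:
            self._cache = (x.shape, arg, ho, wo)
        return y.reshape(n, c, ho, wo)

    def backward(self, dy):
        x_shape, arg, ho, wo = self._cache
        n, c, h, w = x_shape
        dcols = np.zeros((n, c, self.k * self.k, ho * wo))
        np.put_along_axis(dcols, arg[:, :, None], dy.reshape(n, c, 1, -1), axis=2)
        dxp = col2im(dcols.reshape(n, c * self.k * self.k, -1),
                     (n, c, h + 2 * self.pad, w + 2 * self.pad),
                     self.k, self.k, self.stride, 0, 0, ho, wo)
        self._cache = None
        return dxp[:, :, self.pad:self.pad + h, self.pad:self.pad + w]

    def out_shape(self, in_shape):
        c, h, w = in_shape
        ho = (h + 2 * self.pad - self.k) // self.stride + 1
        wo = (w + 2 * self.pad - self.k) // self.stride + 1
        return (c, ho, wo)


class GlobalAvgPool(Layer):
    def forward(self, x, train=False):
        if train:
            self._cache = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, dy):
        n, c, h, w = self._cache
        self._cache = None
        return np.broadcast_to(dy[:, :, None, None], (n, c, h, w)) / (h * w)

    def out_shape(self, in_shape):
        return (in_shape[0], 1, 1)


class Linear(Layer):
    def __init__(self, cin, cout, rng=None):
        rng = rng or np.random.default_rng(0)
        self.weight = _he_init(rng, (cout, cin), cin)
        self.bias = np.zeros(cout)
        self.g_weight = np.zeros_like(self.weight)
        self.g_bias = np.zeros(cout)
        self._cache = None

    def params(self):
        return {"weight": self.weight, "bias": self.bias}

    def grads(self):
        return {"weight": self.g_weight, "bias": self.g_bias}

    def forward(self, x, train=False):
        if train:
            self._cache = x
        return x @ self.weight.T + self.bias

    def backward(self, dy):
        x = self._cache
        self.g_weight += dy.T @ x
        self.g_bias += dy.sum(axis=0)
        self._cache = None
        return dy @ self.weight


class Sequential(Layer):
    def __init__(self, *layers):
        self.layers = list(layers)

    def params(self):
        return {f"{i}.{k}": v for i, l in enumerate(self.layers) for k, v in l.params().items()}

    def grads(self):
        return {f"{i}.{k}": v for i, l in enumerate(self.layers) for k, v in l.grads().items()}

    def buffers(self):
        return {f"{i}.{k}": v for i, l in enumerate(self.layers) for k, v in l.buffers().items()}

    def forward(self, x, train=False):
        for l in self.layers:
            x = l.forward(x, train=train)
        return x

    def backward(self, dy):
        for l in reversed(self.layers):
            dy = l.backward(dy)
        return dy

    def out_shape(self, in_shape):
        for l in self.layers:
            in_shape = l.out_shape(in_shape)
        return in_shape

    def macs(self, in_shape):
        total = 0
        for l in self.layers:
            total += l.macs(in_shape)
            in_shape = l.out_shape(in_shape)
        return total


class ParallelSum(Layer):
    """Sum of branch outputs over a shared input (the multi-branch trunk)."""

    def __init__(self, *branches):
        self.branches = list(branches)

    def params(self):
        return {f"b{i}.{k}": v for i, b in enumerate(self.branches) for k, v in b.params().items()}

    def grads(self):
        return {f"b{i}.{k}": v for i, b in enumerate(self.branches) for k, v in b.grads().items()}

    def buffers(self):
        return {f"b{i}.{k}": v for i, b in enumerate(self.branches) for k, v in b.buffers().items()}

    def forward(self, x, train=False):
        y = None
        for b in self.branches:
            out = b.forward(x, train=train)
            y = out if y is None else y + out
        return y

    def backward(self, dy):
        dx = None
        for b in reversed(self.branches):
            d = b.backward(dy)
            dx = d if dx is None else dx + d
        return dx

    def out_shape(self, in_shape):
        return self.branches[0].out_shape(in_shape)

    def macs(self, in_shape):
        return sum(b.macs(in_shape) for b in self.branches)


class Concat(Layer):
    multi_input = True

    def forward(self, xs, train=False):
        if train:
            self._cache = [x.shape[1] for x in xs]
        return np.concatenate(xs, axis=1)

    def backward(self, dy):
        splits = np.cumsum(self._cache)[:-1]
        self._cache = None
        return list(np.split(dy, splits, axis=1))

    def out_shape(self, in_shapes):
        c = sum(s[0] for s in in_shapes)
        return (c,) + tuple(in_shapes[0][1:])


class Add(Layer):
    multi_input = True

    def forward(self, xs, train=False):
        self._n = len(xs)
        return sum(xs)

    def backward(self, dy):
        return [dy] * self._n

    def out_shape(self, in_shapes):
        return in_shapes[0]


class Graph(Layer):
    """A named DAG of layers.

    ``nodes`` is an ordered list of ``(name, layer, input_names)``; the
    reserved name ``"input"`` refers to the graph input. ``outputs`` lists
    the node names whose activations the graph returns.
    """

    def __init__(self, nodes, outputs):
        self.nodes = list(nodes)
        self.outputs = list(outputs)
        self._order = {name: i for i, (name, _, _) in enumerate(self.nodes)}

    def layers(self):
        return {name: layer for name, layer, _ in self.nodes}

    def params(self):
        return {f"{n}.{k}": v for n, l, _ in self.nodes for k, v in l.params().items()}

    def grads(self):
        return {f"{n}.{k}": v for n, l, _ in self.nodes for k, v in l.grads().items()}

    def buffers(self):
        return {f"{n}.{k}": v for n, l, _ in self.nodes for k, v in l.buffers().items()}

    def forward(self, x, train=False):
        acts = {"input": x}
        for name, layer, ins in self.nodes:
            xs = [acts[i] for i in ins]
            acts[name] = layer.forward(xs if layer.multi_input else xs[0], train=train)
        self._acts_keys = None
        return [acts[o] for o in self.outputs]

    def backward(self, douts):
        grads = {name: None for name, _, _ in self.nodes}
        grads["input"] = None

        def accumulate(name, d):
            grads[name] = d if grads[name] is None else grads[name] + d

        for o, d in zip(self.outputs, douts):
            if d is not None:
                accumulate(o, d)
        for name, layer, ins in reversed(self.nodes):
            dy = grads[name]
            if dy is None:
                continue
            dx = layer.backward(dy)
            if layer.multi_input:
                for i, d in zip(ins, dx):
                    accumulate(i, d)
            else:
                accumulate(ins[0], dx)
        return grads["input"]

    def shapes(self, in_shape):
        shapes = {"input": tuple(in_shape)}
        for name, layer, ins in self.nodes:
            ss = [shapes[i] for i in ins]
            shapes[name] = layer.out_shape(ss if layer.multi_input else ss[0])
        return shapes

    def macs(self, in_shape):
        shapes = self.shapes(in_shape)
        total = {}
        for name, layer, ins in self.nodes:
            s = [shapes[i] for i in ins]
            total[name] = layer.macs(s if layer.multi_input else s[0])
        return total


def num_params(layer):
    """Number of trainable scalars in a layer/graph."""
    return int(sum(v.size for v in layer.params().values()))
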