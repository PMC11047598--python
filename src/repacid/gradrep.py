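"""Gradient reparameterization (GR) for asymmetric-branch blocks.

The quantization-friendly training scheme trains a plain single-branch
(VGG-style) network whose SGD trajectory equals that of a multi-branch
block in which every branch normalization is replaced by a *constant*
per-channel scale (a CSLA block: Constant-Scale Linear Addition).  For a
block with 3x3, 1x3 and 3x1 branches scaled by ``s``, ``h`` and ``v``:

* the fused weight is initialized as
  ``W'(0) = s*embed(W_A(0)) + h*embed(W_B(0)) + v*embed(W_C(0)) [+ I]``;
* every SGD step multiplies the fused-weight gradient elementwise by a
  constant mask M (the "Grad Mult").  The mask entry for output channel c
  is ``s_c**2`` everywhere, plus ``h_c**2`` on the middle row, plus
  ``v_c**2`` on the middle column (the positions those branches touch),
  plus 1 at the center diagonal when the identity branch exists.  At the
  center position this reproduces the scalar cases
  ``1 + s^2 + h^2 + v^2`` (c == d, identity present) and
  ``s^2 + h^2 + v^2`` (c != d).

The scale constants themselves come from Hyper-Search: an auxiliary model
with *trainable* scales is trained briefly on a proxy task and the learned
scales are frozen into masks.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from . import nn
from .nn import ChannelScale, Conv2d, GlobalAvgPool, Linear, Sequential, SiLU
from .reparam import embed_kernel_3x3


@dataclass
class CSLAScales:
    """Constant per-channel scales of one CSLA block."""

    s: np.ndarray                 # after the 3x3 branch
    h: np.ndarray                 # after the 1x3 branch
    v: np.ndarray                 # after the 3x1 branch
    identity: bool = False        # identity branch present (stride 1, cin == cout)

    def __post_init__(self):
        self.s = np.atleast_1d(np.asarray(self.s, dtype=float))
        self.h = np.broadcast_to(np.atleast_1d(np.asarray(self.h, float)), self.s.shape).copy()
        self.v = np.broadcast_to(np.atleast_1d(np.asarray(self.v, float)), self.s.shape).copy()
        if not (np.all(np.isfinite(self.s)) and np.all(np.isfinite(self.h))
                and np.all(np.isfinite(self.v))):
            raise ValueError("scales must be finite")


def _conv(x, kernel, stride, padding):
    layer = Conv2d(kernel.shape[1], kernel.shape[0], kernel.shape[2:],
                   stride=stride, padding=padding, bias=False)
    layer.weight = np.asarray(kernel, dtype=float)
    return layer.forward(x)


def csla_forward(x, square_kernel, hor_kernel, ver_kernel, scales: CSLAScales,
                 stride=1):
    """Reference forward of the CSLA block:
    ``y = s*(x * W_A) + h*(x * W_B) + v*(x * W_C) [+ x]``.

    Used as the equivalence oracle and inside Hyper-Search; never in the
    deployed model.
    """
    square_kernel = np.asarray(square_kernel, float)
    hor_kernel = np.asarray(hor_kernel, float)
    ver_kernel = np.asarray(ver_kernel, float)
    if square_kernel.shape[2:] != (3, 3) or hor_kernel.shape[2:] != (1, 3) \
            or ver_kernel.shape[2:] != (3, 1):
        raise ValueError("branch kernels must be 3x3 / 1x3 / 3x1")
    y = scales.s[None, :, None, None] * _conv(x, square_kernel, stride, (1, 1))
    y = y + scales.h[None, :, None, None] * _conv(x, hor_kernel, stride, (0, 1))
    y = y + scales.v[None, :, None, None] * _conv(x, ver_kernel, stride, (1, 0))
    if scales.identity:
        if stride != 1 or square_kernel.shape[0] != square_kernel.shape[1]:
            raise ValueError("identity branch requires stride 1 and cin == cout")
        y = y + x
    return y


def init_fused_weights(square_kernel, hor_kernel, ver_kernel,
                       scales: CSLAScales) -> np.ndarray:
    """Fused initialization ``W'(0)`` reproducing the CSLA initial map."""
    square_kernel = np.asarray(square_kernel, float)
    if square_kernel.shape[2:] != (3, 3):
        raise ValueError("square kernel must be 3x3")
    w = scales.s[:, None, None, None] * square_kernel
    w = w + scales.h[:, None, None, None] * embed_kernel_3x3(hor_kernel)
    w = w + scales.v[:, None, None, None] * embed_kernel_3x3(ver_kernel)
    if scales.identity:
        w = w + embed_kernel_3x3(None, identity_channels=square_kernel.shape[0])
    return w


def build_grad_mult(scales: CSLAScales, in_ch: int, out_ch: int) -> np.ndarray:
    """The constant elementwise gradient multiplier M[out_ch, in_ch, 3, 3]."""
    if scales.s.shape != (out_ch,):
        raise ValueError("scale vectors must have length out_ch")
    m = np.zeros((out_ch, in_ch, 3, 3))
    m += (scales.s ** 2)[:, None, None, None]
    m[:, :, 1, :] += (scales.h ** 2)[:, None, None]
    m[:, :, :, 1] += (scales.v ** 2)[:, None, None]
    if scales.identity:
        if in_ch != out_ch:
            raise ValueError("identity branch requires in_ch == out_ch")
        c = np.arange(out_ch)
        m[c, c, 1, 1] += 1.0
    return m


# ---------------------------------------------------------------------------
# The optimizer
# ---------------------------------------------------------------------------

class GradReparamSGD:
    """SGD whose masked parameters follow the CSLA trajectory.

    Parameters are registered as ``(layer, name)`` pairs; a re-parameterized
    3x3 layer's weight additionally carries its Grad Mult mask, applied
    elementwise to the raw gradient at every step.  Masks never change
    during training.  With momentum = 0 and weight decay = 0 this is the
    plain update ``W'(i+1) = W'(i) - lr * M o dL/dW'(i)``; weight decay, by
    design, is added *after* masking.
    """

    def __init__(self, momentum=0.0, weight_decay=0.0):
        self.momentum = momentum
        self.weight_decay = weight_decay
        self._entries: List[Tuple[object, str, Optional[np.ndarray]]] = []
        self._buffers: List[np.ndarray] = []
        self.iteration = 0

    def register(self, layer, mask_for: Optional[Dict[str, np.ndarray]] = None):
        """Register a layer's parameters; ``mask_for`` maps param name -> mask."""
        mask_for = mask_for or {}
        for name, p in layer.params().items():
            mask = mask_for.get(name)
            if mask is not None and mask.shape != p.shape:
                raise ValueError(f"mask shape {mask.shape} != param shape {p.shape}")
            self._entries.append((layer, name, None if mask is None else np.asarray(mask, float)))
            self._buffers.append(np.zeros_like(p))
        return self

    def require_all_masked(self, layers):
        """Error out if any registered re-parameterizable layer lacks a mask."""
        registered = {id(l) for l, _, m in self._entries if m is not None}
        for l in layers:
            if id(l) not in registered:
                raise ValueError("re-parameterizable layer missing a Grad Mult mask")

    def step(self, lr):
        for (layer, name, mask), buf in zip(self._entries, self._buffers):
            p = layer.params()[name]
            g = layer.grads()[name]
            update = g * mask if mask is not None else g.copy()
            if self.weight_decay:
                update += self.weight_decay * p
            if self.momentum:
                buf *= self.momentum
                buf += update
                update = buf
            p -= lr * update
        self.iteration += 1

    def zero_grad(self):
        seen = set()
        for layer, _, _ in self._entries:
            if id(layer) not in seen:
                layer.zero_grad()
                seen.add(id(layer))


def gr_sgd_step(layers_and_masks, lr):
    """Functional single vanilla-SGD step with Grad Mult masks.

    ``layers_and_masks`` is a sequence of ``(layer, {param_name: mask})``;
    gradients must already be accumulated on the layers.
    """
    for layer, masks in layers_and_masks:
        params, grads = layer.params(), layer.grads()
        for name, p in params.items():
            g = grads[name]
            m = masks.get(name) if masks else None
            p -= lr * (g * m if m is not None else g)


# ---------------------------------------------------------------------------
# Hyper-Search
# ---------------------------------------------------------------------------

@dataclass
class HyperSearchResult:
    """Searched per-block scale vectors plus provenance."""

    scales: Dict[str, CSLAScales]
    proxy_id: str = "synthetic-classification"
    epochs: int = 0
    seed: int = 0

    def masks(self, geometry: Dict[str, Tuple[int, int]]) -> Dict[str, np.ndarray]:
        """Build Grad Mult masks; ``geometry`` maps block name -> (cin, cout)."""
        return {name: build_grad_mult(sc, *geometry[name])
                for name, sc in self.scales.items()}


class _SearchBlock:
    """CSLA block with trainable scales (the Hyper-Search auxiliary form)."""

    def __init__(self, cin, cout, stride, rng):
        self.cin, self.cout, self.stride = cin, cout, stride
        self.identity = stride == 1 and cin == cout
        mk = lambda shape, pad: Conv2d(cin, cout, shape, stride=stride,
                                       padding=pad, bias=False, rng=rng)
        self.convs = {"square": mk((3, 3), (1, 1)),
                      "hor": mk((1, 3), (0, 1)),
                      "ver": mk((3, 1), (1, 0))}
        self.scales = {k: ChannelScale(cout, init=1.0, trainable=True)
                       for k in self.convs}
        # identity BN is replaced by a *trainable* channel-wise scale
        self.id_scale = ChannelScale(cout, init=1.0, trainable=True) if self.identity else None
        self.act = SiLU()

    def forward(self, x, train=False):
        y = None
        for k in ("square", "hor", "ver"):
            out = self.scales[k].forward(self.convs[k].forward(x, train=train),
                                         train=train)
            y = out if y is None else y + out
        if self.identity:
            y = y + self.id_scale.forward(x, train=train)
        return self.act.forward(y, train=train)

    def backward(self, dy):
        dy = self.act.backward(dy)
        dx = self.id_scale.backward(dy) if self.identity else None
        for k in ("square", "hor", "ver"):
            d = self.convs[k].backward(self.scales[k].backward(dy))
            dx = d if dx is None else dx + d
        return dx

    def all_layers(self):
        out = list(self.convs.values()) + list(self.scales.values())
        if self.id_scale is not None:
            out.append(self.id_scale)
        return out

    def result(self) -> CSLAScales:
        return CSLAScales(self.scales["square"].scale.copy(),
                          self.scales["hor"].scale.copy(),
                          self.scales["ver"].scale.copy(),
                          identity=self.identity)


def hyper_search(block_geometry: Sequence[Tuple[str, int, int, int]],
                 proxy_images: np.ndarray, proxy_labels: np.ndarray,
                 epochs: int = 10, seed: int = 0, lr: float = 0.01,
                 batch_size: int = 16):
    """Search CSLA scale constants on a proxy classification task.

    Parameters
    ----------
    block_geometry
        ``(name, cin, cout, stride)`` for every re-parameterizable block of
        the target model, in forward order (the auxiliary model is the
        corresponding stack with trainable branch scales, topped by global
        average pooling and a linear classifier).
    proxy_images, proxy_labels
        A small labelled image set, e.g. rendered synthetic scenes.
    """
    rng = np.random.default_rng(seed)
    blocks = [(name, _SearchBlock(cin, cout, stride, rng))
              for name, cin, cout, stride in block_geometry]
    n_classes = int(proxy_labels.max()) + 1
    pool = GlobalAvgPool()
    head = Linear(block_geometry[-1][2], n_classes, rng=rng)

    opt = GradReparamSGD()
    for _, b in blocks:
        for l in b.all_layers():
            opt.register(l)
    opt.register(head)

    n = proxy_images.shape[0]
    for _ in range(epochs):
        order = rng.permutation(n)
        for start in range(0, n, batch_size):
            idx = order[start:start + batch_size]
            x = proxy_images[idx]
            opt.zero_grad()
            for _, b in blocks:
                x = b.forward(x, train=True)
            feats = pool.forward(x, train=True)
            logits = head.forward(feats, train=True)
            # softmax cross-entropy
            z = logits - logits.max(axis=1, keepdims=True)
            p = np.exp(z)
            p /= p.sum(axis=1, keepdims=True)
            loss = -np.mean(np.log(p[np.arange(len(idx)), proxy_labels[idx]] + 1e-12))
            if not np.isfinite(loss):
                raise FloatingPointError("Hyper-Search diverged: non-finite loss")
            dlogits = p
            dlogits[np.arange(len(idx)), proxy_labels[idx]] -= 1.0
            dlogits /= len(idx)
            d = pool.backward(head.backward(dlogits))
            for _, b in reversed(blocks):
                d = b.backward(d)
            opt.step(lr)

    return HyperSearchResult({name: b.result() for name, b in blocks},
                             epochs=epochs, seed=seed)
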