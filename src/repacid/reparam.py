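"""Structural re-parameterization: multi-branch training blocks and their
exact fusion into a single 3x3 convolution.

A RepACID block trains a 3x3 convolution alongside 1x3 ("horizontal") and
3x1 ("vertical") asymmetric branches, plus an identity branch when stride is
1 and the channel count is preserved; a RepVGG block uses a 1x1 branch
instead of the asymmetric pair.  Each branch is convolution + batch
normalization.  Because every branch is linear, folding the BN statistics
into each kernel, embedding the sub-kernels into 3x3 (middle row / middle
column / center), and summing yields one convolution whose pre-activation
output is identical to the multi-branch sum.  The nonlinearity is applied
only after the branch summation, which is what makes the fusion exact.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from . import nn
from .nn import ACTIVATIONS, BN_EPS, BatchNorm2d, Conv2d, Layer, ParallelSum, Sequential

BRANCH_SHAPES = {(3, 3), (1, 3), (3, 1), (1, 1)}


@dataclass
class BranchConvBN:
    """One training-time branch: a conv kernel plus its BN statistics."""

    kernel: np.ndarray            # (out_ch, in_ch, kh, kw)
    bn_gamma: np.ndarray
    bn_beta: np.ndarray
    bn_mean: np.ndarray
    bn_var: np.ndarray
    bn_eps: float = BN_EPS

    def __post_init__(self):
        self.kernel = np.asarray(self.kernel, dtype=float)
        kh, kw = self.kernel.shape[2:]
        if (kh, kw) not in BRANCH_SHAPES:
            raise ValueError(f"unsupported branch kernel shape {(kh, kw)}")
        out_ch = self.kernel.shape[0]
        for name in ("bn_gamma", "bn_beta", "bn_mean", "bn_var"):
            v = np.asarray(getattr(self, name), dtype=float)
            if v.shape != (out_ch,):
                raise ValueError(f"{name} must have length out_ch={out_ch}")
            setattr(self, name, v)
        if np.any(self.bn_var < 0):
            raise ValueError("bn_var must be non-negative")


@dataclass
class FusedConv:
    """The deployed single-branch form: one kernel, one bias, nothing else."""

    kernel: np.ndarray            # (out_ch, in_ch, 3, 3)
    bias: np.ndarray              # (out_ch,)
    stride: int = 1
    activation: str = "silu"


def fuse_conv_bn(branch: BranchConvBN):
    """Fold BN statistics into the branch kernel.

    Returns ``(kernel, bias)`` such that ``conv(x, kernel) + bias`` equals
    ``bn(conv(x, branch.kernel))`` exactly in real arithmetic:
    ``k_c' = k_c * gamma_c / sqrt(var_c + eps)`` and
    ``b_c = beta_c - gamma_c * mean_c / sqrt(var_c + eps)``.
    """
    for name in ("bn_gamma", "bn_beta", "bn_mean", "bn_var"):
        if not np.all(np.isfinite(getattr(branch, name))):
            raise ValueError(f"non-finite BN statistics in {name}")
    denom = branch.bn_var + branch.bn_eps
    if np.any(denom <= 0):
        raise ValueError("bn_var + bn_eps must be positive")
    std = np.sqrt(denom)
    scale = branch.bn_gamma / std
    kernel = branch.kernel * scale[:, None, None, None]
    bias = branch.bn_beta - branch.bn_gamma * branch.bn_mean / std
    return kernel, bias


def embed_kernel_3x3(kernel, identity_channels: Optional[int] = None):
    """Zero-pad a sub-kernel into 3x3 position, or build the identity kernel.

    1x3 kernels occupy the middle row, 3x1 the middle column, 1x1 the
    center.  The identity embedding (``kernel=None``) is the Kronecker
    delta: 1 at ``[c, c, 1, 1]``.
    """
    if kernel is None:
        if identity_channels is None:
            raise ValueError("identity embedding needs a channel count")
        c = identity_channels
        out = np.zeros((c, c, 3, 3))
        out[np.arange(c), np.arange(c), 1, 1] = 1.0
        return out
    kernel = np.asarray(kernel, dtype=float)
    o, i, kh, kw = kernel.shape
    if (kh, kw) not in BRANCH_SHAPES:
        raise ValueError(f"unsupported kernel shape {(kh, kw)}")
    out = np.zeros((o, i, 3, 3))
    r0 = (3 - kh) // 2
    c0 = (3 - kw) // 2
    out[:, :, r0:r0 + kh, c0:c0 + kw] = kernel
    return out


def _branch_layer(cin, cout, shape, stride, rng):
    kh, kw = shape
    conv = Conv2d(cin, cout, (kh, kw), stride=stride,
                  padding=(kh // 2, kw // 2), bias=False, rng=rng)
    return Sequential(conv, BatchNorm2d(cout))


class _IdentityBN(Layer):
    """Identity shortcut normalized per channel (BN on the raw input)."""

    def __init__(self, c):
        self.bn = BatchNorm2d(c)

    def params(self):
        return {f"bn.{k}": v for k, v in self.bn.params().items()}

    def grads(self):
        return {f"bn.{k}": v for k, v in self.bn.grads().items()}

    def buffers(self):
        return {f"bn.{k}": v for k, v in self.bn.buffers().items()}

    def forward(self, x, train=False):
        return self.bn.forward(x, train=train)

    def backward(self, dy):
        return self.bn.backward(dy)


class _RepBlockBase(Layer):
    """Shared machinery of the RepACID / RepVGG training blocks."""

    branch_shapes: dict = {}

    def __init__(self, cin, cout, stride=1, activation="silu", rng=None):
        self.cin, self.cout, self.stride = cin, cout, stride
        self.activation = activation
        rng = rng or np.random.default_rng(0)
        self.branches = {name: _branch_layer(cin, cout, shape, stride, rng)
                         for name, shape in self.branch_shapes.items()}
        self.identity_bn = _IdentityBN(cout) if (stride == 1 and cin == cout) else None
        children = list(self.branches.values())
        if self.identity_bn is not None:
            children.append(self.identity_bn)
        self._sum = ParallelSum(*children)
        self.act = ACTIVATIONS[activation]()

    def params(self):
        out = {}
        for name, b in self.branches.items():
            out.update({f"{name}.{k}": v for k, v in b.params().items()})
        if self.identity_bn is not None:
            out.update({f"identity.{k}": v for k, v in self.identity_bn.params().items()})
        return out

    def grads(self):
        out = {}
        for name, b in self.branches.items():
            out.update({f"{name}.{k}": v for k, v in b.grads().items()})
        if self.identity_bn is not None:
            out.update({f"identity.{k}": v for k, v in self.identity_bn.grads().items()})
        return out

    def buffers(self):
        out = {}
        for name, b in self.branches.items():
            out.update({f"{name}.{k}": v for k, v in b.buffers().items()})
        if self.identity_bn is not None:
            out.update({f"identity.{k}": v for k, v in self.identity_bn.buffers().items()})
        return out

    def forward(self, x, train=False):
        return self.act.forward(self._sum.forward(x, train=train), train=train)

    def backward(self, dy):
        return self._sum.backward(self.act.backward(dy))

    def pre_activation(self, x):
        """Branch sum before the nonlinearity (used by equivalence tests)."""
        return self._sum.forward(x, train=False)

    def out_shape(self, in_shape):
        c, h, w = in_shape
        s = self.stride
        return (self.cout, (h + 2 - 3) // s + 1, (w + 2 - 3) // s + 1)

    def macs(self, in_shape):
        return self._sum.macs(in_shape)

    # branch introspection -------------------------------------------------
    def branch_conv_bn(self, name) -> BranchConvBN:
        conv, bn = self.branches[name].layers
        return BranchConvBN(conv.weight, bn.gamma, bn.beta,
                            bn.running_mean, bn.running_var, bn.eps)

    def identity_branch_bn(self) -> Optional[BranchConvBN]:
        if self.identity_bn is None:
            return None
        bn = self.identity_bn.bn
        delta = embed_kernel_3x3(None, identity_channels=self.cout)
        return BranchConvBN(delta[:, :, 1:2, 1:2], bn.gamma, bn.beta,
                            bn.running_mean, bn.running_var, bn.eps)


class RepACIDTrainBlock(_RepBlockBase):
    """3x3 trunk enhanced by 1x3, 3x1 and (when shapes allow) identity."""

    branch_shapes = {"square": (3, 3), "hor": (1, 3), "ver": (3, 1)}


class RepVGGTrainBlock(_RepBlockBase):
    """3x3 trunk enhanced by 1x1 and (when shapes allow) identity."""

    branch_shapes = {"square": (3, 3), "point": (1, 1)}


class FusedConvLayer(Layer):
    """Deploy-time block: a single 3x3 convolution with bias + activation."""

    def __init__(self, fused: FusedConv):
        self.spec = fused
        o, i = fused.kernel.shape[:2]
        self.conv = Conv2d(i, o, 3, stride=fused.stride, bias=True)
        self.conv.weight = np.array(fused.kernel, dtype=float)
        self.conv.g_weight = np.zeros_like(self.conv.weight)
        self.conv.bias = np.array(fused.bias, dtype=float)
        self.conv.g_bias = np.zeros_like(self.conv.bias)
        self.act = ACTIVATIONS[fused.activation]()

    def params(self):
        return {f"conv.{k}": v for k, v in self.conv.params().items()}

    def grads(self):
        return {f"conv.{k}": v for k, v in self.conv.grads().items()}

    def forward(self, x, train=False):
        return self.act.forward(self.conv.forward(x, train=train), train=train)

    def backward(self, dy):
        return self.conv.backward(self.act.backward(dy))

    def pre_activation(self, x):
        return self.conv.forward(x)

    def out_shape(self, in_shape):
        return self.conv.out_shape(in_shape)

    def macs(self, in_shape):
        return self.conv.macs(in_shape)


def reparameterize_block(block) -> FusedConv:
    """Collapse a training block into its equivalent single 3x3 convolution.

    Each branch is BN-folded, embedded into 3x3, and the results are summed
    (kernels and biases alike).  Re-fusing an already fused block is the
    identity.
    """
    if isinstance(block, FusedConvLayer):
        return FusedConv(block.conv.weight.copy(), block.conv.bias.copy(),
                         block.conv.stride, block.spec.activation)
    if isinstance(block, FusedConv):
        return FusedConv(np.array(block.kernel), np.array(block.bias),
                         block.stride, block.activation)
    if not isinstance(block, _RepBlockBase):
        raise TypeError(f"cannot re-parameterize {type(block).__name__}")
    kernel = np.zeros((block.cout, block.cin, 3, 3))
    bias = np.zeros(block.cout)
    for name in block.branches:
        k, b = fuse_conv_bn(block.branch_conv_bn(name))
        kernel += embed_kernel_3x3(k)
        bias += b
    ident = block.identity_branch_bn()
    if ident is not None:
        k, b = fuse_conv_bn(ident)
        kernel += embed_kernel_3x3(k)
        bias += b
    return FusedConv(kernel, bias, block.stride, block.activation)


# ---------------------------------------------------------------------------
# Weight archive: flat key -> array mapping, round-trips bit-exactly.
# Keys follow "stage.block.branch.tensor" naming, e.g.
# "backbone.er3.rep0.square.0.weight".
# ---------------------------------------------------------------------------

def save_weights(path, arrays: dict):
    clean = {}
    for k, v in arrays.items():
        v = np.asarray(v)
        if not np.all(np.isfinite(v)):
            raise ValueError(f"non-finite values in '{k}'")
        clean[k] = v
    np.savez(path, **clean)


def load_weights(path) -> dict:
    with np.load(path) as z:
        return {k: z[k].copy() for k in z.files}
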