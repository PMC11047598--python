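"""Detector assembly, cost accounting, deploy conversion and training.

The detector is the familiar single-stage layout: an EfficientRep-style
backbone whose feature-extraction blocks are re-parameterizable (RepACID
with asymmetric 1x3/3x1 branches, or RepVGG with a 1x1 branch), a CSP-SPPF
pooling tail, a bidirectional-fusion PAN neck built from RepVGG blocks, and
efficient decoupled heads (class and box branches) on either three strides
{8, 16, 32} or the pruned two-stride {16, 32} layout, which drops the
stride-8 head together with its neck up-branch and fusion blocks.

Cost accounting is reported for the deploy form (multi-branch blocks
collapsed to single 3x3 convolutions, BN folded into conv biases), the form
in which re-parameterized detectors are conventionally compared.  FLOPs
count 2 operations per multiply-accumulate over all (transposed)
convolutions, transposed convolutions at output resolution; the convention
is recorded in every report.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from . import nn
from .nn import (ACTIVATIONS, Add, BatchNorm2d, ChannelScale, Concat, Conv2d,
                 ConvTranspose2d, Graph, Layer, MaxPool2d, Sequential, sigmoid)
from .reparam import (FusedConv, FusedConvLayer, RepACIDTrainBlock,
                      RepVGGTrainBlock, _RepBlockBase, embed_kernel_3x3,
                      reparameterize_block, save_weights)
from .gradrep import (CSLAScales, GradReparamSGD, build_grad_mult,
                      init_fused_weights)
from .evaluation import (THREE_HEAD_ANCHORS, TWO_HEAD_ANCHORS, AnchorSet,
                         compute_map, nms)
from .losses import ciou_grad, ciou_loss, iou as box_iou, vfl_loss
from .data import materialize

FLOP_CONVENTION = ("2 FLOPs per multiply-accumulate over convolutions; "
                   "transposed convolutions counted at output resolution; "
                   "bias/normalization/activation ops excluded")

BASE_CHANNELS = (64, 128, 256, 512, 1024)
BASE_REPEATS = (1, 6, 12, 18, 6)
NECK_CHANNELS = (256, 128, 128, 256, 256, 512)
NECK_REPEATS = (12, 12, 12, 12)


@dataclass
class ModelSpec:
    num_classes: int = 7
    width_multiple: float = 0.25
    depth_multiple: float = 0.33
    head_strides: Tuple[int, ...] = (8, 16, 32)
    backbone_block: str = "repacid"            # repacid | repvgg
    neck_block: str = "repvgg"
    anchors: Optional[AnchorSet] = None
    training_mode: str = "multi_branch"        # multi_branch | csla | gr_single_branch | deploy
    activation: str = "silu"
    input_size: int = 640

    def __post_init__(self):
        if tuple(sorted(self.head_strides)) not in ((16, 32), (8, 16, 32)):
            raise ValueError("head_strides must be {16,32} or {8,16,32}")
        self.head_strides = tuple(sorted(self.head_strides))
        if self.backbone_block not in ("repacid", "repvgg"):
            raise ValueError("backbone_block must be repacid or repvgg")
        if self.neck_block != "repvgg":
            raise ValueError("neck blocks are fixed to repvgg")
        if self.training_mode not in ("multi_branch", "csla", "gr_single_branch", "deploy"):
            raise ValueError(f"unknown training_mode {self.training_mode}")
        if self.anchors is None:
            self.anchors = (TWO_HEAD_ANCHORS if len(self.head_strides) == 2
                            else THREE_HEAD_ANCHORS)

    # derived dimensions -------------------------------------------------
    def channels(self):
        return tuple(max(1, round(c * self.width_multiple)) for c in BASE_CHANNELS)

    def repeats(self):
        return tuple(max(1, math.ceil(r * self.depth_multiple)) for r in BASE_REPEATS)

    def neck_channels(self):
        return tuple(max(1, round(c * self.width_multiple)) for c in NECK_CHANNELS)

    def neck_repeats(self):
        return tuple(max(1, math.ceil(r * self.depth_multiple)) for r in NECK_REPEATS)


def baseline_spec(num_classes=7, **kw):
    """The unmodified three-head detector (RepVGG blocks throughout)."""
    kw.setdefault("head_strides", (8, 16, 32))
    kw.setdefault("backbone_block", "repvgg")
    return ModelSpec(num_classes=num_classes, **kw)


def improved_spec(num_classes=7, **kw):
    """The pruned two-head detector with the RepACID backbone."""
    kw.setdefault("head_strides", (16, 32))
    kw.setdefault("backbone_block", "repacid")
    return ModelSpec(num_classes=num_classes, **kw)


def tiny_spec(num_classes=1, **kw):
    """A width/depth-reduced improved spec for desk-scale training."""
    kw.setdefault("width_multiple", 0.0625)
    kw.setdefault("depth_multiple", 0.1)
    kw.setdefault("input_size", 128)
    return improved_spec(num_classes=num_classes, **kw)


# ---------------------------------------------------------------------------
# building blocks
# ---------------------------------------------------------------------------

class ConvBNAct(Sequential):
    """Conv (no bias) + BN + activation; folds into ConvAct at deploy."""

    def __init__(self, cin, cout, k, stride=1, activation="silu", rng=None,
                 padding=None):
        conv = Conv2d(cin, cout, k, stride=stride, padding=padding,
                      bias=False, rng=rng)
        bn = BatchNorm2d(cout)
        super().__init__(conv, bn, ACTIVATIONS[activation]())
        self.conv, self.bn, self.activation = conv, bn, activation

    def fuse(self):
        std = np.sqrt(self.bn.running_var + self.bn.eps)
        scale = self.bn.gamma / std
        out = ConvAct(self.conv.cin, self.conv.cout, (self.conv.kh, self.conv.kw),
                      self.conv.stride, self.activation,
                      padding=(self.conv.ph, self.conv.pw))
        out.conv.weight[...] = self.conv.weight * scale[:, None, None, None]
        out.conv.bias[...] = self.bn.beta - self.bn.gamma * self.bn.running_mean / std
        return out


class ConvAct(Sequential):
    """Deploy-form conv (with bias) + activation."""

    def __init__(self, cin, cout, k, stride=1, activation="silu", rng=None,
                 padding=None):
        conv = Conv2d(cin, cout, k, stride=stride, padding=padding,
                      bias=True, rng=rng)
        super().__init__(conv, ACTIVATIONS[activation]())
        self.conv, self.activation = conv, activation


class CSLABlock(Layer):
    """Multi-branch block with constant branch scales (the CSLA form).

    Branch normalizations are replaced by fixed per-channel scales; the
    identity branch (when present) carries a trainable channel scale.  Used
    as the training-equivalence reference for gradient reparameterization.
    """

    def __init__(self, cin, cout, stride, kind, scales: CSLAScales,
                 activation="silu", rng=None):
        self.cin, self.cout, self.stride, self.kind = cin, cout, stride, kind
        self.scales = scales
        self.identity = stride == 1 and cin == cout
        rng = rng or np.random.default_rng(0)
        mk = lambda shape, pad: Conv2d(cin, cout, shape, stride=stride,
                                       padding=pad, bias=False, rng=rng)
        if kind == "repacid":
            self.convs = {"square": mk((3, 3), (1, 1)), "hor": mk((1, 3), (0, 1)),
                          "ver": mk((3, 1), (1, 0))}
            self.branch_scales = {"square": scales.s, "hor": scales.h, "ver": scales.v}
        else:
            self.convs = {"square": mk((3, 3), (1, 1)), "point": mk((1, 1), (0, 0))}
            self.branch_scales = {"square": scales.s, "point": scales.h}
        self.id_scale = ChannelScale(cout, init=1.0, trainable=True) if self.identity else None
        self.act = ACTIVATIONS[activation]()
        self.activation = activation

    def params(self):
        out = {f"{k}.weight": c.weight for k, c in self.convs.items()}
        if self.id_scale is not None:
            out["identity.scale"] = self.id_scale.scale
        return out

    def grads(self):
        out = {f"{k}.weight": c.g_weight for k, c in self.convs.items()}
        if self.id_scale is not None:
            out["identity.scale"] = self.id_scale.g_scale
        return out

    def forward(self, x, train=False):
        y = None
        for k, c in self.convs.items():
            o = c.forward(x, train=train) * self.branch_scales[k][None, :, None, None]
            y = o if y is None else y + o
        if self.identity:
            y = y + self.id_scale.forward(x, train=train)
        return self.act.forward(y, train=train)

    def backward(self, dy):
        dy = self.act.backward(dy)
        dx = self.id_scale.backward(dy) if self.identity else None
        for k, c in self.convs.items():
            d = c.backward(dy * self.branch_scales[k][None, :, None, None])
            dx = d if dx is None else dx + d
        return dx

    def out_shape(self, in_shape):
        c, h, w = in_shape
        return (self.cout, (h - 1) // self.stride + 1, (w - 1) // self.stride + 1)

    def macs(self, in_shape):
        return sum(c.macs(in_shape) for c in self.convs.values())

    def fused_weight(self):
        """Single 3x3 kernel reproducing this block's current linear map."""
        w = np.zeros((self.cout, self.cin, 3, 3))
        for k, c in self.convs.items():
            w += self.branch_scales[k][:, None, None, None] * embed_kernel_3x3(c.weight)
        if self.identity:
            d = np.arange(self.cout)
            w[d, d, 1, 1] += self.id_scale.scale
        return w

    def grad_mult(self):
        if self.kind == "repacid":
            return build_grad_mult(CSLAScales(self.scales.s, self.scales.h,
                                              self.scales.v, identity=self.identity),
                                   self.cin, self.cout)
        m = np.zeros((self.cout, self.cin, 3, 3))
        m += (self.scales.s ** 2)[:, None, None, None]
        m[:, :, 1, 1] += self.scales.h ** 2
        if self.identity:
            d = np.arange(self.cout)
            m[d, d, 1, 1] += 1.0
        return m


class GRConvBlock(Layer):
    """Single-branch 3x3 conv + activation trained via Grad Mult masks."""

    def __init__(self, cin, cout, stride, mask=None, activation="silu",
                 rng=None, init_weight=None):
        self.conv = Conv2d(cin, cout, 3, stride=stride, bias=True, rng=rng)
        if init_weight is not None:
            self.conv.weight[...] = init_weight
        self.act = ACTIVATIONS[activation]()
        self.activation = activation
        self.mask = mask if mask is not None else np.ones_like(self.conv.weight)

    def params(self):
        return {f"conv.{k}": v for k, v in self.conv.params().items()}

    def grads(self):
        return {f"conv.{k}": v for k, v in self.conv.grads().items()}

    def masks(self):
        return {"conv.weight": self.mask}

    def forward(self, x, train=False):
        return self.act.forward(self.conv.forward(x, train=train), train=train)

    def backward(self, dy):
        return self.conv.backward(self.act.backward(dy))

    def out_shape(self, in_shape):
        return self.conv.out_shape(in_shape)

    def macs(self, in_shape):
        return self.conv.macs(in_shape)


def _rep_block(cin, cout, stride, kind, mode, activation, rng,
               gr_scales: Optional[CSLAScales] = None):
    if mode == "multi_branch":
        cls = RepACIDTrainBlock if kind == "repacid" else RepVGGTrainBlock
        return cls(cin, cout, stride, activation=activation, rng=rng)
    if mode == "deploy":
        return ConvAct(cin, cout, 3, stride, activation, rng=rng)
    scales = gr_scales if gr_scales is not None else CSLAScales(
        np.ones(cout), np.ones(cout), np.ones(cout))
    if scales.s.shape != (cout,):
        scales = CSLAScales(np.full(cout, scales.s.flat[0]),
                            np.full(cout, scales.h.flat[0]),
                            np.full(cout, scales.v.flat[0]))
    if mode == "csla":
        return CSLABlock(cin, cout, stride, kind, scales, activation, rng=rng)
    # gr_single_branch: fused init + Grad Mult mask from the same scales
    probe = CSLABlock(cin, cout, stride, kind, scales, activation, rng=rng)
    return GRConvBlock(cin, cout, stride, mask=probe.grad_mult(),
                       activation=activation, rng=rng,
                       init_weight=probe.fused_weight())


# ---------------------------------------------------------------------------
# the detector graph
# ---------------------------------------------------------------------------

class Detector:
    def __init__(self, spec: ModelSpec, graph: Graph, rep_block_names):
        self.spec = spec
        self.graph = graph
        self.rep_block_names = list(rep_block_names)
        # per-stride (w, h) box priors at unit image size; set by fit() when
        # anchors are re-clustered on the training labels
        self.priors = None

    def forward(self, x, train=False):
        """Returns per-stride (cls_map, reg_map) pairs."""
        outs = self.graph.forward(x, train=train)
        return [(outs[2 * i], outs[2 * i + 1]) for i in range(len(self.spec.head_strides))]

    def backward(self, dmaps):
        douts = []
        for dcls, dreg in dmaps:
            douts += [dcls, dreg]
        return self.graph.backward(douts)

    def rep_blocks(self):
        layers = self.graph.layers()
        return {n: layers[n] for n in self.rep_block_names}

    def state_dict(self):
        out = {f"param.{k}": v.copy() for k, v in self.graph.params().items()}
        out.update({f"buffer.{k}": v.copy() for k, v in self.graph.buffers().items()})
        return out

    def load_state_dict(self, state):
        for k, v in self.graph.params().items():
            v[...] = state[f"param.{k}"]
        for k, v in self.graph.buffers().items():
            v[...] = state[f"buffer.{k}"]

    def save(self, path):
        save_weights(path, self.state_dict())


def build_detector(spec: ModelSpec, seed=0,
                   gr_scales: Optional[Dict[str, CSLAScales]] = None) -> Detector:
    """Assemble the detector graph described by ``spec``.

    ``gr_scales`` optionally supplies searched per-block scales (by block
    name) for the csla / gr_single_branch modes.
    """
    rng = np.random.default_rng(seed)
    act = spec.activation
    mode = spec.training_mode
    ch = spec.channels()
    reps = spec.repeats()
    nch = spec.neck_channels()
    nreps = spec.neck_repeats()
    gr_scales = gr_scales or {}

    nodes = []
    rep_names = []

    def add(name, layer, ins):
        nodes.append((name, layer, ins if isinstance(ins, list) else [ins]))
        return name

    def rep(name, cin, cout, stride, kind, ins):
        layer = _rep_block(cin, cout, stride, kind, mode, act, rng,
                           gr_scales.get(name))
        rep_names.append(name)
        return add(name, layer, ins)

    def cba(name, cin, cout, k, stride, ins, padding=None):
        if mode == "deploy":
            layer = ConvAct(cin, cout, k, stride, act, rng=rng, padding=padding)
        else:
            layer = ConvBNAct(cin, cout, k, stride, act, rng=rng, padding=padding)
        return add(name, layer, ins)

    bk = spec.backbone_block

    # --- backbone ---
    prev = rep("backbone.stem", 3, ch[0], 2, bk, "input")
    taps = {}
    for stage, (c, n, s) in enumerate(zip(ch[1:], reps[1:], (4, 8, 16, 32)), start=2):
        cin = ch[stage - 2]
        prev = rep(f"backbone.er{stage}.down", cin, c, 2, bk, prev)
        for j in range(n):
            prev = rep(f"backbone.er{stage}.rep{j}", c, c, 1, bk, prev)
        taps[s] = prev
    # CSP-SPPF tail on C5
    c5, hid = ch[4], ch[4] // 2
    x1 = cba("backbone.sppf.cv1", c5, hid, 1, 1, prev)
    y0 = cba("backbone.sppf.cv2", c5, hid, 1, 1, prev)
    x1 = cba("backbone.sppf.cv3", hid, hid, 3, 1, x1)
    x1 = cba("backbone.sppf.cv4", hid, hid, 1, 1, x1)
    p1 = add("backbone.sppf.pool1", MaxPool2d(5, 1, 2), x1)
    p2 = add("backbone.sppf.pool2", MaxPool2d(5, 1, 2), p1)
    p3 = add("backbone.sppf.pool3", MaxPool2d(5, 1, 2), p2)
    cat = add("backbone.sppf.cat", Concat(), [x1, p1, p2, p3])
    y1 = cba("backbone.sppf.cv5", 4 * hid, hid, 1, 1, cat)
    y1 = cba("backbone.sppf.cv6", hid, hid, 3, 1, y1)
    cat2 = add("backbone.sppf.cat2", Concat(), [y0, y1])
    c5_out = cba("backbone.sppf.cv7", 2 * hid, c5, 1, 1, cat2)
    taps[32] = c5_out

    # --- neck (bidirectional-fusion PAN) ---
    nb = spec.neck_block
    reduce0 = cba("neck.reduce0", c5, nch[0], 1, 1, c5_out)
    up0 = add("neck.bf0.up", ConvTranspose2d(nch[0], nch[0], 2, 2, rng=rng), reduce0)
    bf0_cv1 = cba("neck.bf0.cv1", ch[3], nch[0], 1, 1, taps[16])
    bf0_cv2 = cba("neck.bf0.cv2", ch[2], nch[0], 1, 1, taps[8])
    bf0_dn = cba("neck.bf0.down", nch[0], nch[0], 3, 2, bf0_cv2)
    bf0_cat = add("neck.bf0.cat", Concat(), [up0, bf0_cv1, bf0_dn])
    prev = cba("neck.bf0.cv3", 3 * nch[0], nch[0], 1, 1, bf0_cat)
    for j in range(nreps[0]):
        prev = rep(f"neck.rep_p4.{j}", nch[0], nch[0], 1, nb, prev)
    p4 = prev

    two_head = len(spec.head_strides) == 2
    if not two_head:
        reduce1 = cba("neck.reduce1", nch[0], nch[1], 1, 1, p4)
        up1 = add("neck.bf1.up", ConvTranspose2d(nch[1], nch[1], 2, 2, rng=rng), reduce1)
        bf1_cv1 = cba("neck.bf1.cv1", ch[2], nch[1], 1, 1, taps[8])
        bf1_cv2 = cba("neck.bf1.cv2", ch[1], nch[1], 1, 1, taps[4])
        bf1_dn = cba("neck.bf1.down", nch[1], nch[1], 3, 2, bf1_cv2)
        bf1_cat = add("neck.bf1.cat", Concat(), [up1, bf1_cv1, bf1_dn])
        prev = cba("neck.bf1.cv3", 3 * nch[1], nch[1], 1, 1, bf1_cat)
        for j in range(nreps[1]):
            prev = rep(f"neck.rep_p3.{j}", nch[1], nch[1], 1, nb, prev)
        p3_out = prev
        dn2 = cba("neck.down2", nch[1], nch[2], 3, 2, p3_out)
        n3_cat = add("neck.n3.cat", Concat(), [dn2, reduce1])
        prev = n3_cat
        cin = nch[1] + nch[2]
        for j in range(nreps[2]):
            prev = rep(f"neck.rep_n3.{j}", cin if j == 0 else nch[3], nch[3], 1, nb, prev)
        n3_out = prev
    else:
        n3_out = p4                                  # stride-16 feature
    dn1 = cba("neck.down1", nch[3] if not two_head else nch[0], nch[4], 3, 2, n3_out)
    n4_cat = add("neck.n4.cat", Concat(), [dn1, reduce0])
    prev = n4_cat
    cin = nch[0] + nch[4]
    for j in range(nreps[3]):
        prev = rep(f"neck.rep_n4.{j}", cin if j == 0 else nch[5], nch[5], 1, nb, prev)
    n4_out = prev

    # --- heads ---
    head_feats = {8: None, 16: None, 32: n4_out}
    if two_head:
        head_feats[16] = p4
        head_ch = {16: nch[0], 32: nch[5]}
    else:
        head_feats[8], head_feats[16] = p3_out, n3_out
        head_ch = {8: nch[1], 16: nch[3], 32: nch[5]}

    outputs = []
    for s in spec.head_strides:
        chh = head_ch[s]
        stem = cba(f"head{s}.stem", chh, chh, 1, 1, head_feats[s])
        ccv = cba(f"head{s}.cls_conv", chh, chh, 3, 1, stem)
        rcv = cba(f"head{s}.reg_conv", chh, chh, 3, 1, stem)
        cls_pred = Conv2d(chh, spec.num_classes, 1, rng=rng)
        cls_pred.bias[...] = -4.0      # focal prior: start scores near 0.018
        cp = add(f"head{s}.cls_pred", cls_pred, ccv)
        rp = add(f"head{s}.reg_pred", Conv2d(chh, 4, 1, rng=rng), rcv)
        outputs += [cp, rp]

    return Detector(spec, Graph(nodes, outputs), rep_names)


# ---------------------------------------------------------------------------
# accounting
# ---------------------------------------------------------------------------

@dataclass
class CostReport:
    params: int
    flops: float                      # raw FLOP count
    input_size: int
    convention: str
    breakdown: Dict[str, Tuple[int, float]]

    @property
    def params_m(self):
        return self.params / 1e6

    @property
    def flops_g(self):
        return self.flops / 1e9

    def __str__(self):
        lines = [f"input {self.input_size}x{self.input_size} | "
                 f"params {self.params_m:.2f} M | FLOPs {self.flops_g:.2f} G",
                 f"convention: {self.convention}"]
        for mod, (p, f) in sorted(self.breakdown.items()):
            lines.append(f"  {mod:<10s} {p / 1e6:8.3f} M  {f / 1e9:8.3f} G")
        return "\n".join(lines)


def count_params(model: Detector) -> int:
    """Exact count of trainable scalars in the model as built."""
    return nn.num_params(model.graph)


def count_flops(model: Detector, input_size=None) -> float:
    """FLOPs in G at the given input size (2 ops per MAC)."""
    s = input_size or model.spec.input_size
    macs = sum(model.graph.macs((3, s, s)).values())
    return 2.0 * macs / 1e9


def cost_report(spec_or_model, input_size=None) -> CostReport:
    """Deploy-form accounting (the convention re-parameterized detectors
    are compared in); accepts a ModelSpec or an already-built Detector."""
    if isinstance(spec_or_model, ModelSpec):
        model = build_detector(replace(spec_or_model, training_mode="deploy"))
    elif spec_or_model.spec.training_mode != "deploy":
        model = convert_to_deploy(spec_or_model)
    else:
        model = spec_or_model
    s = input_size or model.spec.input_size
    macs = model.graph.macs((3, s, s))
    breakdown: Dict[str, list] = {}
    for name, layer, _ in model.graph.nodes:
        mod = name.split(".")[0]
        entry = breakdown.setdefault(mod, [0, 0.0])
        entry[0] += nn.num_params(layer)
        entry[1] += 2.0 * macs[name]
    return CostReport(count_params(model), 2.0 * sum(macs.values()), s,
                      FLOP_CONVENTION,
                      {k: (v[0], v[1]) for k, v in breakdown.items()})


def _to_deploy_layer(layer):
    if isinstance(layer, _RepBlockBase):
        return FusedConvLayer(reparameterize_block(layer))
    if isinstance(layer, CSLABlock):
        fused = FusedConv(layer.fused_weight(), np.zeros(layer.cout),
                          layer.stride, layer.activation)
        return FusedConvLayer(fused)
    if isinstance(layer, GRConvBlock):
        fused = FusedConv(layer.conv.weight.copy(), layer.conv.bias.copy(),
                          layer.conv.stride, layer.activation)
        return FusedConvLayer(fused)
    if isinstance(layer, ConvBNAct):
        return layer.fuse()
    return layer


def convert_to_deploy(model: Detector) -> Detector:
    """Collapse every re-parameterizable block and fold every BN.

    Whole-model outputs are preserved (up to floating-point roundoff);
    converting an already-deployed model warns and returns it unchanged.
    """
    if model.spec.training_mode == "deploy":
        warnings.warn("model is already in deploy form; returning it unchanged")
        return model
    nodes = [(name, _to_deploy_layer(layer), ins)
             for name, layer, ins in model.graph.nodes]
    spec = replace(model.spec, training_mode="deploy")
    return Detector(spec, Graph(nodes, model.graph.outputs), model.rep_block_names)


def block_geometry(spec: ModelSpec):
    """(name, cin, cout, stride) of every backbone re-parameterizable block
    (the layout Hyper-Search mirrors)."""
    probe = build_detector(replace(spec, training_mode="deploy"))
    out = []
    for name in probe.rep_block_names:
        if not name.startswith("backbone."):
            continue
        layer = probe.graph.layers()[name]
        out.append((name, layer.conv.cin, layer.conv.cout, layer.conv.stride))
    return out


# ---------------------------------------------------------------------------
# label assignment, decoding, training
# ---------------------------------------------------------------------------

def stride_scale_range(stride, strides):
    """Receptive-scale band a head stride is responsible for: boxes with
    ``max(w, h)`` in ``[s, 8 s)`` (open-ended at the extremes)."""
    lo = 0.0 if stride == min(strides) else float(stride)
    hi = np.inf if stride == max(strides) else float(8 * stride)
    return lo, hi


def level_anchor(spec: ModelSpec, stride, img_size, priors=None):
    """Box prior of a stride level: the re-clustered training prior when
    available, else the spec's anchor table rescaled from the 640 reference."""
    if priors is not None and stride in priors:
        return np.asarray(priors[stride]) * img_size
    a = spec.anchors.as_array() * (img_size / 640.0)
    if spec.anchors.strides:
        sel = a[np.array(spec.anchors.strides) == stride]
        if len(sel):
            return sel.mean(axis=0)
    return np.array([4.0 * stride, 4.0 * stride])


def recluster_priors(labels_per_image, spec: ModelSpec, img_size, seed=0):
    """K-means anchor re-clustering on the training labels (one prior per
    head stride, ordered by scale).  Returned priors are normalized to the
    unit image so they transfer across input sizes."""
    from .evaluation import kmeans_anchors
    wh = np.array([[l.w, l.h] for labels in labels_per_image for l in labels])
    wh = wh * img_size
    k = len(spec.head_strides)
    if len(np.unique(wh, axis=0)) < k:
        return None
    centers = kmeans_anchors(wh, k, seed=seed).as_array()
    order = np.argsort(centers.max(axis=1))
    return {s: centers[order[i]] / img_size
            for i, s in enumerate(spec.head_strides)}


def assign_targets(labels, spec: ModelSpec, img_size, priors=None):
    """Simplified IoU/ratio-based assigner with neighbor-cell positives.

    Each ground truth goes to the head stride whose scale band contains its
    longest side (fallback: nearest band), into the grid cell holding its
    center plus the two adjacent cells nearest to it (reachable because the
    decode allows offsets in (-0.5, 1.5)).  Returns
    ``{stride: [(gy, gx, cls, box_pixels)]}``.
    """
    strides = spec.head_strides
    out = {s: [] for s in strides}
    for l in labels:
        bw, bh = l.w * img_size, l.h * img_size
        m = max(bw, bh)
        candidates = [s for s in strides
                      if stride_scale_range(s, strides)[0] <= m < stride_scale_range(s, strides)[1]]
        if not candidates:
            candidates = [min(strides, key=lambda s: abs(m - 4 * s))]
        best = min(candidates,
                   key=lambda s: max(np.max([bw, bh] / level_anchor(spec, s, img_size, priors)),
                                     np.max(level_anchor(spec, s, img_size, priors) / [bw, bh])))
        g = img_size // best
        fx, fy = l.cx * img_size / best, l.cy * img_size / best
        gx, gy = min(int(fx), g - 1), min(int(fy), g - 1)
        box = np.array([l.cx, l.cy, l.w, l.h]) * img_size
        cells = {(gy, gx)}
        cells.add((gy, min(max(gx + (1 if fx - gx > 0.5 else -1), 0), g - 1)))
        cells.add((min(max(gy + (1 if fy - gy > 0.5 else -1), 0), g - 1), gx))
        for cy, cx in cells:
            out[best].append((cy, cx, l.cls, box))
    return out


def decode_boxes(reg_map, stride, prior):
    """Map raw regression activations to cxcywh pixel boxes (bounded form):
    ``cx = (gx + 2 sigmoid(tx) - 0.5) * stride`` and
    ``w = prior_w * (2 sigmoid(tw))^2`` (extent capped at 4x the prior).
    """
    n, _, h, w = reg_map.shape
    gx = np.arange(w)[None, None, None, :]
    gy = np.arange(h)[None, None, :, None]
    cx = (gx + 2 * sigmoid(reg_map[:, 0:1]) - 0.5) * stride
    cy = (gy + 2 * sigmoid(reg_map[:, 1:2]) - 0.5) * stride
    bw = prior[0] * (2 * sigmoid(reg_map[:, 2:3])) ** 2
    bh = prior[1] * (2 * sigmoid(reg_map[:, 3:4])) ** 2
    return np.concatenate([cx, cy, bw, bh], axis=1)


@dataclass
class TrainConfig:
    epochs: int = 20
    batch_size: int = 8
    img_size: int = 128
    lr0: float = 0.02
    lrf: float = 0.01                 # final lr = lr0 * lrf (cosine annealing)
    momentum: float = 0.937
    weight_decay: float = 5e-4
    warmup_epochs: float = 3.0
    ema_decay: float = 0.99
    use_ema_weights: bool = False
    optimizer: str = "sgd"            # sgd | repacid (Grad Mult masks)
    box_loss: str = "ciou"
    alpha: float = 3.0
    lambda_box: float = 2.5
    mosaic: bool = False
    recluster_anchors: bool = True    # K-means priors from the training labels
    seed: int = 0


def _lr_at(step, steps_per_epoch, cfg: TrainConfig):
    warm = cfg.warmup_epochs * steps_per_epoch
    total = cfg.epochs * steps_per_epoch
    if warm > 0 and step < warm:
        return cfg.lr0 * (step + 1) / warm
    t = (step - warm) / max(total - warm, 1)
    return cfg.lr0 * (cfg.lrf + (1 - cfg.lrf) * 0.5 * (1 + math.cos(math.pi * t)))


class EMA:
    def __init__(self, model: Detector, decay):
        self.decay = decay
        self.shadow = {k: v.copy() for k, v in model.graph.params().items()}
        self.updates = 0

    def update(self, model):
        self.updates += 1
        d = self.decay * (1 - math.exp(-self.updates / 200.0))
        for k, v in model.graph.params().items():
            self.shadow[k] += (1 - d) * (v - self.shadow[k])


def fit(model: Detector, records, cfg: TrainConfig, val_records=None):
    """Desk-scale training loop on synthetic image records.

    Returns a history dict with per-epoch mean losses (and validation
    mAP_0.5 when ``val_records`` is given).  Deterministic given
    ``cfg.seed``; aborts with a diagnostic on non-finite loss.
    """
    rng = np.random.default_rng(cfg.seed)
    spec = model.spec
    size = cfg.img_size
    images, labels = [], []
    for r in records:
        img, lbl = materialize(r, render_size=(size, size))
        images.append(img.astype(np.float64).transpose(2, 0, 1) / 255.0)
        labels.append(lbl)
    images = np.stack(images)

    opt = GradReparamSGD(momentum=cfg.momentum, weight_decay=cfg.weight_decay)
    layers = model.graph.layers()
    for name in sorted(layers):
        layer = layers[name]
        if cfg.optimizer == "repacid" and isinstance(layer, GRConvBlock):
            opt.register(layer, mask_for=layer.masks())
        else:
            opt.register(layer)
    if cfg.optimizer == "repacid":
        opt.require_all_masked([l for l in layers.values() if isinstance(l, GRConvBlock)])

    ema = EMA(model, cfg.ema_decay) if cfg.ema_decay > 0 else None
    if cfg.recluster_anchors:
        model.priors = recluster_priors(labels, spec, size, seed=cfg.seed) \
            or model.priors
    priors = {s: level_anchor(spec, s, size, model.priors)
              for s in spec.head_strides}
    steps_per_epoch = max(len(records) // cfg.batch_size, 1)
    history = {"loss": [], "map50": []}
    step = 0
    for epoch in range(cfg.epochs):
        order = rng.permutation(len(records))
        epoch_losses = []
        for b in range(steps_per_epoch):
            idx = order[b * cfg.batch_size:(b + 1) * cfg.batch_size]
            x = images[idx]
            targets = [assign_targets(labels[i], spec, size, model.priors)
                       for i in idx]
            opt.zero_grad()
            outs = model.forward(x, train=True)
            dmaps = []
            batch_loss = 0.0
            n_pos_total = sum(len(v) for t in targets for v in t.values()) or 1
            for (cls_map, reg_map), s in zip(outs, spec.head_strides):
                p = sigmoid(cls_map)
                boxes = decode_boxes(reg_map, s, priors[s])
                q = np.zeros_like(p)
                pos_mask = np.zeros_like(p, dtype=bool)
                dreg = np.zeros_like(reg_map)
                for bi, t in enumerate(targets):
                    for gy, gx, cls_id, gt_box in t[s]:
                        pb = boxes[bi, :, gy, gx]
                        quality = float(np.clip(box_iou(pb, gt_box), 0.05, 1.0))
                        q[bi, cls_id, gy, gx] = quality
                        pos_mask[bi, cls_id, gy, gx] = True
                        # box loss gradient, chained through the decode
                        g = ciou_grad(pb, gt_box) * (cfg.lambda_box / n_pos_total)
                        sx, sy, sw, sh = sigmoid(reg_map[bi, :, gy, gx])
                        dreg[bi, 0, gy, gx] += g[0] * 2 * s * sx * (1 - sx)
                        dreg[bi, 1, gy, gx] += g[1] * 2 * s * sy * (1 - sy)
                        dreg[bi, 2, gy, gx] += g[2] * 2 * pb[2] * (1 - sw)
                        dreg[bi, 3, gy, gx] += g[3] * 2 * pb[3] * (1 - sh)
                        batch_loss += cfg.lambda_box * float(
                            ciou_loss(pb, gt_box)) / n_pos_total
                # varifocal classification term, normalized by positives
                # (focal weight treated as constant within the step)
                pc = np.clip(p, 1e-7, 1 - 1e-7)
                weight = np.where(pos_mask, q, 0.75 * pc ** 2.0)
                batch_loss += float(np.sum(vfl_loss(pc, q)) / n_pos_total)
                dcls = weight * (pc - q) / n_pos_total
                dmaps.append((dcls, dreg))
            if not np.isfinite(batch_loss):
                raise FloatingPointError(
                    f"non-finite loss at epoch {epoch} step {b}; "
                    "reduce the learning rate or inspect the data")
            model.backward(dmaps)
            opt.step(_lr_at(step, steps_per_epoch, cfg))
            if ema is not None:
                ema.update(model)
            epoch_losses.append(batch_loss)
            step += 1
        history["loss"].append(float(np.mean(epoch_losses)))
        if val_records is not None:
            m50, _, _ = evaluate(model, val_records, img_size=size)
            history["map50"].append(m50)
    if ema is not None and cfg.use_ema_weights:
        for k, v in model.graph.params().items():
            v[...] = ema.shadow[k]
    history["ema"] = ema.shadow if ema is not None else None
    return history


def predict(model: Detector, image, conf_thr=0.25, nms_thr=0.65):
    """Detections for one HWC uint8 image: list of (cls, box_cxcywh, conf)."""
    size = image.shape[0]
    x = image.astype(np.float64).transpose(2, 0, 1)[None] / 255.0
    outs = model.forward(x, train=False)
    boxes, scores, classes = [], [], []
    for (cls_map, reg_map), s in zip(outs, model.spec.head_strides):
        p = sigmoid(cls_map[0])
        b = decode_boxes(reg_map, s,
                         level_anchor(model.spec, s, size, model.priors))[0]
        cbest = p.argmax(axis=0)
        pbest = p.max(axis=0)
        keep = pbest >= conf_thr
        ys, xs = np.nonzero(keep)
        for y, xg in zip(ys, xs):
            boxes.append(b[:, y, xg])
            scores.append(float(pbest[y, xg]))
            classes.append(int(cbest[y, xg]))
    if not boxes:
        return []
    boxes = np.array(boxes)
    keep = nms(boxes, scores, nms_thr)
    return [(classes[i], boxes[i], scores[i]) for i in keep]


def evaluate(model: Detector, records, img_size=96, conf_thr=0.05,
             iou_thresholds=(0.5,)):
    """Render records, run the model, and score with mAP."""
    dets, gts = [], []
    for r in records:
        img, labels = materialize(r, render_size=(img_size, img_size))
        for cls_id, box, conf in predict(model, img, conf_thr=conf_thr):
            dets.append((r.image_id, cls_id, box, conf))
        for l in labels:
            gts.append((r.image_id, l.cls, l.as_array() * img_size))
    m50, m5095, per_class = compute_map(dets, gts, iou_thresholds,
                                        num_classes=model.spec.num_classes)
    return m50, m5095, per_class
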