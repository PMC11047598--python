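"""CSLA blocks, Grad Mult masks and trajectory equivalence of GR training."""
import numpy as np
import pytest

from repacid.gradrep import (CSLAScales, GradReparamSGD, build_grad_mult,
                             csla_forward, gr_sgd_step, hyper_search,
                             init_fused_weights)
from repacid.nn import Conv2d
from repacid.reparam import embed_kernel_3x3


def rand_kernels(rng, cout, cin):
    return (rng.normal(size=(cout, cin, 3, 3)),
            rng.normal(size=(cout, cin, 1, 3)),
            rng.normal(size=(cout, cin, 3, 1)))


def conv3x3(x, w, stride=1):
    layer = Conv2d(w.shape[1], w.shape[0], 3, stride=stride, bias=False)
    layer.weight = w
    return layer.forward(x)


class TestCSLAForward:
    def test_all_zero_scales_give_zero(self, rng):
        ws = rand_kernels(rng, 3, 2)
        sc = CSLAScales(np.zeros(3), np.zeros(3), np.zeros(3))
        y = csla_forward(rng.normal(size=(1, 2, 8, 8)), *ws, sc)
        np.testing.assert_array_equal(y, 0.0)

    def test_square_only_is_plain_conv(self, rng):
        ws = rand_kernels(rng, 3, 3)
        sc = CSLAScales(np.ones(3), np.zeros(3), np.zeros(3))
        x = rng.normal(size=(2, 3, 8, 8))
        np.testing.assert_allclose(csla_forward(x, *ws, sc), conv3x3(x, ws[0]),
                                   atol=1e-12)

    def test_matches_componentwise_weighted_sum(self, rng):
        """Oracle: three separate convolutions, scaled and summed."""
        wa, wb, wc = rand_kernels(rng, 4, 4)
        sc = CSLAScales(rng.normal(size=4), rng.normal(size=4), rng.normal(size=4),
                        identity=True)
        x = rng.normal(size=(2, 4, 9, 9))
        ref = (sc.s[None, :, None, None] * conv3x3(x, wa)
               + sc.h[None, :, None, None] * conv3x3(x, embed_kernel_3x3(wb))
               + sc.v[None, :, None, None] * conv3x3(x, embed_kernel_3x3(wc))
               + x)
        assert np.abs(csla_forward(x, wa, wb, wc, sc) - ref).max() < 1e-6


class TestInitFusedWeights:
    def test_unit_scales_zero_aux_recovers_square(self, rng):
        wa = rng.normal(size=(3, 3, 3, 3))
        zb, zc = np.zeros((3, 3, 1, 3)), np.zeros((3, 3, 3, 1))
        sc = CSLAScales(np.ones(3), np.ones(3), np.ones(3))
        w0 = init_fused_weights(wa, zb, zc, sc)
        np.testing.assert_allclose(w0, wa)

    def test_zero_scales_give_zero_weights(self, rng):
        ws = rand_kernels(rng, 2, 2)
        sc = CSLAScales(np.zeros(2), np.zeros(2), np.zeros(2))
        np.testing.assert_array_equal(init_fused_weights(*ws, sc), 0.0)

    def test_initial_forward_agreement(self, rng):
        """Oracle: conv with W'(0) equals the CSLA forward on random inputs."""
        ws = rand_kernels(rng, 5, 5)
        sc = CSLAScales(rng.normal(size=5), rng.normal(size=5), rng.normal(size=5),
                        identity=True)
        w0 = init_fused_weights(*ws, sc)
        for _ in range(10):
            x = rng.normal(size=(1, 5, 7, 7))
            assert np.abs(csla_forward(x, *ws, sc) - conv3x3(x, w0)).max() < 1e-6


class TestGradMult:
    def test_unit_square_only_mask_is_all_ones(self):
        m = build_grad_mult(CSLAScales(np.ones(4), np.zeros(4), np.zeros(4)), 4, 4)
        np.testing.assert_array_equal(m, 1.0)

    def test_center_diagonal_with_identity(self):
        # s = h = v = 0.5, identity present: center diag = 1 + 3 * 0.25
        sc = CSLAScales(np.full(2, 0.5), np.full(2, 0.5), np.full(2, 0.5),
                        identity=True)
        m = build_grad_mult(sc, 2, 2)
        assert m[0, 0, 1, 1] == pytest.approx(1.75)
        assert m[0, 1, 1, 1] == pytest.approx(0.75)     # c != d: s2+h2+v2
        assert m[0, 1, 1, 0] == pytest.approx(0.5)      # middle row: s2+h2
        assert m[0, 1, 0, 1] == pytest.approx(0.5)      # middle col: s2+v2
        assert m[0, 1, 0, 0] == pytest.approx(0.25)     # corner: s2

    def test_mask_matches_finite_difference_csla_gradient(self, rng):
        """Oracle: finite-difference gradients of the CSLA block, combined
        into the fused parameterization, equal mask * fused gradient."""
        cout = cin = 3
        ws = rand_kernels(rng, cout, cin)
        sc = CSLAScales(rng.uniform(0.5, 1.5, cout), rng.uniform(0.2, 1.0, cout),
                        rng.uniform(0.2, 1.0, cout), identity=True)
        x = rng.normal(size=(1, cin, 6, 6))
        r = rng.normal(size=(1, cout, 6, 6))      # L = sum(y * r)

        w0 = init_fused_weights(*ws, sc)
        # analytic fused gradient dL/dW' via correlation
        layer = Conv2d(cin, cout, 3, bias=False)
        layer.weight = w0
        layer.forward(x, train=True)
        layer.backward(r)
        fused_grad = layer.g_weight

        # finite-difference branch gradients, mapped into the fused kernel
        eps = 1e-5

        def loss(wa, wb, wc, idm):
            y = csla_forward(x, wa, wb, wc,
                             CSLAScales(sc.s, sc.h, sc.v, identity=False))
            y = y + idm[None, :, None, None] * x
            return float((y * r).sum())

        idm = np.ones(cout)
        combined = np.zeros_like(w0)
        for arr, scale, embed in ((ws[0], sc.s, False), (ws[1], sc.h, True),
                                  (ws[2], sc.v, True)):
            g = np.zeros_like(arr)
            it = np.nditer(arr, flags=["multi_index"])
            for _ in it:
                idx = it.multi_index
                arr[idx] += eps
                up = loss(*ws, idm)
                arr[idx] -= 2 * eps
                dn = loss(*ws, idm)
                arr[idx] += eps
                g[idx] = (up - dn) / (2 * eps)
            emb = embed_kernel_3x3(g) if embed else g
            combined += scale[:, None, None, None] * emb
        # identity trainable scale gradient -> center diagonal
        g_id = np.zeros(cout)
        for c in range(cout):
            idm[c] += eps
            up = loss(*ws, idm)
            idm[c] -= 2 * eps
            dn = loss(*ws, idm)
            idm[c] += eps
            g_id[c] = (up - dn) / (2 * eps)
        d = np.arange(cout)
        combined[d, d, 1, 1] += g_id

        mask = build_grad_mult(sc, cin, cout)
        np.testing.assert_allclose(combined, mask * fused_grad, rtol=1e-4,
                                   atol=1e-5)


class _CSLATwin:
    """Explicit CSLA training reference: branches + trainable identity."""

    def __init__(self, ws, sc):
        self.wa, self.wb, self.wc = [w.copy() for w in ws]
        self.sc = sc
        self.t = np.ones(ws[0].shape[0]) if sc.identity else None

    def forward(self, x):
        y = csla_forward(x, self.wa, self.wb, self.wc,
                         CSLAScales(self.sc.s, self.sc.h, self.sc.v))
        if self.t is not None:
            y = y + self.t[None, :, None, None] * x
        return y

    def step(self, x, dy, lr):
        def conv_grad(x, dy, kh, kw, ph, pw):
            layer = Conv2d(x.shape[1], dy.shape[1], (kh, kw), padding=(ph, pw),
                           bias=False)
            layer.weight = np.zeros((dy.shape[1], x.shape[1], kh, kw))
            layer.forward(x, train=True)
            layer.backward(dy)
            return layer.g_weight

        ga = conv_grad(x, dy * self.sc.s[None, :, None, None], 3, 3, 1, 1)
        gb = conv_grad(x, dy * self.sc.h[None, :, None, None], 1, 3, 0, 1)
        gc = conv_grad(x, dy * self.sc.v[None, :, None, None], 3, 1, 1, 0)
        self.wa -= lr * ga
        self.wb -= lr * gb
        self.wc -= lr * gc
        if self.t is not None:
            self.t -= lr * (dy * x).sum(axis=(0, 2, 3))


@pytest.mark.parametrize("identity", [False, True])
def test_gr_trajectory_matches_csla_twin(rng, identity):
    """50 vanilla-SGD steps on a toy regression: the masked fused layer
    tracks the explicit CSLA block step for step."""
    cout = cin = 4
    ws = rand_kernels(rng, cout, cin)
    ws = tuple(0.3 * w for w in ws)
    sc = CSLAScales(rng.uniform(0.5, 1.2, cout), rng.uniform(0.3, 0.9, cout),
                    rng.uniform(0.3, 0.9, cout), identity=identity)
    twin = _CSLATwin(ws, sc)
    fused = Conv2d(cin, cout, 3, bias=False)
    fused.weight = init_fused_weights(*ws, sc)
    mask = build_grad_mult(sc, cin, cout)

    x = rng.normal(size=(4, cin, 8, 8))
    target = rng.normal(size=(4, cout, 8, 8))
    lr = 5e-3
    for step in range(50):
        y_twin = twin.forward(x)
        fused.zero_grad()
        y_gr = fused.forward(x, train=True)
        assert np.abs(y_twin - y_gr).max() < 1e-4, f"diverged at step {step}"
        dy = 2 * (y_gr - target) / y_gr.size
        fused.backward(dy)
        gr_sgd_step([(fused, {"weight": mask})], lr)
        twin.step(x, 2 * (y_twin - target) / y_twin.size, lr)
    # final outputs still agree
    assert np.abs(twin.forward(x) - fused.forward(x)).max() < 1e-4


def test_mask_of_ones_recovers_plain_sgd(rng):
    a = Conv2d(2, 3, 3, bias=False, rng=np.random.default_rng(7))
    b = Conv2d(2, 3, 3, bias=False, rng=np.random.default_rng(7))
    x = rng.normal(size=(1, 2, 6, 6))
    dy = rng.normal(size=(1, 3, 6, 6))
    for layer in (a, b):
        layer.forward(x, train=True)
        layer.backward(dy)
    gr_sgd_step([(a, {"weight": np.ones_like(a.weight)})], 0.1)
    gr_sgd_step([(b, None)], 0.1)
    np.testing.assert_array_equal(a.weight, b.weight)


def test_zero_learning_rate_keeps_state(rng):
    layer = Conv2d(2, 2, 3, bias=False, rng=rng)
    before = layer.weight.copy()
    layer.forward(rng.normal(size=(1, 2, 5, 5)), train=True)
    layer.backward(rng.normal(size=(1, 2, 5, 5)))
    gr_sgd_step([(layer, None)], 0.0)
    np.testing.assert_array_equal(layer.weight, before)


def test_missing_mask_is_rejected():
    opt = GradReparamSGD()
    layer = Conv2d(2, 2, 3)
    opt.register(layer)  # registered without a mask
    with pytest.raises(ValueError, match="missing a Grad Mult"):
        opt.require_all_masked([layer])


class TestHyperSearch:
    @staticmethod
    def proxy(rng, n=24, classes=2):
        imgs = rng.random((n, 3, 12, 12))
        for i in range(n):
            if i % classes:
                imgs[i, :, 3:9, 3:9] += 1.0
        return imgs, np.arange(n) % classes

    GEOM = [("b0", 3, 4, 2), ("b1", 4, 4, 1)]

    def test_zero_epochs_returns_initialization(self, rng):
        imgs, lbls = self.proxy(rng)
        res = hyper_search(self.GEOM, imgs, lbls, epochs=0, seed=5)
        for sc in res.scales.values():
            np.testing.assert_array_equal(sc.s, 1.0)
            np.testing.assert_array_equal(sc.h, 1.0)
            np.testing.assert_array_equal(sc.v, 1.0)
        assert res.scales["b1"].identity and not res.scales["b0"].identity

    def test_same_seed_same_scales(self, rng):
        imgs, lbls = self.proxy(rng)
        r1 = hyper_search(self.GEOM, imgs, lbls, epochs=2, seed=5)
        r2 = hyper_search(self.GEOM, imgs, lbls, epochs=2, seed=5)
        for k in r1.scales:
            np.testing.assert_array_equal(r1.scales[k].s, r2.scales[k].s)
            np.testing.assert_array_equal(r1.scales[k].h, r2.scales[k].h)
            np.testing.assert_array_equal(r1.scales[k].v, r2.scales[k].v)

    def test_searched_scales_yield_positive_center_masks(self, rng):
        imgs, lbls = self.proxy(rng)
        res = hyper_search(self.GEOM, imgs, lbls, epochs=2, seed=3)
        masks = res.masks({"b0": (3, 4), "b1": (4, 4)})
        for m in masks.values():
            assert np.all(m[:, :, 1, 1] > 0)
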