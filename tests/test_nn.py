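"""Autodiff engine: gradients against finite differences, layer contracts."""

import numpy as np
import pytest

from cardiopyramid import nn


def gradcheck(f, inputs, eps=1e-5, tol=1e-6):
    """Compare reverse-mode gradients with central finite differences."""
    ts = [nn.Tensor(np.asarray(a, np.float64), requires_grad=True) for a in inputs]
    f(*ts).backward()
    for t in ts:
        num = np.zeros_like(t.data)
        it = np.nditer(t.data, flags=["multi_index"])
        for _ in it:
            i = it.multi_index
            orig = t.data[i]
            t.data[i] = orig + eps
            fp = float(f(*ts).data)
            t.data[i] = orig - eps
            fm = float(f(*ts).data)
            t.data[i] = orig
            num[i] = (fp - fm) / (2 * eps)
        scale = max(np.abs(num).max(), 1.0)
        assert np.abs(num - t.grad).max() / scale < tol, "gradient mismatch"


class TestElementwiseGradients:
    @pytest.mark.parametrize(
        "op",
        [
            lambda a: (a.relu() * nn.Tensor(np.linspace(-1, 1, 12).reshape(3, 4))).sum(),
            lambda a: (a.mish() ** 2).sum(),
            lambda a: a.tanh().sum(),
            lambda a: a.softplus().sum(),
            lambda a: (a * 2.0 + 1.0).exp().sum() * 1e-2,
            lambda a: ((a * a + 1.5).log()).sum(),
            lambda a: (a**3).mean(),
        ],
        ids=["relu", "mish", "tanh", "softplus", "exp", "log", "pow"],
    )
    def test_unary(self, op, rng):
        gradcheck(op, [rng.standard_normal((3, 4))])

    def test_binary_broadcast(self, rng):
        a = rng.standard_normal((2, 3, 4))
        b = rng.standard_normal((3, 1))
        gradcheck(lambda x, y: ((x * y) + (x / (y * y + 2.0))).sum(), [a, b])

    def test_matmul(self, rng):
        gradcheck(
            lambda x, y: (x @ y).sum(),
            [rng.standard_normal((3, 4)), rng.standard_normal((4, 2))],
        )

    def test_softmax(self, rng):
        m = nn.Tensor(rng.standard_normal((3, 5)))
        gradcheck(lambda a: (a.softmax(axis=1) * m).sum(), [rng.standard_normal((3, 5))])

    def test_maximum(self, rng):
        m = nn.Tensor(rng.standard_normal((2, 4)))
        gradcheck(
            lambda a, b: (nn.maximum(a, b) * m).sum(),
            [rng.standard_normal((2, 4)), rng.standard_normal((1, 4))],
        )

    def test_concat_and_reductions(self, rng):
        gradcheck(
            lambda a, b: nn.concat([a, b], axis=1).mean(axis=(0, 1)).sum(),
            [rng.standard_normal((2, 3)), rng.standard_normal((2, 2))],
        )


class TestConvGradients:
    @pytest.mark.parametrize(
        "stride,pad",
        [((1, 1, 1), (0, 0, 0)), ((1, 1, 1), (1, 1, 1)), ((2, 1, 2), (1, 0, 1))],
    )
    def test_conv3d(self, stride, pad, rng):
        x = rng.standard_normal((2, 2, 4, 4, 5))
        w = rng.standard_normal((3, 2, 3, 3, 3))
        gradcheck(lambda a, b: (a.conv3d(b, stride=stride, pad=pad) ** 2).sum(), [x, w])

    def test_conv3d_forward_against_direct_sum(self, rng):
        x = rng.standard_normal((2, 3, 5, 6, 7))
        w = rng.standard_normal((4, 3, 3, 1, 3))
        out = nn.Tensor(x).conv3d(nn.Tensor(w), stride=(2, 1, 1), pad=(1, 0, 1)).data
        xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (0, 0), (1, 1)))
        for n, o, i, j, k in [(0, 0, 0, 0, 0), (1, 3, 1, 2, 3), (1, 2, 2, 5, 4)]:
            ref = np.sum(xp[n, :, 2 * i : 2 * i + 3, j : j + 1, k : k + 3] * w[o])
            assert out[n, o, i, j, k] == pytest.approx(ref, rel=1e-10)

    def test_zero_insert_and_transposed_conv(self, rng):
        x = rng.standard_normal((1, 2, 3, 3, 4))
        w = rng.standard_normal((2, 3, 2, 2, 4))

        def f(a, b):
            z = a.zero_insert((1, 1, 2))
            return (z.conv3d(b.flip((2, 3, 4)).swapaxes(0, 1), pad=(1, 1, 2)) ** 2).sum()

        gradcheck(f, [x, w])

    def test_maxpool3d(self, rng):
        x = rng.standard_normal((2, 2, 4, 5, 6))
        m = nn.Tensor(rng.standard_normal((2, 2, 2, 2, 3)))
        gradcheck(lambda a: (a.maxpool3d((2, 2, 2)) * m).sum(), [x])

    def test_maxpool_small_axis_left_unpooled(self, rng):
        x = nn.Tensor(rng.standard_normal((1, 1, 1, 4, 4)))
        assert x.maxpool3d((2, 2, 2)).shape == (1, 1, 1, 2, 2)

    def test_batchnorm(self, rng):
        x = rng.standard_normal((3, 2, 2, 2, 3))
        g = rng.standard_normal(2)
        b = rng.standard_normal(2)
        m = nn.Tensor(rng.standard_normal((3, 2, 2, 2, 3)))
        gradcheck(lambda a, gg, bb: (a.batchnorm(gg, bb)[0] * m).sum(), [x, g, b], tol=1e-5)


class TestLayers:
    def test_convtranspose_inverts_pool_shape(self, rng):
        ct = nn.ConvTranspose3d(3, 2, (3, 3, 4), stride=(1, 1, 2), pad=(1, 1, 1))
        y = ct(nn.Tensor(rng.standard_normal((1, 3, 5, 5, 8)).astype(np.float32)))
        assert y.shape == (1, 2, 5, 5, 16)

    def test_batchnorm_layer_normalizes(self, rng):
        bn = nn.BatchNorm3d(4)
        x = nn.Tensor(rng.standard_normal((8, 4, 3, 3, 3)).astype(np.float32) * 5 + 2)
        y = bn(x).data
        assert np.abs(y.mean(axis=(0, 2, 3, 4))).max() < 1e-4
        assert np.abs(y.var(axis=(0, 2, 3, 4)) - 1).max() < 1e-2

    def test_batchnorm_eval_uses_running_stats(self, rng):
        bn = nn.BatchNorm3d(2, momentum=1.0)
        x = rng.standard_normal((16, 2, 2, 2, 2)).astype(np.float32)
        bn(nn.Tensor(x))
        bn.eval()
        y = bn(nn.Tensor(x)).data
        assert np.abs(y.mean(axis=(0, 2, 3, 4))).max() < 0.05

    def test_dropout_modes(self, rng):
        d = nn.Dropout(0.5, rng=np.random.default_rng(1))
        x = nn.Tensor(np.ones((100, 100), np.float32))
        train_out = d(x).data
        assert np.mean(train_out == 0) == pytest.approx(0.5, abs=0.05)
        assert train_out.mean() == pytest.approx(1.0, abs=0.05)  # inverted scaling
        d.eval()
        np.testing.assert_array_equal(d(x).data, x.data)

    def test_module_parameter_discovery(self):
        seq = nn.Sequential(
            nn.Conv3d(1, 2, (1, 1, 3), bias=True), nn.BatchNorm3d(2), nn.Mish()
        )
        # conv weight + bias + bn gamma + bn beta
        assert len(seq.parameters()) == 4

    def test_adam_minimizes_quadratic(self):
        x = nn.Tensor(np.array([5.0, -3.0], np.float64), requires_grad=True)
        opt = nn.Adam([x], lr=0.1)
        for _ in range(300):
            loss = (x * x).sum()
            opt.zero_grad()
            loss.backward()
            opt.step()
        assert np.abs(x.data).max() < 1e-3

    def test_cross_entropy_matches_manual(self, rng):
        logits = rng.standard_normal((6, 3))
        labels = np.array([0, 1, 2, 0, 1, 2])
        got = float(nn.cross_entropy(nn.Tensor(logits), labels).data)
        p = np.exp(logits - logits.max(axis=1, keepdims=True))
        p /= p.sum(axis=1, keepdims=True)
        ref = -np.mean(np.log(p[np.arange(6), labels]))
        assert got == pytest.approx(ref, rel=1e-6)
        gradcheck(lambda a: nn.cross_entropy(a, labels), [logits], tol=1e-5)

    def test_no_grad_suppresses_tape(self, rng):
        w = nn.Tensor(rng.standard_normal((3, 3)), requires_grad=True)
        with nn.no_grad():
            y = nn.Tensor(rng.standard_normal((2, 3))) @ w
        assert not y.requires_grad
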