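"""Tri-pattern attention: normalization, correction, fusion, equivariances."""

import numpy as np
import pytest

from cardiopyramid import nn
from cardiopyramid.attention import (
    TPAM,
    TPAMConfig,
    compute_attention_maps,
    tpam_fuse,
    weight_correction,
)


class TestAttentionMaps:
    def test_constant_input_gives_uniform_maps(self):
        beta = np.ones((3, 4, 5))
        maps = compute_attention_maps(beta)
        np.testing.assert_allclose(maps.att_spe, np.full((3, 4), 1 / 12), atol=1e-12)
        np.testing.assert_allclose(maps.att_tem, np.full((4, 3), 1 / 12), atol=1e-12)
        np.testing.assert_allclose(maps.att_spa, np.full(5, 1 / 5), atol=1e-12)

    def test_maps_sum_to_one(self, rng):
        for _ in range(100):
            H, W, K = rng.integers(1, 7, size=3)
            beta = rng.standard_normal((H, W, K))
            maps = compute_attention_maps(beta)
            assert abs(maps.att_spe.sum() - 1) < 1e-6
            assert abs(maps.att_tem.sum() - 1) < 1e-6
            assert abs(maps.att_spa.sum() - 1) < 1e-6
            for m in (maps.att_spe, maps.att_tem, maps.att_spa):
                assert np.all(m > 0) and np.all(m < 1 + 1e-12)

    def test_hand_softmax_example(self):
        """Scores (1,0,0,0) on a 2x2 grid -> softmax (0.4754, 0.1749, ...)."""
        beta = np.array([1.0, 0.0, 0.0, 0.0]).reshape(2, 2, 1)
        maps = compute_attention_maps(beta)  # identity-sum dense weights
        expect = np.exp([1, 0, 0, 0]) / np.exp([1.0, 0, 0, 0]).sum()
        np.testing.assert_allclose(maps.att_spe.ravel(), expect, atol=1e-4)
        np.testing.assert_allclose(
            maps.att_spe.ravel(), [0.4754, 0.1749, 0.1749, 0.1749], atol=1e-4
        )

    def test_non_finite_input_rejected(self):
        beta = np.ones((2, 2, 1))
        beta[0, 0, 0] = np.nan
        with pytest.raises(FloatingPointError):
            compute_attention_maps(beta)

    def test_spatial_permutation_equivariance(self, rng):
        beta = rng.standard_normal((3, 3, 6))
        perm = rng.permutation(6)
        a = compute_attention_maps(beta).att_spa
        b = compute_attention_maps(beta[:, :, perm]).att_spa
        np.testing.assert_allclose(b, a[perm], atol=1e-12)

    def test_transpose_consistency_with_tied_weights(self, rng):
        """att_tem on beta equals att_spe on beta^T when weights are shared."""
        beta = rng.standard_normal((4, 3, 5))
        w = rng.standard_normal(5)
        maps = compute_attention_maps(beta, w_spe=w, w_tem=w)
        maps_t = compute_attention_maps(beta.transpose(1, 0, 2), w_spe=w, w_tem=w)
        np.testing.assert_allclose(maps.att_tem, maps_t.att_spe, atol=1e-12)


class TestWeightCorrection:
    def test_degenerate_1x1_grid(self):
        maps = compute_attention_maps(np.ones((1, 1, 1)))
        cw = weight_correction(maps)
        assert cw.att_add[0, 0, 0] == pytest.approx(3.0)
        assert cw.att_max[0, 0, 0] == pytest.approx(1.0)

    def test_uniform_2x2_grid_k2(self):
        """Uniform maps: add = 0.25+0.25+0.5 = 1.0; max = max(0.0625, 0.5)."""
        maps = compute_attention_maps(np.ones((2, 2, 2)))
        cw = weight_correction(maps)
        np.testing.assert_allclose(cw.att_add, 1.0, atol=1e-12)
        np.testing.assert_allclose(cw.att_max, 0.5, atol=1e-12)

    def test_max_dominates_both_constituents(self, rng):
        for _ in range(20):
            H, W, K = rng.integers(1, 6, size=3)
            maps = compute_attention_maps(rng.standard_normal((H, W, K)))
            cw = weight_correction(maps)
            prod = (maps.att_spe * maps.att_tem.T)[:, :, None]
            spa = maps.att_spa[None, None, :]
            assert np.all(cw.att_max >= prod - 1e-15)
            assert np.all(cw.att_max >= spa - 1e-15)
            assert np.all(cw.att_max <= np.maximum(prod, spa) + 1e-15)


class TestFusion:
    def test_attention_neutral_identity(self, rng):
        """att_add == 1 with the identity kernel leaves beta unchanged."""
        beta = rng.standard_normal((4, 4, 3))
        maps = compute_attention_maps(np.ones((4, 4, 3)))
        cw = weight_correction(maps)
        cw.att_add = np.ones_like(cw.att_add)
        out = tpam_fuse(beta, cw)
        np.testing.assert_allclose(out.i_add, beta, atol=1e-6)

    def test_channel_arithmetic_and_pooling(self, rng):
        """K=8, K_add=8 -> 24 fused channels on a halved grid."""
        beta = rng.standard_normal((6, 6, 8))
        cw = weight_correction(compute_attention_maps(beta))
        out = tpam_fuse(beta, cw)
        assert out.i_max.shape == (6, 6, 16)
        assert out.i_tpam.shape == (3, 3, 24)

    def test_zero_input_gives_zero_output(self):
        beta = np.zeros((4, 4, 2))
        cw = weight_correction(compute_attention_maps(beta))
        out = tpam_fuse(beta, cw)
        np.testing.assert_array_equal(out.i_tpam, 0.0)


class TestTPAMModule:
    def _batch(self, rng, n=2, k=5, h=4, w=4, b=6):
        return nn.Tensor(rng.standard_normal((n, k, h, w, b)).astype(np.float32))

    def test_batched_maps_normalized(self, rng):
        tpam = TPAM(5, TPAMConfig(seed=1))
        att_spe, att_tem_t, att_spa = tpam.attention(self._batch(rng))
        np.testing.assert_allclose(att_spe.data.sum(axis=(1, 2)), 1.0, atol=1e-5)
        np.testing.assert_allclose(att_tem_t.data.sum(axis=(1, 2)), 1.0, atol=1e-5)
        np.testing.assert_allclose(att_spa.data.sum(axis=1), 1.0, atol=1e-5)

    def test_output_channels_and_pooling(self, rng):
        tpam = TPAM(5, TPAMConfig(conv_out_channels=3))
        out = tpam(self._batch(rng))
        assert out.shape == (2, 13, 2, 2, 6)  # 2K + K_add = 13; H,W halved
        assert tpam.out_channels == 13

    def test_modes(self, rng):
        x = self._batch(rng)
        assert TPAM(5, TPAMConfig(mode="add", conv_out_channels=3))(x).shape[1] == 3
        assert TPAM(5, TPAMConfig(mode="max"))(x).shape[1] == 10

    def test_module_matches_functional_on_singleton(self, rng):
        """Batched module path agrees with the single-map functional path."""
        beta = rng.standard_normal((3, 4, 5)).astype(np.float64)
        tpam = TPAM(5, TPAMConfig(seed=3))
        bt = nn.Tensor(beta.transpose(2, 0, 1)[None, :, :, :, None])
        att_spe, att_tem_t, att_spa = tpam.attention(bt)
        maps = compute_attention_maps(
            beta,
            w_spe=tpam.w_spe.data, b_spe=float(tpam.b_spe.data[0]),
            w_tem=tpam.w_tem.data, b_tem=float(tpam.b_tem.data[0]),
            w_spa=float(tpam.w_spa.data[0]), b_spa=float(tpam.b_spa.data[0]),
        )
        np.testing.assert_allclose(att_spe.data[0], maps.att_spe, atol=1e-6)
        np.testing.assert_allclose(att_tem_t.data[0], maps.att_tem.T, atol=1e-6)
        np.testing.assert_allclose(att_spa.data[0], maps.att_spa, atol=1e-6)

    def test_every_effective_parameter_receives_gradient(self, rng):
        """All output-affecting parameters get nonzero gradients.

        The dense biases sit inside a softmax over positions (or channels),
        and softmax is invariant to a uniform score shift, so those biases
        are structurally gradient-free and excluded here.
        """
        tpam = TPAM(4, TPAMConfig(seed=2, conv_out_channels=2))
        x = self._batch(rng, k=4)
        out = tpam(x)
        (out * nn.Tensor(np.random.default_rng(1).standard_normal(out.shape).astype(np.float32))).sum().backward()
        biases = {id(tpam.b_spe), id(tpam.b_tem), id(tpam.b_spa)}
        checked = 0
        for p in tpam.parameters():
            if id(p) in biases:
                continue
            assert p.grad is not None
            assert np.any(p.grad != 0)
            checked += 1
        assert checked >= 3  # w_spe, w_tem, w_spa, conv weight

    def test_gradient_finite_difference_spot_check(self, rng):
        """Autodiff gradients match finite differences for 3 parameters."""
        tpam = TPAM(3, TPAMConfig(seed=5, conv_out_channels=2))
        x = self._batch(rng, k=3, b=4)
        mult = nn.Tensor(np.random.default_rng(2).standard_normal((2, 8, 2, 2, 4)).astype(np.float32))

        def loss_value():
            return float((tpam(x) * mult).sum().data)

        (tpam(x) * mult).sum().backward()
        eps = 1e-3
        checked = 0
        for p in (tpam.w_spe, tpam.w_spa, tpam.conv.weight):
            flat = p.data.ravel()
            g_flat = p.grad.ravel()
            idx = 0
            orig = flat[idx]
            flat[idx] = orig + eps
            fp = loss_value()
            flat[idx] = orig - eps
            fm = loss_value()
            flat[idx] = orig
            num = (fp - fm) / (2 * eps)
            assert num == pytest.approx(float(g_flat[idx]), rel=0.05, abs=1e-4)
            checked += 1
        assert checked == 3

    def test_double_axes_option(self, rng):
        x = self._batch(rng)
        base = TPAM(5, TPAMConfig(seed=1))
        doubled = TPAM(5, TPAMConfig(seed=1, double_axes=True))
        a = base(x).data
        b = doubled(x).data
        assert not np.allclose(a, b)
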