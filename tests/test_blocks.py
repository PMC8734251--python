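"""SE and attention-guided-filter operators against brute-force oracles."""

import itertools

import numpy as np
import pytest

from agsevnet.blocks import (
    AGFParams,
    AttentionBlockParams,
    SEParams,
    attention_block,
    attention_guided_filter,
    downsample_average,
    excite,
    guided_filter_coeffs,
    se_block,
    squeeze,
)


def brute_force_guided_filter_coeffs(i_l, o, t, r, eps):
    """Per-window weighted ridge regression via explicit 2x2 normal
    equations at every window, then averaging over covering windows."""
    _, D, H, W, C = o.shape
    a = np.zeros((D, H, W, C))
    b = np.zeros((D, H, W, C))
    for k in itertools.product(range(D), range(H), range(W)):
        sl = tuple(slice(max(0, c - r), min(n, c + r + 1))
                   for c, n in zip(k, (D, H, W)))
        w = (t[0][sl + (slice(None),)][..., 0] ** 2).ravel()
        iv = i_l[0][sl + (slice(None),)][..., 0].ravel()
        n_in = w.size
        for c in range(C):
            ov = o[0][sl + (slice(None),)][..., c].ravel()
            m = np.array([[np.sum(w * iv * iv) + n_in * eps, np.sum(w * iv)],
                          [np.sum(w * iv), np.sum(w)]])
            rhs = np.array([np.sum(w * iv * ov), np.sum(w * ov)])
            a[k + (c,)], b[k + (c,)] = np.linalg.solve(m, rhs)
    A = np.zeros_like(a)
    B = np.zeros_like(b)
    for k in itertools.product(range(D), range(H), range(W)):
        sl = tuple(slice(max(0, c - r), min(n, c + r + 1))
                   for c, n in zip(k, (D, H, W)))
        A[k] = a[sl].reshape(-1, C).mean(axis=0)
        B[k] = b[sl].reshape(-1, C).mean(axis=0)
    return A[None], B[None]


class TestSqueeze:
    def test_constant_channel_returns_value(self):
        u = np.full((1, 3, 4, 5, 2), 7.0)
        u[..., 1] = -2.0
        np.testing.assert_allclose(squeeze(u), [[7.0, -2.0]])

    def test_two_voxel_mean(self):
        u = np.array([1.0, 3.0]).reshape(1, 2, 1, 1, 1)
        np.testing.assert_allclose(squeeze(u), [[2.0]])

    def test_matches_triple_loop_mean(self, rng):
        u = rng.normal(size=(2, 3, 4, 5, 6))
        expected = np.empty((2, 6))
        for n in range(2):
            for c in range(6):
                acc = 0.0
                for z in range(3):
                    for y in range(4):
                        for x in range(5):
                            acc += u[n, z, y, x, c]
                expected[n, c] = acc / (3 * 4 * 5)
        np.testing.assert_allclose(squeeze(u), expected, atol=1e-6)


class TestExcite:
    def test_zero_weights_give_half_gates(self):
        params = SEParams(W1=np.zeros((2, 8)), W2=np.zeros((8, 2)))
        s = excite(np.ones(8), params)
        np.testing.assert_allclose(s, 0.5)

    def test_saturation_with_large_weights(self):
        params = SEParams(W1=np.full((2, 8), 10.0), W2=np.full((8, 2), 10.0))
        s = excite(np.ones(8), params)
        assert np.all(s > 0.999)

    def test_matches_matrix_oracle(self, rng):
        params = SEParams.init(8, m=4, rng=rng)
        z = rng.normal(size=(3, 8))
        expected = 1.0 / (1.0 + np.exp(
            -(np.maximum(z @ params.W1.T, 0) @ params.W2.T)))
        np.testing.assert_allclose(excite(z, params), expected, atol=1e-6)

    def test_gates_strictly_in_unit_interval(self, rng):
        params = SEParams.init(8, rng=rng, scale=2.0)
        s = excite(rng.normal(size=(4, 8)), params)
        assert np.all((s > 0) & (s < 1))

    def test_indivisible_channels_rejected(self):
        with pytest.raises(ValueError, match="divisible"):
            SEParams.init(6, m=4)


class TestSEBlock:
    def _forced_gate_params(self, channels, logit):
        # W1 = 0 rows -> relu output 0; bias-free second layer cannot hit
        # arbitrary gates, so drive via W2 @ relu(W1 z) with constant z=1:
        # instead use identity-free construction: W1 zero, gates = 0.5.
        return SEParams(W1=np.zeros((channels // 4, channels)),
                        W2=np.full((channels, channels // 4), logit))

    def test_half_gates_halve_input(self, rng):
        x = rng.normal(size=(1, 3, 3, 3, 4))
        params = SEParams(W1=np.zeros((1, 4)), W2=np.zeros((4, 1)))
        np.testing.assert_allclose(se_block(x, params), x / 2.0, atol=1e-7)

    def test_unit_gates_identity(self, rng):
        # saturate the gate towards 1: huge positive composed weights
        x = np.abs(rng.normal(size=(1, 3, 3, 3, 4))) + 1.0
        params = SEParams(W1=np.full((1, 4), 50.0), W2=np.full((4, 1), 50.0))
        np.testing.assert_allclose(se_block(x, params), x, rtol=1e-4)

    def test_gate_ordering_preserves_norm_ordering(self, rng):
        # two equal-norm channels; construct gates s0 < s1 by hand
        x = np.zeros((1, 2, 2, 2, 4))
        x[..., 0] = 1.0
        x[..., 1] = -1.0  # equal norm, different sign pattern
        params = SEParams.init(4, rng=rng)
        s = excite(squeeze(x), params)[0]
        out = se_block(x, params)[0]
        norms = [np.linalg.norm(out[..., c]) for c in range(2)]
        if s[0] > s[1]:
            assert norms[0] > norms[1]
        elif s[0] < s[1]:
            assert norms[0] < norms[1]


class TestAttentionBlock:
    def test_zero_weights_give_half(self, rng):
        params = AttentionBlockParams(
            wo=np.zeros((3, 3)), wi=np.zeros((1, 3)), bo=np.zeros(3),
            bi=np.zeros(3), wt=np.zeros((3, 1)), bt=np.zeros(1))
        t = attention_block(rng.normal(size=(1, 2, 2, 2, 3)),
                            rng.normal(size=(1, 2, 2, 2, 1)), params)
        np.testing.assert_allclose(t, 0.5)

    def test_output_in_open_unit_interval(self, rng):
        params = AttentionBlockParams.init(3, 1, rng=rng, scale=1.0)
        t = attention_block(rng.normal(size=(1, 3, 3, 3, 3)),
                            rng.normal(size=(1, 3, 3, 3, 1)), params)
        assert t.shape == (1, 3, 3, 3, 1)
        assert np.all((t > 0) & (t < 1))

    def test_constant_inputs_closed_form(self):
        # zero O and I_l: T = sigmoid(wt . relu(bo + bi) + bt)
        bo = np.array([0.3, -1.0])
        bi = np.array([0.2, 0.5])
        wt = np.array([[1.5], [2.0]])
        bt = np.array([0.1])
        params = AttentionBlockParams(
            wo=np.zeros((2, 2)), wi=np.zeros((1, 2)),
            bo=bo, bi=bi, wt=wt, bt=bt)
        t = attention_block(np.zeros((1, 2, 2, 2, 2)),
                            np.zeros((1, 2, 2, 2, 1)), params)
        expected = 1 / (1 + np.exp(-(np.maximum(bo + bi, 0) @ wt + bt)))
        np.testing.assert_allclose(t, expected[0], atol=1e-12)

    def test_spatial_mismatch_rejected(self, rng):
        params = AttentionBlockParams.init(2, 1, rng=rng)
        with pytest.raises(ValueError, match="spatial"):
            attention_block(np.zeros((1, 2, 2, 2, 2)),
                            np.zeros((1, 4, 4, 4, 1)), params)


class TestGuidedFilterCoeffs:
    @pytest.mark.parametrize("r", [1, 2])
    @pytest.mark.parametrize("weighted", [False, True])
    def test_matches_brute_force_normal_equations(self, rng, r, weighted):
        i_l = rng.normal(size=(1, 6, 7, 6, 1))
        o = rng.normal(size=(1, 6, 7, 6, 2))
        t = (rng.uniform(0.2, 0.95, size=(1, 6, 7, 6, 1)) if weighted
             else np.ones((1, 6, 7, 6, 1)))
        params = AGFParams(r=r, epsilon=0.01)
        fc = guided_filter_coeffs(i_l, o, t, params)
        A, B = brute_force_guided_filter_coeffs(i_l, o, t, r, params.epsilon)
        np.testing.assert_allclose(fc.A, A, atol=1e-5)
        np.testing.assert_allclose(fc.B, B, atol=1e-5)

    def test_unit_attention_equals_unweighted_closed_form(self, rng):
        """With T == 1 the weighted solution reduces to the classical
        unweighted guided-filter coefficients."""
        i_l = rng.normal(size=(1, 6, 6, 6, 1))
        o = rng.normal(size=(1, 6, 6, 6, 1))
        ones = np.ones((1, 6, 6, 6, 1))
        weighted = guided_filter_coeffs(i_l, o, ones, AGFParams(r=2))
        unweighted = guided_filter_coeffs(
            i_l, o, None, AGFParams(r=2, attention=False))
        np.testing.assert_allclose(weighted.A, unweighted.A, atol=1e-12)
        np.testing.assert_allclose(weighted.B, unweighted.B, atol=1e-12)

    def test_self_guidance_identity_limit(self, rng):
        i_l = rng.normal(size=(1, 8, 8, 8, 1))
        params = AGFParams(r=2, epsilon=1e-10)
        fc = guided_filter_coeffs(i_l, i_l, None, params)
        filtered = fc.A * i_l + fc.B
        np.testing.assert_allclose(filtered, i_l, atol=1e-4)

    def test_constant_o_gives_zero_slope(self, rng):
        i_l = rng.normal(size=(1, 6, 6, 6, 1))
        o = np.full((1, 6, 6, 6, 1), 3.25)
        fc = guided_filter_coeffs(i_l, o, None, AGFParams(r=2, epsilon=0.5))
        np.testing.assert_allclose(fc.A, 0.0, atol=1e-10)
        np.testing.assert_allclose(fc.B, 3.25, atol=1e-10)

    def test_epsilon_must_be_positive(self):
        with pytest.raises(ValueError):
            AGFParams(r=2, epsilon=0.0)


class TestAttentionGuidedFilter:
    def test_reconstruction_limit(self, rng):
        i = rng.normal(size=(1, 12, 12, 12, 1))
        o = downsample_average(i, 2)
        out = attention_guided_filter(
            i, o, AGFParams(r=2, epsilon=1e-8, attention=False))
        # low-pass reconstruction: close to the guidance away from borders
        core = (slice(0, 1), slice(2, 10), slice(2, 10), slice(2, 10))
        assert np.abs(out - i)[core].mean() < 0.2

    def test_constant_o_propagates_constant(self, rng):
        i = rng.normal(size=(1, 8, 8, 8, 1))
        o = np.full((1, 4, 4, 4, 3), -1.5)
        out = attention_guided_filter(i, o, AGFParams(r=2))
        np.testing.assert_allclose(out, -1.5, atol=1e-10)

    def test_output_shape_contract(self, rng):
        i = rng.normal(size=(1, 32, 32, 32, 1))
        o = rng.normal(size=(1, 16, 16, 16, 8))
        attn = AttentionBlockParams.init(8, 1, rng=rng)
        out = attention_guided_filter(i, o, AGFParams(r=2), attn=attn)
        assert out.shape == (1, 32, 32, 32, 8)

    def test_non_integer_scale_rejected(self, rng):
        i = rng.normal(size=(1, 12, 12, 12, 1))
        o = rng.normal(size=(1, 8, 8, 8, 1))
        with pytest.raises(ValueError):
            attention_guided_filter(i, o, AGFParams(r=2))
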