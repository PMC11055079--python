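"""Attention mechanisms against hand arithmetic and the loop oracle."""

import math

import numpy as np
import pytest

import reference_attention as ref
from timetector.attention import (
    AttentionOutput,
    AttentionParams,
    AttentionSpec,
    combine_heads,
    cross_mha,
    feature_enhanced_mha,
    fuse,
    hierarchical_mha,
    multi_head_attention,
    project_qkv,
    scaled_dot_attention,
    split_heads,
)

RNG = np.random.default_rng(7)


def random_params(d, rng, d_f=None):
    return AttentionParams(
        w_q=rng.standard_normal((d, d)),
        w_k=rng.standard_normal((d, d)),
        w_v=rng.standard_normal((d, d)),
        w_o=rng.standard_normal((d, d)),
        w_f=rng.standard_normal((d_f, d)) if d_f else None,
    )


class TestSpec:
    def test_default_head_depth_is_eight(self):
        assert AttentionSpec(64, 8).head_depth == 8

    def test_indivisible_heads_rejected(self):
        with pytest.raises(ValueError):
            AttentionSpec(64, 7)


class TestPrimitives:
    def test_identity_projection(self):
        H = RNG.standard_normal((5, 4))
        eye = AttentionParams(np.eye(4), np.eye(4), np.eye(4), np.eye(4))
        Q, K, V = project_qkv(H, eye)
        for M in (Q, K, V):
            np.testing.assert_allclose(M, H)

    def test_hand_matrix_product(self):
        H = np.array([[1.0, 2.0], [3.0, 4.0]])
        p = AttentionParams(
            np.array([[1.0, 0.0], [1.0, 1.0]]),
            np.array([[2.0, 0.0], [0.0, 2.0]]),
            np.array([[0.0, 1.0], [1.0, 0.0]]),
            np.eye(2),
        )
        Q, K, V = project_qkv(H, p)
        np.testing.assert_allclose(Q, [[3.0, 2.0], [7.0, 4.0]])
        np.testing.assert_allclose(K, [[2.0, 4.0], [6.0, 8.0]])
        np.testing.assert_allclose(V, [[2.0, 1.0], [4.0, 3.0]])

    def test_projection_width_mismatch(self):
        with pytest.raises(ValueError):
            project_qkv(RNG.standard_normal((5, 3)), random_params(4, RNG))

    def test_split_combine_round_trip(self):
        M = RNG.standard_normal((6, 8))
        for h in (1, 2, 4, 8):
            np.testing.assert_array_equal(combine_heads(split_heads(M, h)), M)
        assert split_heads(M, 4).shape == (4, 6, 2)
        assert np.array_equal(split_heads(M, 1)[0], M)

    def test_split_indivisible_rejected(self):
        with pytest.raises(ValueError):
            split_heads(RNG.standard_normal((6, 8)), 3)

    def test_softmax_of_singleton_is_one(self):
        out, w = scaled_dot_attention(
            np.array([[1.0, 2.0]]), np.array([[3.0, 4.0]]), np.array([[5.0, 6.0]])
        )
        np.testing.assert_allclose(w, [[1.0]])
        np.testing.assert_allclose(out, [[5.0, 6.0]])

    def test_identical_keys_give_uniform_weights(self):
        T = 5
        K = np.tile([1.0, 2.0], (T, 1))
        _, w = scaled_dot_attention(RNG.standard_normal((T, 2)), K, RNG.standard_normal((T, 2)))
        np.testing.assert_allclose(w, np.full((T, T), 1.0 / T), atol=1e-12)

    def test_two_by_two_closed_form(self):
        """Identity Q/K with V=[[1,2],[3,4]]: weights follow exp(1/sqrt(2))."""
        Q = np.eye(2)
        K = np.eye(2)
        V = np.array([[1.0, 2.0], [3.0, 4.0]])
        a = math.exp(1.0 / math.sqrt(2.0))
        w_big = a / (a + 1.0)
        w_small = 1.0 / (a + 1.0)
        out, w = scaled_dot_attention(Q, K, V)
        np.testing.assert_allclose(w, [[w_big, w_small], [w_small, w_big]], atol=1e-12)
        expected = np.array(
            [
                [w_big * 1 + w_small * 3, w_big * 2 + w_small * 4],
                [w_small * 1 + w_big * 3, w_small * 2 + w_big * 4],
            ]
        )
        np.testing.assert_allclose(out, expected, atol=1e-12)

    def test_sqrt_dk_scaling_applied_exactly_once(self):
        Q = RNG.standard_normal((4, 4))
        K = RNG.standard_normal((4, 4))
        V = RNG.standard_normal((4, 4))
        _, w = scaled_dot_attention(Q, K, V)

        def soft(s):
            e = np.exp(s - s.max(axis=1, keepdims=True))
            return e / e.sum(axis=1, keepdims=True)

        np.testing.assert_allclose(w, soft(Q @ K.T / 2.0), atol=1e-12)  # sqrt(4) = 2
        assert not np.allclose(w, soft(Q @ K.T))  # unscaled
        assert not np.allclose(w, soft(Q @ K.T / 4.0))  # double-scaled

    def test_non_finite_inputs_rejected(self):
        bad = np.array([[np.nan, 1.0]])
        with pytest.raises(ValueError):
            scaled_dot_attention(bad, bad, bad)


def instances(n, seed=13):
    rng = np.random.default_rng(seed)
    for _ in range(n):
        heads = int(rng.choice([1, 2, 4]))
        d = heads * int(rng.choice([1, 2]))
        if d > 8:
            d = 8
        T = int(rng.integers(1, 7))
        yield T, d, heads, rng


class TestMechanismOracles:
    def test_mha_matches_loop_reference(self):
        for T, d, heads, rng in instances(30):
            H = rng.standard_normal((T, d))
            p = random_params(d, rng)
            got = multi_head_attention(H, p, AttentionSpec(d, heads, 0))
            want, w = ref.ref_mha(H, p, heads)
            np.testing.assert_allclose(got.values, want, atol=1e-6)
            np.testing.assert_allclose(got.weights, w, atol=1e-6)

    def test_hierarchical_matches_loop_reference(self):
        for T, d, heads, rng in instances(20):
            H = rng.standard_normal((T, d))
            layers = int(rng.integers(1, 4))
            ps = [random_params(d, rng) for _ in range(layers)]
            got = hierarchical_mha(H, ps, AttentionSpec(d, heads, layers))
            want, _ = ref.ref_hierarchical(H, ps, heads)
            np.testing.assert_allclose(got.values, want, atol=1e-6)

    def test_cross_matches_loop_reference(self):
        for T, d, heads, rng in instances(20):
            H = rng.standard_normal((T, d))
            Tk = int(rng.integers(1, 7))
            K = rng.standard_normal((Tk, d))
            V = rng.standard_normal((Tk, d))
            for add_self in (False, True):
                got = cross_mha(H, K, V, (p := random_params(d, rng)), AttentionSpec(d, heads, 0),
                                add_self=add_self)
                want, _ = ref.ref_cross(H, K, V, p, heads, add_self=add_self)
                np.testing.assert_allclose(got.values, want, atol=1e-6)

    def test_feature_enhanced_matches_loop_reference(self):
        for T, d, heads, rng in instances(20):
            H = rng.standard_normal((T, d))
            d_f = int(rng.integers(1, 6))
            F = rng.standard_normal((T, d_f))
            layers = int(rng.integers(1, 4))
            ps = [random_params(d, rng, d_f=d_f) for _ in range(layers)]
            got = feature_enhanced_mha(H, F, ps, AttentionSpec(d, heads, layers))
            want, _ = ref.ref_feature_enhanced(H, F, ps, heads)
            np.testing.assert_allclose(got.values, want, atol=1e-6)


class TestReductions:
    """Degenerate configurations must collapse onto plain multi-head attention."""

    def test_hierarchical_single_layer_reduces_to_mha(self):
        H = RNG.standard_normal((5, 8))
        p = random_params(8, RNG)
        a = hierarchical_mha(H, [p], AttentionSpec(8, 2, 1))
        b = multi_head_attention(H, p, AttentionSpec(8, 2, 0))
        np.testing.assert_allclose(a.values, b.values, atol=1e-12)

    def test_hierarchical_two_layers_equals_manual_composition(self):
        H = RNG.standard_normal((5, 8))
        p1, p2 = random_params(8, RNG), random_params(8, RNG)
        spec = AttentionSpec(8, 2, 2)
        got = hierarchical_mha(H, [p1, p2], spec)
        # manual: layer-1 output as query source, layer-1 K/V retained
        out1 = multi_head_attention(H, p1, spec).values
        K1, V1 = H @ p1.w_k, H @ p1.w_v
        q2 = split_heads(out1 @ p2.w_q, 2)
        o2, _ = scaled_dot_attention(q2, split_heads(K1, 2), split_heads(V1, 2))
        want = combine_heads(o2) @ p2.w_o
        np.testing.assert_allclose(got.values, want, atol=1e-10)

    def test_cross_with_self_kv_reduces_to_mha(self):
        H = RNG.standard_normal((6, 8))
        p = random_params(8, RNG)
        spec = AttentionSpec(8, 4, 0)
        a = cross_mha(H, H @ p.w_k, H @ p.w_v, p, spec)
        b = multi_head_attention(H, p, spec)
        np.testing.assert_allclose(a.values, b.values, atol=1e-10)

    def test_feature_enhanced_with_zero_features_reduces_to_mha(self):
        H = RNG.standard_normal((6, 8))
        p = random_params(8, RNG, d_f=3)
        a = feature_enhanced_mha(H, np.zeros((6, 3)), [p], AttentionSpec(8, 2, 1))
        b = multi_head_attention(H, p, AttentionSpec(8, 2, 0))
        np.testing.assert_allclose(a.values, b.values, atol=1e-12)

    def test_feature_matrix_shape_enforced(self):
        H = RNG.standard_normal((6, 8))
        p = random_params(8, RNG, d_f=3)
        with pytest.raises(ValueError):
            feature_enhanced_mha(H, np.zeros((5, 3)), [p], AttentionSpec(8, 2, 1))
        with pytest.raises(ValueError):
            feature_enhanced_mha(H, np.zeros((6, 4)), [p], AttentionSpec(8, 2, 1))


class TestInvariants:
    def test_weight_rows_normalised_all_mechanisms(self):
        H = RNG.standard_normal((6, 8))
        F = RNG.standard_normal((6, 4))
        spec = AttentionSpec(8, 2, 0)
        outs = [
            multi_head_attention(H, random_params(8, RNG), spec),
            hierarchical_mha(H, [random_params(8, RNG) for _ in range(3)], AttentionSpec(8, 2, 3)),
            cross_mha(H, RNG.standard_normal((4, 8)), RNG.standard_normal((4, 8)),
                      random_params(8, RNG), spec),
            feature_enhanced_mha(H, F, [random_params(8, RNG, d_f=4) for _ in range(2)],
                                 AttentionSpec(8, 2, 2)),
        ]
        for o in outs:
            assert np.all(o.weights >= 0)
            np.testing.assert_allclose(o.weights.sum(axis=-1), 1.0, atol=1e-6)

    def test_self_attention_permutation_equivariance(self):
        """Without positional terms, permuting timesteps permutes outputs."""
        rng = np.random.default_rng(3)
        for _ in range(10):
            H = rng.standard_normal((6, 8))
            p = random_params(8, rng)
            perm = rng.permutation(6)
            spec = AttentionSpec(8, 4, 0)
            direct = multi_head_attention(H[perm], p, spec).values
            permuted = multi_head_attention(H, p, spec).values[perm]
            np.testing.assert_allclose(direct, permuted, atol=1e-8)

    def test_batched_input_matches_per_sequence(self):
        H = RNG.standard_normal((3, 5, 8))
        p = random_params(8, RNG)
        spec = AttentionSpec(8, 2, 0)
        batched = multi_head_attention(H, p, spec)
        for i in range(3):
            single = multi_head_attention(H[i], p, spec)
            np.testing.assert_allclose(batched.values[i], single.values, atol=1e-10)


class TestFuse:
    def test_dimension_arithmetic(self):
        outs = [AttentionOutput(RNG.standard_normal((5, 64)), None) for _ in range(4)]
        fused = fuse(outs)
        assert fused.shape == (5, 256)

    def test_column_blocks_recover_inputs(self):
        outs = [RNG.standard_normal((4, 8)) for _ in range(4)]
        fused = fuse(outs)
        for i, o in enumerate(outs):
            np.testing.assert_array_equal(fused[:, i * 8 : (i + 1) * 8], o)

    def test_order_is_part_of_the_contract(self):
        outs = [RNG.standard_normal((4, 8)) for _ in range(4)]
        assert not np.array_equal(fuse(outs), fuse(outs[::-1]))

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            fuse([RNG.standard_normal((4, 8)), RNG.standard_normal((5, 8))])
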