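"""Fusion math: averaging, scalar weights, attention, cross-entropy."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from leaffuse import (
    AttentionParams,
    ScalarWeights,
    attention_alpha,
    attention_fuse,
    average_fuse,
    categorical_cross_entropy,
    fit_attention,
    fuse_table,
    fused_accuracy,
    gen_member_probs,
    scalar_fuse,
)


def random_member_outputs(n, n_models, k, seed):
    rng = np.random.default_rng(seed)
    x = rng.gamma(1.0, size=(n, n_models, k))
    return x / x.sum(axis=2, keepdims=True)


class TestAverageFuse:
    def test_elementwise_mean(self):
        out = average_fuse([[0.6, 0.4], [0.2, 0.8]])
        np.testing.assert_allclose(out, [0.4, 0.6], atol=1e-15)

    def test_idempotent_on_identical_members(self):
        v = np.array([0.1, 0.2, 0.7])
        np.testing.assert_allclose(average_fuse([v, v, v]), v, atol=1e-15)

    def test_single_member_identity(self):
        v = np.array([0.3, 0.7])
        np.testing.assert_allclose(average_fuse([v]), v, atol=1e-15)


class TestScalarFuse:
    def test_vertex_weight_selects_member(self):
        o1, o2 = np.array([0.9, 0.1]), np.array([0.2, 0.8])
        out = scalar_fuse([o1, o2], ScalarWeights(w=(1.0, 0.0)))
        np.testing.assert_allclose(out, o1, atol=1e-15)

    def test_uniform_weights_equal_average(self):
        outputs = random_member_outputs(10, 2, 4, seed=0)
        np.testing.assert_allclose(
            scalar_fuse(outputs, ScalarWeights(w=(0.5, 0.5))),
            average_fuse(outputs),
            atol=1e-12,
        )

    def test_hand_arithmetic(self):
        """0.45:0.55 mixture of opposing one-hot members."""
        out = scalar_fuse(
            [np.array([1.0, 0.0]), np.array([0.0, 1.0])],
            ScalarWeights.from_w1(0.45),
        )
        np.testing.assert_allclose(out, [0.45, 0.55], atol=1e-15)

    def test_invalid_weights_rejected(self):
        with pytest.raises(ValueError):
            ScalarWeights(w=(0.5, 0.6))
        with pytest.raises(ValueError):
            ScalarWeights(w=(-0.1, 1.1))


class TestAttention:
    def test_zero_matrix_gives_uniform_alpha(self):
        outputs = random_member_outputs(5, 3, 4, seed=1)
        alpha = attention_alpha(AttentionParams.zeros(3, 4), outputs)
        np.testing.assert_allclose(alpha, 1.0 / 3.0, atol=1e-12)

    def test_softmax_closed_form(self):
        """Logits (ln 2, ln 1) -> alpha (2/3, 1/3)."""
        # craft W so W @ concat reproduces the target logits for this input
        outputs = np.array([[0.5, 0.5], [0.5, 0.5]])
        # concat = (0.5, 0.5, 0.5, 0.5) sums to 2, so rows of ln2/2 give
        # logits (ln2, 0)
        w = np.array([[np.log(2) / 2] * 4, [0.0] * 4])
        alpha = attention_alpha(AttentionParams(W=w), outputs)
        np.testing.assert_allclose(alpha, [2 / 3, 1 / 3], atol=1e-12)

    def test_alpha_sums_to_one(self):
        outputs = random_member_outputs(100, 2, 4, seed=2)
        W = np.random.default_rng(3).standard_normal((2, 8))
        alpha = attention_alpha(AttentionParams(W=W), outputs)
        np.testing.assert_allclose(alpha.sum(axis=1), 1.0, atol=1e-9)

    def test_zero_matrix_fuse_equals_average(self):
        outputs = random_member_outputs(50, 2, 4, seed=4)
        np.testing.assert_allclose(
            attention_fuse(AttentionParams.zeros(2, 4), outputs),
            average_fuse(outputs),
            atol=1e-12,
        )

    def test_saturated_attention_selects_member(self):
        outputs = random_member_outputs(10, 2, 3, seed=5)
        W = np.zeros((2, 6))
        W[0, :] = 50.0  # huge logit gap toward member 1
        fused = attention_fuse(AttentionParams(W=W), outputs)
        np.testing.assert_allclose(fused, outputs[:, 0, :], atol=1e-6)

    def test_shared_argmax_preserved(self):
        """Convex combinations keep a class every member ranks first."""
        outputs = np.array([[[0.7, 0.2, 0.1], [0.5, 0.3, 0.2]]])
        W = np.random.default_rng(6).standard_normal((2, 6))
        fused = attention_fuse(AttentionParams(W=W), outputs)
        assert fused[0].argmax() == 0

    def test_dimension_mismatch_raises(self):
        with pytest.raises(ValueError):
            attention_alpha(
                AttentionParams.zeros(2, 4), random_member_outputs(5, 2, 3, 0)
            )


class TestCrossEntropy:
    def test_perfect_prediction_zero_loss(self):
        assert categorical_cross_entropy([1, 0, 0, 0], [1.0, 0, 0, 0]) == 0.0

    def test_uniform_k4_is_ln4(self):
        loss = categorical_cross_entropy([0, 1, 0, 0], [0.25] * 4)
        np.testing.assert_allclose(loss, np.log(4), atol=1e-12)

    def test_binary_half_is_ln2(self):
        loss = categorical_cross_entropy([0, 1], [0.5, 0.5])
        np.testing.assert_allclose(loss, np.log(2), atol=1e-12)

    def test_zero_probability_clipped_not_inf(self):
        loss = categorical_cross_entropy([0, 1], [1.0, 0.0])
        assert np.isfinite(loss) and loss > 0

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(2, 6), st.integers(0, 10_000))
    def test_minimized_at_one_hot_target(self, k, seed):
        """Over the simplex, loss is minimal exactly at o_hat = y."""
        rng = np.random.default_rng(seed)
        c = int(rng.integers(k))
        y = np.eye(k)[c]
        x = rng.gamma(1.0, size=k)
        o = x / x.sum()
        assert categorical_cross_entropy(y, y) <= categorical_cross_entropy(y, o)


class TestSimplexPreservation:
    def test_all_fusion_modes_stay_on_simplex(self):
        """10^4 random member outputs through each fusion route."""
        outputs = random_member_outputs(10_000, 3, 5, seed=7)
        w = ScalarWeights(w=(0.2, 0.5, 0.3))
        W = np.random.default_rng(8).standard_normal((3, 15))
        for fused in (
            average_fuse(outputs),
            scalar_fuse(outputs, w),
            attention_fuse(AttentionParams(W=W), outputs),
        ):
            assert (fused >= -1e-12).all()
            np.testing.assert_allclose(fused.sum(axis=1), 1.0, atol=1e-9)

    def test_three_mode_equivalence_at_uniformity(self):
        outputs = random_member_outputs(200, 2, 4, seed=9)
        avg = average_fuse(outputs)
        np.testing.assert_allclose(
            scalar_fuse(outputs, ScalarWeights(w=(0.5, 0.5))), avg, atol=1e-12
        )
        np.testing.assert_allclose(
            attention_fuse(AttentionParams.zeros(2, 4), outputs), avg, atol=1e-12
        )


class TestFitAttention:
    def test_favours_accurate_member(self, skewed_member_table):
        """0.95-vs-0.25 members: fitted attention leans on the strong one.

        Cross-checked against a direct 1-D grid search over scalar weights,
        whose optimum also lies on the accurate member's side.
        """
        t = skewed_member_table
        fitted, _ = fit_attention(
            AttentionParams.zeros(2, 4), t, epochs=10, seed=0
        )
        alpha = attention_alpha(fitted, t.probs)
        assert alpha[:, 0].mean() > 0.5

        # independent oracle: scalar-weight grid search
        grid = np.linspace(0, 1, 21)
        accs = [
            fused_accuracy(t, scalar_fuse(t.probs, ScalarWeights.from_w1(w1)))
            for w1 in grid
        ]
        assert grid[int(np.argmax(accs))] > 0.5

    def test_beats_plain_averaging(self, skewed_member_table):
        t = skewed_member_table
        fitted, _ = fit_attention(
            AttentionParams.zeros(2, 4), t, epochs=10, seed=0
        )
        att_acc = fused_accuracy(t, fuse_table(t, "attention", params=fitted))
        avg_acc = fused_accuracy(t, fuse_table(t, "average"))
        assert att_acc >= avg_acc

    def test_identical_members_are_stationary(self):
        labels = np.arange(100) % 4
        single = gen_member_probs(labels, [0.8], K=4, seed=1)
        probs = np.repeat(single.probs, 2, axis=1)
        from leaffuse import MemberOutputTable

        t = MemberOutputTable(labels, probs)
        params0 = AttentionParams.zeros(2, 4)
        fitted, losses = fit_attention(params0, t, epochs=5, seed=0)
        np.testing.assert_allclose(fitted.W, params0.W, atol=1e-12)
        np.testing.assert_allclose(losses, losses[0], atol=1e-12)

    def test_zero_epochs_is_noop(self, skewed_member_table):
        rng = np.random.default_rng(0)
        params = AttentionParams(W=rng.standard_normal((2, 8)))
        fitted, losses = fit_attention(params, skewed_member_table, epochs=0)
        np.testing.assert_array_equal(fitted.W, params.W)
        assert losses == []

    def test_loss_at_best_not_above_start(self, skewed_member_table):
        fitted, losses = fit_attention(
            AttentionParams.zeros(2, 4), skewed_member_table, epochs=8, seed=3
        )
        assert min(losses) <= losses[0]

    def test_empty_table_rejected(self):
        from leaffuse import MemberOutputTable

        t = MemberOutputTable(np.empty(0, int), np.empty((0, 2, 4)))
        with pytest.raises(ValueError):
            fit_attention(AttentionParams.zeros(2, 4), t, epochs=1)
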