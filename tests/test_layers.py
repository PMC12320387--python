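import math

import numpy as np
import pytest

from dgat.graph import make_adjacency_state
from dgat.layers import (
    DGATLayer,
    GATLayerParams,
    NeighborhoodSpec,
    attention_scores,
    dgat_layer_forward,
    dynamic_update,
    gat_head_forward,
    multi_head_forward,
    normalize_attention,
)

from conftest import random_layer, random_valid_w0
from reference_layers import (
    reference_dynamic_layer,
    reference_scores,
    reference_static_multihead,
)


def _params(W, a, **kw):
    return GATLayerParams(W_heads=np.asarray(W)[None], a_heads=np.asarray(a)[None], **kw)


class TestAttentionScores:
    def test_zero_attention_vector_gives_zero_scores(self, rng):
        p = _params(rng.normal(size=(2, 3)), np.zeros(4))
        e = attention_scores(rng.normal(size=(5, 3)), p, head=0)
        assert np.all(e == 0)

    def test_matches_scalar_reference_on_small_graph(self, rng):
        W = rng.normal(size=(2, 3))
        a = rng.normal(size=4)
        h = rng.normal(size=(3, 3))
        e = attention_scores(h, _params(W, a), head=0)
        assert np.allclose(e, reference_scores(h, W, a), atol=1e-12)

    def test_permutation_equivariance(self, rng):
        p = _params(rng.normal(size=(2, 3)), rng.normal(size=4))
        h = rng.normal(size=(6, 3))
        perm = rng.permutation(6)
        e = attention_scores(h, p, 0)
        e_p = attention_scores(h[perm], p, 0)
        assert np.allclose(e_p, e[np.ix_(perm, perm)])

    def test_nonfinite_input_rejected(self, rng):
        p = _params(rng.normal(size=(2, 3)), rng.normal(size=4))
        h = np.full((3, 3), np.nan)
        with pytest.raises(ValueError, match="finite"):
            attention_scores(h, p, 0)


class TestNormalizeAttention:
    def test_single_neighbor_gets_everything(self):
        mask = NeighborhoodSpec(np.eye(3, dtype=bool))
        alpha = normalize_attention(np.zeros((3, 3)), mask)
        assert np.allclose(alpha, np.eye(3))

    def test_uniform_scores_uniform_weights(self):
        mask = NeighborhoodSpec.full(4)
        alpha = normalize_attention(np.full((4, 4), 2.7), mask)
        assert np.allclose(alpha, 0.25)

    def test_hand_computed_softmax(self):
        mask = NeighborhoodSpec(np.array([[True, True], [True, True]]))
        e = np.array([[0.0, math.log(2.0)], [0.0, 0.0]])
        alpha = normalize_attention(e, mask)
        assert np.allclose(alpha[0], [1 / 3, 2 / 3])

    def test_rows_sum_to_one_under_random_masks(self, rng):
        for _ in range(20):
            n = int(rng.integers(2, 8))
            mask = NeighborhoodSpec(rng.random((n, n)) < 0.5)
            alpha = normalize_attention(rng.normal(size=(n, n)), mask)
            assert np.allclose(alpha.sum(axis=1), 1.0, atol=1e-6)
            assert np.all(alpha[~mask.mask] == 0)


class TestGatHeadForward:
    def test_identity_configuration(self):
        h = np.array([[1.0, 0.0], [0.0, 1.0]])
        out = gat_head_forward(h, np.eye(2), np.eye(2), activation="identity")
        assert np.allclose(out, h)

    def test_uniform_attention_averages(self, rng):
        h = rng.normal(size=(4, 3))
        alpha = np.full((4, 4), 0.25)
        out = gat_head_forward(h, alpha, np.eye(3), activation="identity")
        assert np.allclose(out, np.tile(h.mean(axis=0), (4, 1)))

    def test_hand_computed_two_nodes(self):
        h = np.array([[1.0, 0.0], [0.0, 1.0]])
        alpha = np.array([[1.0, 0.0], [0.5, 0.5]])
        out = gat_head_forward(h, alpha, np.eye(2), activation="identity")
        assert np.allclose(out, [[1.0, 0.0], [0.5, 0.5]])


class TestMultiHead:
    def test_single_head_reduction(self, rng):
        p1 = GATLayerParams.init(rng, 1, 3, 2)
        h = rng.normal(size=(4, 3))
        out = multi_head_forward(h, p1)
        e = attention_scores(h, p1, 0, NeighborhoodSpec.full(4))
        alpha = normalize_attention(e, NeighborhoodSpec.full(4))
        assert np.allclose(out, gat_head_forward(h, alpha, p1.W_heads[0]))

    def test_output_width_is_k_times_fprime(self, rng):
        p = GATLayerParams.init(rng, 2, 3, 4)
        assert multi_head_forward(rng.normal(size=(5, 3)), p).shape == (5, 8)

    def test_identical_heads_identical_blocks(self, rng):
        W = rng.normal(size=(2, 3))
        a = rng.normal(size=4)
        p = GATLayerParams(np.stack([W, W]), np.stack([a, a]))
        out = multi_head_forward(rng.normal(size=(4, 3)), p)
        assert np.allclose(out[:, :2], out[:, 2:])

    def test_matches_scalar_reference(self, rng):
        for n in (2, 3, 5):
            p = GATLayerParams.init(rng, 2, 3, 2)
            h = rng.normal(size=(n, 3))
            mask = NeighborhoodSpec.full(n)
            ours = multi_head_forward(h, p, mask)
            ref = reference_static_multihead(h, p.W_heads, p.a_heads, mask.mask)
            assert np.allclose(ours, ref, atol=1e-6)


class TestDynamicUpdate:
    def test_momentum_limits(self, rng):
        w0 = random_valid_w0(rng, 4)
        e = rng.normal(size=(4, 4))
        st1 = make_adjacency_state(w0, beta=1.0)
        dynamic_update(st1, e)
        assert np.array_equal(st1.w, w0)
        st0 = make_adjacency_state(w0, beta=0.0)
        dynamic_update(st0, e)
        assert np.allclose(st0.w[st0.mask()], e[st0.mask()])

    def test_halfway_arithmetic(self):
        w0 = np.array([[1.0, 0.4], [0.4, 1.0]])
        st = make_adjacency_state(w0, beta=0.5)
        dynamic_update(st, np.full((2, 2), 0.8))
        assert st.w[0, 1] == pytest.approx(0.6)

    def test_eval_mode_is_warned_noop(self, rng):
        st = make_adjacency_state(random_valid_w0(rng, 3), beta=0.5)
        before = st.w.copy()
        with pytest.warns(UserWarning, match="no-op"):
            dynamic_update(st, rng.normal(size=(3, 3)), training=False)
        assert np.array_equal(st.w, before)


class TestDgatLayerForward:
    def test_beta_one_reduces_to_static_logits(self, rng):
        """Frozen buffer at beta=1: attention logits are exactly w0."""
        n = 5
        p = GATLayerParams.init(rng, 2, 3, 2)
        w0 = random_valid_w0(rng, n)
        st = make_adjacency_state(w0, beta=1.0, trainable=False)
        h = rng.normal(size=(n, 3))
        out, _ = dgat_layer_forward(h, p, st, training=True)
        mask = NeighborhoodSpec.from_adjacency(w0)
        blocks = []
        for k in range(2):
            alpha = normalize_attention(np.where(mask.mask, w0, -1e9), mask)
            blocks.append(gat_head_forward(h, alpha, p.W_heads[k]))
        assert np.allclose(out, np.concatenate(blocks, axis=1), atol=1e-12)

    def test_matches_scalar_reference_dynamic(self, rng):
        for n in (2, 4, 5):
            p = GATLayerParams.init(rng, 2, 3, 2)
            w0 = random_valid_w0(rng, n)
            st = make_adjacency_state(w0, beta=0.5)
            h = rng.normal(size=(n, 3))
            mask = NeighborhoodSpec.from_adjacency(w0)
            ref_out, ref_w = reference_dynamic_layer(
                h, p.W_heads, p.a_heads, w0, 0.5, mask.mask, update=True
            )
            out, st = dgat_layer_forward(h, p, st, training=True)
            assert np.allclose(out, ref_out, atol=1e-6)
            assert np.allclose(st.w, ref_w, atol=1e-6)

    def test_repeated_passes_contract_buffer_toward_scores(self, rng):
        """With beta=0.5 and fixed input, |w - e| halves every pass."""
        layer, p, st = random_layer(rng, 4, 3, 2, n_heads=2, beta=0.5)
        h = rng.normal(size=(4, 3))
        e_mean = np.mean(
            [attention_scores(h, p, k) for k in range(2)], axis=0
        )
        m = st.mask()
        gaps = []
        for _ in range(3):
            dgat_layer_forward(h, p, st, training=True)
            gaps.append(np.abs(st.w - e_mean)[m].max())
        assert gaps[1] == pytest.approx(gaps[0] / 2, rel=1e-9)
        assert gaps[2] == pytest.approx(gaps[1] / 2, rel=1e-9)

    def test_permutation_equivariance_including_state(self, rng):
        n = 6
        p = GATLayerParams.init(rng, 2, 3, 2)
        w0 = random_valid_w0(rng, n)
        h = rng.normal(size=(n, 3))
        perm = rng.permutation(n)
        st = make_adjacency_state(w0, beta=0.5)
        out, st = dgat_layer_forward(h, p, st, training=True)
        st_p = make_adjacency_state(w0[np.ix_(perm, perm)], beta=0.5)
        out_p, st_p = dgat_layer_forward(h[perm], p, st_p, training=True)
        assert np.allclose(out_p, out[perm], atol=1e-10)
        assert np.allclose(st_p.w, st.w[np.ix_(perm, perm)], atol=1e-10)


class TestBatchedLayer:
    def test_batched_matches_single_instance(self, rng):
        layer, p, st = random_layer(rng, 5, 3, 2, n_heads=2, beta=0.5)
        h = rng.normal(size=(3, 5, 3))
        out = layer.forward(h, training=False)
        for s in range(3):
            st_s = make_adjacency_state(st.w0, beta=0.5)
            single, _ = dgat_layer_forward(h[s], p, st_s, training=False)
            assert np.allclose(out[s], single, atol=1e-12)

    def test_training_buffer_update_uses_batch_mean(self, rng):
        layer, p, st = random_layer(rng, 4, 3, 2, n_heads=2, beta=0.5)
        h = rng.normal(size=(6, 4, 3))
        e_mean = np.mean(
            [[np.asarray(attention_scores(h[s], p, k)) for s in range(6)] for k in range(2)],
            axis=(0, 1),
        )
        expect = st.w.copy()
        m = st.mask()
        expect[m] = 0.5 * expect[m] + 0.5 * e_mean[m]
        layer.forward(h, training=True, rng=rng)
        assert np.allclose(layer.state.w, expect, atol=1e-10)

    def test_gradients_match_finite_differences(self, rng):
        """Analytic W/a/buffer/input gradients vs central differences."""
        layer, p, st = random_layer(rng, 4, 3, 2, n_heads=2, beta=0.5)
        h = rng.normal(size=(3, 4, 3))
        probe = rng.normal(size=(3, 4, 4))  # fixed projection -> scalar loss

        def loss():
            return float((layer.forward(h, training=False) * probe).sum())

        loss()
        d_h, grads = layer.backward(probe)
        eps = 1e-6
        for arr, grad in [
            (p.W_heads, grads["W"]),
            (p.a_heads, grads["a"]),
            (st.w, grads["w"]),
            (h, d_h),
        ]:
            num = np.zeros_like(arr)
            it = np.nditer(arr, flags=["multi_index"])
            for _ in it:
                i = it.multi_index
                old = arr[i]
                arr[i] = old + eps
                lp = loss()
                arr[i] = old - eps
                lm = loss()
                arr[i] = old
                num[i] = (lp - lm) / (2 * eps)
            denom = max(1e-8, float(np.abs(num).max()))
            assert float(np.abs(num - grad).max()) / denom < 1e-4

    def test_per_head_adjacency_buffers(self, rng):
        layer, p, st = random_layer(
            rng, 4, 3, 2, n_heads=3, beta=0.5, per_head_adjacency=True
        )
        assert st.w.shape == (3, 4, 4)
        h = rng.normal(size=(2, 4, 3))
        layer.forward(h, training=True, rng=rng)
        # heads drift independently: buffers are no longer identical
        assert not np.allclose(st.w[0], st.w[1])
        out = layer.forward(h, training=False)
        assert out.shape == (2, 4, 3 * 2)  # K * F'

    def test_row_stochastic_attention_cache(self, rng):
        layer, _, _ = random_layer(rng, 6, 4, 3, n_heads=2, beta=0.3)
        layer.forward(rng.normal(size=(4, 6, 4)), training=False)
        alpha = layer._cache["alpha"]
        assert np.allclose(alpha.sum(axis=-1), 1.0, atol=1e-6)
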