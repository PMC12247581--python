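"""Dual-granularity guidance: saliency, ROI selection, gated attention."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from hypothesis.extra.numpy import arrays

from diffage.autograd import Tensor
from diffage.guidance import (compute_saliency, dcg_loss, extract_rois,
                              gated_attention, gated_attention_t, global_prior,
                              local_prior)
from diffage.nn import Conv2d, Linear, ResNetEncoder


@pytest.fixture
def encoder():
    rng = np.random.default_rng(0)
    return ResNetEncoder((4, 8), 8, rng)


@pytest.fixture
def saliency_conv():
    return Conv2d(8, 1, 1, np.random.default_rng(1))


class TestComputeSaliency:
    def test_deterministic(self, encoder, saliency_conv, rng):
        img = rng.random((32, 32))
        a = compute_saliency(img, encoder, saliency_conv)
        b = compute_saliency(img, encoder, saliency_conv)
        assert np.array_equal(a, b)

    def test_shape_matches_encoder_grid(self, encoder, saliency_conv, rng):
        sal = compute_saliency(rng.random((32, 32)), encoder, saliency_conv)
        assert sal.shape == (8, 8)     # two stride-2 stages from 32

    def test_zero_input_bias_free_gives_constant_map(self, encoder, saliency_conv):
        for p in encoder.parameters() + saliency_conv.parameters():
            if p.data.ndim == 1:       # biases
                p.data = np.zeros_like(p.data)
        sal = compute_saliency(np.zeros((32, 32)), encoder, saliency_conv)
        assert np.allclose(sal, sal.flat[0])

    def test_too_small_input_rejected(self, encoder, saliency_conv):
        with pytest.raises(ValueError, match="smaller"):
            compute_saliency(np.zeros((2, 2)), encoder, saliency_conv)


class TestGlobalPrior:
    def test_constant_map(self):
        assert global_prior(np.full((4, 4), 2.5)) == 2.5

    def test_small_map_mean(self):
        assert global_prior(np.array([[1.0, 2.0], [3.0, 4.0]])) == 2.5

    def test_matches_double_loop_oracle(self, rng):
        sal = rng.normal(size=(7, 5))
        total = 0.0
        for i in range(7):
            for j in range(5):
                total += sal[i, j]
        assert global_prior(sal) == pytest.approx(total / 35, abs=1e-9)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            global_prior(np.empty((0, 0)))


def _greedy_topk_oracle(sal, img_shape, k, patch_size):
    """Brute-force greedy selection with Chebyshev suppression."""
    scale = (img_shape[0] / sal.shape[0], img_shape[1] / sal.shape[1])
    chosen = []
    remaining = [(r, c) for r in range(sal.shape[0]) for c in range(sal.shape[1])]
    while len(chosen) < k and remaining:
        best = max(remaining, key=lambda rc: (sal[rc], -rc[0] * sal.shape[1] - rc[1]))
        cy, cx = (best[0] + 0.5) * scale[0], (best[1] + 0.5) * scale[1]
        chosen.append((int(cy), int(cx)))
        remaining = [rc for rc in remaining
                     if max(abs((rc[0] + 0.5) * scale[0] - cy),
                            abs((rc[1] + 0.5) * scale[1] - cx)) >= patch_size / 2]
    return chosen


class TestExtractROIs:
    def test_single_spike(self, rng):
        sal = np.zeros((8, 8))
        sal[3, 5] = 1.0
        img = rng.random((32, 32))
        rois = extract_rois(sal, img, k=1, patch_size=8)
        assert (rois[0].row, rois[0].col) == (14, 22)   # grid cell centers x4

    def test_tie_breaks_row_major(self):
        sal = np.zeros((4, 4))
        sal[2, 1] = sal[1, 3] = 5.0    # equal maxima; (1, 3) comes first row-major
        rois = extract_rois(sal, np.zeros((16, 16)), k=1, patch_size=4)
        assert (rois[0].row, rois[0].col) == (6, 14)

    def test_matches_brute_force_greedy(self, rng):
        for _ in range(20):
            sal = rng.normal(size=(8, 8))
            rois = extract_rois(sal, np.zeros((32, 32)), k=3, patch_size=8)
            oracle = _greedy_topk_oracle(sal, (32, 32), 3, 8)
            assert [(r.row, r.col) for r in rois] == oracle

    def test_fewer_than_k_warns(self):
        sal = np.ones((2, 2))
        with pytest.warns(UserWarning, match="ROIs"):
            rois = extract_rois(sal, np.zeros((32, 32)), k=10, patch_size=32)
        assert len(rois) < 10

    def test_patch_is_centered_crop(self, rng):
        img = rng.random((32, 32))
        sal = np.zeros((8, 8))
        sal[4, 4] = 1.0
        roi = extract_rois(sal, img, k=1, patch_size=8)[0]
        assert np.array_equal(roi.patch, img[14:22, 14:22])


class TestGatedAttention:
    def _params(self, d, d_att, seed=0):
        r = np.random.default_rng(seed)
        return r.normal(size=(d_att, d)), r.normal(size=(d_att, d)), r.normal(size=d_att)

    def test_single_feature_weight_one(self):
        V, U, w = self._params(4, 3)
        assert np.allclose(gated_attention(np.ones((1, 4)), V, U, w), [1.0])

    def test_identical_features_equal_weights(self, rng):
        V, U, w = self._params(4, 3)
        h = rng.normal(size=4)
        weights = gated_attention(np.stack([h, h]), V, U, w)
        assert np.allclose(weights, [0.5, 0.5])

    def test_matches_direct_formula(self, rng):
        V, U, w = self._params(5, 4)
        H = rng.normal(size=(6, 5))
        scores = np.array([w @ (np.tanh(V @ h) * (1 / (1 + np.exp(-U @ h))))
                           for h in H])
        expected = np.exp(scores) / np.exp(scores).sum()
        assert np.allclose(gated_attention(H, V, U, w), expected, atol=1e-9)

    @given(arrays(np.float64, (5, 3),
                  elements=st.floats(-50, 50, allow_nan=False)))
    def test_probability_vector(self, H):
        V, U, w = self._params(3, 4)
        weights = gated_attention(H, V, U, w)
        assert np.all(weights >= 0)
        assert abs(weights.sum() - 1.0) < 1e-6

    def test_tensor_version_matches_numpy(self, rng):
        V, U, w = self._params(4, 3)
        H = rng.normal(size=(2, 5, 4))     # batched
        got = gated_attention_t(Tensor(H), Tensor(V), Tensor(U), Tensor(w)).data
        for b in range(2):
            assert np.allclose(got[b], gated_attention(H[b], V, U, w), atol=1e-12)

    def test_dimension_mismatch_rejected(self):
        V, U, w = self._params(4, 3)
        with pytest.raises(ValueError):
            gated_attention(np.ones((2, 7)), V, U, w)


class _Attention:
    def __init__(self, d, d_att, seed=3):
        r = np.random.default_rng(seed)
        self.V = Tensor(r.normal(size=(d_att, d)))
        self.U = Tensor(r.normal(size=(d_att, d)))
        self.w = Tensor(r.normal(size=d_att))


class TestLocalPrior:
    @pytest.fixture
    def parts(self):
        rng = np.random.default_rng(2)
        enc = ResNetEncoder((4,), 6, rng)
        head = Linear(6, 1, rng)
        att = _Attention(6, 4)
        return enc, att, head

    def _roi(self, rng, seed=0):
        from diffage.guidance import ROI

        r = np.random.default_rng(seed)
        return ROI(row=4, col=4, patch=r.random((8, 8)))

    def test_single_roi_equals_head_of_encoding(self, parts, rng):
        enc, att, head = parts
        roi = self._roi(rng)
        got = local_prior([roi], enc, att, head)
        feats = enc(Tensor(roi.patch[None, :, :, None])).data
        expected = float(head(Tensor(feats)).data[0, 0])
        assert got == pytest.approx(expected, abs=1e-9)

    def test_duplicated_rois_invariant(self, parts, rng):
        enc, att, head = parts
        roi = self._roi(rng)
        assert local_prior([roi] * 4, enc, att, head) == \
            pytest.approx(local_prior([roi], enc, att, head), abs=1e-9)

    def test_permutation_invariant(self, parts, rng):
        enc, att, head = parts
        rois = [self._roi(rng, seed=s) for s in range(3)]
        a = local_prior(rois, enc, att, head)
        b = local_prior(rois[::-1], enc, att, head)
        assert a == pytest.approx(b, abs=1e-9)

    def test_stepwise_composition_oracle(self, parts, rng):
        enc, att, head = parts
        rois = [self._roi(rng, seed=s) for s in range(3)]
        feats = np.stack([enc(Tensor(r.patch[None, :, :, None])).data[0]
                          for r in rois])
        weights = gated_attention(feats, att.V.data, att.U.data, att.w.data)
        pooled = weights @ feats
        expected = float(head(Tensor(pooled[None])).data[0, 0])
        assert local_prior(rois, enc, att, head) == pytest.approx(expected, abs=1e-6)

    def test_empty_rois_falls_back_to_global(self, parts):
        enc, att, head = parts
        with pytest.warns(UserWarning, match="global"):
            assert local_prior([], enc, att, head, fallback_y_g=0.3) == 0.3


class TestDCGLoss:
    def test_zero_when_exact(self):
        assert dcg_loss(0.2, 0.2, 0.2) == 0.0

    def test_unit_offset(self):
        assert dcg_loss(1.2, 0.2, 0.2) == pytest.approx(1.0)

    def test_batch_mean_matches_hand_sum(self):
        y_g = np.array([0.1, 0.5])
        y_l = np.array([0.0, 0.4])
        y = np.array([0.2, 0.2])
        hand = (((0.1 - 0.2) ** 2 + (0.0 - 0.2) ** 2)
                + ((0.5 - 0.2) ** 2 + (0.4 - 0.2) ** 2)) / 2
        assert dcg_loss(y_g, y_l, y) == pytest.approx(hand, abs=1e-12)

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            dcg_loss(np.nan, 0.0, 0.0)
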