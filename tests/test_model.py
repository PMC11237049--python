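"""Residual network mechanics: shapes, parameter accounting, weight
duplication linearity, serialisation, gradients, and the small ANN."""

from __future__ import annotations

import numpy as np
import pytest

from ramancnn.nn import (
    Adam,
    AnnSpec,
    ModelSpec,
    adapt_first_layer,
    build_ann,
    build_resnet,
    grid_search_hidden_size,
    load_pretrained,
    save_model,
    softmax_cross_entropy,
)
from ramancnn.nn.ann import HIDDEN_GRID
from ramancnn.nn.resnet import LoadError, SpecError

TINY = ModelSpec(in_channels=2, n_blocks=2, hidden_filters=4, kernel_size=3,
                 input_length=32)


class TestBuildResnet:
    def test_forward_shape_full_scale(self):
        spec = ModelSpec(in_channels=8, n_blocks=2, hidden_filters=8,
                         kernel_size=5, input_length=1015)
        model = build_resnet(spec, seed=0)
        x = np.random.default_rng(0).normal(0, 1, (3, 8, 1015))
        logits = model.forward(x)
        assert logits.shape == (3, 2)

    def test_parameter_count_closed_form(self):
        # conv0: F*C*k; per block: 2 BN (2F each) + 2 convs (F*F*k) and a
        # 1x1 projection (F*F) on downsampling blocks; final BN 2F;
        # head F*2 + 2
        spec = TINY
        f, c, k, b = spec.hidden_filters, spec.in_channels, spec.kernel_size, spec.n_blocks
        expected = f * c * k  # conv0
        expected += (4 * f + 2 * f * f * k) * b  # blocks: 2 BN + 2 convs
        expected += f * f * (b - 1)  # projections on stride-2 blocks
        expected += 2 * f  # output BN
        expected += f * 2 + 2  # head
        assert build_resnet(spec).n_parameters() == expected

    def test_doubling_filters_increases_parameters(self):
        small = build_resnet(TINY).n_parameters()
        from dataclasses import replace
        big = build_resnet(replace(TINY, hidden_filters=8)).n_parameters()
        assert big > small

    def test_too_short_input_rejected(self):
        with pytest.raises(SpecError):
            ModelSpec(n_blocks=10, input_length=32).validate()

    def test_eval_forward_deterministic(self):
        model = build_resnet(TINY, seed=3)
        x = np.random.default_rng(1).normal(0, 1, (2, 2, 32))
        np.testing.assert_array_equal(model.forward(x), model.forward(x))

    def test_gradients_match_finite_differences(self):
        model = build_resnet(TINY, seed=0)
        rng = np.random.default_rng(0)
        x = rng.normal(0, 1, (3, 2, 32))
        y = np.array([0, 1, 1])
        loss, dl = softmax_cross_entropy(model.forward(x, train=True), y)
        for p in model.params():
            p.grad[...] = 0.0
        dx = model.backward(dl)
        eps = 1e-6
        for p in model.params()[::4]:
            flat = p.value.ravel()
            idx = int(rng.integers(0, flat.size))
            orig = flat[idx]
            flat[idx] = orig + eps
            lp, _ = softmax_cross_entropy(model.forward(x, train=True), y)
            flat[idx] = orig - eps
            lm, _ = softmax_cross_entropy(model.forward(x, train=True), y)
            flat[idx] = orig
            num = (lp - lm) / (2 * eps)
            assert abs(num - p.grad.ravel()[idx]) < 1e-6 + 1e-4 * abs(num), p.name
        i0 = (1, 0, 13)
        orig = x[i0]
        x[i0] = orig + eps
        lp, _ = softmax_cross_entropy(model.forward(x, train=True), y)
        x[i0] = orig - eps
        lm, _ = softmax_cross_entropy(model.forward(x, train=True), y)
        x[i0] = orig
        num = (lp - lm) / (2 * eps)
        assert abs(num - dx[i0]) < 1e-6 + 1e-4 * abs(num)


class TestAdaptFirstLayer:
    def test_single_channel_identity(self):
        w = np.random.default_rng(0).normal(0, 1, (4, 1, 5))
        np.testing.assert_array_equal(adapt_first_layer(w, 1), w)

    def test_slices_bitwise_equal(self):
        w = np.random.default_rng(1).normal(0, 1, (4, 1, 5))
        tiled = adapt_first_layer(w, 8)
        assert tiled.shape == (4, 8, 5)
        for c in range(8):
            np.testing.assert_array_equal(tiled[:, c, :], w[:, 0, :])

    def test_duplication_linearity_eight_channels(self):
        # all-equal channels through the duplicated kernel reproduce 8x the
        # single-channel first-layer pre-activation
        rng = np.random.default_rng(2)
        single = build_resnet(
            ModelSpec(in_channels=1, n_blocks=2, hidden_filters=16,
                      kernel_size=5, input_length=128), seed=0)
        multi = build_resnet(
            ModelSpec(in_channels=8, n_blocks=2, hidden_filters=16,
                      kernel_size=5, input_length=128), seed=0)
        multi.conv0.weight.value = adapt_first_layer(single.conv0.weight.value, 8)
        x = rng.normal(0, 1, (2, 1, 128))
        x8 = np.repeat(x, 8, axis=1)
        pre_single = single.first_layer_preactivation(x)
        pre_multi = multi.first_layer_preactivation(x8)
        np.testing.assert_allclose(pre_multi, 8.0 * pre_single, rtol=1e-12, atol=1e-12)

    def test_invalid_arguments_rejected(self):
        w = np.zeros((4, 1, 5))
        with pytest.raises(ValueError):
            adapt_first_layer(w, 0)
        with pytest.raises(ValueError):
            adapt_first_layer(np.zeros((4, 2, 5)), 8)


class TestSerialisation:
    def test_save_load_round_trip(self, tmp_path):
        model = build_resnet(TINY, seed=5)
        x = np.random.default_rng(3).normal(0, 1, (2, 2, 32))
        path = tmp_path / "weights.npz"
        save_model(model, path)
        back = load_pretrained(path, TINY, seed=99)
        np.testing.assert_array_equal(back.forward(x), model.forward(x))

    def test_absent_path_gives_seeded_random_model(self):
        a = load_pretrained(None, TINY, seed=7)
        b = build_resnet(TINY, seed=7)
        x = np.random.default_rng(0).normal(0, 1, (1, 2, 32))
        np.testing.assert_array_equal(a.forward(x), b.forward(x))

    def test_single_channel_weights_adapt_to_multichannel(self, tmp_path):
        from dataclasses import replace
        single_spec = replace(TINY, in_channels=1)
        single = build_resnet(single_spec, seed=1)
        path = tmp_path / "single.npz"
        save_model(single, path)
        multi = load_pretrained(path, TINY, seed=2)
        np.testing.assert_array_equal(
            multi.conv0.weight.value,
            adapt_first_layer(single.conv0.weight.value, TINY.in_channels),
        )

    def test_incompatible_filters_raise_load_error(self, tmp_path):
        from dataclasses import replace
        model = build_resnet(TINY, seed=0)
        path = tmp_path / "w.npz"
        save_model(model, path)
        with pytest.raises(LoadError, match="conv"):
            load_pretrained(path, replace(TINY, hidden_filters=8))


class TestAnn:
    def test_forward_shape_three_features(self):
        model = build_ann(AnnSpec(), 3, seed=0)
        logits = model.forward(np.random.default_rng(0).normal(0, 1, (5, 3)))
        assert logits.shape == (5, 2)

    def test_default_spec_is_22_22_dropout_02(self):
        spec = AnnSpec()
        assert spec.hidden_sizes == (22, 22)
        assert spec.dropout_rate == pytest.approx(0.2)

    def test_eval_mode_disables_dropout(self):
        model = build_ann(AnnSpec(), 4, seed=1)
        x = np.random.default_rng(2).normal(0, 1, (6, 4))
        np.testing.assert_array_equal(model.forward(x), model.forward(x))

    def test_train_mode_dropout_varies(self):
        model = build_ann(AnnSpec(dropout_rate=0.5), 4, seed=1)
        x = np.random.default_rng(2).normal(0, 1, (6, 4))
        a = model.forward(x, train=True)
        b = model.forward(x, train=True)
        assert not np.array_equal(a, b)

    def test_grid_search_returns_member_of_grid(self):
        # favour a specific width via a rigged objective
        best, scores = grid_search_hidden_size(lambda spec: -abs(spec.hidden_sizes[0] - 16))
        assert best == 16
        assert set(scores) == set(HIDDEN_GRID)

    def test_learns_xor_like_toy_task(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0, 1, (200, 2))
        y = (x[:, 0] * x[:, 1] > 0).astype(int)
        model = build_ann(AnnSpec(dropout_rate=0.0), 2, seed=0)
        opt = Adam(model.params(), lr=1e-2)
        for _ in range(300):
            loss, dl = softmax_cross_entropy(model.forward(x, train=True), y)
            opt.zero_grad()
            model.backward(dl)
            opt.step()
        acc = (model.predict(x) == y).mean()
        assert acc > 0.9
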