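"""The four models: shape contracts, forward oracles, mask wiring, locality."""

import numpy as np
import pytest

from gofuse import nn
from gofuse.errors import ConfigurationError, ShapeError
from gofuse.models import (
    DomainNet,
    DomainSubmodelConfig,
    PPINet,
    PPISubmodelConfig,
    SequenceNet,
    SequenceSubmodelConfig,
    WeightedClassifier,
    build_classifier_masks,
    load_checkpoint,
    save_checkpoint,
)
from test_nn import conv1d_loops


def maxpool_loops(x, k):
    b, c, length = x.shape
    out = np.zeros((b, c, length // k))
    for n in range(b):
        for ch in range(c):
            for p in range(length // k):
                out[n, ch, p] = max(x[n, ch, p * k : (p + 1) * k])
    return out


def _walk_oracle(layers, x):
    """Recompute a Sequential stack with explicit loop primitives."""
    h = x.astype(np.float64)
    for layer in layers:
        if isinstance(layer, nn.Conv1d):
            h = conv1d_loops(h, layer.weight.value.astype(float),
                             layer.bias.value.astype(float), layer.stride)
        elif isinstance(layer, nn.ReLU):
            h = np.maximum(h, 0.0)
        elif isinstance(layer, nn.MaxPool1d):
            h = maxpool_loops(h, layer.kernel)
        elif isinstance(layer, nn.Flatten):
            h = h.reshape(h.shape[0], -1)
        elif isinstance(layer, (nn.Linear, nn.MaskedLinear)):
            w = layer.weight.value.astype(float)
            if isinstance(layer, nn.MaskedLinear):
                w = w * layer.mask
            h = h @ w.T + layer.bias.value.astype(float)
        else:  # pragma: no cover
            raise AssertionError(f"unexpected layer {layer}")
    return h


class TestSequenceNet:
    def _toy(self, rng, n_terms=4):
        cfg = SequenceSubmodelConfig(
            input_len=10, in_channels=5, conv_out_channels=(3, 2),
            conv_kernel=3, output_dim=n_terms,
        )
        return SequenceNet(cfg, rng)

    def test_output_in_unit_interval(self, rng):
        model = self._toy(rng)
        out = model.predict_proba(rng.normal(size=(6, 10, 5)))
        assert out.shape == (6, 4)
        assert (out >= 0).all() and (out <= 1).all() and np.isfinite(out).all()

    def test_zero_input_zero_bias_gives_half(self, rng):
        model = self._toy(rng)
        out = model.predict_proba(np.zeros((2, 10, 5)))
        np.testing.assert_allclose(out, 0.5, atol=1e-7)  # biases init to zero

    def test_matches_loop_by_loop_recomputation(self, rng):
        model = self._toy(rng)
        x = rng.normal(size=(3, 10, 5)).astype(np.float32)
        expected = nn.sigmoid(_walk_oracle(model.net.layers, x.transpose(0, 2, 1)))
        np.testing.assert_allclose(model.predict_proba(x), expected, atol=1e-5)

    def test_shape_mismatch_reports_expected_and_actual(self, rng):
        model = self._toy(rng)
        with pytest.raises(ShapeError, match=r"10, 5"):
            model.forward_logits(np.zeros((2, 9, 5)))

    def test_default_config_consumes_1498_by_100(self, rng):
        model = SequenceNet(SequenceSubmodelConfig(output_dim=3), rng)
        out = model.predict_proba(np.zeros((1, 1498, 100)))
        assert out.shape == (1, 3)


class TestPPINet:
    def test_hand_set_weights_match_matrix_arithmetic(self, rng):
        model = PPINet(PPISubmodelConfig(input_dim=6, hidden_dim=4, output_dim=3), rng)
        x = rng.normal(size=(2, 6)).astype(np.float32)
        w1, b1 = model.net.layers[0].weight.value, model.net.layers[0].bias.value
        w2, b2 = model.net.layers[2].weight.value, model.net.layers[2].bias.value
        expected = nn.sigmoid(np.maximum(x @ w1.T + b1, 0) @ w2.T + b2)
        np.testing.assert_allclose(model.predict_proba(x), expected, atol=1e-6)

    def test_zero_input_gives_half(self, rng):
        model = PPINet(PPISubmodelConfig(input_dim=6, output_dim=3), rng)
        np.testing.assert_allclose(model.predict_proba(np.zeros((1, 6))), 0.5, atol=1e-7)

    def test_default_hidden_is_intermediate(self):
        cfg = PPISubmodelConfig(input_dim=500, output_dim=20)
        assert cfg.output_dim <= cfg.resolved_hidden() <= cfg.input_dim


class TestDomainNet:
    def _toy(self, rng):
        cfg = DomainSubmodelConfig(
            vocab_size=7, sentence_len=4, embed_dim=16,
            conv_out_channels=(4, 3), output_dim=3,
        )
        return DomainNet(cfg, rng)

    def test_all_padding_sentence_gives_half(self, rng):
        model = self._toy(rng)
        out = model.predict_proba(np.zeros((2, 4), dtype=np.int64))
        np.testing.assert_allclose(out, 0.5, atol=1e-7)  # frozen zero padding row

    def test_output_contract(self, rng):
        model = self._toy(rng)
        out = model.predict_proba(rng.integers(0, 7, size=(5, 4)))
        assert out.shape == (5, 3) and (out >= 0).all() and (out <= 1).all()

    def test_matches_loop_oracle_through_embedding(self, rng):
        model = self._toy(rng)
        idx = rng.integers(0, 7, size=(2, 4))
        embedded = model.embedding.weight.value[idx]  # (2, 4, 16): channels = positions
        expected = nn.sigmoid(_walk_oracle(model.net.layers[1:], embedded))
        np.testing.assert_allclose(model.predict_proba(idx), expected, atol=1e-5)

    def test_out_of_vocabulary_index_rejected(self, rng):
        model = self._toy(rng)
        with pytest.raises(ShapeError):
            model.forward_logits(np.full((1, 4), 7))

    def test_conventional_orientation_switch(self, rng):
        cfg = DomainSubmodelConfig(
            vocab_size=7, sentence_len=16, embed_dim=16,
            conv_out_channels=(4, 3), output_dim=3, channels_are_positions=False,
        )
        model = DomainNet(cfg, rng)
        out = model.predict_proba(rng.integers(0, 7, size=(2, 16)))
        assert out.shape == (2, 3)


class TestClassifierMasks:
    def test_smallest_case(self):
        masks = build_classifier_masks(1)
        np.testing.assert_array_equal(masks.input_mask, [[1, 1, 1]])
        np.testing.assert_array_equal(masks.output_mask, [[1]])

    def test_t3_row_one_columns(self):
        masks = build_classifier_masks(3)
        np.testing.assert_array_equal(np.flatnonzero(masks.input_mask[1]), [1, 4, 7])

    @pytest.mark.parametrize("n_terms", [1, 2, 7, 50])
    def test_row_sums_and_identity(self, n_terms):
        masks = build_classifier_masks(n_terms)
        np.testing.assert_array_equal(masks.input_mask.sum(axis=1), 3)
        np.testing.assert_array_equal(masks.output_mask, np.eye(n_terms))

    def test_two_branch_variant_rows_sum_to_two(self):
        masks = build_classifier_masks(5, n_branches=2)
        np.testing.assert_array_equal(masks.input_mask.sum(axis=1), 2)

    def test_invalid_sizes_rejected(self):
        with pytest.raises(ConfigurationError):
            build_classifier_masks(0)


class TestWeightedClassifier:
    def test_hand_arithmetic_single_term(self, rng):
        clf = WeightedClassifier(1, rng)
        clf.hidden.weight.value[...] = 1.0
        clf.hidden.bias.value[...] = 0.0
        clf.out.weight.value[...] = 1.0
        clf.out.bias.value[...] = 0.0
        out = clf.forward_branches(
            np.array([[0.2]]), np.array([[0.3]]), np.array([[0.5]])
        )
        assert out[0, 0] == pytest.approx(0.7310585786, abs=1e-9)  # sigmoid(1.0)

    def test_zero_inputs_zero_biases_give_half(self, rng):
        clf = WeightedClassifier(4, rng)
        z = np.zeros((2, 4))
        np.testing.assert_allclose(clf.forward_branches(z, z, z), 0.5, atol=1e-7)

    def test_masked_locality_is_exact(self, rng):
        clf = WeightedClassifier(5, rng)
        base = [rng.random((3, 5)).astype(np.float32) for _ in range(3)]
        ref = clf.forward_branches(*base)
        perturbed = [m.copy() for m in base]
        perturbed[0][:, 2] += 0.25  # sequence branch, term 2 only
        out = clf.forward_branches(*perturbed)
        unchanged = [j for j in range(5) if j != 2]
        np.testing.assert_array_equal(out[:, unchanged], ref[:, unchanged])

    def test_finite_difference_locality(self, rng):
        """d out[j] / d input[k] == 0 whenever k mod T != j."""
        n_terms = 4
        clf = WeightedClassifier(n_terms, rng)
        x = rng.random((1, 3 * n_terms)).astype(np.float32)
        base = nn.sigmoid(clf.forward_logits(x.copy()))
        for k in range(3 * n_terms):
            xp = x.copy()
            xp[0, k] += 1e-3
            delta = nn.sigmoid(clf.forward_logits(xp)) - base
            for j in range(n_terms):
                if k % n_terms != j:
                    assert delta[0, j] == 0.0

    def test_branch_shape_mismatch_rejected(self, rng):
        clf = WeightedClassifier(3, rng)
        with pytest.raises(ShapeError):
            clf.forward_branches(np.zeros((2, 3)), np.zeros((2, 4)), np.zeros((2, 3)))


class TestCheckpointing:
    def test_bit_exact_reload(self, rng, tmp_path):
        model = PPINet(PPISubmodelConfig(input_dim=6, output_dim=3), rng)
        x = rng.normal(size=(2, 6)).astype(np.float32)
        before = model.predict_proba(x)
        save_checkpoint(model, tmp_path / "m.npz", {"seed": 1})
        fresh = PPINet(PPISubmodelConfig(input_dim=6, output_dim=3),
                       np.random.default_rng(99))
        manifest = load_checkpoint(fresh, tmp_path / "m.npz")
        assert manifest == {"seed": 1}
        np.testing.assert_array_equal(fresh.predict_proba(x), before)

    def test_shape_mismatch_rejected(self, rng, tmp_path):
        model = PPINet(PPISubmodelConfig(input_dim=6, output_dim=3), rng)
        save_checkpoint(model, tmp_path / "m.npz", {})
        other = PPINet(PPISubmodelConfig(input_dim=7, output_dim=3), rng)
        with pytest.raises(ShapeError):
            load_checkpoint(other, tmp_path / "m.npz")
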