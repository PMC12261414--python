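"""Forward-pass operations: encoder, attention stages, heads, loss, checkpoints."""

import math

import numpy as np
import pytest

from hamil import (
    ModelConfig,
    cross_entropy_loss,
    forward,
    init_params,
    load_checkpoint,
    predict_proba,
    save_checkpoint,
)
from hamil.model import (
    aggregate_cells,
    cell_attention,
    cell_type_attention,
    encode_cells,
    sample_representation,
    ablation_representation,
)
from hamil.data import Sample

from conftest import random_cohort, random_model, random_sample


class TestEncoder:
    def test_zero_input_zero_bias_gives_zero(self, rng):
        config, params = random_model(rng, m=3, hidden_dim=4)
        for b in params.enc_b:
            b[:] = 0.0
        H = encode_cells(np.zeros((5, 3)), params, config)
        assert np.all(H == 0.0)

    def test_hand_computed_single_unit(self):
        config = ModelConfig(input_dim=2, hidden_dim=1, n_classes=2)
        params = init_params(config)
        params.enc_W[0] = np.array([[1.0, -1.0]])
        params.enc_b[0] = np.array([0.0])
        H = encode_cells(np.array([[3.0, 1.0]]), params, config)
        np.testing.assert_allclose(H, [[2.0]])

    def test_row_wise_map_duplicates_rows(self, rng):
        config, params = random_model(rng, m=5)
        X = rng.normal(size=(3, 5))
        X2 = np.vstack([X, X[1]])
        H2 = encode_cells(X2, params, config)
        np.testing.assert_allclose(H2[3], H2[1])

    def test_two_layer_composition(self, rng):
        config, params = random_model(rng, m=4, n_hidden_layers=2)
        X = rng.normal(size=(6, 4))
        H1 = np.maximum(X @ params.enc_W[0].T + params.enc_b[0], 0)
        H2 = np.maximum(H1 @ params.enc_W[1].T + params.enc_b[1], 0)
        np.testing.assert_allclose(encode_cells(X, params, config), H2)

    def test_shape_mismatch_raises(self, rng):
        config, params = random_model(rng, m=5)
        with pytest.raises(ValueError):
            encode_cells(np.zeros((4, 3)), params, config)


class TestCellAttention:
    def test_zero_vector_gives_uniform(self, rng):
        H = rng.normal(size=(7, 4))
        alpha = cell_attention(H, np.zeros(4), 0.3)
        np.testing.assert_allclose(alpha, np.full(7, 1 / 7))

    def test_singleton_is_one(self, rng):
        alpha = cell_attention(rng.normal(size=(1, 4)), rng.normal(size=4), 0.0)
        assert alpha == pytest.approx([1.0])

    def test_logits_one_zero(self):
        # e = (1, 0) -> softmax = (0.7311, 0.2689)
        H = np.array([[1.0], [0.0]])
        alpha = cell_attention(H, np.array([1.0]), 0.0)
        assert alpha == pytest.approx([0.73105857863, 0.26894142137], abs=1e-8)

    def test_shift_invariance(self, rng):
        H = rng.normal(size=(6, 3))
        w = rng.normal(size=3)
        a1 = cell_attention(H, w, 0.0)
        a2 = cell_attention(H, w, 57.0)  # constant shift of every logit
        np.testing.assert_allclose(a1, a2, atol=1e-7)


class TestAggregation:
    def test_identical_cells_convexity(self, rng):
        row = rng.normal(size=4)
        H = np.tile(row, (5, 1))
        alpha = rng.dirichlet(np.ones(5))
        np.testing.assert_allclose(aggregate_cells(H, alpha), row)

    def test_cta_mean(self):
        h = aggregate_cells(np.array([[1.0, 0.0], [0.0, 1.0]]), np.array([0.5, 0.5]))
        assert h == pytest.approx([0.5, 0.5])

    def test_weighted_sum(self):
        h = aggregate_cells(np.array([[4.0, 0.0], [0.0, 4.0]]), np.array([0.75, 0.25]))
        assert h == pytest.approx([3.0, 1.0])


class TestTypeAttention:
    def test_single_type_is_one(self, rng):
        beta = cell_type_attention(rng.normal(size=(1, 4)), rng.normal(size=4), 0.1)
        assert beta == pytest.approx([1.0])

    def test_zero_vector_uniform(self, rng):
        beta = cell_type_attention(rng.normal(size=(3, 4)), np.zeros(4), 0.0)
        np.testing.assert_allclose(beta, np.full(3, 1 / 3))

    def test_logits_two_zero_zero(self):
        R = np.array([[2.0], [0.0], [0.0]])
        beta = cell_type_attention(R, np.array([1.0]), 0.0)
        assert beta == pytest.approx([0.78698604, 0.10650698, 0.10650698], abs=1e-6)


class TestSampleRepresentation:
    @pytest.mark.parametrize("mode", ["cta", "ha"])
    def test_normalization_chain(self, rng, mode):
        """Per-type alphas, betas and combined gammas each sum to one."""
        for _ in range(20):
            config, params = random_model(rng, m=5, mode=mode)
            s = random_sample(rng, int(rng.integers(2, 15)), 4, 5, ensure_absent=True)
            h, rec = sample_representation(s, params, config, n_cell_types=4)
            for a in rec.alpha:
                assert a.sum() == pytest.approx(1.0, abs=1e-6)
                assert np.all(a > 0)
            assert rec.beta.sum() == pytest.approx(1.0, abs=1e-6)
            assert rec.gamma.sum() == pytest.approx(1.0, abs=1e-6)

    @pytest.mark.parametrize("mode", ["cta", "ha"])
    def test_two_path_identity(self, rng, mode):
        """sum_i beta_i h_i equals sum_ij gamma_ij h_ij."""
        for _ in range(10):
            config, params = random_model(rng, m=5, mode=mode)
            s = random_sample(rng, int(rng.integers(2, 12)), 4, 5)
            cache = forward(s, params, config, n_cell_types=4)
            rec = cache.record
            via_types = rec.beta @ rec.type_reprs
            via_cells = rec.gamma @ cache.H
            np.testing.assert_allclose(via_types, via_cells, atol=1e-6)
            np.testing.assert_allclose(cache.h, via_types, atol=1e-6)

    def test_single_present_type_passthrough(self, rng):
        config, params = random_model(rng, m=5, mode="ha")
        s = Sample(X=rng.normal(size=(4, 5)), cell_types=np.array([2, 2, 2, 2]),
                   label=0, sample_id="T")
        h, rec = sample_representation(s, params, config, n_cell_types=4)
        assert rec.beta == pytest.approx([1.0])
        np.testing.assert_allclose(h, rec.type_reprs[0])

    def test_absent_types_receive_no_weight(self, rng):
        config, params = random_model(rng, m=5, mode="ha")
        s = random_sample(rng, 8, 5, 5, ensure_absent=True)
        _, rec = sample_representation(s, params, config, n_cell_types=5)
        assert set(rec.present_types) == set(np.unique(s.cell_types))
        assert len(rec.beta) == len(rec.present_types) < 5

    @pytest.mark.parametrize("mode", ["cta", "ha", "mean_pool", "cell_att"])
    def test_cell_order_invariance(self, rng, mode):
        config, params = random_model(rng, m=5, mode=mode)
        s = random_sample(rng, 10, 3, 5)
        perm = rng.permutation(10)
        s_perm = Sample(X=s.X[perm], cell_types=s.cell_types[perm], label=0, sample_id="P")
        c1 = forward(s, params, config, n_cell_types=3)
        c2 = forward(s_perm, params, config, n_cell_types=3)
        np.testing.assert_allclose(c1.h, c2.h, atol=1e-6)
        np.testing.assert_allclose(c1.probs, c2.probs, atol=1e-6)


class TestModeEquivalences:
    def test_ha_with_zero_attention_equals_cta(self, rng):
        config, params = random_model(rng, m=5, mode="ha")
        params.att_w = np.zeros_like(params.att_w)
        params.att_b = 0.0
        config_cta = ModelConfig(**{**config.__dict__, "mode": "cta"})
        s = random_sample(rng, 9, 4, 5)
        h_ha = forward(s, params, config, n_cell_types=4).h
        h_cta = forward(s, params, config_cta, n_cell_types=4).h
        np.testing.assert_allclose(h_ha, h_cta, atol=1e-12)

    def test_cell_att_with_zero_attention_equals_mean_pool(self, rng):
        config, params = random_model(rng, m=5, mode="cell_att")
        params.att_w = np.zeros_like(params.att_w)
        config_mp = ModelConfig(**{**config.__dict__, "mode": "mean_pool"})
        s = random_sample(rng, 9, 4, 5)
        np.testing.assert_allclose(
            forward(s, params, config, n_cell_types=4).h,
            forward(s, params, config_mp, n_cell_types=4).h, atol=1e-12)

    def test_cell_att_equals_ha_on_single_type_sample(self, rng):
        config, params = random_model(rng, m=5, mode="cell_att")
        config_ha = ModelConfig(**{**config.__dict__, "mode": "ha"})
        s = Sample(X=rng.normal(size=(7, 5)), cell_types=np.zeros(7, dtype=int),
                   label=0, sample_id="U")
        np.testing.assert_allclose(
            forward(s, params, config, n_cell_types=1).h,
            forward(s, params, config_ha, n_cell_types=1).h, atol=1e-6)

    def test_mean_pool_identical_cells(self, rng):
        config, params = random_model(rng, m=5, mode="mean_pool")
        row = rng.normal(size=5)
        s = Sample(X=np.tile(row, (6, 1)), cell_types=np.zeros(6, dtype=int),
                   label=0, sample_id="V")
        cache = forward(s, params, config)
        np.testing.assert_allclose(cache.h, cache.H[0])

    def test_ablation_representation_dispatch(self, rng):
        config, params = random_model(rng, m=5, mode="mean_pool")
        s = random_sample(rng, 6, 3, 5)
        h = ablation_representation(s, params, config)
        np.testing.assert_allclose(h, forward(s, params, config).h)
        with pytest.raises(ValueError):
            sample_representation(s, params, config)


class TestHead:
    def test_zero_head_uniform(self, rng):
        config, params = random_model(rng, m=5, n_classes=3, force_softmax_head=True)
        params.head_W = np.zeros_like(params.head_W)
        params.head_b = np.zeros_like(params.head_b)
        p = predict_proba(rng.normal(size=4), params, config)
        np.testing.assert_allclose(p, np.full(3, 1 / 3))

    def test_binary_zero_logit(self, rng):
        config, params = random_model(rng, m=5)
        params.head_W = np.zeros_like(params.head_W)
        params.head_b = np.zeros(())
        p = predict_proba(rng.normal(size=4), params, config)
        np.testing.assert_allclose(p, [0.5, 0.5])

    def test_binary_unit_logit(self):
        config = ModelConfig(input_dim=2, hidden_dim=1, n_classes=2)
        params = init_params(config)
        params.head_W = np.array([1.0])
        params.head_b = np.zeros(())
        p = predict_proba(np.array([1.0]), params, config)
        assert p[1] == pytest.approx(0.73105857863, abs=1e-8)
        assert p.sum() == pytest.approx(1.0)


class TestCrossEntropy:
    def test_perfect_predictions_zero_loss(self):
        probs = np.array([[1.0, 0.0], [0.0, 1.0]])
        assert cross_entropy_loss(probs, [0, 1]) == pytest.approx(0.0, abs=1e-9)

    def test_coin_flip_is_ln2(self):
        assert cross_entropy_loss(np.array([[0.5, 0.5]]), [1]) == pytest.approx(math.log(2))

    def test_monotone_in_correct_probability(self):
        lo = cross_entropy_loss(np.array([[0.4, 0.6]]), [1])
        hi = cross_entropy_loss(np.array([[0.2, 0.8]]), [1])
        assert hi < lo

    def test_label_out_of_range(self):
        with pytest.raises(ValueError):
            cross_entropy_loss(np.array([[0.5, 0.5]]), [2])


class TestCheckpoint:
    def test_round_trip_lossless(self, rng, tmp_path):
        config, params = random_model(rng, m=6, n_hidden_layers=2, n_classes=3,
                                      force_softmax_head=True)
        path = tmp_path / "model.json"
        save_checkpoint(path, params, config, ["a", "b"], ["x", "y", "z"])
        params2, config2, types, classes = load_checkpoint(path)
        assert config2 == config
        assert types == ["a", "b"] and classes == ["x", "y", "z"]
        for l in range(2):
            np.testing.assert_array_equal(params.enc_W[l], params2.enc_W[l])
        np.testing.assert_array_equal(params.att_w, params2.att_w)
        np.testing.assert_array_equal(params.head_W, params2.head_W)

    def test_rejects_foreign_file(self, tmp_path):
        path = tmp_path / "junk.json"
        path.write_text('{"some": "json"}')
        with pytest.raises(ValueError):
            load_checkpoint(path)
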