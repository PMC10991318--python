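import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cardioml.attgru import (
    AttGRUConfig,
    FitnessSpec,
    attention_weights,
    fitness,
    flatten,
    forward,
    forward_batch,
    gru_cell,
    mape,
    param_count,
    softmax,
    unflatten,
    weighted_input,
    zero_params,
)

CFG44 = AttGRUConfig(n_features_in=5, hidden_units=(4, 4))


def random_params(config, seed=0, scale=0.5):
    g = np.random.default_rng(seed)
    return unflatten(g.normal(scale=scale, size=param_count(config)), config)


class TestAttention:
    def test_softmax_frozen_values(self):
        # exp(1), exp(2), exp(3) normalized
        out = softmax(np.array([1.0, 2.0, 3.0]))
        np.testing.assert_allclose(
            out, [0.09003057317038046, 0.24472847105479767, 0.6652409557748219],
            atol=1e-12,
        )

    def test_softmax_shift_invariant(self):
        s = np.array([0.3, -1.2, 2.5, 0.0])
        np.testing.assert_allclose(softmax(s), softmax(s + 123.4), atol=1e-12)

    def test_equal_scores_give_uniform_weights(self):
        params = zero_params(CFG44)  # w_a = b_a = 0 -> all scores equal
        alpha = attention_weights(np.array([5.0, -3.0, 0.1, 2.0, 7.0]), params)
        np.testing.assert_allclose(alpha, np.full(5, 0.2), atol=1e-12)

    def test_single_element_weight_is_one(self):
        params = random_params(AttGRUConfig(n_features_in=1, hidden_units=(2, 2)))
        alpha = attention_weights(np.array([3.3]), params)
        np.testing.assert_allclose(alpha, [1.0], atol=1e-15)

    def test_scorer_matches_hand_evaluation(self):
        params = random_params(CFG44, seed=3)
        x = np.array([0.4, -1.0, 2.0, 0.0, -0.3])
        e = np.tanh(params.w_a * x + params.b_a)
        expected = np.exp(e) / np.exp(e).sum()
        np.testing.assert_allclose(attention_weights(x, params), expected, atol=1e-12)

    @given(st.lists(st.floats(-50, 50), min_size=1, max_size=12))
    @settings(max_examples=100, deadline=None)
    def test_weights_always_sum_to_one(self, xs):
        params = random_params(CFG44, seed=1)
        alpha = attention_weights(np.array(xs), params)
        assert abs(alpha.sum() - 1.0) < 1e-12
        assert np.all(alpha >= 0)

    def test_non_finite_input_rejected(self):
        with pytest.raises(ValueError):
            attention_weights(np.array([1.0, np.inf]), zero_params(CFG44))


class TestWeightedInput:
    def test_mean_case(self):
        assert weighted_input(np.array([2.0, 4.0]), np.array([0.5, 0.5])) == 3.0

    def test_one_hot_selects(self):
        x = np.array([1.0, 7.0, -2.0])
        assert weighted_input(x, np.array([0.0, 1.0, 0.0])) == 7.0

    def test_unit_weights_on_constant_input(self):
        alpha = softmax(np.tanh(np.array([1.0, 2.0, 3.0])))
        assert weighted_input(np.ones(3), alpha) == pytest.approx(1.0, abs=1e-12)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            weighted_input(np.ones(3), np.ones(2))


class TestGruCell:
    def test_zero_parameters_hand_value(self):
        # all gates sigmoid(0)=0.5, candidate tanh(0)=0; h = 0.5*0 + 0.5*1
        params = zero_params(AttGRUConfig(n_features_in=1, hidden_units=(1, 1)))
        h = gru_cell(np.array([0.7]), np.array([1.0]), params.layers[0])
        np.testing.assert_allclose(h, [0.5], atol=1e-15)

    def test_update_gate_saturation_keeps_previous_state(self):
        params = random_params(CFG44, seed=2)
        layer = params.layers[0]
        layer.b_v[:] = 50.0  # v -> 1, so h_t -> h_prev
        h_prev = np.array([0.3, -0.2, 0.9, 0.0])
        h = gru_cell(np.array([1.5]), h_prev, layer)
        np.testing.assert_allclose(h, h_prev, atol=1e-12)

    @given(st.integers(0, 1000))
    @settings(max_examples=60, deadline=None)
    def test_state_stays_bounded(self, seed):
        g = np.random.default_rng(seed)
        params = random_params(CFG44, seed=seed, scale=2.0)
        h_prev = g.uniform(-1, 1, size=4)
        h = gru_cell(g.normal(size=1), h_prev, params.layers[0])
        assert np.all(np.abs(h) <= max(np.max(np.abs(h_prev)), 1.0) + 1e-12)

    def test_non_finite_rejected(self):
        params = zero_params(CFG44)
        with pytest.raises(ValueError):
            gru_cell(np.array([np.nan]), np.zeros(4), params.layers[0])


class TestForward:
    def test_zero_network_outputs_half(self, rng):
        params = zero_params(CFG44)
        X = rng.normal(size=(20, 5))
        np.testing.assert_allclose(forward_batch(X, params, CFG44), 0.5, atol=1e-15)

    def test_output_in_open_unit_interval(self, rng):
        params = random_params(CFG44, seed=5, scale=2.0)
        X = rng.normal(size=(1000, 5)) * 3
        out = forward_batch(X, params, CFG44)
        assert np.all((out > 0) & (out < 1))

    def test_deterministic(self, rng):
        params = random_params(CFG44, seed=6)
        x = rng.normal(size=5)
        assert forward(x, params, CFG44) == forward(x, params, CFG44)

    def test_batch_matches_stepwise_reference(self, rng):
        """The vectorized forward equals composing attention + gru_cell by hand."""
        params = random_params(CFG44, seed=7)
        X = rng.normal(size=(6, 5))
        expected = []
        for x in X:
            alpha = attention_weights(x, params)
            seq = alpha * x
            h1, h2 = np.zeros(4), np.zeros(4)
            for t in range(5):
                h1 = gru_cell(np.array([seq[t]]), h1, params.layers[0])
                h2 = gru_cell(h1, h2, params.layers[1])
            logit = h2 @ params.w_out + params.b_out
            expected.append(1.0 / (1.0 + np.exp(-logit)))
        np.testing.assert_allclose(
            forward_batch(X, params, CFG44), expected, atol=1e-12
        )

    def test_small_parameter_change_small_output_change(self, rng):
        vec = np.random.default_rng(8).normal(size=param_count(CFG44))
        X = rng.normal(size=(50, 5))
        out0 = forward_batch(X, unflatten(vec, CFG44), CFG44)
        out1 = forward_batch(X, unflatten(vec + 1e-6, CFG44), CFG44)
        assert np.max(np.abs(out1 - out0)) < 1e-3

    def test_shape_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            forward_batch(rng.normal(size=(3, 4)), zero_params(CFG44), CFG44)


class TestFitness:
    def test_mape_printed_form_example(self):
        assert mape(np.array([1.0, 1.0, 5.0]), np.array([1.0, 2.0, 4.0])) == 0.25

    def test_mape_perfect_on_positive_labels(self):
        assert mape(np.ones(4), np.ones(4)) == 0.0

    def test_mape_zero_labels_guarded_finite(self):
        val = mape(np.full(10, 0.5), np.zeros(10), epsilon=1e-7)
        assert np.isfinite(val)
        assert val == pytest.approx(0.5 / 1e-7)

    def test_zero_network_mape_on_balanced_labels(self):
        # E = 0.5 always; on labels {0,1} half the terms are 0.5/1, half 0.5/eps
        X = np.random.default_rng(0).normal(size=(10, 5))
        y = np.r_[np.ones(5), np.zeros(5)]
        val = fitness(np.zeros(param_count(CFG44)), X, y, CFG44, FitnessSpec())
        expected = 0.5 * 0.5 + 0.5 * (0.5 / 1e-7)
        assert val == pytest.approx(expected)

    def test_cross_entropy_of_zero_network_is_log2(self):
        X = np.random.default_rng(1).normal(size=(8, 5))
        y = np.r_[np.ones(4), np.zeros(4)]
        val = fitness(
            np.zeros(param_count(CFG44)), X, y, CFG44,
            FitnessSpec(kind="cross_entropy"),
        )
        assert val == pytest.approx(np.log(2.0))

    def test_empty_data_rejected(self):
        with pytest.raises(ValueError):
            fitness(np.zeros(param_count(CFG44)), np.empty((0, 5)), np.empty(0), CFG44)


class TestFlattening:
    def test_round_trip_identity(self):
        params = random_params(CFG44, seed=9)
        vec = flatten(params)
        back = flatten(unflatten(vec, CFG44))
        np.testing.assert_array_equal(vec, back)

    def test_parameter_count_hand_derivation(self):
        # attention 2; layer1 3*(4*(4+1)+4)=72; layer2 3*(4*(4+4)+4)=108; out 5
        assert param_count(CFG44) == 2 + 72 + 108 + 5 == 187

    def test_wrong_length_rejected_with_counts(self):
        with pytest.raises(ValueError, match="187"):
            unflatten(np.zeros(10), CFG44)

    def test_zero_vector_gives_constant_half_network(self, rng):
        params = unflatten(np.zeros(param_count(CFG44)), CFG44)
        out = forward_batch(rng.normal(size=(7, 5)), params, CFG44)
        np.testing.assert_allclose(out, 0.5, atol=1e-15)
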