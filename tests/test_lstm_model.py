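import numpy as np
import pytest

from adprog import (
    PreprocessPipeline,
    TrainConfig,
    fit,
    init_params,
    loss_and_grads,
    loss_with_l2,
    lstm_cell_forward,
    network_forward,
    predict_next_stage,
)
from adprog.lstm_model import (
    FitResult,
    load_model,
    numeric_gradient,
    save_model,
    weight_keys,
)


def _zero_cell(hidden, width):
    cell = {}
    for g in ("Wf", "Wi", "Wc", "Wo"):
        cell[g] = np.zeros((hidden, hidden + width))
    for b in ("bf", "bi", "bc", "bo"):
        cell[b] = np.zeros(hidden)
    return cell


def test_cell_zero_parameters_zero_state():
    cell = _zero_cell(3, 4)
    h, C, cache = lstm_cell_forward(np.zeros((1, 4)), np.zeros((1, 3)),
                                    np.zeros((1, 3)), cell)
    _, f, i, g, o, _, _ = cache
    np.testing.assert_allclose(f, 0.5)
    np.testing.assert_allclose(o, 0.5)
    np.testing.assert_allclose(C, 0.0)
    np.testing.assert_allclose(h, 0.0)


def test_cell_scalar_hand_computation():
    """Zero weights, C_prev = 1: C = 0.5, h = 0.5 tanh(0.5)."""
    cell = _zero_cell(1, 1)
    h, C, _ = lstm_cell_forward(np.zeros((1, 1)), np.zeros((1, 1)),
                                np.ones((1, 1)), cell)
    assert C[0, 0] == pytest.approx(0.5)
    assert h[0, 0] == pytest.approx(0.231059, abs=1e-6)


def test_gates_strictly_inside_unit_interval(rng):
    cell = {k: rng.normal(scale=2.0, size=v.shape)
            for k, v in _zero_cell(4, 6).items()}
    _, _, cache = lstm_cell_forward(rng.normal(size=(8, 6)),
                                    rng.normal(size=(8, 4)),
                                    rng.normal(size=(8, 4)), cell)
    _, f, i, g, o, _, _ = cache
    for gate in (f, i, o):
        assert np.all(gate > 0) and np.all(gate < 1)


def test_cell_rejects_shape_mismatch():
    cell = _zero_cell(3, 4)
    with pytest.raises(ValueError):
        lstm_cell_forward(np.zeros((1, 5)), np.zeros((1, 3)),
                          np.zeros((1, 3)), cell)


def test_zero_network_outputs_uniform(rng):
    params = {k: np.zeros_like(v) for k, v in init_params(6, 3, seed=0).items()}
    X = rng.normal(size=(4, 3, 6))
    probs = network_forward(X, np.ones((4, 3)), params)
    np.testing.assert_allclose(probs, 0.2)


def test_outputs_are_distributions_and_mask_invariant(rng):
    params = init_params(6, hidden=5, seed=3)
    X = rng.normal(size=(4, 3, 6))
    mask = np.ones((4, 3))
    probs = network_forward(X, mask, params)
    np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-9)
    assert np.all(probs > 0)
    # appending masked pad rows leaves the output unchanged
    Xpad = np.concatenate([X, rng.normal(size=(4, 2, 6))], axis=1)
    mpad = np.concatenate([mask, np.zeros((4, 2))], axis=1)
    np.testing.assert_allclose(network_forward(Xpad, mpad, params), probs,
                               atol=1e-12)


def test_forward_rejects_empty_batch():
    params = init_params(6, hidden=5, seed=3)
    with pytest.raises(ValueError):
        network_forward(np.zeros((2, 3, 6)), np.zeros((2, 3)), params)


def test_loss_values():
    params = {k: np.zeros_like(v) for k, v in init_params(4, 2, seed=0).items()}
    y = np.array([[0, 0, 1, 0, 0.0]])
    assert loss_with_l2(y, y, params, 0.0, "binary_ce") == pytest.approx(0.0, abs=1e-9)
    uniform = np.full((1, 5), 0.2)
    expected = -(np.log(0.2) + 4 * np.log(0.8))
    assert loss_with_l2(uniform, y, params, 0.0, "binary_ce") == pytest.approx(
        expected, abs=1e-9)
    assert expected == pytest.approx(2.50201, abs=1e-5)
    # with all-zero weights the L2 term contributes nothing even at lambda 1
    assert loss_with_l2(uniform, y, params, 1.0, "binary_ce") == pytest.approx(
        expected, abs=1e-9)
    assert loss_with_l2(uniform, y, params, 0.0, "categorical_ce") == \
        pytest.approx(-np.log(0.2), abs=1e-9)


@pytest.mark.parametrize("variant", ["binary_ce", "categorical_ce"])
def test_gradients_match_finite_differences(variant, rng):
    B, T, D, H = 5, 3, 4, 3
    X = rng.normal(size=(B, T, D))
    mask = np.ones((B, T))
    mask[1, 2] = 0
    y = np.eye(5)[rng.integers(0, 5, B)]
    params = init_params(D, hidden=H, seed=7)
    _, grads, _ = loss_and_grads(X, mask, y, params, 1e-3, variant)
    checked = 0
    for key in params:
        flat = grads[key].reshape(-1)
        for i in rng.choice(flat.size, size=min(4, flat.size), replace=False):
            num = numeric_gradient(X, mask, y, params, 1e-3, variant, key, int(i))
            denom = max(abs(num), abs(flat[i]), 1e-8)
            assert abs(flat[i] - num) / denom < 1e-4, key
            checked += 1
    assert checked >= 20


def test_l2_adds_exactly_two_lambda_w(rng):
    X = rng.normal(size=(3, 3, 4))
    mask = np.ones((3, 3))
    y = np.eye(5)[rng.integers(0, 5, 3)]
    params = init_params(4, hidden=3, seed=1)
    lam = 0.37
    _, g0, _ = loss_and_grads(X, mask, y, params, 0.0, "binary_ce")
    _, g1, _ = loss_and_grads(X, mask, y, params, lam, "binary_ce")
    wkeys = set(weight_keys(params))
    for k in params:
        if k in wkeys:
            np.testing.assert_allclose(g1[k] - g0[k], 2 * lam * params[k],
                                       atol=1e-12)
        else:
            np.testing.assert_allclose(g1[k], g0[k], atol=1e-12)


def test_head_bias_gradient_closed_form_at_uniform(rng):
    """Zero params give uniform softmax; d/db = sum(p - y) for categorical CE."""
    params = {k: np.zeros_like(v) for k, v in init_params(4, 3, seed=0).items()}
    X = np.zeros((6, 2, 4))
    mask = np.ones((6, 2))
    y = np.eye(5)[rng.integers(0, 5, 6)]
    _, grads, probs = loss_and_grads(X, mask, y, params, 0.0, "categorical_ce")
    np.testing.assert_allclose(grads["head_b"], (probs - y).sum(0), atol=1e-12)
    np.testing.assert_allclose(probs, 0.2)


@pytest.fixture(scope="module")
def encoded_small():
    from adprog import CohortConfig, simulate_cohort

    cohort = simulate_cohort(
        CohortConfig(n_patients=150, seed=13, p_fid=1.0, inject_missing=False))
    pipeline = PreprocessPipeline.fit(cohort.visits, cohort.schema)
    return pipeline.encode(cohort.visits, cohort.truth)


def test_training_reduces_loss_and_is_deterministic(encoded_small):
    config = TrainConfig(epochs=3, hidden=16, seed=2)
    a = fit(encoded_small, config)
    b = fit(encoded_small, config)
    assert a.history[-1]["loss"] < a.history[0]["loss"]
    for k in a.params:
        np.testing.assert_array_equal(a.params[k], b.params[k])
        np.testing.assert_array_equal(a.ema_params[k], b.ema_params[k])


def test_zero_learning_rate_freezes_parameters(encoded_small):
    config = TrainConfig(epochs=2, hidden=8, seed=4, learning_rate=0.0)
    result = fit(encoded_small, config)
    init = init_params(encoded_small.X.shape[2], hidden=8, seed=4)
    for k, v in init.items():
        np.testing.assert_array_equal(result.params[k], v)
    assert result.history[0]["loss"] == pytest.approx(result.history[1]["loss"],
                                                      rel=1e-9)


def test_tie_break_predicts_lowest_stage(encoded_small):
    zero = {k: np.zeros_like(v)
            for k, v in init_params(encoded_small.X.shape[2], 4, seed=0).items()}
    stages, probs = predict_next_stage(encoded_small, zero)
    np.testing.assert_allclose(probs, 0.2)
    assert np.all(stages == 0.0)


def test_model_bundle_round_trip(tmp_path, encoded_small):
    config = TrainConfig(epochs=1, hidden=8, seed=4)
    result = fit(encoded_small, config)
    save_model(tmp_path / "model", result, "{}")
    loaded = load_model(tmp_path / "model")
    assert loaded.config == config
    for k in result.params:
        np.testing.assert_array_equal(loaded.params[k], result.params[k])
        np.testing.assert_array_equal(loaded.ema_params[k], result.ema_params[k])
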