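"""Transition tables and the four dopamine-to-transition models."""

import warnings

import numpy as np
import pytest

from striatalrl.dopamine_models import (
    ModelFit,
    TransitionTables,
    compare_models,
    compute_transition_tables,
    fit_all_models,
    fit_q_table,
    fit_v_model,
    predict_p_action_value,
    predict_p_state_value,
)
from striatalrl.synth import generate_dlight_session


def _full_tables(D):
    D = np.asarray(D, dtype=float)
    S = D.shape[0]
    return TransitionTables(
        n_syllables=S, D=D, P=np.ones((S, S)) / S,
        counts=np.ones((S, S), dtype=int), mask=np.ones((S, S), dtype=bool),
    )


def test_transition_tables_alternation():
    seq = np.array([0, 1, 0, 1])
    t = compute_transition_tables(seq, np.array([0.0, 2.0, 2.0, 2.0]))
    assert t.P[0, 1] == 1.0 and t.P[1, 0] == 1.0
    assert t.D[0, 1] == 2.0 and t.D[1, 0] == 2.0
    assert not t.mask[0, 0]
    # constant dopamine -> D constant on observed cells
    t2 = compute_transition_tables(seq, np.full(4, 3.5))
    assert np.all(t2.D[t2.mask] == 3.5)
    with pytest.raises(ValueError):
        compute_transition_tables(np.array([0]), np.array([1.0]))


def test_transition_tables_against_enumeration():
    seq = np.array([0, 2, 1, 2, 0])
    dop = np.array([0.0, 1.0, -1.0, 2.0, 0.5])
    t = compute_transition_tables(seq, dop, n_syllables=3)
    # brute-force enumeration of the 4 transitions
    pairs = list(zip(seq[:-1], seq[1:], dop[1:]))
    for i in range(3):
        for j in range(3):
            obs = [d for (a, b, d) in pairs if a == i and b == j]
            if obs:
                assert t.D[i, j] == pytest.approx(np.mean(obs))
                n_from_i = sum(a == i for (a, _, _) in pairs)
                assert t.P[i, j] == pytest.approx(len(obs) / n_from_i)
            else:
                assert not t.mask[i, j]


def test_q_fit_zero_and_sanity():
    t = _full_tables(np.zeros((3, 3)))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = fit_q_table(t)
    assert np.all(fit.Q == 0.0)
    # optimizer does at least as well as the zero init on a toy table
    D = np.array([[0.5, -0.5], [1.0, 0.0]])
    fit2 = fit_q_table(_full_tables(D))
    pred = fit2.Q.max(axis=1)[None, :] - fit2.Q
    assert ((pred - D) ** 2).mean() <= (D ** 2).mean()
    np.testing.assert_allclose(fit2.P_hat.sum(axis=1), 1.0)


def test_q_fit_noiseless_roundtrip():
    """D tables generated from a known Q are fit nearly perfectly (the
    descent can stop in a local optimum of the nonconvex max-coupled
    problem, so recovery is asserted by correlation, not exact MSE)."""
    Q = np.random.default_rng(0).normal(size=(5, 5))
    D = Q.max(axis=1)[None, :] - Q
    fit = fit_q_table(_full_tables(D))
    pred = fit.Q.max(axis=1)[None, :] - fit.Q
    assert np.corrcoef(pred.ravel(), D.ravel())[0, 1] > 0.99
    assert ((pred - D) ** 2).mean() < 0.05 * D.var()


def test_v_model_recovery_and_shared_rows():
    v = np.array([0.0, 1.0, -0.5, 2.0])
    D = v[None, :] - v[:, None]
    fit = fit_v_model(_full_tables(D))
    np.testing.assert_allclose(fit.V - fit.V[0], v, atol=1e-8)
    # predicted rows are identical (independent of the previous syllable)
    assert np.allclose(fit.P_hat, fit.P_hat[0][None, :])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit0 = fit_v_model(_full_tables(np.zeros((3, 3))))
    np.testing.assert_allclose(fit0.P_hat, 1.0 / 3.0)


def test_action_value_normalization():
    fit = predict_p_action_value(_full_tables([[1.0, 3.0], [2.0, 2.0]]))
    np.testing.assert_allclose(fit.P_hat[0], [0.25, 0.75])
    np.testing.assert_allclose(fit.P_hat[1], [0.5, 0.5])
    D = np.array([[1.0, 2.0, 3.0], [0.5, 0.5, 1.0], [3.0, 0.0, 0.0]])
    fit3 = predict_p_action_value(_full_tables(D))
    np.testing.assert_allclose(fit3.P_hat, D / D.sum(axis=1, keepdims=True))
    with pytest.warns(UserWarning, match="negative"):
        predict_p_action_value(_full_tables([[1.0, -0.5], [0.5, 0.5]]))


def test_state_value_rows_identical():
    fit = predict_p_state_value(_full_tables([[2.0, 2.0], [2.0, 2.0]]))
    np.testing.assert_allclose(fit.P_hat, 0.5)
    D = np.array([[1.0, 3.0], [3.0, 1.0]])
    fit2 = predict_p_state_value(_full_tables(D))
    assert np.allclose(fit2.P_hat[0], fit2.P_hat[1])
    np.testing.assert_allclose(fit2.P_hat[0], [0.5, 0.5])


def test_compare_models_perfect_and_degenerate():
    t = _full_tables(np.zeros((2, 2)))
    t.P = np.array([[0.2, 0.8], [0.6, 0.4]])
    perfect = ModelFit(model="m", P_hat=t.P.copy())
    rs = compare_models(t, [perfect])
    assert rs["m"] == pytest.approx(1.0)
    with pytest.warns(UserWarning, match="degenerate"):
        rs = compare_models(t, [ModelFit(model="u", P_hat=np.full((2, 2), 0.5))])
    assert rs["u"] == 0.0


def test_all_predictions_row_stochastic():
    rng = np.random.default_rng(9)
    Q = rng.normal(size=(8, 8))
    seq, dop, _ = generate_dlight_session(Q, n_transitions=2000, rng=rng)
    t = compute_transition_tables(seq, dop)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fits = [
            fit_q_table(t), fit_v_model(t),
            predict_p_action_value(t), predict_p_state_value(t),
        ]
    for fit in fits:
        np.testing.assert_allclose(fit.P_hat.sum(axis=1), 1.0, atol=1e-9)
        assert np.all(fit.P_hat >= -1e-12) or fit.model in (
            "action_value", "state_value"  # negative z-scored dopamine
        )


def test_q_model_wins_on_q_generated_sessions():
    rng = np.random.default_rng(17)
    wins = 0
    for _ in range(5):
        Q = rng.normal(size=(20, 20))
        seq, dop, _ = generate_dlight_session(Q, n_transitions=10_000, rng=rng)
        t = compute_transition_tables(seq, dop)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rs = fit_all_models(t)
        wins += max(rs, key=rs.get) == "q_learning"
    assert wins == 5
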