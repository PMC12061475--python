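"""Feedforward activity, softmax policy, efference and post-selection models."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from striatalrl.learning import PlasticityRuleSpec, weight_update
from striatalrl.network import (
    NO_ACTION,
    SPNActivity,
    StriatalNetwork,
    action_probabilities,
    apply_efference,
    canonical_postselection,
    feedforward_activity,
    select_action,
    shared_control_probabilities,
)


def test_feedforward_symmetric_init():
    net = StriatalNetwork(n_actions=3, n_inputs=2)
    x = np.array([1.0, 0.0])
    act = feedforward_activity(net, x)
    np.testing.assert_array_equal(act.y_d, 1.0)
    np.testing.assert_array_equal(act.y_i, 1.0)
    np.testing.assert_array_equal(act.logits, 0.0)


def test_feedforward_rectification_and_linearity():
    net = StriatalNetwork(n_actions=1, n_inputs=1, W_d=[[-2.0]], W_i=[[0.5]])
    act = feedforward_activity(net, np.array([1.0]))
    assert act.y_d[0] == 0.0
    net2 = StriatalNetwork(n_actions=1, n_inputs=2, W_d=[[2.0, 1.0]],
                           W_i=[[0.0, 0.0]])
    assert feedforward_activity(net2, np.array([1.0, 1.0])).y_d[0] == 3.0
    with pytest.raises(ValueError):
        feedforward_activity(net, np.ones(3))


def test_action_probabilities():
    act = SPNActivity(y_d=np.zeros(2), y_i=np.zeros(2))
    np.testing.assert_allclose(action_probabilities(act, 10.0, 0.0), 0.5)
    # go/no-go: single action at logit 0 against c_nogo = 1
    one = SPNActivity(y_d=np.zeros(1), y_i=np.zeros(1))
    np.testing.assert_allclose(action_probabilities(one, 10.0, 1.0), 0.5)
    # beta=10, logits (0.1, 0): p(1) = e / (e + 1)
    act = SPNActivity(y_d=np.array([0.1, 0.0]), y_i=np.zeros(2))
    p = action_probabilities(act, 10.0, 0.0)
    assert p[0] == pytest.approx(np.e / (np.e + 1.0))
    with pytest.raises(ValueError):
        action_probabilities(act, 10.0, -1.0)


def test_probabilities_sum_to_one_with_noaction():
    act = SPNActivity(y_d=np.array([0.4, 0.0]), y_i=np.array([0.0, 0.2]))
    p = action_probabilities(act, 5.0, c_nogo=2.0)
    assert 0 < p.sum() < 1
    manual = np.exp(5.0 * act.logits)
    np.testing.assert_allclose(p, manual / (2.0 + manual.sum()))


def test_max_shift_guard_keeps_probabilities():
    act = SPNActivity(y_d=np.array([500.0, 0.0]), y_i=np.zeros(2))
    p = action_probabilities(act, 10.0, c_nogo=1.0)
    assert np.all(np.isfinite(p))
    assert p[0] == pytest.approx(1.0)


def test_constant_logit_shift_invariance_only_without_nogo():
    base = SPNActivity(y_d=np.array([0.3, 0.1]), y_i=np.zeros(2))
    shifted = SPNActivity(y_d=np.array([0.8, 0.6]), y_i=np.zeros(2))
    np.testing.assert_allclose(
        action_probabilities(base, 7.0, 0.0),
        action_probabilities(shifted, 7.0, 0.0),
    )
    assert not np.allclose(
        action_probabilities(base, 7.0, 1.0),
        action_probabilities(shifted, 7.0, 1.0),
    )


def test_select_action():
    rng = np.random.default_rng(0)
    assert select_action(np.array([1.0, 0.0]), rng) == 0
    # fixed seed reproducibility
    s1 = [select_action(np.array([0.3, 0.3]), np.random.default_rng(5))
          for _ in range(3)]
    assert len(set(s1)) == 1
    with pytest.raises(ValueError):
        select_action(np.array([-0.1, 1.1]), rng)


def test_select_action_frequencies_match_probs():
    """Empirical frequencies over many draws match p within 3 sigma."""
    probs = np.array([0.5, 0.3])  # 0.2 no-action mass
    rng = np.random.default_rng(42)
    n = 20_000
    draws = [select_action(probs, rng) for _ in range(n)]
    counts = np.array([
        sum(d == 0 for d in draws),
        sum(d == 1 for d in draws),
        sum(d is NO_ACTION for d in draws),
    ])
    expect = np.array([0.5, 0.3, 0.2]) * n
    sigma = np.sqrt(expect * (1 - expect / n))
    assert np.all(np.abs(counts - expect) < 3 * sigma)


def test_apply_efference_arithmetic():
    net = StriatalNetwork(n_actions=3, n_inputs=1, c_efference=1.5)
    x = np.array([1.0])
    act = apply_efference(net, x, 0)
    assert act.y_d[0] == act.y_i[0] == 2.5
    np.testing.assert_array_equal(act.y_d[1:], 1.0)
    np.testing.assert_array_equal(act.y_i[1:], 1.0)
    # zero efference reduces to feedforward
    net0 = StriatalNetwork(n_actions=3, n_inputs=1, c_efference=0.0)
    ff = feedforward_activity(net0, x)
    eff = apply_efference(net0, x, 1)
    np.testing.assert_array_equal(ff.y_d, eff.y_d)
    np.testing.assert_array_equal(ff.logits, eff.logits)
    with pytest.raises(ValueError):
        apply_efference(net, x, NO_ACTION)


@settings(max_examples=50, deadline=None)
@given(st.integers(0, 2**32 - 1))
def test_efference_orthogonality_bit_exact(seed):
    """With positive pre-activations, efferent input lies in the sum mode
    and leaves every logit — hence the action probabilities — bit-identical."""
    rng = np.random.default_rng(seed)
    net = StriatalNetwork(
        n_actions=4, n_inputs=3,
        W_d=rng.uniform(0.1, 2.0, (4, 3)),
        W_i=rng.uniform(0.1, 2.0, (4, 3)),
        c_efference=float(rng.uniform(0.1, 3.0)),
    )
    x = rng.uniform(0.05, 1.0, 3)   # positive input: pre-activations > 0
    chosen = int(rng.integers(4))
    ff = feedforward_activity(net, x)
    eff = apply_efference(net, x, chosen)
    assert np.array_equal(ff.logits, eff.logits)
    p_ff = action_probabilities(ff, 10.0, 0.0)
    p_eff = action_probabilities(eff, 10.0, 0.0)
    assert np.array_equal(p_ff, p_eff)


def test_efference_with_binding_rectification_changes_logit():
    net = StriatalNetwork(n_actions=1, n_inputs=1, W_d=[[-1.0]], W_i=[[0.5]],
                          c_efference=1.5)
    x = np.array([1.0])
    ff = feedforward_activity(net, x)
    eff = apply_efference(net, x, 0)
    # dSPN pre-activation was rectified at 0; efference unmasks it
    assert eff.y_d[0] == 0.5 and eff.y_i[0] == 2.0
    assert eff.logits[0] != ff.logits[0]


@pytest.mark.parametrize(
    "A,chosen,y_d,y_i",
    [
        (2, 0, (1, 0), (0, 1)),
        (1, NO_ACTION, (0,), (1,)),
        (3, 2, (0, 0, 1), (1, 1, 0)),
    ],
)
def test_canonical_postselection(A, chosen, y_d, y_i):
    act = canonical_postselection(A, chosen)
    np.testing.assert_array_equal(act.y_d, y_d)
    np.testing.assert_array_equal(act.y_i, y_i)


def test_shared_control_probabilities():
    act = SPNActivity(y_d=np.array([0.3, 0.0]), y_i=np.zeros(2))
    # weight 1, zero bias: identical to the plain policy
    np.testing.assert_allclose(
        shared_control_probabilities(act, np.zeros(2), 1.0, 10.0, 0.0),
        action_probabilities(act, 10.0, 0.0),
    )
    # overwhelming tutor: its action is chosen almost surely
    p = shared_control_probabilities(act, np.array([0.0, 50.0]), 0.0, 10.0, 0.0)
    assert p[1] == pytest.approx(1.0)
    # weight 0.5 halves the striatal logit contribution
    p_half = shared_control_probabilities(act, np.zeros(2), 0.5, 10.0, 0.0)
    act_half = SPNActivity(y_d=0.5 * act.logits, y_i=np.zeros(2))
    np.testing.assert_allclose(p_half, action_probabilities(act_half, 10.0, 0.0))


def test_sum_mode_drives_difference_mode_learning():
    """One linear-rule learning step changes each logit by exactly
    alpha * delta * (y_d + y_i) * (x . x)."""
    rng = np.random.default_rng(3)
    # dyadic-rational parameters: every intermediate is exactly
    # representable, so the identity holds as float equality
    rule = PlasticityRuleSpec(kind="linear", alpha=0.0625)
    net = StriatalNetwork(n_actions=3, n_inputs=2, c_efference=1.5)
    x = np.array([0.0, 1.0])
    delta = 1.0
    act = apply_efference(net, x, 1)
    l_before = feedforward_activity(net, x).logits
    net.W_d += weight_update(rule, "direct", delta, act.y_d, x)
    net.W_i += weight_update(rule, "indirect", delta, act.y_i, x)
    l_after = feedforward_activity(net, x).logits
    predicted = rule.alpha * delta * (act.y_d + act.y_i) * (x @ x)
    np.testing.assert_array_equal(l_after - l_before, predicted)
    # dense input: equality to numerical precision
    net2 = StriatalNetwork(n_actions=2, n_inputs=3,
                           W_d=rng.uniform(0.5, 1.5, (2, 3)),
                           W_i=rng.uniform(0.5, 1.5, (2, 3)))
    x2 = rng.uniform(0.1, 1.0, 3)
    act2 = feedforward_activity(net2, x2)
    l0 = act2.logits.copy()
    net2.W_d += weight_update(rule, "direct", delta, act2.y_d, x2)
    net2.W_i += weight_update(rule, "indirect", delta, act2.y_i, x2)
    l1 = feedforward_activity(net2, x2).logits
    np.testing.assert_allclose(
        l1 - l0, rule.alpha * delta * (act2.y_d + act2.y_i) * (x2 @ x2),
        rtol=1e-12,
    )
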