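"""Trial-based striatal learning experiments.

Three families of tasks are simulated with the tabular network:

* **go/no-go** — a single cue and a single "go" action that is correct;
  withholding action is the alternative (no-action weight c_nogo = 1).
* **action selection** — N cortical states, N actions, one correct action
  per state (c_nogo = 0).
* **shared control** — a 10-state / 10-action task in which action
  selection is driven by a weighted combination of striatal logits and a
  "tutor" pathway biased toward the correct action; the striatum learns
  off- or on-policy and is periodically evaluated on its own.

Each trial draws a state uniformly, computes feedforward SPN activity,
selects an action from the softmax policy, delivers reward according to the
protocol, computes the dopamine signal δ from a TD or Q critic, forms the
post-selection activity (canonical or efference model) and applies the
three-factor weight update to both pathways.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .learning import (
    CriticState,
    PlasticityRuleSpec,
    q_error,
    td_error_and_update,
    weight_update,
)
from .network import (
    NO_ACTION,
    StriatalNetwork,
    action_probabilities,
    apply_efference,
    canonical_postselection,
    feedforward_activity,
    select_action,
    shared_control_probabilities,
)

__all__ = [
    "TaskSpec",
    "LearningCurve",
    "run_trial",
    "run_gonogo_experiment",
    "run_action_selection_experiment",
    "run_shared_control_experiment",
]

PROTOCOLS = ("reward_correct", "punish_incorrect", "both")
POSTSELECTION_MODELS = ("canonical", "efference", "none")


@dataclass
class TaskSpec:
    """Task structure: states, actions, correct mapping and reward protocol.

    ``protocol`` decides feedback: ``reward_correct`` gives +1 for the
    correct action and 0 otherwise, ``punish_incorrect`` gives −1 for any
    incorrect outcome and 0 for the correct one, ``both`` gives +1/−1.
    In the go/no-go task (n_actions = 1) "incorrect" means withholding the
    go action.
    """

    n_states: int
    n_actions: int
    correct_action: dict
    protocol: str = "reward_correct"
    reward_magnitude: float = 1.0
    punish_magnitude: float = -1.0

    def __post_init__(self) -> None:
        if self.protocol not in PROTOCOLS:
            raise ValueError(f"unknown protocol {self.protocol!r}")
        for s in range(self.n_states):
            if s not in self.correct_action:
                raise ValueError(f"correct_action undefined for state {s}")

    def reward(self, state: int, action) -> float:
        correct = action == self.correct_action[state]
        if correct:
            return self.reward_magnitude if self.protocol in ("reward_correct", "both") else 0.0
        return self.punish_magnitude if self.protocol in ("punish_incorrect", "both") else 0.0

    @classmethod
    def gonogo(cls, protocol: str = "reward_correct") -> "TaskSpec":
        return cls(n_states=1, n_actions=1, correct_action={0: 0}, protocol=protocol)

    @classmethod
    def action_selection(cls, n: int = 2, protocol: str = "reward_correct") -> "TaskSpec":
        return cls(
            n_states=n,
            n_actions=n,
            correct_action={s: s for s in range(n)},
            protocol=protocol,
        )


@dataclass
class LearningCurve:
    """Per-trial records of one or more runs, with a running p(correct)."""

    records: pd.DataFrame
    window: int = 50

    def final_p_correct(self, last: int = 50) -> float:
        """Mean fraction of correct trials over the last `last` trials,
        averaged across seeds."""
        per_seed = (
            self.records.groupby("seed")
            .apply(lambda df: df.sort_values("trial").tail(last)["correct"].mean(),
                   include_groups=False)
        )
        return float(per_seed.mean())


def run_trial(
    net: StriatalNetwork,
    critic: CriticState,
    rule: PlasticityRuleSpec,
    task: TaskSpec,
    postselection_model: str,
    critic_kind: str,
    rng: np.random.Generator,
    tutor=None,
    state: int | None = None,
) -> dict:
    """Run a single trial and apply learning in place.

    ``tutor``, if given, is a dict with keys ``bias`` (length-A logit bias
    vector per state, or callable state → vector) and ``striatal_weight``;
    selection then uses the shared-control policy.  ``critic_kind`` is
    ``"td"`` or ``"q"``.  Returns a record dict.
    """
    if postselection_model not in POSTSELECTION_MODELS:
        raise ValueError(f"unknown postselection model {postselection_model!r}")
    if state is None:
        state = int(rng.integers(task.n_states))
    x = np.zeros(net.n_inputs)
    x[state] = 1.0

    activity = feedforward_activity(net, x)
    if tutor is not None:
        bias = tutor["bias"](state) if callable(tutor["bias"]) else tutor["bias"]
        probs = shared_control_probabilities(
            activity, bias, tutor["striatal_weight"], net.beta, net.c_nogo
        )
    else:
        probs = action_probabilities(activity, net.beta, net.c_nogo)
    action = select_action(probs, rng)
    reward = task.reward(state, action)

    # δ from the pre-update critic / network
    if critic_kind == "td":
        delta = td_error_and_update(critic, state, reward)
    elif critic_kind == "q":
        # Q(s, a) is the feedforward striatal logit of the executed action;
        # no-action outcomes carry no action value (ℓ = 0)
        logit = float(activity.logits[action]) if action is not NO_ACTION else 0.0
        delta = q_error(logit, reward)
    else:
        raise ValueError(f"unknown critic kind {critic_kind!r}")

    # post-selection activity used for plasticity only
    if postselection_model == "canonical":
        post = canonical_postselection(net.n_actions, action)
    elif postselection_model == "efference":
        # plasticity in the efference model is action-triggered: a no-action
        # outcome produces no efferent input and no weight update (the
        # critic above still updates)
        post = apply_efference(net, x, action) if action is not NO_ACTION else None
    else:
        post = activity

    if post is not None:
        net.W_d += weight_update(rule, "direct", delta, post.y_d, x)
        net.W_i += weight_update(rule, "indirect", delta, post.y_i, x)

    return {
        "state": state,
        "action": -1 if action is NO_ACTION else action,
        "reward": reward,
        "delta": delta,
        "correct": action == task.correct_action[state],
    }


def _run_learning(
    task: TaskSpec,
    rule_kind: str,
    postselection_model: str,
    n_trials: int,
    n_seeds: int,
    seed: int,
    beta: float = 10.0,
    c_nogo: float = 0.0,
    c_efference: float = 1.5,
    alpha: float = 0.05,
    alpha_v: float = 0.05,
    window: int = 50,
) -> LearningCurve:
    rows = []
    for k in range(n_seeds):
        rng = np.random.default_rng(np.random.SeedSequence([seed, k]))
        net = StriatalNetwork(
            n_actions=task.n_actions,
            n_inputs=task.n_states,
            beta=beta,
            c_nogo=c_nogo,
            c_efference=c_efference,
        )
        critic = CriticState(alpha_v=alpha_v)
        rule = PlasticityRuleSpec(kind=rule_kind, alpha=alpha)
        for t in range(n_trials):
            rec = run_trial(
                net, critic, rule, task, postselection_model, "td", rng
            )
            rec.update(seed=k, trial=t)
            rows.append(rec)
    df = pd.DataFrame(rows)
    df["p_correct_window"] = (
        df.groupby("seed")["correct"]
        .transform(lambda s: s.rolling(window, min_periods=1).mean())
    )
    return LearningCurve(records=df, window=window)


def run_gonogo_experiment(
    rule_kind: str = "linear",
    postselection_model: str = "efference",
    protocol: str = "reward_correct",
    n_trials: int = 500,
    n_seeds: int = 20,
    seed: int = 0,
    **kwargs,
) -> LearningCurve:
    """Go/no-go learning: single cue, single go action, c_nogo = 1."""
    task = TaskSpec.gonogo(protocol)
    return _run_learning(
        task, rule_kind, postselection_model, n_trials, n_seeds, seed,
        c_nogo=1.0, **kwargs,
    )


def run_action_selection_experiment(
    rule_kind: str = "linear",
    postselection_model: str = "efference",
    protocol: str = "reward_correct",
    n_states: int = 2,
    n_trials: int = 500,
    n_seeds: int = 20,
    seed: int = 0,
    **kwargs,
) -> LearningCurve:
    """Multi-state action selection: one correct action per state."""
    task = TaskSpec.action_selection(n_states, protocol)
    return _run_learning(
        task, rule_kind, postselection_model, n_trials, n_seeds, seed,
        c_nogo=0.0, **kwargs,
    )


def striatal_alone_p_correct(net: StriatalNetwork, task: TaskSpec) -> float:
    """Probability of the correct action under the striatal policy alone
    (tutor disabled), averaged over states; computed analytically."""
    p = 0.0
    for s in range(task.n_states):
        x = np.zeros(net.n_inputs)
        x[s] = 1.0
        probs = action_probabilities(feedforward_activity(net, x), net.beta, net.c_nogo)
        p += probs[task.correct_action[s]]
    return float(p / task.n_states)


def run_shared_control_experiment(
    striatal_weight: float = 0.1,
    efference_mode: str = "off_policy",
    critic_kind: str = "q",
    tutor_bias: float = 1.0,
    n_states: int = 10,
    n_trials: int = 500,
    n_seeds: int = 20,
    seed: int = 0,
    alpha: float = 0.01,
    alpha_v: float = 0.25,
    beta: float = 10.0,
    c_efference: float = 1.5,
    eval_interval: int = 25,
    rule_kind: str = "rectified",
) -> pd.DataFrame:
    """Shared-control (tutoring) learning, Fig.-7B/D style.

    A tutor pathway adds a logit bias ``tutor_bias`` on the correct action;
    the striatal contribution to the combined logit is scaled by
    ``striatal_weight``.  ``efference_mode`` decides which action receives
    efferent excitation: ``off_policy`` — the executed action;
    ``on_policy`` — the action most favored by the striatum (argmax ℓ,
    ties to lowest index).  The striatum's own performance is measured every
    ``eval_interval`` trials with the tutor disabled.

    Returns a tidy DataFrame with columns seed, trial, p_correct_alone.
    """
    if efference_mode not in ("off_policy", "on_policy"):
        raise ValueError(f"unknown efference mode {efference_mode!r}")
    task = TaskSpec.action_selection(n_states, "reward_correct")
    rows = []
    for k in range(n_seeds):
        rng = np.random.default_rng(np.random.SeedSequence([seed, k]))
        net = StriatalNetwork(
            n_actions=n_states, n_inputs=n_states, beta=beta,
            c_nogo=0.0, c_efference=c_efference,
        )
        critic = CriticState(alpha_v=alpha_v)
        rule = PlasticityRuleSpec(kind=rule_kind, alpha=alpha)
        for t in range(n_trials):
            state = int(rng.integers(n_states))
            x = np.zeros(n_states)
            x[state] = 1.0
            activity = feedforward_activity(net, x)
            bias = np.zeros(n_states)
            bias[task.correct_action[state]] = tutor_bias
            probs = shared_control_probabilities(
                activity, bias, striatal_weight, beta, 0.0
            )
            action = select_action(probs, rng)
            reward = task.reward(state, action)

            if critic_kind == "td":
                delta = td_error_and_update(critic, state, reward)
            elif critic_kind == "q":
                logit = float(activity.logits[action]) if action is not NO_ACTION else 0.0
                delta = q_error(logit, reward)
            else:
                raise ValueError(f"unknown critic kind {critic_kind!r}")

            if efference_mode == "off_policy":
                target = action
            else:
                logits = activity.logits
                target = int(np.flatnonzero(logits == logits.max())[0])
            post = apply_efference(net, x, target) if target is not NO_ACTION else activity
            net.W_d += weight_update(rule, "direct", delta, post.y_d, x)
            net.W_i += weight_update(rule, "indirect", delta, post.y_i, x)

            if (t + 1) % eval_interval == 0 or t == n_trials - 1:
                rows.append({
                    "seed": k,
                    "trial": t + 1,
                    "p_correct_alone": striatal_alone_p_correct(net, task),
                })
    return pd.DataFrame(rows)
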