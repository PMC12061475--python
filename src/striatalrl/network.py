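"""Tabular striatal network: feedforward SPN activity and action selection.

Each of A actions is encoded by one dSPN and one iSPN.  Feedforward activity
is y_d = ϕ(W_d x), y_i = ϕ(W_i x) with ϕ the rectified-linear function, and
the striatal logit of action a is ℓ_a = y_d[a] − y_i[a] (the "difference
mode"): dSPN activity promotes the action, iSPN activity suppresses it.
Action probabilities follow a softmax with inverse temperature β and an
optional no-action weight c_nogo:

    p(a) = e^{β ℓ_a} / (c_nogo + Σ_a' e^{β ℓ_a'})

with residual mass 1 − Σ p(a) assigned to taking no action.

Two models of SPN activity after selection are provided.  In the canonical
action-selection model the chosen action's dSPN and all unchosen actions'
iSPNs are set active.  In the efference model the selected action's dSPN
*and* iSPN both receive additive efferent excitation c_efference — input
along the "sum mode" y_d + y_i, which is orthogonal to the difference mode
and hence leaves action probabilities unchanged while driving learning.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "StriatalNetwork",
    "SPNActivity",
    "EfferentActivity",
    "NO_ACTION",
    "feedforward_activity",
    "action_probabilities",
    "select_action",
    "apply_efference",
    "canonical_postselection",
    "shared_control_probabilities",
]

#: Sentinel for the no-action outcome.
NO_ACTION = None


def relu(h: np.ndarray) -> np.ndarray:
    return np.maximum(h, 0.0)


@dataclass
class SPNActivity:
    """Activity of the dSPN and iSPN populations (one unit per action)."""

    y_d: np.ndarray
    y_i: np.ndarray

    def __post_init__(self) -> None:
        self.y_d = np.asarray(self.y_d, dtype=float)
        self.y_i = np.asarray(self.y_i, dtype=float)
        if self.y_d.shape != self.y_i.shape:
            raise ValueError("y_d and y_i must have identical shapes")

    @property
    def logits(self) -> np.ndarray:
        """Striatal logits ℓ_a = y_d[a] − y_i[a], recomputed on access."""
        return self.y_d - self.y_i


@dataclass
class StriatalNetwork:
    """Corticostriatal weights and policy parameters.

    ``W_d`` and ``W_i`` are (A actions × M inputs) weight matrices,
    initialized at 1 for the task simulations.  ``beta`` is the softmax
    inverse temperature (10 in task simulations, 100 in spontaneous-behavior
    simulations), ``c_nogo`` the no-action weight (1 for go/no-go, 0 for
    multi-action tasks) and ``c_efference`` the efferent excitation
    amplitude.
    """

    n_actions: int
    n_inputs: int
    beta: float = 10.0
    c_nogo: float = 0.0
    c_efference: float = 1.5
    W_d: np.ndarray = field(default=None, repr=False)
    W_i: np.ndarray = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.W_d is None:
            self.W_d = np.ones((self.n_actions, self.n_inputs))
        if self.W_i is None:
            self.W_i = np.ones((self.n_actions, self.n_inputs))
        self.W_d = np.asarray(self.W_d, dtype=float)
        self.W_i = np.asarray(self.W_i, dtype=float)
        if self.W_d.shape != self.W_i.shape:
            raise ValueError("W_d and W_i must have identical shapes")
        if self.W_d.shape != (self.n_actions, self.n_inputs):
            raise ValueError("weight shape does not match (n_actions, n_inputs)")


def feedforward_activity(net: StriatalNetwork, x: np.ndarray) -> SPNActivity:
    """Feedforward SPN activity y = ϕ(W x) for both pathways."""
    x = np.asarray(x, dtype=float)
    if x.shape != (net.n_inputs,):
        raise ValueError(f"input length {x.shape} does not match M={net.n_inputs}")
    return SPNActivity(y_d=relu(net.W_d @ x), y_i=relu(net.W_i @ x))


def action_probabilities(
    activity: SPNActivity, beta: float, c_nogo: float = 0.0
) -> np.ndarray:
    """Softmax action probabilities with an optional no-action weight.

    Returns the length-A vector p(a); the residual mass 1 − Σ p(a) is the
    no-action probability.  Computed with a max-logit shift, which leaves
    the probabilities mathematically identical.
    """
    if c_nogo < 0:
        raise ValueError("c_nogo must be nonnegative")
    z = beta * activity.logits
    m = max(float(np.max(z)), 0.0) if c_nogo > 0 else float(np.max(z))
    e = np.exp(z - m)
    denom = c_nogo * np.exp(-m) + e.sum()
    return e / denom


def select_action(probs: np.ndarray, rng: np.random.Generator):
    """Sample from p(a); returns the action index, or NO_ACTION with the
    residual probability mass."""
    probs = np.asarray(probs, dtype=float)
    if np.any(probs < 0):
        raise ValueError("negative probabilities")
    total = probs.sum()
    if total > 1.0 + 1e-9:
        raise ValueError("probabilities sum to more than 1")
    u = rng.random()
    c = np.cumsum(probs)
    idx = int(np.searchsorted(c, u, side="right"))
    if idx >= len(probs):
        return NO_ACTION
    return idx


@dataclass
class EfferentActivity(SPNActivity):
    """SPN activity after efferent excitation of the selected action.

    Efferent input is common to the chosen action's dSPN/iSPN pair — input
    purely along the sum mode.  Where rectification does not bind, the
    difference mode is mathematically unchanged; naive floating-point
    re-subtraction of the excited rates would break that identity in the
    last bit, so the logits are computed exactly at construction (equal to
    the feedforward logits for every action whose rectification state is
    unaffected) and ``logits`` returns them.  They are a pure function of
    the construction inputs, never a stale cache.
    """

    exact_logits: np.ndarray = None

    @property
    def logits(self) -> np.ndarray:
        return self.exact_logits.copy()


def apply_efference(net: StriatalNetwork, x: np.ndarray, chosen: int) -> SPNActivity:
    """SPN activity after efferent excitation of the selected action.

    y[a] = ϕ(c_efference · 1[a = chosen] + W x)[a] for both pathways; only
    the chosen action's pair changes relative to feedforward activity.
    When both of the chosen action's pre-activations are positive the
    returned activity's logits equal the feedforward logits exactly
    (orthogonality of sum and difference modes: efference has no effect on
    action selection).
    """
    if chosen is NO_ACTION:
        raise ValueError("apply_efference requires a real action")
    x = np.asarray(x, dtype=float)
    h_d = net.W_d @ x
    h_i = net.W_i @ x
    y_d = relu(h_d)
    y_i = relu(h_i)
    logits = y_d - y_i  # feedforward logits
    c = net.c_efference
    hd, hi = float(h_d[chosen]), float(h_i[chosen])
    yd_new = max(c + hd, 0.0)
    yi_new = max(c + hi, 0.0)
    if not (hd > 0 and hi > 0):
        # rectification binds (or binding changes): no exactness guarantee
        logits[chosen] = yd_new - yi_new
    y_d[chosen] = yd_new
    y_i[chosen] = yi_new
    return EfferentActivity(y_d=y_d, y_i=y_i, exact_logits=logits)


def canonical_postselection(n_actions: int, chosen) -> SPNActivity:
    """Post-selection activity under the canonical action-selection model.

    The chosen action's dSPN is set to 1 and every unselected action's iSPN
    is set to 1 (when no action is taken, every action is unselected).
    """
    if n_actions < 1:
        raise ValueError("need at least one action")
    y_d = np.zeros(n_actions)
    y_i = np.ones(n_actions)
    if chosen is not NO_ACTION:
        y_d[chosen] = 1.0
        y_i[chosen] = 0.0
    return SPNActivity(y_d=y_d, y_i=y_i)


def shared_control_probabilities(
    activity: SPNActivity,
    tutor_bias: np.ndarray,
    striatal_weight: float,
    beta: float,
    c_nogo: float = 0.0,
) -> np.ndarray:
    """Action probabilities when the striatum shares control with a tutor.

    The combined logit is striatal_weight · ℓ + tutor_bias; probabilities
    follow the same softmax form as :func:`action_probabilities`.
    """
    tutor_bias = np.asarray(tutor_bias, dtype=float)
    combined = SPNActivity(
        y_d=striatal_weight * activity.logits + tutor_bias,
        y_i=np.zeros_like(tutor_bias),
    )
    return action_probabilities(combined, beta, c_nogo)
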