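"""Dopamine-dependent plasticity rules and the critics that produce δ.

Corticostriatal plasticity is modeled as a three-factor rule: the change of
the weight from cortical unit j onto the SPN encoding action a is

    ΔW[a, j] = α · f_pathway(δ) · y[a] · x[j]

where δ is a global scalar dopamine signal (reward prediction error), y is
postsynaptic SPN activity and x presynaptic cortical activity.  The
dopamine-dependence f differs between the direct (D1) and indirect (D2)
pathways: f_dSPN increases with δ while f_iSPN decreases, reflecting the
opposite dopamine sensitivity of the two SPN classes.  Several functional
forms are provided (linear, rectified, offset sigmoid) together with a
control rule in which iSPNs share the dSPN dependence.

δ itself comes from a critic: either a TD critic maintaining state values
V(s) (δ = r − V(s)), or an off-policy Q-learning error in which the value of
the executed action is read directly out of the striatal logit
(δ = r − ℓ_a, no stored Q-table).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PlasticityRuleSpec",
    "CriticState",
    "dopamine_factor",
    "weight_update",
    "td_error_and_update",
    "q_error",
    "RULE_KINDS",
]

RULE_KINDS = ("linear", "rectified", "offset_sigmoid", "same_sign_indirect")

_PATHWAYS = ("direct", "indirect")


@dataclass
class PlasticityRuleSpec:
    """Specification of the dopamine dependence f(δ) and learning rate α.

    Parameters
    ----------
    kind:
        One of ``linear`` (f_dSPN = δ, f_iSPN = −δ), ``rectified``
        (f_dSPN = max(δ,0), f_iSPN = max(−δ,0)), ``offset_sigmoid``
        (saturating sigmoids of ±δ with offset), or ``same_sign_indirect``
        (control rule: iSPNs use the dSPN linear factor).
    sigmoid_a, sigmoid_b, sigmoid_c, sigmoid_d:
        Parameters of the offset sigmoid,
        f(δ) = ½ (a + b / (1 + c e^{1 ∓ dδ})).
    alpha:
        Learning rate α; 0.05 in the basic learning simulations, 0.01 in
        shared-control (tutoring) experiments.
    """

    kind: str = "linear"
    sigmoid_a: float = -3.5
    sigmoid_b: float = 11.5
    sigmoid_c: float = 0.9
    sigmoid_d: float = 1.0
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.kind not in RULE_KINDS:
            raise ValueError(
                f"unknown plasticity rule kind {self.kind!r}; "
                f"expected one of {RULE_KINDS}"
            )


@dataclass
class CriticState:
    """TD critic state: V(s) per state, lazily created at 0."""

    alpha_v: float = 0.05
    values: dict = field(default_factory=dict)

    def value(self, state) -> float:
        return self.values.get(state, 0.0)


def dopamine_factor(rule: PlasticityRuleSpec, pathway: str, delta: float) -> float:
    """Evaluate f_pathway(δ) for the given rule.

    ``pathway`` is ``"direct"`` (dSPN) or ``"indirect"`` (iSPN).  For the
    ``same_sign_indirect`` control both pathways use the linear dSPN factor.
    """
    if pathway not in _PATHWAYS:
        raise ValueError(f"unknown pathway {pathway!r}")
    kind = rule.kind
    if kind == "same_sign_indirect":
        return float(delta)
    # sign convention: the indirect pathway sees −δ
    s = 1.0 if pathway == "direct" else -1.0
    if kind == "linear":
        return s * float(delta)
    if kind == "rectified":
        return max(s * float(delta), 0.0)
    if kind == "offset_sigmoid":
        a, b, c, d = rule.sigmoid_a, rule.sigmoid_b, rule.sigmoid_c, rule.sigmoid_d
        return 0.5 * (a + b / (1.0 + c * np.exp(1.0 - s * d * float(delta))))
    raise ValueError(f"unknown plasticity rule kind {kind!r}")


def weight_update(
    rule: PlasticityRuleSpec,
    pathway: str,
    delta: float,
    y: np.ndarray,
    x: np.ndarray,
) -> np.ndarray:
    """Three-factor weight increment ΔW = α f_pathway(δ) · y xᵀ.

    Returns the (len(y), len(x)) outer-product increment; the caller adds it
    to the weight matrix.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    if y.ndim != 1 or x.ndim != 1:
        raise ValueError("y and x must be 1-D vectors")
    if not (np.all(np.isfinite(y)) and np.all(np.isfinite(x))):
        raise ValueError("y and x must be finite")
    f = dopamine_factor(rule, pathway, delta)
    return rule.alpha * f * np.outer(y, x)


def td_error_and_update(critic: CriticState, state, reward: float) -> float:
    """TD error δ = r − V(s); V(s) ← V(s) + α_V δ.  Returns the pre-update δ."""
    delta = float(reward) - critic.value(state)
    if delta != 0.0 or state in critic.values:
        critic.values[state] = critic.value(state) + critic.alpha_v * delta
    return delta


def q_error(chosen_logit: float, reward: float) -> float:
    """Off-policy Q-learning error δ = r − Q(s, a), with Q(s, a) = ℓ_a.

    The action value is read out of the striatal feedforward logit of the
    executed action each trial; no table is stored.
    """
    return float(reward) - float(chosen_logit)
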