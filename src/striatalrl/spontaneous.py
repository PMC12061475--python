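"""Spontaneous-behavior simulations of the efference model.

These simulations generate the predictions tested against recordings of
freely behaving mice: A = 50 actions, each encoded by a dSPN/iSPN pair,
feedforward activity drawn from stationary Gaussian processes with an
exponential kernel (time constant 10 steps), softmax action selection with
β = 100 every 10 timesteps (with a no-action option calibrated to be chosen
50% of the time), and efferent excitation of amplitude c_efference = 1.5
added to the chosen action's dSPN and iSPN, decaying exponentially with a
10-step time constant.  No plasticity operates: there are no rewards or
task structure.

Because β = 100 multiplies O(1) logits, Σ e^{βℓ} overflows float64; the
no-action weight is therefore held and calibrated in log space
(``log_c_nogo``) and the policy is evaluated by log-sum-exp — numerically
different from, but mathematically identical to, the plain softmax.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

__all__ = [
    "SpontaneousConfig",
    "SimSession",
    "sample_gp_activity",
    "calibrate_nogo_offset",
    "run_spontaneous_session",
]


@dataclass
class SpontaneousConfig:
    """Parameters of the spontaneous-behavior simulation (times in steps)."""

    n_actions: int = 50
    beta: float = 100.0
    c_efference: float = 1.5
    gp_tau: float = 10.0
    efference_tau: float = 10.0
    action_interval: int = 10
    n_steps: int = 50_000
    target_noaction_frac: float = 0.5
    log_c_nogo: float | None = None   # calibrated; -inf disables no-action


@dataclass
class SimSession:
    """A simulated session: per-pathway activity and the selection events."""

    dspn_activity: np.ndarray     # (time, A), rectified total activity
    ispn_activity: np.ndarray     # (time, A)
    action_labels: np.ndarray     # per selection event: action id or -1 (none)
    onsets: np.ndarray            # onset step of each selection event
    config: SpontaneousConfig


def sample_gp_activity(
    n_actions: int, n_steps: int, gp_tau: float, rng: np.random.Generator
) -> np.ndarray:
    """Feedforward traces, shape (n_steps, n_actions).

    Each neuron's trace is a stationary zero-mean unit-variance Gaussian
    process with kernel e^{−|Δt|/gp_tau}; on a regular grid this is an AR(1)
    process, sampled exactly.  Traces are independent across neurons.
    """
    from scipy.signal import lfilter

    if n_steps < 2:
        raise ValueError("need at least 2 steps")
    rho = np.exp(-1.0 / gp_tau)
    drive = np.empty((n_steps, n_actions))
    drive[0] = rng.normal(0.0, 1.0, n_actions)            # stationary start
    drive[1:] = rng.normal(0.0, np.sqrt(1.0 - rho * rho),
                           (n_steps - 1, n_actions))
    return lfilter([1.0], [1.0, -rho], drive, axis=0)


def _select_actions(logits: np.ndarray, log_c_nogo: float,
                    beta: float, rng: np.random.Generator) -> int:
    """Sample Eq.-10-style policy in log space; returns action id or -1."""
    z = beta * logits
    lse = logsumexp(np.append(z, log_c_nogo))
    p = np.exp(z - lse)
    u = rng.random()
    c = np.cumsum(p)
    idx = int(np.searchsorted(c, u, side="right"))
    return idx if idx < len(logits) else -1


def _noaction_frequency(config: SpontaneousConfig, log_c: float,
                        rng: np.random.Generator, n_events: int = 2000) -> float:
    """Fraction of selection events choosing no action, measured by running
    a short session with the given offset (including efference, whose
    rectified transients slightly shape the logits)."""
    from dataclasses import replace

    short = replace(config, n_steps=(n_events + 1) * config.action_interval,
                    log_c_nogo=log_c)
    sess = run_spontaneous_session(short, rng)
    return float(np.mean(sess.action_labels < 0))


def calibrate_nogo_offset(
    config: SpontaneousConfig, rng: np.random.Generator,
    tol: float = 0.01, max_iter: int = 30,
) -> float:
    """Bisect log c_nogo until the no-action frequency matches the target.

    Returns the calibrated log c_nogo.  The simulated frequency is a
    monotone function of log c_nogo: −inf gives 0, +inf gives 1.
    """
    target = config.target_noaction_frac
    if not 0.0 < target < 1.0:
        raise ValueError("target no-action fraction must be in (0, 1)")
    lo, hi = -500.0, 1500.0
    f_lo = _noaction_frequency(config, lo, rng)
    f_hi = _noaction_frequency(config, hi, rng)
    if not (f_lo < target < f_hi):
        raise ValueError("bisection interval does not bracket the target")
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        f = _noaction_frequency(config, mid, rng)
        if abs(f - target) <= tol:
            return mid
        if f < target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def run_spontaneous_session(
    config: SpontaneousConfig, rng: np.random.Generator
) -> SimSession:
    """Simulate a spontaneous session.

    Every ``action_interval`` steps an action (or no action) is sampled from
    the softmax policy applied to the previous timestep's activity.  Upon
    selection, efferent input of amplitude c_efference, decaying as
    e^{−t/efference_tau}, is added to the chosen action's dSPN and iSPN.
    Overlapping transients sum linearly.  Total activity is
    ϕ(feedforward + efference).
    """
    if config.log_c_nogo is None:
        raise ValueError("log_c_nogo must be calibrated (or set) first")
    A, T = config.n_actions, config.n_steps
    ff_d = sample_gp_activity(A, T, config.gp_tau, rng)
    ff_i = sample_gp_activity(A, T, config.gp_tau, rng)
    eff = np.zeros(A)  # current efference level per action (both pathways)
    decay = np.exp(-1.0 / config.efference_tau)
    act_d = np.empty((T, A))
    act_i = np.empty((T, A))
    labels, onsets = [], []
    for t in range(T):
        if t > 0:
            eff *= decay
        if t > 0 and t % config.action_interval == 0:
            logits = act_d[t - 1] - act_i[t - 1]
            a = _select_actions(logits, config.log_c_nogo, config.beta, rng)
            labels.append(a)
            onsets.append(t)
            if a >= 0:
                eff[a] += config.c_efference
        act_d[t] = np.maximum(ff_d[t] + eff, 0.0)
        act_i[t] = np.maximum(ff_i[t] + eff, 0.0)
    return SimSession(
        dspn_activity=act_d,
        ispn_activity=act_i,
        action_labels=np.array(labels, dtype=int),
        onsets=np.array(onsets, dtype=int),
        config=config,
    )
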