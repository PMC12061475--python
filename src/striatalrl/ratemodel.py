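"""Continuous-time firing-rate model of the two-alternative forced choice task.

Four SPNs are simulated (a dSPN/iSPN pair per action).  The rate of SPN i
follows leaky dynamics with rectification,

    τ dy_i/dt = −y_i + [ Σ_j w_ij x_j + η_i(t) + e_i(t) + b ]_+

with Ornstein–Uhlenbeck noise η (time constant 600 ms, stationary variance
1/60 Hz²), efferent input e, and bias b = 5 Hz.  Each trial presents one of
two one-hot stimuli for 2 s; the action is chosen as the argmax of the two
per-action difference modes (y_dSPN − y_iSPN) averaged over the first 1 s.
During the second 1 s the chosen action's dSPN and iSPN receive efferent
input of 7.5 Hz, and the corticostriatal weights learn online,

    dw_ij/dt = η_lr f_i(δ) (y_i(t) − b) x_j(t)

with f_i(δ) = +1 for dSPNs after a correct choice and for iSPNs after an
incorrect choice, −1 otherwise.

The membrane time constant τ is not part of the published parameter set;
it defaults to 100 ms and is exposed in the configuration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "RateModelParams",
    "RateTrace",
    "simulate_ou",
    "run_rate_trial",
    "run_rate_experiment",
    "project_sum_diff_modes",
]

# neuron layout: [dSPN-1, iSPN-1, dSPN-2, iSPN-2]
DSPN = np.array([0, 2])
ISPN = np.array([1, 3])


@dataclass
class RateModelParams:
    """Parameters of the firing-rate 2AFC simulation (times in ms, rates in Hz)."""

    tau_rate: float = 100.0       # membrane time constant (unpublished; default)
    dt: float = 20.0
    bias: float = 5.0
    ou_tau: float = 600.0
    ou_var: float = 1.0 / 60.0
    efference_rate: float = 7.5
    eta: float = 5e-4             # learning rate, per ms
    weight_init_sd: float = 1.0
    stim_duration: float = 2000.0
    decision_window: float = 1000.0
    consec_correct_criterion: int = 10

    def __post_init__(self) -> None:
        if self.dt <= 0 or self.dt > self.ou_tau:
            raise ValueError("require 0 < dt <= ou_tau")

    @property
    def n_steps(self) -> int:
        return int(round(self.stim_duration / self.dt))

    @property
    def n_decision(self) -> int:
        return int(round(self.decision_window / self.dt))


@dataclass
class RateTrace:
    """One trial's rate trajectories and outcome."""

    rates: np.ndarray          # (time, 4), Hz
    stimulus: int
    chosen: int
    correct: bool

    @property
    def diff_modes(self) -> np.ndarray:
        """(time, 2) difference mode y_dSPN − y_iSPN per action."""
        return self.rates[:, DSPN] - self.rates[:, ISPN]

    @property
    def sum_modes(self) -> np.ndarray:
        """(time, 2) sum mode y_dSPN + y_iSPN per action."""
        return self.rates[:, DSPN] + self.rates[:, ISPN]


def simulate_ou(
    tau: float, variance: float, dt: float, n_steps: int,
    rng: np.random.Generator, size: int = 1,
) -> np.ndarray:
    """Stationary Ornstein–Uhlenbeck samples, shape (n_steps, size).

    Uses the exact discretization x_{t+1} = ρ x_t + √(σ²(1−ρ²)) ξ with
    ρ = e^{−dt/τ}, so the stationary variance equals ``variance`` for any
    dt, and starts from the stationary distribution.
    """
    if tau <= 0 or variance <= 0 or dt <= 0:
        raise ValueError("tau, variance, dt must be positive")
    from scipy.signal import lfilter

    rho = np.exp(-dt / tau)
    innov_sd = np.sqrt(variance * (1.0 - rho * rho))
    drive = np.empty((n_steps, size))
    drive[0] = rng.normal(0.0, np.sqrt(variance), size)   # stationary start
    drive[1:] = rng.normal(0.0, innov_sd, (n_steps - 1, size))
    # x[t] = rho x[t-1] + drive[t] — AR(1) recursion
    return lfilter([1.0], [1.0, -rho], drive, axis=0)


def run_rate_trial(
    params: RateModelParams,
    weights: np.ndarray,
    stimulus: int,
    rng: np.random.Generator,
) -> tuple[RateTrace, np.ndarray]:
    """Simulate one 2-s trial by Euler integration and apply online learning.

    ``weights`` is the 4 × 2 (neurons × stimuli) corticostriatal matrix;
    a copy with the learned increments is returned alongside the trace.
    The correct action equals the stimulus index.
    """
    weights = np.asarray(weights, dtype=float).copy()
    if weights.shape != (4, 2):
        raise ValueError("weights must be 4 x 2 (neurons x stimuli)")
    n = params.n_steps
    nd = params.n_decision
    x = np.zeros(2)
    x[stimulus] = 1.0

    noise = simulate_ou(params.ou_tau, params.ou_var, params.dt, n, rng, size=4)
    rates = np.empty((n, 4))
    y = np.full(4, params.bias)  # start at the no-input fixed point
    e = np.zeros(4)
    chosen = -1
    a = params.dt / params.tau_rate
    eta_dt = params.eta * params.dt

    for t in range(n):
        drive = weights @ x + noise[t] + e + params.bias
        y = y + a * (-y + np.maximum(drive, 0.0))
        rates[t] = y
        if t == nd - 1:
            # decision: argmax of decision-window-averaged difference modes
            diffs = rates[:nd, DSPN] - rates[:nd, ISPN]
            mean_diff = diffs.mean(axis=0)
            chosen = int(np.flatnonzero(mean_diff == mean_diff.max())[0])
            e = np.zeros(4)
            e[[2 * chosen, 2 * chosen + 1]] = params.efference_rate
            correct = chosen == stimulus
            # f_i(δ): +1 for dSPNs after correct / iSPNs after incorrect
            f = np.where(
                np.isin(np.arange(4), DSPN),
                1.0 if correct else -1.0,
                -1.0 if correct else 1.0,
            )
        if t >= nd:
            # plasticity during the efference window
            weights += eta_dt * f[:, None] * np.outer(y - params.bias, x)

    trace = RateTrace(rates=rates, stimulus=stimulus, chosen=chosen,
                      correct=chosen == stimulus)
    return trace, weights


def run_rate_experiment(
    params: RateModelParams | None = None,
    n_trials: int = 60,
    seed: int = 0,
    keep_traces: bool = True,
) -> dict:
    """Run a learning session of the 2AFC task.

    Returns a dict with ``trials_to_criterion`` (1-based index of the trial
    completing the first run of ``consec_correct_criterion`` consecutive
    correct trials, or None if censored), the per-trial correctness vector,
    the final weights and (optionally) all traces.
    """
    params = params or RateModelParams()
    rng = np.random.default_rng(seed)
    weights = rng.normal(0.0, params.weight_init_sd, (4, 2))
    traces = []
    correct = np.zeros(n_trials, dtype=bool)
    streak = 0
    criterion_trial = None
    for t in range(n_trials):
        stimulus = int(rng.integers(2))
        trace, weights = run_rate_trial(params, weights, stimulus, rng)
        correct[t] = trace.correct
        if keep_traces:
            traces.append(trace)
        streak = streak + 1 if trace.correct else 0
        if criterion_trial is None and streak >= params.consec_correct_criterion:
            criterion_trial = t + 1
    return {
        "trials_to_criterion": criterion_trial,
        "correct": correct,
        "weights": weights,
        "traces": traces,
    }


def project_sum_diff_modes(trace: RateTrace) -> dict:
    """Sum and difference mode time series per action, as exact linear
    combinations of the stored rates."""
    return {"sum": trace.sum_modes, "diff": trace.diff_modes}
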