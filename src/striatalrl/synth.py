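"""Synthetic session generators with known ground truth.

These generators produce data with the statistical structure the analysis
procedures assume — syllable-segmented behavior at 30 Hz, two pathways of
neurons, per-syllable dopamine values — so that every analysis stage can be
tested for recovery of planted structure without any recorded data.

* :func:`generate_markov_syllable_sequence` emulates the output of
  behavioral segmentation: a first-order Markov chain over syllables with
  geometric durations.
* :func:`generate_neural_session` plants, around each syllable's onsets,
  the signatures the efference model predicts — a pre-onset difference-mode
  ramp (dSPN mode up, iSPN mode down) and a post-onset sum-mode transient
  (both up) — on top of white noise, and records every planted quantity.
* :func:`generate_dlight_session` inverts the Q-learning dopamine model:
  transitions are sampled from a softmax of a known Q-table and dopamine is
  max_{s'} Q(s_t, s') − Q(s_{t−1}, s_t) plus noise, z-scored per session.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .analysis import UNLABELED, NeuralSession

__all__ = [
    "GroundTruth",
    "generate_markov_syllable_sequence",
    "generate_neural_session",
    "generate_dlight_session",
    "generate_task_fixtures",
]


@dataclass
class GroundTruth:
    """Planted structure of a generated session, kept for recovery tests."""

    seed: int
    modes_dspn: np.ndarray | None = None     # (S, n_dspn)
    modes_ispn: np.ndarray | None = None     # (S, n_ispn)
    ramp_amplitude: float = 0.0
    transient_amplitude: float = 0.0
    noise_sd: float = 0.0
    transition_matrix: np.ndarray | None = None
    Q: np.ndarray | None = None
    beta: float | None = None

    def to_dict(self) -> dict:
        return {
            k: (v.tolist() if isinstance(v, np.ndarray) else v)
            for k, v in self.__dict__.items()
        }


def generate_markov_syllable_sequence(
    n_syllables: int,
    transition_matrix: np.ndarray,
    n_events: int,
    mean_duration_frames: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """First-order Markov syllable sequence with geometric durations.

    Returns (per-frame labels, onset frames, per-event syllable ids); the
    framing is nominally 30 Hz.
    """
    P = np.asarray(transition_matrix, dtype=float)
    if P.shape != (n_syllables, n_syllables):
        raise ValueError("transition matrix shape mismatch")
    if not np.allclose(P.sum(axis=1), 1.0):
        raise ValueError("transition matrix must be row-stochastic")
    if mean_duration_frames < 1:
        raise ValueError("mean duration must be at least one frame")
    p_end = 1.0 / mean_duration_frames
    states = np.empty(n_events, dtype=int)
    states[0] = rng.integers(n_syllables)
    for k in range(1, n_events):
        states[k] = rng.choice(n_syllables, p=P[states[k - 1]])
    durations = rng.geometric(p_end, n_events)
    onsets = np.concatenate([[0], np.cumsum(durations)[:-1]])
    labels = np.repeat(states, durations)
    return labels, onsets.astype(int), states


def _unit_rows(x: np.ndarray) -> np.ndarray:
    return x / np.linalg.norm(x, axis=1, keepdims=True)


def generate_neural_session(
    n_syllables: int = 10,
    n_neurons_per_pathway: int = 30,
    n_events: int = 400,
    mean_duration_frames: float = 15.0,
    ramp_amplitude: float = 1.0,
    transient_amplitude: float = 1.0,
    noise_sd: float = 0.5,
    ramp_frames: int = 10,
    transient_frames: int = 10,
    null: bool = False,
    seed: int = 0,
    transition_matrix: np.ndarray | None = None,
) -> tuple[NeuralSession, GroundTruth]:
    """Synthetic two-pathway session with planted efference-like structure.

    Around each onset of syllable s: in the ``ramp_frames`` before onset,
    activity ramps up along the dSPN mode of s and down along the iSPN mode
    (difference-mode lead); in the ``transient_frames`` after onset, both
    modes are excited (sum-mode transient, decaying).  ``null=True`` zeroes
    all planted amplitudes, leaving pure noise.  Modes are random
    nonnegative unit vectors.  Returns the session and its ground truth.
    """
    rng = np.random.default_rng(seed)
    S = n_syllables
    if transition_matrix is None:
        # uniform over other syllables (no immediate repeats)
        transition_matrix = (np.ones((S, S)) - np.eye(S)) / (S - 1)
    labels, onsets, states = generate_markov_syllable_sequence(
        S, transition_matrix, n_events, mean_duration_frames, rng
    )
    T = len(labels)
    n = n_neurons_per_pathway
    # signed unit vectors: z-scored activity modes have entries of both signs
    modes_d = _unit_rows(rng.normal(size=(S, n)))
    modes_i = _unit_rows(rng.normal(size=(S, n)))
    amp_r = 0.0 if null else ramp_amplitude
    amp_t = 0.0 if null else transient_amplitude

    act_d = rng.normal(0.0, noise_sd, (T, n))
    act_i = rng.normal(0.0, noise_sd, (T, n))
    # difference mode leads onset: ramps up before, decays back after;
    # sum mode (efference-like transient) rises only after onset
    ramp_up = amp_r * np.linspace(0.0, 1.0, ramp_frames, endpoint=False)
    ramp_down = amp_r * np.exp(-np.arange(ramp_frames) / (ramp_frames / 4.0))
    transient = amp_t * np.exp(-np.arange(transient_frames)
                               / (transient_frames / 2.0))
    for t0, s in zip(onsets, states):
        a = max(t0 - ramp_frames, 0)
        r = ramp_up[ramp_frames - (t0 - a):]
        act_d[a:t0] += np.outer(r, modes_d[s])
        act_i[a:t0] -= np.outer(r, modes_i[s])
        b = min(t0 + transient_frames, T)
        rd = ramp_down[: b - t0]
        tr = transient[: b - t0]
        act_d[t0:b] += np.outer(rd + tr, modes_d[s])
        act_i[t0:b] += np.outer(tr - rd, modes_i[s])

    session = NeuralSession(
        activity=np.hstack([act_d, act_i]),
        pathway=np.array(["dSPN"] * n + ["iSPN"] * n),
        syllables=labels,
        frame_rate=30.0,
        session_id=f"synthetic-{seed}",
    )
    truth = GroundTruth(
        seed=seed,
        modes_dspn=modes_d,
        modes_ispn=modes_i,
        ramp_amplitude=amp_r,
        transient_amplitude=amp_t,
        noise_sd=noise_sd,
        transition_matrix=np.asarray(transition_matrix),
    )
    return session, truth


def generate_dlight_session(
    Q: np.ndarray,
    beta: float = 1.0,
    noise_sd: float = 0.25,
    n_transitions: int = 10_000,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray, GroundTruth]:
    """Syllable sequence + per-syllable dopamine from a known Q-table.

    Transitions are sampled with probability ∝ e^{β Q(s_{t−1}, ·)};
    dopamine at each transition is max_{s'} Q(s_t, s') − Q(s_{t−1}, s_t)
    plus Gaussian noise, then z-scored across the session (matching the
    per-session preprocessing of the recorded dLight data).  Returns
    (sequence, dopamine, ground truth).
    """
    rng = rng if rng is not None else np.random.default_rng(0)
    Q = np.asarray(Q, dtype=float)
    if not np.all(np.isfinite(Q)):
        raise ValueError("Q must be finite")
    S = Q.shape[0]
    Z = beta * Q
    Z = Z - Z.max(axis=1, keepdims=True)
    P = np.exp(Z)
    P /= P.sum(axis=1, keepdims=True)
    seq = np.empty(n_transitions + 1, dtype=int)
    seq[0] = rng.integers(S)
    cum = np.cumsum(P, axis=1)
    u = rng.random(n_transitions)
    for t in range(n_transitions):
        seq[t + 1] = np.searchsorted(cum[seq[t]], u[t], side="right")
    M = Q.max(axis=1)
    dop = np.empty(n_transitions + 1)
    dop[0] = 0.0
    dop[1:] = M[seq[1:]] - Q[seq[:-1], seq[1:]]
    dop += rng.normal(0.0, noise_sd, n_transitions + 1) if noise_sd > 0 else 0.0
    sd = dop.std()
    dop = (dop - dop.mean()) / (sd if sd > 0 else 1.0)  # constant -> zeros
    truth = GroundTruth(seed=-1, Q=Q, beta=beta, noise_sd=noise_sd,
                        transition_matrix=P)
    return seq, dop, truth


def generate_task_fixtures(seed: int = 1234) -> dict:
    """Small deterministic fixtures for the task and rate-model tests.

    Returns a dict of miniature, fixed-seed inputs: a tiny two-action
    network weight pair, a 4 × 2 rate-model weight init, and a short
    deterministic syllable sequence with dopamine values.
    """
    rng = np.random.default_rng(seed)
    W_d = 1.0 + 0.1 * rng.normal(size=(2, 2))
    W_i = 1.0 + 0.1 * rng.normal(size=(2, 2))
    rate_weights = rng.normal(0.0, 1.0, (4, 2))
    seq = np.array([0, 1, 2, 0, 1, 2, 1, 0, 2, 1])
    dop = np.round(rng.normal(size=seq.shape), 3)
    return {
        "W_d": W_d,
        "W_i": W_i,
        "rate_weights": rate_weights,
        "syllable_sequence": seq,
        "dopamine": dop,
        "seed": seed,
    }
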