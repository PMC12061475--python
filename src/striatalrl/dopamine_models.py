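"""Models relating per-syllable dopamine to syllable transition statistics.

From a syllable sequence and per-syllable dopamine values (per-syllable
maxima of the dLight signal, z-scored per session), two S × S tables are
built: D(s_{t−1}, s_t), the mean dopamine during syllable s_t given the
previous syllable, and P(s_{t−1}, s_t), the empirical transition
probabilities.  Four models then predict P from D:

* **q_learning** — dopamine is an off-policy prediction error
  D(s_{t−1}, s_t) = max_{s'} Q(s_t, s') − Q(s_{t−1}, s_t); a Q-table is fit
  by gradient descent on the squared error and transitions are predicted by
  a per-row softmax of Q with β(s_{t−1}) = 1 / std(Q(s_{t−1}, ·)).
* **v_td** — dopamine is a state-value TD error
  D(s_{t−1}, s_t) = V(s_t) − V(s_{t−1}); V is fit by least squares (gauge
  fixed by V[0] = 0) and rows of P̂ are a shared softmax of βV.
* **action_value** — dopamine directly reflects transition probability:
  P̂ = row-normalized D.
* **state_value** — dopamine reflects syllable probability independent of
  the previous syllable: all rows equal the normalized per-syllable mean
  dopamine.

Models are compared by the Pearson correlation between vectorized P̂ and P
over the observed transitions.  Note that z-scored dopamine can be
negative, which breaks the normalization-based models as written; they are
computed as printed, with a warning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import pearsonr

__all__ = [
    "TransitionTables",
    "ModelFit",
    "compute_transition_tables",
    "fit_q_table",
    "fit_v_model",
    "predict_p_action_value",
    "predict_p_state_value",
    "compare_models",
    "fit_all_models",
    "MODEL_IDS",
]

MODEL_IDS = ("q_learning", "v_td", "action_value", "state_value")


@dataclass
class TransitionTables:
    """Mean-dopamine table D, transition probabilities P and counts.

    ``mask`` marks transitions that were observed at least once; D is
    defined only there.
    """

    n_syllables: int
    D: np.ndarray          # (S, S), nan where unobserved
    P: np.ndarray          # (S, S), rows sum to 1 over observed transitions
    counts: np.ndarray     # (S, S) int
    mask: np.ndarray       # (S, S) bool


@dataclass
class ModelFit:
    """A fitted dopamine model and its transition-probability prediction."""

    model: str
    P_hat: np.ndarray
    pearson_r: float | None = None
    Q: np.ndarray | None = None
    V: np.ndarray | None = None
    beta: np.ndarray | None = None


def compute_transition_tables(
    sequence: np.ndarray, dopamine: np.ndarray, n_syllables: int | None = None
) -> TransitionTables:
    """Build D and P from a syllable sequence and per-syllable dopamine.

    ``dopamine[t]`` is the dopamine value during ``sequence[t]`` (the
    per-syllable max-then-z-score preprocessing is the caller's
    responsibility).  D(i, j) is the mean of dopamine[t] over transitions
    i → j; P(i, j) their empirical frequency given i.
    """
    seq = np.asarray(sequence, dtype=int)
    dop = np.asarray(dopamine, dtype=float)
    if len(seq) < 2:
        raise ValueError("need at least two syllables")
    if seq.shape != dop.shape:
        raise ValueError("sequence and dopamine lengths differ")
    S = int(n_syllables or seq.max() + 1)
    counts = np.zeros((S, S), dtype=int)
    dsum = np.zeros((S, S))
    np.add.at(counts, (seq[:-1], seq[1:]), 1)
    np.add.at(dsum, (seq[:-1], seq[1:]), dop[1:])
    mask = counts > 0
    D = np.full((S, S), np.nan)
    D[mask] = dsum[mask] / counts[mask]
    row = counts.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore"):
        P = np.where(row > 0, counts / np.maximum(row, 1), 0.0)
    return TransitionTables(n_syllables=S, D=D, P=P, counts=counts, mask=mask)


def _row_betas(Q: np.ndarray) -> np.ndarray:
    """β(s) = 1 / std(Q(s, ·)); zero-std rows fall back to 1 with a warning."""
    sd = Q.std(axis=1)
    if np.any(sd == 0):
        warnings.warn("zero row std in fitted values; beta falls back to 1",
                      stacklevel=2)
    return np.where(sd > 0, 1.0 / np.where(sd > 0, sd, 1.0), 1.0)


def _row_softmax(Z: np.ndarray) -> np.ndarray:
    Z = Z - Z.max(axis=1, keepdims=True)
    E = np.exp(Z)
    return E / E.sum(axis=1, keepdims=True)


def fit_q_table(
    tables: TransitionTables,
    lr: float = 0.1,
    max_iter: int = 10_000,
    tol: float = 1e-8,
) -> ModelFit:
    """Fit the Q-learning dopamine model by gradient descent.

    The Q-table starts at zero and descends the mean squared error between
    max_{s'} Q(s_t, s') − Q(s_{t−1}, s_t) and the observed D over observed
    cells, until the gradient norm drops below ``tol`` or ``max_iter``
    iterations.  The D → Q inverse has a per-row additive gauge freedom
    (coupled through the max); the descent selects one solution implicitly.
    """
    S = tables.n_syllables
    mask = tables.mask
    D = np.where(mask, tables.D, 0.0)
    n_obs = int(mask.sum())
    Q = np.zeros((S, S))
    for _ in range(max_iter):
        argmax = Q.argmax(axis=1)
        M = Q[np.arange(S), argmax]
        pred = M[None, :] - Q
        R = np.where(mask, pred - D, 0.0)      # residuals on observed cells
        grad = -2.0 * R / n_obs
        # max-term contribution: residual at (i, j) backpropagates to
        # Q[j, argmax_j]
        col_res = R.sum(axis=0)
        np.add.at(grad, (np.arange(S), argmax), 2.0 * col_res / n_obs)
        gn = np.linalg.norm(grad)
        if gn < tol:
            break
        Q -= lr * grad
    beta = _row_betas(Q)
    P_hat = _row_softmax(beta[:, None] * Q)
    return ModelFit(model="q_learning", P_hat=P_hat, Q=Q, beta=beta)


def fit_v_model(tables: TransitionTables) -> ModelFit:
    """Fit the V(s) TD dopamine model by least squares.

    D(s_{t−1}, s_t) = V(s_t) − V(s_{t−1}) is linear in V, with an additive
    gauge freedom fixed by V[0] = 0.  Rows of P̂ are all equal to the
    softmax of βV with β = 1 / std(V).
    """
    S = tables.n_syllables
    ii, jj = np.nonzero(tables.mask)
    d = tables.D[ii, jj]
    # design over V[1:] (V[0] = 0 gauge)
    X = np.zeros((len(d), S - 1))
    for r, (i, j) in enumerate(zip(ii, jj)):
        if j > 0:
            X[r, j - 1] += 1.0
        if i > 0:
            X[r, i - 1] -= 1.0
    v_rest, *_ = np.linalg.lstsq(X, d, rcond=None)
    V = np.concatenate([[0.0], v_rest])
    sd = V.std()
    if sd == 0:
        warnings.warn("zero std in fitted V; beta falls back to 1", stacklevel=2)
        beta = 1.0
    else:
        beta = 1.0 / sd
    row = _row_softmax((beta * V)[None, :])[0]
    P_hat = np.tile(row, (S, 1))
    return ModelFit(model="v_td", P_hat=P_hat, V=V,
                    beta=np.full(S, beta))


def _normalized_rows(D_rows: np.ndarray, model: str) -> np.ndarray:
    """Row normalization as printed; warns on negative entries or zero rows."""
    if np.any(D_rows < 0):
        warnings.warn(
            f"{model}: negative dopamine entries break the printed "
            "normalization; computed as printed",
            stacklevel=3,
        )
    sums = D_rows.sum(axis=1, keepdims=True)
    S = D_rows.shape[1]
    out = np.empty_like(D_rows)
    for r in range(D_rows.shape[0]):
        if sums[r, 0] == 0:
            warnings.warn(f"{model}: zero row sum; uniform fallback",
                          stacklevel=3)
            out[r] = 1.0 / S
        else:
            out[r] = D_rows[r] / sums[r, 0]
    return out


def predict_p_action_value(tables: TransitionTables) -> ModelFit:
    """Action-value model: P̂ = D row-normalized (unobserved cells as 0)."""
    D = np.where(tables.mask, tables.D, 0.0)
    return ModelFit(model="action_value",
                    P_hat=_normalized_rows(D, "action_value"))


def predict_p_state_value(tables: TransitionTables) -> ModelFit:
    """State-value model: all rows equal the normalized mean dopamine per
    syllable, D(s) averaged over observed incoming transitions."""
    S = tables.n_syllables
    D = np.where(tables.mask, tables.D, 0.0)
    occ = tables.counts.sum(axis=0)
    with np.errstate(invalid="ignore"):
        Ds = np.where(occ > 0,
                      (D * tables.counts).sum(axis=0) / np.maximum(occ, 1),
                      0.0)
    P_hat = _normalized_rows(Ds[None, :], "state_value")
    return ModelFit(model="state_value", P_hat=np.tile(P_hat[0], (S, 1)))


def compare_models(tables: TransitionTables, fits: list[ModelFit]) -> dict:
    """Pearson r between vectorized P̂ and P over observed cells, per model.

    A prediction with zero variance across observed cells (e.g. uniform
    rows) has undefined correlation; it is scored r = 0 with a warning.
    Each fit's ``pearson_r`` is filled in place.
    """
    mask = tables.mask
    p = tables.P[mask]
    out = {}
    for fit in fits:
        q = fit.P_hat[mask]
        if np.std(q) == 0 or np.std(p) == 0:
            warnings.warn(
                f"{fit.model}: degenerate prediction (zero variance); r = 0",
                stacklevel=2,
            )
            r = 0.0
        else:
            r = float(pearsonr(p, q).statistic)
        fit.pearson_r = r
        out[fit.model] = r
    return out


def fit_all_models(tables: TransitionTables) -> dict:
    """Fit all four models and return {model id: pearson r}."""
    fits = [
        fit_q_table(tables),
        fit_v_model(tables),
        predict_p_action_value(tables),
        predict_p_state_value(tables),
    ]
    return compare_models(tables, fits)
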