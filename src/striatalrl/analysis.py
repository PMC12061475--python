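"""Analyses of SPN population recordings (real or simulated).

The procedures here mirror what is applied to calcium-imaging and
photometry recordings of dorsolateral striatum during spontaneous behavior,
where behavior has been segmented into discrete "syllables" at 30 Hz:

* lagged cross-correlation of total dSPN and iSPN activity, and a scalar
  asymmetry index summarizing its skew (efferent excitation predicts that
  dSPN activity leads iSPN activity);
* per-syllable population activity modes, obtained by regressing each
  neuron's activity change during syllable instances on one-hot syllable
  identity, with split-half cross-validation (instances assigned to halves
  by the parity of their onset time rounded to the nearest second);
* linear time-warping of each syllable instance onto a common 10-step
  axis, and onset-aligned projections of activity onto the syllable modes
  (around the associated syllable's onsets versus all other syllables');
* a selectivity index (mean t)² / mean(t²) of a neuron's nonnegative
  tuning profile across syllables.

All analyses operate on :class:`NeuralSession`, which holds a time × neuron
activity matrix, a pathway label per neuron and a syllable label per frame.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "NeuralSession",
    "SyllableModes",
    "OnsetAlignedTraces",
    "cross_correlation",
    "asymmetry_index",
    "bootstrap_asymmetry_ci",
    "zscore_neurons",
    "split_half_by_onset_parity",
    "syllable_mode_regression",
    "time_warp_syllables",
    "onset_aligned_projection",
    "cross_validated_onset_projection",
    "split_half_mode_correlation",
    "mode_correlation_permutation_test",
    "selectivity_index",
    "neural_session_from_sim",
    "retained_inventory",
]

#: frame label for frames not assigned to any syllable
UNLABELED = -1


@dataclass
class NeuralSession:
    """Time × neuron activity with pathway labels and syllable annotations.

    ``syllables`` assigns a syllable id (or −1) to every frame; instances
    are maximal runs of a constant label.  ``frame_rate`` is nominally
    30 Hz.
    """

    activity: np.ndarray                 # (T, N)
    pathway: np.ndarray                  # (N,) of {"dSPN", "iSPN"}
    syllables: np.ndarray                # (T,) int, -1 = unlabeled
    frame_rate: float = 30.0
    session_id: str = "session"

    def __post_init__(self) -> None:
        self.activity = np.asarray(self.activity, dtype=float)
        self.pathway = np.asarray(self.pathway)
        self.syllables = np.asarray(self.syllables, dtype=int)
        if self.activity.shape[0] != self.syllables.shape[0]:
            raise ValueError("activity and syllable labels disagree in length")
        if self.activity.shape[1] != self.pathway.shape[0]:
            raise ValueError("activity and pathway labels disagree in width")

    def instances(self, include_unlabeled: bool = False) -> list[tuple[int, int, int]]:
        """Maximal constant-label runs as (start, stop, syllable) with
        stop exclusive; onsets are strictly increasing by construction."""
        labels = self.syllables
        bounds = np.flatnonzero(np.diff(labels)) + 1
        starts = np.concatenate([[0], bounds])
        stops = np.concatenate([bounds, [len(labels)]])
        out = []
        for a, b in zip(starts, stops):
            s = int(labels[a])
            if s != UNLABELED or include_unlabeled:
                out.append((int(a), int(b), s))
        return out

    def pathway_mask(self, which: str) -> np.ndarray:
        return self.pathway == which


@dataclass
class SyllableModes:
    """Per-syllable activity modes (regression coefficients over neurons)."""

    inventory: list
    modes: np.ndarray            # (n_syllables, n_neurons)
    pathway: np.ndarray          # (n_neurons,)

    def mode(self, syllable: int) -> np.ndarray:
        return self.modes[self.inventory.index(syllable)]


@dataclass
class OnsetAlignedTraces:
    """Onset-aligned mode projections, mean ± SEM across syllables.

    ``time`` is the warped-time axis relative to onset; ``traces`` maps
    (component, alignment) to a mean trace, where component is one of
    "dSPN", "iSPN", "sum", "diff" and alignment is "associated" or
    "other"; ``sem`` holds matching standard errors.
    """

    time: np.ndarray
    traces: dict
    sem: dict


# ---------------------------------------------------------------------------
# cross-correlation


def cross_correlation(trace_a: np.ndarray, trace_b: np.ndarray,
                      max_lag: int) -> np.ndarray:
    """Pearson correlation of mean-subtracted traces at each integer lag in
    [−max_lag, max_lag].  Positive lag means ``trace_a`` leads (a(t) is
    correlated with b(t + lag))."""
    from scipy.signal import fftconvolve

    a = np.asarray(trace_a, dtype=float)
    b = np.asarray(trace_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("traces must be equal-length 1-D arrays")
    if np.std(a) == 0 or np.std(b) == 0:
        raise ValueError("correlation undefined for a constant trace")
    T = len(a)
    if max_lag >= T:
        raise ValueError("max_lag must be smaller than the trace length")
    # exact per-lag Pearson from running sums; the lagged cross products
    # Σ_t a[t] b[t+lag] come from one FFT-based full correlation
    f = fftconvolve(a, b[::-1])           # f[T-1-lag] = Σ_t a[t] b[t+lag]
    pa = np.concatenate([[0.0], np.cumsum(a)])
    pb = np.concatenate([[0.0], np.cumsum(b)])
    pa2 = np.concatenate([[0.0], np.cumsum(a * a)])
    pb2 = np.concatenate([[0.0], np.cumsum(b * b)])
    lags = np.arange(-max_lag, max_lag + 1)
    out = np.empty(lags.shape)
    for i, lag in enumerate(lags):
        if lag >= 0:
            sx = pa[T - lag] - pa[0]
            sxx = pa2[T - lag] - pa2[0]
            sy = pb[T] - pb[lag]
            syy = pb2[T] - pb2[lag]
        else:
            sx = pa[T] - pa[-lag]
            sxx = pa2[T] - pa2[-lag]
            sy = pb[T + lag] - pb[0]
            syy = pb2[T + lag] - pb2[0]
        n = T - abs(lag)
        sxy = f[T - 1 - lag]
        cov = sxy - sx * sy / n
        vx = sxx - sx * sx / n
        vy = syy - sy * sy / n
        out[i] = cov / np.sqrt(vx * vy) if vx > 0 and vy > 0 else np.nan
    return out


def asymmetry_index(xcorr: np.ndarray) -> float:
    """mean(positive-lag correlations) − mean(negative-lag correlations)
    on a symmetric lag grid (lag 0 excluded)."""
    xcorr = np.asarray(xcorr, dtype=float)
    if len(xcorr) % 2 != 1:
        raise ValueError("expected a symmetric lag grid (odd length)")
    m = len(xcorr) // 2
    return float(np.mean(xcorr[m + 1:]) - np.mean(xcorr[:m]))


def bootstrap_asymmetry_ci(
    trace_a: np.ndarray,
    trace_b: np.ndarray,
    max_lag: int = 50,
    n_boot: int = 200,
    block_len: int = 1000,
    ci: float = 0.95,
    rng: np.random.Generator | None = None,
) -> tuple[float, float, float]:
    """Block-bootstrap confidence interval for the asymmetry index.

    The traces are cut into contiguous blocks of ``block_len`` frames
    (long relative to the autocorrelation time, preserving within-block
    temporal structure); blocks are resampled with replacement and the
    cross-correlation asymmetry recomputed.  Returns (observed, lo, hi).
    """
    rng = rng or np.random.default_rng(0)
    observed = asymmetry_index(cross_correlation(trace_a, trace_b, max_lag))
    n_blocks = len(trace_a) // block_len
    a_blocks = trace_a[: n_blocks * block_len].reshape(n_blocks, block_len)
    b_blocks = trace_b[: n_blocks * block_len].reshape(n_blocks, block_len)
    stats = np.empty(n_boot)
    for k in range(n_boot):
        idx = rng.integers(n_blocks, size=n_blocks)
        stats[k] = asymmetry_index(
            cross_correlation(
                a_blocks[idx].ravel(), b_blocks[idx].ravel(), max_lag
            )
        )
    alpha = (1.0 - ci) / 2.0
    lo, hi = np.quantile(stats, [alpha, 1.0 - alpha])
    return observed, float(lo), float(hi)


# ---------------------------------------------------------------------------
# preprocessing


def zscore_neurons(session: NeuralSession) -> NeuralSession:
    """Z-score each neuron across the session (mean 0, variance 1).

    Neurons with zero variance are excluded with a warning.
    """
    mu = session.activity.mean(axis=0)
    sd = session.activity.std(axis=0)
    # a constant neuron's float std can be ~1e-16 rather than 0; use the
    # exact range to detect it
    keep = (sd > 0) & (np.ptp(session.activity, axis=0) > 0)
    if not np.all(keep):
        warnings.warn(
            f"excluding {int((~keep).sum())} zero-variance neuron(s)",
            stacklevel=2,
        )
    z = (session.activity[:, keep] - mu[keep]) / sd[keep]
    return replace(session, activity=z, pathway=session.pathway[keep])


def split_half_by_onset_parity(
    session: NeuralSession,
) -> tuple[list[tuple[int, int, int]], list[tuple[int, int, int]]]:
    """Partition syllable instances into two halves by the parity of their
    onset timestamp rounded to the nearest second (even → half 1)."""
    even, odd = [], []
    for inst in session.instances():
        sec = int(round(inst[0] / session.frame_rate))
        (even if sec % 2 == 0 else odd).append(inst)
    return even, odd


def retained_inventory(session: NeuralSession, min_count: int = 5) -> list:
    """Syllables appearing at least ``min_count`` times in the session."""
    from collections import Counter

    counts = Counter(s for _, _, s in session.instances())
    return sorted(s for s, c in counts.items() if c >= min_count)


# ---------------------------------------------------------------------------
# syllable modes


def _instance_responses(
    session: NeuralSession,
    instances: list[tuple[int, int, int]],
    baseline: str = "pre",
) -> tuple[np.ndarray, np.ndarray]:
    """Per-instance, per-neuron activity change.

    ``baseline="pre"``: mean activity during the instance minus the mean
    over an equal-length window immediately before onset (instances whose
    pre-window would start before the session are dropped).
    ``baseline="none"``: raw mean during the instance.
    Returns (responses, syllable ids).
    """
    rows, labs = [], []
    for start, stop, s in instances:
        dur = stop - start
        during = session.activity[start:stop].mean(axis=0)
        if baseline == "pre":
            if start - dur < 0:
                continue
            pre = session.activity[start - dur:start].mean(axis=0)
            rows.append(during - pre)
        elif baseline == "none":
            rows.append(during)
        else:
            raise ValueError(f"unknown baseline {baseline!r}")
        labs.append(s)
    return np.array(rows), np.array(labs)


def syllable_mode_regression(
    session: NeuralSession,
    instances: list[tuple[int, int, int]],
    inventory: list,
    baseline: str = "pre",
) -> SyllableModes:
    """Least-squares regression of activity change on one-hot syllable id.

    The coefficient vector for each syllable is that syllable's activity
    mode (with a one-hot design and no intercept this equals the mean
    response over the syllable's instances, but it is computed as the
    least-squares solution).
    """
    responses, labs = _instance_responses(session, instances, baseline)
    missing = [s for s in inventory if s not in set(labs.tolist())]
    if missing:
        raise ValueError(
            f"rank-deficient design: no instances for syllables {missing}"
        )
    mask = np.isin(labs, inventory)
    responses, labs = responses[mask], labs[mask]
    design = np.zeros((len(labs), len(inventory)))
    for j, s in enumerate(inventory):
        design[:, j] = labs == s
    coef, *_ = np.linalg.lstsq(design, responses, rcond=None)
    return SyllableModes(inventory=list(inventory), modes=coef,
                         pathway=session.pathway)


def split_half_mode_correlation(
    session: NeuralSession,
    inventory: list | None = None,
    baseline: str = "pre",
) -> float:
    """Mean Pearson correlation, across syllables, between the mode vectors
    estimated from the two parity halves of the session."""
    if inventory is None:
        inventory = retained_inventory(session)
    h1, h2 = split_half_by_onset_parity(session)
    m1 = syllable_mode_regression(session, h1, inventory, baseline)
    m2 = syllable_mode_regression(session, h2, inventory, baseline)
    rs = [
        np.corrcoef(m1.modes[k], m2.modes[k])[0, 1]
        for k in range(len(inventory))
    ]
    return float(np.mean(rs))


def mode_correlation_permutation_test(
    session: NeuralSession,
    n_perm: int = 199,
    rng: np.random.Generator | None = None,
    inventory: list | None = None,
) -> tuple[float, np.ndarray, float]:
    """One-sided permutation test of the split-half mode correlation.

    The null shuffles syllable identities across instances (within the
    whole session, preserving the instance segmentation) before the
    split-half mode estimation.  Returns (observed, null values, p), with
    p = (1 + #null ≥ observed) / (1 + n_perm).
    """
    rng = rng or np.random.default_rng(0)
    if inventory is None:
        inventory = retained_inventory(session)
    observed = split_half_mode_correlation(session, inventory)
    insts = session.instances()
    null = np.empty(n_perm)
    labels = np.array([s for _, _, s in insts])
    for p in range(n_perm):
        perm = rng.permutation(labels)
        shuffled = session.syllables.copy()
        for (start, stop, _), s in zip(insts, perm):
            shuffled[start:stop] = s
        shuf_sess = replace(session, syllables=shuffled)
        null[p] = split_half_mode_correlation(shuf_sess, inventory)
    pval = (1.0 + np.sum(null >= observed)) / (1.0 + n_perm)
    return observed, null, float(pval)


# ---------------------------------------------------------------------------
# time-warping and onset-aligned projections


def time_warp_syllables(
    session: NeuralSession, steps_per_syllable: int = 10
) -> NeuralSession:
    """Linearly time-warp each instance onto ``steps_per_syllable`` steps.

    Every maximal constant-label run — including unlabeled background runs,
    which keeps the timeline contiguous — is interpolated onto exactly
    ``steps_per_syllable`` frames (endpoints preserved; single-frame
    instances become constant traces).
    """
    segs = session.instances(include_unlabeled=True)
    k = steps_per_syllable
    act = np.empty((len(segs) * k, session.activity.shape[1]))
    labels = np.empty(len(segs) * k, dtype=int)
    grid_cache: dict[int, np.ndarray] = {}
    for j, (start, stop, s) in enumerate(segs):
        L = stop - start
        if L not in grid_cache:
            grid_cache[L] = (
                np.linspace(0.0, L - 1.0, k) if L > 1 else np.zeros(k)
            )
        grid = grid_cache[L]
        chunk = session.activity[start:stop]
        lo = np.floor(grid).astype(int)
        hi = np.minimum(lo + 1, L - 1)
        w = (grid - lo)[:, None]
        act[j * k:(j + 1) * k] = (1 - w) * chunk[lo] + w * chunk[hi]
        labels[j * k:(j + 1) * k] = s
    return replace(session, activity=act, syllables=labels,
                   frame_rate=float(k))


def onset_aligned_projection(
    session: NeuralSession,
    modes: SyllableModes,
    instances: list[tuple[int, int, int]],
    window: int = 20,
) -> dict:
    """Mean projection of activity onto each syllable's mode around onsets.

    For each syllable in the mode inventory, activity is projected onto the
    syllable's (per-pathway unit-normalized) mode and averaged over a
    ±``window``-frame window around that syllable's onsets within
    ``instances`` ("associated") and around all other syllables' onsets
    ("other").  Returns per-syllable trace arrays keyed by
    (component, alignment), each of shape (n_syllables, 2·window).
    ``modes`` should come from the opposite data half for cross-validation.
    """
    T = session.activity.shape[0]
    masks = {p: session.pathway_mask(p) for p in ("dSPN", "iSPN")}
    have = {p: masks[p].any() for p in masks}
    n_syll = len(modes.inventory)
    out = {}
    for comp in ("dSPN", "iSPN"):
        if have[comp]:
            out[(comp, "associated")] = np.full((n_syll, 2 * window), np.nan)
            out[(comp, "other")] = np.full((n_syll, 2 * window), np.nan)

    onsets_by_syll = {s: [] for s in modes.inventory}
    for start, stop, s in instances:
        if s in onsets_by_syll:
            onsets_by_syll[s].append(start)

    for k, s in enumerate(modes.inventory):
        m = modes.modes[k]
        proj = {}
        for comp in ("dSPN", "iSPN"):
            if not have[comp]:
                continue
            v = m[masks[comp]]
            norm = np.linalg.norm(v)
            if norm == 0:
                norm = 1.0
            proj[comp] = session.activity[:, masks[comp]] @ (v / norm)
        for alignment in ("associated", "other"):
            if alignment == "associated":
                onsets = onsets_by_syll[s]
            else:
                onsets = [
                    t for s2, ts in onsets_by_syll.items() if s2 != s for t in ts
                ]
            snippets = {comp: [] for comp in proj}
            for t in onsets:
                if t - window < 0 or t + window > T:
                    continue
                for comp in proj:
                    snippets[comp].append(proj[comp][t - window:t + window])
            for comp in proj:
                if snippets[comp]:
                    out[(comp, alignment)][k] = np.mean(snippets[comp], axis=0)
    return out


def cross_validated_onset_projection(
    session: NeuralSession,
    window: int = 20,
    steps_per_syllable: int = 10,
    inventory: list | None = None,
    baseline: str = "pre",
) -> OnsetAlignedTraces:
    """Split-half cross-validated onset-aligned mode projections.

    Modes are fit on one parity half and projected around onsets of the
    other half (both directions, averaged); instances are first time-warped
    onto ``steps_per_syllable`` steps.  Returns mean ± SEM across syllables
    for dSPN, iSPN and (when both pathways are present) sum and difference
    components.
    """
    if inventory is None:
        inventory = retained_inventory(session)
    warped = time_warp_syllables(session, steps_per_syllable)
    h1, h2 = split_half_by_onset_parity(warped)
    per_syll = None
    for fit_half, eval_half in ((h1, h2), (h2, h1)):
        modes = syllable_mode_regression(warped, fit_half, inventory, baseline)
        res = onset_aligned_projection(warped, modes, eval_half, window)
        if per_syll is None:
            per_syll = {key: [val] for key, val in res.items()}
        else:
            for key, val in res.items():
                per_syll[key].append(val)
    averaged = {
        key: np.nanmean(np.stack(vals), axis=0) for key, vals in per_syll.items()
    }
    both = ("dSPN", "associated") in averaged and ("iSPN", "associated") in averaged
    if both:
        for alignment in ("associated", "other"):
            d = averaged[("dSPN", alignment)]
            i = averaged[("iSPN", alignment)]
            averaged[("sum", alignment)] = d + i
            averaged[("diff", alignment)] = d - i
    traces, sem = {}, {}
    for key, arr in averaged.items():
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            traces[key] = np.nanmean(arr, axis=0)
            n = np.sum(~np.isnan(arr[:, 0]))
            sem[key] = np.nanstd(arr, axis=0, ddof=1) / np.sqrt(max(n, 1))
    time = np.arange(-window, window)
    return OnsetAlignedTraces(time=time, traces=traces, sem=sem)


# ---------------------------------------------------------------------------
# selectivity


def selectivity_index(tuning: np.ndarray) -> float:
    """Selectivity (mean t)² / mean(t²) of a nonnegative tuning profile.

    Equals 1 for uniform tuning and 1/A for one-hot tuning over A
    syllables; 0/0 is defined as 0.  The caller chooses |a_i| or
    max(a_i, 0) as the nonnegative tuning measure.
    """
    t = np.asarray(tuning, dtype=float)
    if np.any(t < 0):
        raise ValueError("tuning values must be nonnegative")
    denom = np.mean(t * t)
    if denom == 0:
        return 0.0
    return float(np.mean(t) ** 2 / denom)


# ---------------------------------------------------------------------------
# adapters


def neural_session_from_sim(sim) -> NeuralSession:
    """Convert a spontaneous :class:`~striatalrl.spontaneous.SimSession`
    into a :class:`NeuralSession` (actions become syllables; no-action
    blocks stay unlabeled)."""
    T, A = sim.dspn_activity.shape
    activity = np.hstack([sim.dspn_activity, sim.ispn_activity])
    pathway = np.array(["dSPN"] * A + ["iSPN"] * A)
    syll = np.full(T, UNLABELED, dtype=int)
    interval = sim.config.action_interval
    for t, a in zip(sim.onsets, sim.action_labels):
        if a >= 0:
            syll[t:t + interval] = a
    return NeuralSession(activity=activity, pathway=pathway, syllables=syll,
                         frame_rate=30.0, session_id="sim")
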