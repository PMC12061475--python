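# Methods

This note records the models implemented by `striatalrl`, the parameter
values they default to, the design choices made where the design was
genuinely open, and what the synthetic data can and cannot establish.

## Tabular striatal model

Each of `A` actions is encoded by one dSPN and one iSPN.  Feedforward
activity is `y = ϕ(W x)` with `ϕ` rectified-linear; the action logit is
the difference mode `ℓ_a = y_d[a] − y_i[a]`, and actions are drawn from

```
p(a) = exp(β ℓ_a) / (c_nogo + Σ_a' exp(β ℓ_a'))
```

with the residual mass interpreted as taking no action.  Defaults: weights
initialized at 1 for task simulations; `β = 10` in trial-based tasks and
`100` in spontaneous simulations; `c_nogo = 1` for go/no-go and `0` for
multi-action tasks.

Plasticity is three-factor: `ΔW[a,j] = α f_pathway(δ) y[a] x[j]` with
`α = 0.05` (`0.01` in shared-control experiments).  Dopamine dependence
`f(δ)`:

| kind               | f_dSPN                  | f_iSPN                  |
|--------------------|-------------------------|-------------------------|
| linear             | δ                       | −δ                      |
| rectified          | max(δ, 0)               | max(−δ, 0)              |
| offset_sigmoid     | ½(a + b/(1+c·e^{1−dδ})) | ½(a + b/(1+c·e^{1+dδ})) |
| same_sign_indirect | δ                       | δ (control rule)        |

with `a = −3.5, b = 11.5, c = 0.9, d = 1`.  Note the offset sigmoid is
nonzero at `δ = 0` (≈ −0.082), so baseline dopamine causes slow weight
drift; it is implemented as written, with no baseline subtraction.  The
same-sign rule exists only as the control in which iSPN plasticity copies
the (linear) dSPN rule.

The dopamine signal comes from one of two critics.  The TD critic keeps
per-state values `V(s)` (initialized 0, `α_V = 0.05`, `0.25` in
shared-control runs) and emits `δ = r − V(s)`, updating `V` afterwards.
The Q critic emits `δ = r − ℓ_a` with the action value read from the
*feedforward* striatal logit of the executed action each trial — no stored
table.  Within a trial the order is: compute `δ` from pre-update
critic/weights, update the critic, then update the weights.

### Post-selection activity

Two models supply the activity used for plasticity.  The *canonical*
model sets the chosen action's dSPN to 1 and every unselected action's
iSPN to 1 (when no action is taken, all iSPNs are active).  The
*efference* model adds `c_efference` (default 1.5) to both pre-activations
of the chosen pair: `y[a] = ϕ(c·1[a=a*] + Wx)[a]`.  The already-selected
action is never re-sampled.

When no action is selected, the efference model applies no efferent input
and performs **no weight update** (the critic still updates).  Plasticity
in this model is action-triggered — the efferent volley reports an
executed movement, and without one there is no postsynaptic teaching
signal.  This choice is load-bearing: if no-action trials instead learned
from feedforward activity, the early punishments of a punish-on-no-go
protocol would drive the go logit into an absorbing low-probability regime
before the critic saturates, and the task would never be learned.  The
canonical model is unaffected (its no-action activity pattern is exactly
the pathological iSPN pattern the opponent rules mishandle).

### Orthogonality in floating point

Efferent input is common to the chosen pair, i.e. purely along the sum
mode, so mathematically it leaves every logit unchanged wherever
rectification does not bind.  Recomputing `ℓ` by subtracting the excited
rates would break this identity in the last bit (float addition does not
cancel exactly), so `apply_efference` returns an activity object whose
logits are computed exactly at construction — equal to the feedforward
logits for all actions whose rectification state is unchanged, and to the
naive difference where rectification binds.  The logits remain a pure
function of the inputs; nothing is cached across mutations.

### Shared control (tutoring)

A tutor pathway contributes an additive logit bias `b_t = 1.0` on the
correct action; the striatal logits enter the combined softmax scaled by
the "striatal control weight" (swept over e.g. 0.1–1.0).  `b_t = 1.0`
with `β = 10` makes the tutor nearly deterministic, which is the regime
where the contrast between critics is meaningful: a state-value TD critic
then predicts the (tutor-earned) rewards almost perfectly, its prediction
error vanishes, and striatal learning starves, while the Q critic's error
`r − ℓ_a` persists until the striatum itself encodes the action values.
Striatal-alone performance is evaluated every 25 trials as the exact
softmax probability of the correct action with the tutor removed.

The shared-control experiments default to the **rectified** plasticity
rule.  Two reasons: the tutoring protocol delivers only rewards (0/+1),
and under the linear rule every positive prediction error depresses all
active iSPN synapses, silencing the indirect pathway over training; and
the rectified form matches the physiological observation that dopamine
elevations have little effect on D2-receptor signaling.  Under the linear
rule the TD critic additionally retains a small transient-driven gain
(logit gap ≈ `2 c_efference α / α_V`) before its values saturate.

## Firing-rate forced-choice model

Four neurons (a dSPN/iSPN pair per action) follow

```
τ dy/dt = −y + [W x + η(t) + e(t) + b]_+
```

integrated by Euler steps of `dt = 20 ms` for 2-s one-hot stimuli, with
bias `b = 5 Hz`, OU noise `η` (time constant 600 ms, stationary variance
1/60 Hz², simulated with the exact AR(1) discretization so the stationary
variance is `dt`-independent), and Gaussian weight initialization
(sd 1 Hz).  The membrane time constant `τ` is not part of the published
parameter set; it defaults to 100 ms and is exposed in the configuration.
The action is the argmax of the difference modes averaged over the first
second; during the second second the chosen pair receives `e = 7.5 Hz`
and the weights integrate `dw/dt = η_lr f(δ)(y − b)x` with
`η_lr = 5×10⁻⁴ ms⁻¹` and `f = +1` for dSPNs after correct / iSPNs after
incorrect choices, `−1` otherwise — applied during the efference window
only.  Stimuli are drawn uniformly per trial; "learned" means 10
consecutive correct trials, and trials-to-criterion is the (1-based) index
of the trial completing that run.  With these defaults the median over
seeds is ~12 trials.  Because the rule has no weight decay or saturation,
weights keep growing after the task is learned; runs are kept to tens of
trials.

## Spontaneous-behavior simulation

`A = 50` actions; each SPN's feedforward trace is an independent
stationary Gaussian process with kernel `exp(−|Δt|/10)` (unit variance,
sampled exactly as an AR(1) process).  Every 10 steps an action is drawn
from the softmax (`β = 100`) applied to the previous timestep's total
activity, with the no-action weight calibrated by bisection so no action
is chosen 50% of the time; because `β·ℓ` reaches several hundred, the
offset is held in log space and the policy evaluated by log-sum-exp
(mathematically identical to the plain form).  Upon selection the chosen
pair receives an efferent transient of amplitude 1.5 decaying with a
10-step time constant; overlapping transients sum, and total activity is
`ϕ(feedforward + efference)`.  No plasticity operates.  Sessions default
to 5×10⁴ steps.

The cross-correlation asymmetry this produces is small: a 4×10⁵-step run
gives ≈ +0.026 (Pearson cross-correlation, lags ±20; the skew is confined
to about two efference time constants, which fixes the default lag range),
and single 5×10⁴-step sessions scatter around +0.015 with sd ≈ 0.012 —
the independent feedforward processes dominate the variance of the summed
traces.  A single session of that length therefore shows a positive point
estimate but usually not a bootstrap-significant one; the paired design
(efference vs. `c_efference = 0` on identical feedforward draws) isolates
the effect reliably and is what the test suite uses as the robust check.

## Session analyses

Analyses operate on time × neuron activity with a pathway label per
neuron and a syllable label per frame (30 Hz).  Steps: per-neuron
z-scoring across the session (constant neurons excluded); syllable
instances split into halves by the parity of the onset time rounded to
the nearest second; per-syllable modes fit by least squares of the
per-instance activity change on one-hot syllable identity.  "Activity
change during a syllable" defaults to the mean z-scored activity during
the instance minus the mean over an equal-length window immediately
before onset (this makes the pre-onset baseline of the projections
interpretable); the raw during-instance mean is available as an
alternative.  The syllable inventory keeps syllables with ≥ 5 instances.

For onset-aligned projections, every maximal constant-label run —
including unlabeled background runs, so the timeline stays contiguous —
is linearly time-warped onto 10 steps.  Activity is projected onto each
syllable's per-pathway unit-normalized mode and averaged over ±2 warped
syllables around the syllable's own onsets ("associated") or all other
syllables' onsets ("other"), with modes always fit on the opposite parity
half (both directions averaged).  Mode reliability is quantified by the
mean split-half mode correlation, with significance from permuting
syllable identities across instances (199 permutations).

The selectivity of a nonnegative tuning profile `t` over `A` syllables is
`(mean t)² / mean(t²)` (1 for uniform, 1/A for one-hot; 0/0 := 0), using
either `|a_i|` or `max(a_i, 0)` as the tuning measure.

Cross-correlation is per-lag Pearson on mean-subtracted traces (computed
exactly via FFT cross-products and running window sums), with positive
lag meaning the first trace leads; the asymmetry index is the mean over
positive lags minus the mean over negative lags, and its confidence
interval comes from a block bootstrap (1000-frame blocks, 200 resamples).

## Dopamine models

From a syllable sequence and per-syllable dopamine values (per-syllable
maxima, z-scored per session), two tables are built: `D(s_{t−1}, s_t)`,
conditional mean dopamine, and `P(s_{t−1}, s_t)`, empirical transition
probabilities.  Never-observed transitions are masked and excluded from
fitting losses and correlations.  The four predictive models are the
Q-learning error model (`D = max_s' Q(s_t,s') − Q(s_{t−1},s_t)`; Q fit by
full-batch gradient descent from zero init, learning rate 0.1, up to 10⁴
iterations, gradient-norm tolerance 10⁻⁸, rows converted to probabilities
by a softmax with `β(s) = 1/std(Q(s,·))`), the state-value TD model
(`D = V(s_t) − V(s_{t−1})`, least squares with the gauge fixed by
`V[0] = 0`, shared softmax rows), and the two normalization models
(row-normalized `D`, and normalized per-syllable mean dopamine).  The
D→Q inversion is nonconvex through the max term and carries per-row gauge
freedom; the descent selects one solution and can land in local minima
with small residual error even on noiseless tables (observed ≈ 1% of the
table variance), which does not affect model ranking.  Z-scored dopamine
can be negative, which the two normalization models as written do not
handle; they are computed as written and emit a warning.  Model fit is
the Pearson correlation between vectorized predicted and empirical `P`
over observed cells; a zero-variance prediction scores 0 with a warning.

## Synthetic data

The generators provide positive and null controls with recorded ground
truth.  Syllable sequences are first-order Markov chains with geometric
durations (default mean 15 frames at 30 Hz, i.e. ~500 ms).  Neural
sessions plant, around each syllable onset, the efference-model
signature: a difference-mode ramp (dSPN mode up, iSPN mode down over the
10 pre-onset frames, decaying back after onset) and a post-onset sum-mode
transient on both pathways, on top of white noise (sd 0.5); modes are
random signed unit vectors, amplitudes default to 1, and the `null`
switch zeroes all structure.  dLight-style sessions sample transitions
from `softmax(βQ)` with `Q ~ N(0,1)`, `β = 1`, and emit
`max Q − Q + noise` (sd 0.25), z-scored per session.

What passing these tests shows — and does not.  The generators reproduce
the *structure* the analyses assume (two labeled pathways, syllable
segmentation, per-syllable dopamine, planted onset signatures), so
recovery tests establish that the pipeline measures what it claims.  They
do not emulate calcium-indicator kinetics, bleaching, correlated noise
across neurons, kinematic similarity between syllables, or non-Markov
behavioral statistics, so passing them says nothing about effect sizes in
real recordings.

## Numerical and reproducibility choices

Softmaxes subtract the maximum logit (and use log-sum-exp at `β = 100`);
argmax ties break to the lowest index.  OU and GP processes use exact
AR(1) discretizations started from stationarity.  The sum/difference-mode
identity is asserted float-exactly under dyadic-rational parameters
(α = 1/16, unit weights, one-hot inputs) where every intermediate is
exactly representable, and to 10⁻¹² relative precision otherwise.  All
experiment-level randomness derives from a single seed through named
per-module child streams, so adding one simulation never perturbs
another's draws; fixed seeds reproduce results bit-exactly.

## Known limitations

Single neuron per action (a distributed-population variant is a natural
extension but not exercised); no lateral inhibition between SPNs; no
inter-trial temporal credit assignment in the tabular tasks; unbounded
weight growth in the rate model after learning; the spontaneous
simulation's cross-correlation asymmetry is intrinsically small relative
to single-session sampling noise at the default session length.
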