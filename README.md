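# striatalrl

Simulation and analysis of reinforcement learning in the dorsolateral
striatum with opponent direct/indirect pathways and efferent excitation.

## The problem

Spiny projection neurons (SPNs) of the striatum come in two opponent
classes: direct-pathway dSPNs promote actions and indirect-pathway iSPNs
suppress them, and their corticostriatal synapses follow opposite
dopamine-dependent three-factor plasticity rules,

```
ΔW_dSPN = α · f_dSPN(δ) · y_dSPN · x        f_dSPN increasing in δ
ΔW_iSPN = α · f_iSPN(δ) · y_iSPN · x        f_iSPN decreasing in δ
```

where `x` is presynaptic cortical activity, `y` postsynaptic SPN activity
and `δ` a global dopamine reward-prediction-error signal.  Under the
textbook ("canonical") picture of action selection — the chosen action's
dSPN active, the unchosen actions' iSPNs active — these rules *mis*learn:
when a punished outcome suppresses dopamine, the iSPNs representing the
*unselected* actions get potentiated, making the punished action more
likely.

The resolution implemented here is an efference model: action probabilities
follow a softmax over the per-action "difference mode" `ℓ_a = y_dSPN_a −
y_iSPN_a`, and after an action is executed an efference signal excites the
selected action's dSPN **and** iSPN together — input along the orthogonal
"sum mode" `y_dSPN + y_iSPN`, which drives correct plasticity (one linear
learning step changes `ℓ_a` by exactly `α·δ·(y_d+y_i)·(x·x)`) while
leaving action selection untouched.  Because the efference reports the
*executed* action, pairing it with an off-policy Q-learning dopamine
signal (`δ = r − ℓ_a`, the action value read directly from the striatal
logit) lets a weak striatum learn from actions imposed by other motor
pathways.

The package provides, as library modules:

- `learning` — the plasticity rules (linear, rectified, offset sigmoid,
  same-sign control), the three-factor update, and TD / Q critics;
- `network` — the tabular striatal network, softmax policy with a
  no-action option, canonical and efference post-selection models, and
  shared-control (tutor) policies;
- `tasks` — go/no-go, multi-state action-selection, and shared-control
  learning experiments;
- `ratemodel` — a continuous-time four-neuron firing-rate model of the
  two-alternative forced-choice task with Ornstein–Uhlenbeck noise and
  online plasticity;
- `spontaneous` — continuous action selection from Gaussian-process
  feedforward input with decaying efferent transients, emulating
  recordings of freely behaving mice;
- `analysis` — the neural-data analysis pipeline: dSPN/iSPN
  cross-correlation and its asymmetry, per-syllable population modes with
  split-half cross-validation, linear time-warping, onset-aligned mode
  projections, and a selectivity index;
- `dopamine_models` — four models relating per-syllable dopamine to
  syllable transition statistics (Q-learning error, state-value TD error,
  action-value, state-value), compared by Pearson correlation;
- `synth` — synthetic session generators with recorded ground truth;
- `config` / `cli` — config-driven experiment runner, HDF5 session I/O,
  and a thin `striatal` command-line wrapper.

## Worked example

```
python examples/shared_control.py
```

prints

```
off_policy + q  critic: striatal-alone p(correct) = 0.92   (chance 0.10)
on_policy  + q  critic: striatal-alone p(correct) = 0.09   (chance 0.10)
off_policy + td critic: striatal-alone p(correct) = 0.17   (chance 0.10)
```

A tutor pathway drives a 10-state/10-action task to mostly-correct
performance while the striatal contribution to the combined policy is
weighted by only 0.1.  The numbers are the striatum's own accuracy with
the tutor disabled after 500 trials: with efference targeting the executed
action and a Q-learning dopamine signal the striatum absorbs the tutor's
policy (0.92); efference targeting the striatum's own favored action
(on-policy) leaves it at chance; and a state-value TD critic stops
learning as soon as its reward prediction saturates (0.17).

Other examples, one per capability, live in `examples/`: the
canonical-vs-efference learning contrast, the firing-rate forced-choice
task, the spontaneous-session cross-correlation asymmetry, the
syllable-mode analysis pipeline, and the dopamine model comparison.  Each
prints a few numbers and a sentence on what they mean.

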