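"""Which model of dopamine best predicts syllable transitions?

Generates synthetic dLight-style sessions in which transitions follow a
softmax of a hidden Q-table and per-syllable dopamine is the off-policy
prediction error max Q(s_t, ·) − Q(s_{t−1}, s_t) (plus noise, z-scored per
session), then fits all four models and prints each model's Pearson
correlation between predicted and empirical transition probabilities.
"""

import warnings

import numpy as np

from striatalrl.dopamine_models import compute_transition_tables, fit_all_models
from striatalrl.synth import generate_dlight_session

rng = np.random.default_rng(0)
totals = {m: [] for m in ("q_learning", "v_td", "action_value", "state_value")}
for _ in range(5):
    Q = rng.normal(size=(20, 20))
    seq, dop, _ = generate_dlight_session(Q, beta=1.0, noise_sd=0.25,
                                          n_transitions=10_000, rng=rng)
    tables = compute_transition_tables(seq, dop)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for model, r in fit_all_models(tables).items():
            totals[model].append(r)

for model, rs in totals.items():
    print(f"{model:12s} Pearson r = {np.mean(rs):+.3f} "
          f"(range {min(rs):+.3f} … {max(rs):+.3f})")

print("\nOnly the Q-learning model, whose prediction depends on the "
      "previous syllable, recovers the transition structure; the others "
      "sit near or below zero.")
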