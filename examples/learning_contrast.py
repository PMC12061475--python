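"""Canonical vs efference model on trial-based learning tasks.

Runs the go/no-go and two-state action-selection tasks under reward-only
and punishment-only feedback with the linear plasticity rule, and prints
the final fraction of correct choices (last 50 of 500 trials, mean over 10
seeds).  The canonical activity model fails when punishment drives
learning — depressed dopamine potentiates the iSPNs of *unselected*
actions, reinforcing the punished behavior — while the efference model,
in which the selected action's dSPN and iSPN are excited together, learns
every protocol.
"""

from striatalrl.tasks import (
    run_action_selection_experiment,
    run_gonogo_experiment,
)

for model in ("canonical", "efference"):
    for protocol in ("reward_correct", "punish_incorrect"):
        g = run_gonogo_experiment("linear", model, protocol,
                                  n_trials=500, n_seeds=10, seed=0)
        a = run_action_selection_experiment("linear", model, protocol,
                                            n_trials=500, n_seeds=10, seed=0)
        print(f"{model:10s} {protocol:16s}  "
              f"p(correct): go/no-go {g.final_p_correct():.2f}  "
              f"2-state {a.final_p_correct():.2f}")

print("\nChance is 0.5; values near 1 mean the task was learned, values")
print("near 0 mean the system learned the *wrong* behavior.")
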