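"""Off-policy learning when the striatum shares control with a tutor.

A tutor pathway biases action selection toward the correct response in a
10-state/10-action task while the striatal contribution is weak (weight
0.1).  Prints the striatum's stand-alone accuracy (tutor disabled) after
learning, for three dopamine/efference configurations.  Only off-policy
efference (exciting the *executed* action's SPNs) combined with a
Q-learning dopamine signal lets the weak striatum absorb the tutor's
policy.
"""

from striatalrl.tasks import run_shared_control_experiment

for mode, critic in (("off_policy", "q"), ("on_policy", "q"),
                     ("off_policy", "td")):
    df = run_shared_control_experiment(
        striatal_weight=0.1, efference_mode=mode, critic_kind=critic,
        n_seeds=10, n_trials=500, seed=0,
    )
    final = df[df.trial == df.trial.max()].p_correct_alone.mean()
    print(f"{mode:10s} + {critic:2s} critic: "
          f"striatal-alone p(correct) = {final:.2f}   (chance 0.10)")
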