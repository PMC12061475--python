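"""Cross-correlation asymmetry of total dSPN and iSPN activity.

Simulates spontaneous behavior (50 actions, softmax selection every 10
steps with a 50% no-action option, efferent excitation of the selected
pair) and prints the lagged cross-correlation asymmetry of the summed
pathway activities, against a no-efference control on identical
feedforward input.  Positive asymmetry means present dSPN activity
correlates more with *future* than past iSPN activity — the signature of
action-triggered efferent excitation.
"""

import dataclasses

import numpy as np

from striatalrl.analysis import asymmetry_index, cross_correlation
from striatalrl.spontaneous import (
    SpontaneousConfig,
    calibrate_nogo_offset,
    run_spontaneous_session,
)

cfg = SpontaneousConfig(n_steps=50_000)
cfg.log_c_nogo = calibrate_nogo_offset(cfg, np.random.default_rng(0))
print(f"calibrated log c_no-go = {cfg.log_c_nogo:.1f} "
      "(no-action chosen ~50% of the time)")

for label, ce in (("efference", 1.5), ("control  ", 0.0)):
    sim = run_spontaneous_session(
        dataclasses.replace(cfg, c_efference=ce), np.random.default_rng(1)
    )
    d = sim.dspn_activity.sum(axis=1)
    i = sim.ispn_activity.sum(axis=1)
    asym = asymmetry_index(cross_correlation(d, i, 20))
    print(f"{label}: asymmetry index {asym:+.4f}")

print("\nThe efference session is skewed toward positive lags (dSPN leads "
      "iSPN); the matched control is not.")
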