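"""Syllable-mode analysis of a simulated two-pathway session.

Generates a synthetic session with planted efference-like structure,
runs the full analysis pipeline — z-scoring, split-half mode regression,
time-warping, onset-aligned cross-validated projections — and prints the
split-half mode reliability and the pre/post-onset projection means.
"""

import numpy as np

from striatalrl.analysis import (
    cross_validated_onset_projection,
    mode_correlation_permutation_test,
    zscore_neurons,
)
from striatalrl.synth import generate_neural_session

session, truth = generate_neural_session(seed=3)
z = zscore_neurons(session)

obs, null, p = mode_correlation_permutation_test(
    z, n_perm=99, rng=np.random.default_rng(0)
)
print(f"split-half mode correlation: {obs:.2f} "
      f"(label-shuffled null max {null.max():.2f}, permutation p = {p:.3f})")

tr = cross_validated_onset_projection(z, window=20)
w = 20
for comp in ("dSPN", "iSPN", "sum", "diff"):
    t = tr.traces[(comp, "associated")]
    print(f"{comp:4s} associated-mode projection: "
          f"pre-onset {t[:w].mean():+.2f}, post-onset {t[w:].mean():+.2f}")
other = max(np.abs(tr.traces[("dSPN", "other")]).max(),
            np.abs(tr.traces[("iSPN", "other")]).max())
print(f"other-syllable projections stay within ±{other:.2f}")

print("\ndSPN modes are above baseline and iSPN modes below baseline "
      "before the associated syllable's onset (difference-mode lead); "
      "both rise after onset (sum-mode efference).")
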