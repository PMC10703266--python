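"""Bayesian observer: sensory noise controls which algorithm dominates.

Sweeps the observer's sensory noise sigma_s at the slow tempo for both
prior algorithms.  With the duration-based prior the observer crosses
from duration-dominant (low noise: the sensed last tone is trustworthy)
to rhythm-dominant (high noise: the prior, which integrates all tones,
takes over).  With the rhythm-based prior it is rhythm-dominant
throughout.

Runtime: about half a minute.
"""

import numpy as np

from tempopred import run_observer_experiment

grid = np.geomspace(0.02, 0.5, 6)
for prior in ("absolute", "relative"):
    out = run_observer_experiment(
        conditions=("1.2hz",),
        prior_type=prior,
        sigma_s_grid=grid,
        n_trials=300,
        seed=0,
    )
    print(f"{prior}-prior observer (slow tempo):")
    print("  sigma_s [s]   slope_diff   dominant")
    for s in out:
        d = s.slope_diff
        print(f"  {s.extra['sigma_s']:8.3f}    {d:+8.2f}   "
              f"{'duration' if d > 0 else 'rhythm'}")
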