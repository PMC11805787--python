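"""Simulate a behavioral cohort and inspect its level-2 structure.

Generates 160 participant profiles whose seven cognitive measures follow
the documented marginal means/SDs and rank correlations, then draws the
item-probe reaction-time trials each profile implies.
"""

import numpy as np

from spoarcnet import defaults
from spoarcnet.synthdata import GenConfig, generate_participants, generate_probe_trials

cfg = GenConfig(seed=1)
profiles = generate_participants(cfg)
trials, truth = generate_probe_trials(profiles, cfg)

print("cohort:", len(profiles), "participants,", len(trials), "probe trials")
print("\ncognitive measures (sample mean / sd vs. target):")
for name in defaults.COGNITIVE_MEASURES:
    mean, sd, lo, hi = defaults.L2_MARGINALS[name]
    x = profiles[name]
    print(f"  {name:6s} {x.mean():7.3f} / {x.std(ddof=1):6.3f}"
          f"   target {mean:7.3f} / {sd:6.3f}   range [{lo}, {hi}]")

counts = trials.groupby("participant_id").size()
print(f"\ntrials per participant: {counts.min()}..{counts.max()}"
      f" (mean {counts.mean():.1f}) — each RT is the two-level linear"
      " predictor plus participant random effects and Gaussian noise")
print(f"re-drawn negative RTs: {truth.n_redrawn_rts}")
rho = np.corrcoef(truth.random_effects.T)
print("realized random-effect correlations (intercept x slopes):",
      np.round(rho[0, 1:], 2))
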