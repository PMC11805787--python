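"""Compute the seven cognitive measures from raw task trials.

Builds attention and working-memory task trials for a small cohort, trims
reaction times (absolute window then 3xIQR fences), recomputes each
capacity from the trials, and applies the exact-binomial exclusion rules.
"""

from spoarcnet.app import measured_profiles, _task_summaries
from spoarcnet.measures import apply_exclusions, binomial_chance_threshold, exclusion_table
from spoarcnet.synthdata import GenConfig, generate_attention_and_wm_trials, generate_participants

cfg = GenConfig(n_participants=12, seed=3)
profiles = generate_participants(cfg)
tasks = generate_attention_and_wm_trials(profiles, cfg)

measured = measured_profiles(profiles, tasks)
print("task-derived vs. generating capacities (first 5 participants):")
cols = ["boa", "exo", "viwm", "vsowm"]
for pid in profiles.index[:5]:
    got = "  ".join(f"{c}={measured.loc[pid, c]:6.2f}" for c in cols)
    true = "  ".join(f"{profiles.loc[pid, c]:6.2f}" for c in cols)
    print(f"  p{pid:02d}  measured: {got}")
    print(f"       planted:  {'     '.join(true.split())}")

print("\nexact-binomial chance thresholds (accuracy at or below => guessing):")
for n in (20, 80, 120):
    print(f"  {n:3d} trials -> {100 * binomial_chance_threshold(n, 0.05):.2f}%")

reports = apply_exclusions(_task_summaries(profiles, tasks))
table = exclusion_table(reports)
print(f"\nexclusions: {int((~table.kept).sum())}/{len(table)} participants"
      " flagged (catch-rate, task-accuracy, or WM-conjunction rules)")
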