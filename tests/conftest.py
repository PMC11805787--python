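import warnings

import numpy as np
import pandas as pd
import pytest

from spoarcnet.synthdata import GenConfig, generate_participants, generate_probe_trials

# constant design columns (e.g. no altL speakers drawn) are expected in
# small synthetic cohorts and are handled by dropping the column
warnings.filterwarnings("ignore", message="dropping constant design columns")


@pytest.fixture(scope="session")
def small_cohort():
    """24 participants x 25 trials at the published generating values."""
    cfg = GenConfig(n_participants=24, trials_per_participant_range=(25, 25), seed=7)
    profiles = generate_participants(cfg)
    trials, truth = generate_probe_trials(profiles, cfg)
    return cfg, profiles, trials, truth


@pytest.fixture()
def linear_probe_trials():
    """Noiseless linear RT profile: left 500 + 10*pos, right 600 - 10*pos."""
    rows = []
    for hand, intercept, slope in ((-1, 500.0, 10.0), (1, 600.0, -10.0)):
        for pos in range(1, 6):
            for _ in range(3):
                rows.append({"participant_id": 1, "task": 1, "hand": hand,
                             "position": pos, "rt_ms": intercept + slope * pos,
                             "correct": True, "probe_positive": True})
    return pd.DataFrame(rows)


def planted_two_block_graph(seed: int, block: int = 10, p_in: float = 0.9,
                            p_out: float = 0.05):
    """Stochastic-block-model binary graph with two planted blocks."""
    rng = np.random.default_rng(seed)
    n = 2 * block
    labels = np.repeat([0, 1], block)
    a = np.zeros((n, n), dtype=int)
    for i in range(n):
        for j in range(i + 1, n):
            p = p_in if labels[i] == labels[j] else p_out
            if rng.random() < p:
                a[i, j] = a[j, i] = 1
    return a, labels
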