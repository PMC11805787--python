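"""Synthetic item-probe trials following the two-level reaction-time model.

Each trial's RT is the fixed-effect linear predictor (level-1 design plus
grand-mean-centered cognitive moderators and uncentered demographic
controls) plus the participant's realized random effects over (intercept,
Hand x Position, Task, Task x Hand x Position) and a Gaussian residual.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .. import defaults
from .config import GenConfig, GroundTruth

__all__ = ["generate_probe_trials", "linear_predictor"]

# fixed-effect symbols for each cognitive measure's main effect and its
# Hand x Position cross-level interaction, in defaults.COGNITIVE_MEASURES order
_MAIN_BY_MEASURE = {"boa": "g01", "exo": "g02", "endo": "g03", "viwm": "g05",
                    "vsowm": "g06", "siwm": "g04", "ssowm": "g07"}
_CLI_BY_MEASURE = {"boa": "g31", "exo": "g32", "endo": "g33", "viwm": "g35",
                   "vsowm": "g36", "siwm": "g34", "ssowm": "g37"}
_DEMO_SYMBOLS = {"handedness": "g08", "altL": "g09", "school": "g010",
                 "education_years": "g011", "gender": "g012"}


def linear_predictor(hand, position, task, profile_row: pd.Series,
                     centered: pd.Series, gamma: dict[str, float]) -> np.ndarray:
    """Fixed-effect mean RT for trials of one participant."""
    hp = hand * position
    eta = (
        gamma["g00"]
        + gamma["g10"] * hand
        + gamma["g20"] * position
        + gamma["g30"] * hp
        + gamma["g40"] * task
        + gamma["g50"] * task * hp
    )
    for name, sym in _MAIN_BY_MEASURE.items():
        eta = eta + gamma[sym] * centered[name]
    for name, sym in _DEMO_SYMBOLS.items():
        eta = eta + gamma[sym] * profile_row[name]
    cli = sum(gamma[sym] * centered[name] for name, sym in _CLI_BY_MEASURE.items())
    cli += gamma["g347"] * centered["siwm"] * centered["ssowm"]
    return eta + cli * hp


def generate_probe_trials(profiles: pd.DataFrame,
                          config: GenConfig | None = None) -> tuple[pd.DataFrame, GroundTruth]:
    """Simulate correct positive-probe trials for every profile.

    Per participant the trial count is uniform on the configured range,
    ``hand`` is +-1, ``position`` uniform on 1..5 and ``task`` a fair coin
    over {1, 2}.  Negative RTs are re-drawn (default) or floored at 1 ms
    per ``config.negative_rt``; counts are recorded in the ground truth.
    """
    if profiles.empty:
        raise ValueError("profiles must be nonempty")
    config = config or GenConfig()
    gamma = config.fixed_effects
    tau = config.tau
    resid_sd = float(np.sqrt(config.sigma2))

    cognitive = [m for m in defaults.COGNITIVE_MEASURES if m in profiles.columns]
    centered_all = profiles[cognitive] - profiles[cognitive].mean()

    root = np.random.SeedSequence(config.seed)
    # one spawn consumed by the participant generator; trial streams follow
    streams = root.spawn(1 + len(profiles) + 1)
    u_rng = np.random.default_rng(streams[-1])
    if tau.any():
        # eigendecomposition root handles singular (boundary) tau
        vals, vecs = np.linalg.eigh(tau)
        root = vecs * np.sqrt(np.clip(vals, 0.0, None))
        u = u_rng.standard_normal((len(profiles), 4)) @ root.T
    else:
        u = np.zeros((len(profiles), 4))

    lo, hi = config.trials_per_participant_range
    frames = []
    n_redrawn = n_floored = 0
    for k, (pid, row) in enumerate(profiles.iterrows()):
        rng = np.random.default_rng(streams[1 + k])
        n_t = int(rng.integers(lo, hi + 1))
        hand = rng.choice([-1, 1], size=n_t)
        position = rng.integers(1, 6, size=n_t).astype(float)
        task = rng.integers(1, 3, size=n_t).astype(float)
        eta = linear_predictor(hand, position, task, row, centered_all.loc[pid], gamma)
        zmat = np.column_stack([np.ones(n_t), hand * position, task, task * hand * position])
        mu = eta + zmat @ u[k]
        rt = mu + rng.normal(0.0, resid_sd, size=n_t)
        neg = rt <= 0
        if config.negative_rt == "floor":
            n_floored += int(neg.sum())
            rt = np.where(neg, 1.0, rt)
        else:
            while neg.any():
                n_redrawn += int(neg.sum())
                rt[neg] = mu[neg] + rng.normal(0.0, resid_sd, size=int(neg.sum()))
                neg = rt <= 0
        frames.append(pd.DataFrame({
            "participant_id": pid,
            "task": task.astype(int),
            "hand": hand,
            "position": position.astype(int),
            "rt_ms": rt,
            "correct": True,
            "probe_positive": True,
        }))
    trials = pd.concat(frames, ignore_index=True)
    truth = GroundTruth(config=config, random_effects=u,
                        participant_ids=list(profiles.index),
                        n_redrawn_rts=n_redrawn, n_floored_rts=n_floored)
    return trials, truth
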