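"""Synthetic attention and working-memory task trials.

Three task families feed the behavioral measures:

* breadth of attention — 132 trials (33 cluster distances on a 0.5 cm
  grid, 4 trials each); accuracy falls off logistically with distance and
  crosses 75% at the profile's ``boa``;
* cueing (exogenous/endogenous orienting) — 168 trials: 126 valid, 22
  invalid, 20 catch; invalid-trial RTs exceed valid ones by the profile's
  cueing effect plus trial noise;
* sequence matching (verbal/spatial WM) — 120 trials in equal thirds of
  identical, item-changing and order-swapping; nonidentical-trial accuracy
  is Bernoulli at the profile's capacity.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import GenConfig

__all__ = ["generate_attention_and_wm_trials", "boa_accuracy_curve"]

N_BOA_TRIALS = 132
# 33 tested between-cluster distances spanning the measure's 0..86.8 cm range
BOA_DISTANCES = np.linspace(86.8 / 33, 86.8, 33)
N_CUEING = {"valid": 126, "invalid": 22, "catch": 20}
N_WM_TRIALS = 120
BOA_SLOPE_CM = 2.0
CUEING_NOISE_SD = 50.0
CUEING_BASE_RT = 350.0
CATCH_RESPONSE_P = 0.05
WM_IDENTICAL_ACC = 0.90


def boa_accuracy_curve(distance, breadth: float, *, slope: float = BOA_SLOPE_CM,
                       criterion: float = 0.75) -> np.ndarray:
    """P(correct) as a decreasing logistic of cluster distance.

    Calibrated so the curve crosses `criterion` exactly at ``breadth`` cm.
    """
    d0 = breadth + slope * np.log(criterion / (1 - criterion))
    return 1.0 / (1.0 + np.exp((np.asarray(distance, float) - d0) / slope))


def _boa_trials(rng, profile) -> pd.DataFrame:
    distance = np.repeat(BOA_DISTANCES, N_BOA_TRIALS // len(BOA_DISTANCES))
    p = boa_accuracy_curve(distance, float(profile["boa"]))
    return pd.DataFrame({
        "distance": distance,
        "correct": rng.random(distance.size) < p,
        "rt_ms": rng.normal(800.0, 150.0, distance.size).clip(150, 2900),
    })


def _cueing_trials(rng, effect_ms: float, *, noise_sd: float = CUEING_NOISE_SD) -> pd.DataFrame:
    kinds = np.repeat(list(N_CUEING), list(N_CUEING.values()))
    rng.shuffle(kinds)
    rt = rng.normal(CUEING_BASE_RT, noise_sd, kinds.size)
    rt[kinds == "invalid"] += effect_ms
    responded = np.ones(kinds.size, dtype=bool)
    responded[kinds == "catch"] = rng.random((kinds == "catch").sum()) < CATCH_RESPONSE_P
    rt[~responded] = np.nan
    return pd.DataFrame({
        "trial_type": kinds,
        "responded": responded,
        "correct": np.where(kinds == "catch", ~responded, True),
        "rt_ms": rt,
    })


def _wm_trials(rng, item_capacity: float, order_capacity: float) -> pd.DataFrame:
    per_type = N_WM_TRIALS // 3
    kinds = np.repeat(["identical", "item_change", "order_swap"], per_type)
    rng.shuffle(kinds)
    p = np.select(
        [kinds == "item_change", kinds == "order_swap"],
        [item_capacity, order_capacity],
        default=WM_IDENTICAL_ACC,
    )
    return pd.DataFrame({
        "trial_type": kinds,
        "correct": rng.random(kinds.size) < p,
        "rt_ms": rng.normal(1200.0, 300.0, kinds.size).clip(150, 2900),
    })


def generate_attention_and_wm_trials(profiles: pd.DataFrame,
                                     config: GenConfig | None = None,
                                     *, cueing_noise_sd: float = CUEING_NOISE_SD,
                                     ) -> dict[str, pd.DataFrame]:
    """Trial tables for the five capacity tasks, keyed by task name.

    Returns long tables (with a ``participant_id`` column) under keys
    'boa', 'exo', 'endo', 'verbal_wm', 'spatial_wm'.
    """
    if profiles.empty:
        raise ValueError("profiles must be nonempty")
    config = config or GenConfig()
    streams = np.random.SeedSequence((config.seed, 0xA77E)).spawn(len(profiles))

    out: dict[str, list[pd.DataFrame]] = {k: [] for k in
                                          ("boa", "exo", "endo", "verbal_wm", "spatial_wm")}
    for k, (pid, row) in enumerate(profiles.iterrows()):
        rng = np.random.default_rng(streams[k])
        tables = {
            "boa": _boa_trials(rng, row),
            "exo": _cueing_trials(rng, float(row["exo"]), noise_sd=cueing_noise_sd),
            "endo": _cueing_trials(rng, float(row["endo"]), noise_sd=cueing_noise_sd),
            "verbal_wm": _wm_trials(rng, float(row["viwm"]), float(row["vsowm"])),
            "spatial_wm": _wm_trials(rng, float(row["siwm"]), float(row["ssowm"])),
        }
        for key, table in tables.items():
            table.insert(0, "participant_id", pid)
            out[key].append(table)
    return {k: pd.concat(v, ignore_index=True) for k, v in out.items()}
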