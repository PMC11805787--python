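"""Per-participant SPoARC magnitude and group summaries.

The SPoARC (Spatial Position Association of Response Codes) effect is a
left-early / right-late response-time asymmetry for probed positions of a
memorized list.  Per participant it is quantified from correct,
positive-probe item-probe trials as the OLS slope of RT on probe serial
position fit separately within each responding hand; the magnitude is the
right-hand slope minus the left-hand slope.  Negative magnitudes indicate
the effect, and more negative means a larger effect.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .measures import TrimRule, trim_rts

__all__ = ["SpoarcMagnitude", "spoarc_magnitude", "spoarc_table", "group_spoarc_summary"]

MIN_TRIALS_PER_HAND = 5


@dataclass
class SpoarcMagnitude:
    participant_id: object
    slope_left: float      # ms per serial position
    slope_right: float
    magnitude: float       # slope_right - slope_left
    n_trials_used: int
    low_trials: bool = False  # flagged (not dropped) when a hand has <5 trials


def _ols_slope(position: np.ndarray, rt: np.ndarray) -> float:
    """Least-squares slope of rt on position; NaN if <2 distinct positions."""
    if np.unique(position).size < 2:
        return float("nan")
    pc = position - position.mean()
    return float(pc @ (rt - rt.mean()) / (pc @ pc))


def spoarc_magnitude(trials: pd.DataFrame, *, trim: bool = True) -> SpoarcMagnitude:
    """SPoARC magnitude for one participant's item-probe trials.

    `trials` needs columns ``hand`` (+1 right / -1 left), ``position``
    (1..5), ``rt_ms``, ``correct``, ``probe_positive`` and ``task``.  Only
    correct positive-probe trials enter the regression; trimming is applied
    per material type (task) before pooling, matching how the two probe
    tasks are preprocessed separately.
    """
    used = trials[(trials["correct"].astype(bool)) & (trials["probe_positive"].astype(bool))]
    if trim and not used.empty:
        rule = TrimRule.for_task("item_probe")
        keep = np.zeros(len(used), dtype=bool)
        for _, idx in used.groupby("task").indices.items():
            keep[idx] = trim_rts(used["rt_ms"].to_numpy()[idx], rule)
        used = used.iloc[keep]

    pid = trials["participant_id"].iloc[0] if "participant_id" in trials else None
    slopes = {}
    counts = {}
    for hand in (-1, 1):
        sub = used[used["hand"] == hand]
        counts[hand] = len(sub)
        slopes[hand] = (
            _ols_slope(sub["position"].to_numpy(float), sub["rt_ms"].to_numpy(float))
            if len(sub) >= 2 else float("nan")
        )
    magnitude = slopes[1] - slopes[-1]
    return SpoarcMagnitude(
        participant_id=pid,
        slope_left=slopes[-1],
        slope_right=slopes[1],
        magnitude=magnitude,
        n_trials_used=counts[-1] + counts[1],
        low_trials=min(counts.values()) < MIN_TRIALS_PER_HAND,
    )


def spoarc_table(trials: pd.DataFrame, *, trim: bool = True) -> pd.DataFrame:
    """Per-participant SPoARC slopes/magnitudes for a long trial table."""
    rows = []
    for pid, sub in trials.groupby("participant_id", sort=True):
        m = spoarc_magnitude(sub, trim=trim)
        rows.append(
            {
                "participant_id": pid,
                "slope_left": m.slope_left,
                "slope_right": m.slope_right,
                "magnitude": m.magnitude,
                "n_trials_used": m.n_trials_used,
                "low_trials": m.low_trials,
            }
        )
    return pd.DataFrame(rows)


def group_spoarc_summary(magnitudes) -> dict[str, float]:
    """Moment summary (mean, sd, min, max, skew, excess kurtosis) of magnitudes."""
    x = np.asarray(magnitudes, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 2:
        raise ValueError("need at least two finite magnitudes")
    return {
        "mean": float(x.mean()),
        "sd": float(x.std(ddof=1)),
        "min": float(x.min()),
        "max": float(x.max()),
        "skew": float(stats.skew(x)),
        "kurtosis": float(stats.kurtosis(x)),  # excess (normal = 0)
        "n": int(x.size),
    }
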