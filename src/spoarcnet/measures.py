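"""Trial-level trimming, participant exclusion, and the level-2 cognitive measures.

Reaction-time trimming follows the two-stage rule used throughout the task
battery: an absolute window (task-specific floor/ceiling) followed by an
interquartile fence of Q1 - 3*IQR .. Q3 + 3*IQR computed on the
window-surviving trials.  Participant exclusion applies exact-binomial
chance thresholds to task accuracies plus a catch-trial response rule and,
for the working-memory tasks, a conjunction of low accuracy and
implausibly fast responding relative to the group.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .defaults import RT_WINDOWS

__all__ = [
    "TrimRule",
    "ExclusionReport",
    "trim_rts",
    "binomial_chance_threshold",
    "compute_boa",
    "compute_cueing_effect",
    "compute_wm_capacities",
    "apply_exclusions",
]


@dataclass(frozen=True)
class TrimRule:
    """Two-stage RT trimming rule: absolute window then interquartile fences.

    Parameters
    ----------
    rt_floor, rt_ceiling
        Absolute window in ms; trials outside are "extreme" and removed first.
    fence_multiplier
        Fences are ``Q1 - m*IQR`` and ``Q3 + m*IQR`` computed on the
        window-surviving trials (default m = 3).
    quantile_method
        Quantile convention passed to :func:`numpy.quantile`; the default
        ``"linear"`` interpolates between order statistics.
    """

    rt_floor: float = 100.0
    rt_ceiling: float = 3000.0
    fence_multiplier: float = 3.0
    quantile_method: str = "linear"

    def __post_init__(self) -> None:
        if not self.rt_floor < self.rt_ceiling:
            raise ValueError("rt_floor must be below rt_ceiling")
        if self.fence_multiplier <= 0:
            raise ValueError("fence_multiplier must be positive")

    @classmethod
    def for_task(cls, task: str) -> "TrimRule":
        """Trimming window for a task family: 'boa', 'cueing', 'wm', 'item_probe'."""
        floor, ceiling = RT_WINDOWS[task]
        return cls(rt_floor=floor, rt_ceiling=ceiling)


def trim_rts(rts, rule: TrimRule = TrimRule()) -> np.ndarray:
    """Boolean keep-mask for a vector of RTs under a :class:`TrimRule`.

    The absolute window is applied first; quartiles and fences are then
    computed on the surviving values only, so one wild outlier cannot
    inflate the fences.  A constant surviving sample has IQR = 0 and
    degenerate fences equal to that constant, keeping everything.
    """
    rts = np.asarray(rts, dtype=float)
    if rts.size == 0:
        raise ValueError("rts must be nonempty")
    inside = (rts >= rule.rt_floor) & (rts <= rule.rt_ceiling)
    if not inside.any():
        warnings.warn("all RTs fall outside the absolute window; empty mask")
        return inside
    surviving = rts[inside]
    q1, q3 = np.quantile(surviving, [0.25, 0.75], method=rule.quantile_method)
    iqr = q3 - q1
    lo = q1 - rule.fence_multiplier * iqr
    hi = q3 + rule.fence_multiplier * iqr
    return inside & (rts >= lo) & (rts <= hi)


def binomial_chance_threshold(n_trials: int, alpha: float = 0.05) -> float:
    """Highest accuracy still consistent with guessing at one-sided level alpha.

    Returns ``k*/n_trials`` with ``k* = max{k : P(X >= k) > alpha}`` for
    ``X ~ Binomial(n_trials, 1/2)`` — accuracies at or below this proportion
    cannot be distinguished from coin-flipping.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    k = np.arange(n_trials + 1)
    upper_tail = stats.binom.sf(k - 1, n_trials, 0.5)  # P(X >= k)
    k_star = int(k[upper_tail > alpha].max())
    return k_star / n_trials


def compute_boa(trials: pd.DataFrame, *, criterion: float = 0.75,
                monotone: bool = False) -> float:
    """Breadth of attention (cm) from trimmed divided-attention trials.

    `trials` needs columns ``distance`` (cm, on the 0.5 cm grid) and
    ``correct`` (0/1).  Returns the largest tested cluster distance whose
    accuracy exceeds `criterion`, or 0.0 if none does.  With
    ``monotone=True`` the largest distance such that *all* smaller tested
    distances also exceed the criterion is returned instead (a stricter
    reading for non-monotonic accuracy profiles).
    """
    if trials.empty:
        raise ValueError("no trials")
    acc = trials.groupby("distance")["correct"].mean().sort_index()
    above = acc > criterion
    if not above.any():
        return 0.0
    if monotone:
        run = above.cummin()
        if not run.iloc[0]:
            return 0.0
        return float(acc.index[run].max())
    return float(acc.index[above].max())


def compute_cueing_effect(valid_rts, invalid_rts) -> float:
    """Cueing effect in ms: mean invalid RT minus mean valid RT.

    Positive values indicate efficient orienting toward the cued location.
    """
    valid_rts = np.asarray(valid_rts, dtype=float)
    invalid_rts = np.asarray(invalid_rts, dtype=float)
    if valid_rts.size == 0 or invalid_rts.size == 0:
        raise ValueError("both trial lists must be nonempty after trimming")
    return float(invalid_rts.mean() - valid_rts.mean())


def compute_wm_capacities(trials: pd.DataFrame) -> tuple[float, float]:
    """(item capacity, order capacity) from nonidentical sequence-matching trials.

    Item capacity is mean correctness over item-changing trials, order
    capacity over order-swapping trials.  `trials` needs columns
    ``trial_type`` in {'item_change', 'order_swap'} and ``correct``.
    """
    out = []
    for ttype in ("item_change", "order_swap"):
        sub = trials.loc[trials["trial_type"] == ttype, "correct"]
        if sub.empty:
            raise ValueError(f"no {ttype} trials")
        out.append(float(sub.mean()))
    return out[0], out[1]


@dataclass
class ExclusionReport:
    """Per-participant exclusion outcome; ``kept`` iff ``reasons`` is empty."""

    participant_id: object
    kept: bool = True
    reasons: list[str] = field(default_factory=list)

    def flag(self, reason: str) -> None:
        self.reasons.append(reason)
        self.kept = False


# summary columns checked against the chance threshold for the given trial count
_ACCURACY_RULES = [
    ("exo_accuracy", 168, "exo_task_accuracy"),
    ("endo_accuracy", 168, "endo_task_accuracy"),
    ("consonant_accuracy", 80, "consonant_probe_accuracy"),
    ("color_accuracy", 80, "color_probe_accuracy"),
]

_WM_RULES = [
    ("verbal_wm_accuracy", "verbal_wm_mean_rt", "verbal_wm_guessing"),
    ("spatial_wm_accuracy", "spatial_wm_mean_rt", "spatial_wm_guessing"),
]


def apply_exclusions(summaries: pd.DataFrame, *, alpha: float = 0.05,
                     n_catch: int = 20, n_wm: int = 120,
                     fence_multiplier: float = 3.0) -> list[ExclusionReport]:
    """Apply the participant-level guessing screens to task summaries.

    Expected columns of `summaries` (missing columns simply skip their
    rule): ``participant_id``; ``exo_catch_response_rate`` /
    ``endo_catch_response_rate``; the accuracies listed in
    ``_ACCURACY_RULES``; and for each WM task an accuracy plus mean-RT
    column.  Rules, in order:

    1. catch-trial rule — responding on more than ``1 - threshold(n_catch)``
       of catch trials (i.e. catch accuracy at or below the 20-trial
       chance level, 70%);
    2. task-accuracy rules — accuracy at or below the exact-binomial
       chance threshold for that task's trial count;
    3. WM conjunction rule — accuracy below the ``n_wm`` threshold AND
       mean RT below ``Q1 - m*IQR`` of the group's mean-RT distribution,
       so slow-but-inaccurate participants are retained.
    """
    catch_limit = 1.0 - binomial_chance_threshold(n_catch, alpha)  # 0.30
    wm_threshold = binomial_chance_threshold(n_wm, alpha)

    reports = []
    for _, row in summaries.iterrows():
        rep = ExclusionReport(row["participant_id"])
        for col in ("exo_catch_response_rate", "endo_catch_response_rate"):
            if col in summaries.columns and row[col] > catch_limit:
                rep.flag(col.replace("_response_rate", "_rate"))
        for col, n_trials, reason in _ACCURACY_RULES:
            if col in summaries.columns and row[col] <= binomial_chance_threshold(n_trials, alpha):
                rep.flag(reason)
        for acc_col, rt_col, reason in _WM_RULES:
            if acc_col not in summaries.columns:
                continue
            group_rts = summaries[rt_col].to_numpy(dtype=float)
            q1, q3 = np.quantile(group_rts, [0.25, 0.75])
            fast_fence = q1 - fence_multiplier * (q3 - q1)
            if row[acc_col] < wm_threshold and row[rt_col] < fast_fence:
                rep.flag(reason)
        reports.append(rep)
    return reports


def exclusion_table(reports: list[ExclusionReport]) -> pd.DataFrame:
    """Exclusion reports as a DataFrame with semicolon-joined reason codes."""
    return pd.DataFrame(
        {
            "participant_id": [r.participant_id for r in reports],
            "kept": [r.kept for r in reports],
            "reasons": [";".join(r.reasons) for r in reports],
        }
    )
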