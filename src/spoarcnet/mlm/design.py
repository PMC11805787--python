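"""Model specification and design-matrix construction for the RT mixed model.

The full model regresses trial RT on the level-1 trial terms (Hand,
Position, Hand x Position, Task, Task x Hand x Position), the seven
grand-mean-centered cognitive measures plus five uncentered demographic
controls at level 2, seven measure x Hand x Position cross-level
interactions and one four-way siwm x ssowm x Hand x Position term, with
by-participant random intercept and slopes for Hand x Position, Task and
Task x Hand x Position under an unstructured covariance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ..defaults import COGNITIVE_MEASURES, RANDOM_TERMS

__all__ = ["ModelSpec", "grand_mean_center", "build_design", "SYMBOL_BY_COLUMN"]

DEMOGRAPHICS = ("handedness", "altL", "school", "education_years", "gender")

#: design-column name -> published gamma symbol
SYMBOL_BY_COLUMN = {
    "intercept": "g00",
    "hand": "g10",
    "position": "g20",
    "hand:position": "g30",
    "task": "g40",
    "task:hand:position": "g50",
    "boa_c": "g01", "exo_c": "g02", "endo_c": "g03", "viwm_c": "g05",
    "vsowm_c": "g06", "siwm_c": "g04", "ssowm_c": "g07",
    "handedness": "g08", "altL": "g09", "school": "g010",
    "education_years": "g011", "gender": "g012",
    "boa_c:hand:position": "g31", "exo_c:hand:position": "g32",
    "endo_c:hand:position": "g33", "viwm_c:hand:position": "g35",
    "vsowm_c:hand:position": "g36", "siwm_c:hand:position": "g34",
    "ssowm_c:hand:position": "g37",
    "siwm_c:ssowm_c:hand:position": "g347",
}


@dataclass(frozen=True)
class ModelSpec:
    """Which blocks of terms enter the model and how it is estimated.

    ``estimation`` is 'REML' (coefficient estimates and SEs) or 'FIML'
    (full-information ML; deviance/AIC/BIC for model comparison).
    """

    l1_terms: bool = True
    l2_cognitive: bool = True
    l2_controls: bool = True
    cross_level: bool = True
    random_terms: tuple[str, ...] = RANDOM_TERMS
    estimation: str = "REML"

    def __post_init__(self) -> None:
        if self.estimation not in ("REML", "FIML"):
            raise ValueError("estimation must be 'REML' or 'FIML'")
        unknown = set(self.random_terms) - set(RANDOM_TERMS)
        if unknown:
            raise ValueError(f"unknown random terms: {sorted(unknown)}")
        if self.random_terms and "intercept" not in self.random_terms:
            raise ValueError("a nonempty random structure must include the intercept")
        if self.cross_level and not self.l1_terms:
            raise ValueError("cross-level interactions require the level-1 terms")
        slopes_need_l1 = set(self.random_terms) - {"intercept"}
        if slopes_need_l1 and not self.l1_terms:
            raise ValueError("random slopes require the level-1 terms")

    @classmethod
    def null(cls) -> "ModelSpec":
        """Intercept-only model with a by-participant random intercept."""
        return cls(l1_terms=False, l2_cognitive=False, l2_controls=False,
                   cross_level=False, random_terms=("intercept",))

    @classmethod
    def full(cls, estimation: str = "REML") -> "ModelSpec":
        return cls(estimation=estimation)


def grand_mean_center(values) -> np.ndarray:
    """Subtract the grand mean; output mean is 0 to machine precision."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("values must be nonempty")
    return values - values.mean()


@dataclass
class Design:
    X: np.ndarray
    y: np.ndarray
    Z: np.ndarray
    groups: np.ndarray            # dense 0..G-1 group codes per row
    x_names: list[str]
    z_names: list[str]
    group_ids: list
    dropped: list[str] = field(default_factory=list)


def build_design(trials: pd.DataFrame, profiles: pd.DataFrame | None,
                 spec: ModelSpec) -> Design:
    """Assemble fixed (X) and random (Z) design matrices from long trials.

    Cognitive measures are grand-mean-centered over the participants
    present in `trials`.  Constant fixed-effect columns (possible in small
    cohorts, e.g. no left-handers drawn) are dropped with a warning and
    reported in ``Design.dropped``.
    """
    pid = trials["participant_id"].to_numpy()
    group_ids, groups = np.unique(pid, return_inverse=True)

    hand = trials["hand"].to_numpy(float)
    position = trials["position"].to_numpy(float)
    task = trials["task"].to_numpy(float)
    hp = hand * position
    y = trials["rt_ms"].to_numpy(float)

    cols: dict[str, np.ndarray] = {"intercept": np.ones(len(trials))}
    if spec.l1_terms:
        cols.update({"hand": hand, "position": position, "hand:position": hp,
                     "task": task, "task:hand:position": task * hp})

    centered: dict[str, np.ndarray] = {}
    if spec.l2_cognitive or spec.cross_level:
        if profiles is None:
            raise ValueError("profiles required for level-2 terms")
        prof = profiles.loc[group_ids]
        for m in COGNITIVE_MEASURES:
            centered[m] = grand_mean_center(prof[m].to_numpy())[groups]
    if spec.l2_cognitive:
        for m in COGNITIVE_MEASURES:
            cols[f"{m}_c"] = centered[m]
    if spec.l2_controls:
        prof = profiles.loc[group_ids]
        for d in DEMOGRAPHICS:
            cols[d] = prof[d].to_numpy(float)[groups]
    if spec.cross_level:
        for m in COGNITIVE_MEASURES:
            cols[f"{m}_c:hand:position"] = centered[m] * hp
        cols["siwm_c:ssowm_c:hand:position"] = centered["siwm"] * centered["ssowm"] * hp

    dropped = [name for name, v in cols.items()
               if name != "intercept" and np.ptp(v) == 0]
    if dropped:
        warnings.warn(f"dropping constant design columns: {dropped}")
        for name in dropped:
            del cols[name]

    z_cols = {"intercept": np.ones(len(trials)), "hand_position": hp,
              "task": task, "task_hand_position": task * hp}
    z_names = [t for t in RANDOM_TERMS if t in spec.random_terms]

    X = np.column_stack(list(cols.values()))
    Z = (np.column_stack([z_cols[t] for t in z_names])
         if z_names else np.empty((len(trials), 0)))
    return Design(X=X, y=y, Z=Z, groups=groups, x_names=list(cols),
                  z_names=z_names, group_ids=list(group_ids), dropped=dropped)
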