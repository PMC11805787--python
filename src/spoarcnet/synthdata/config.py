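"""Generator configuration and ground-truth bookkeeping."""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np

from .. import defaults

__all__ = ["GenConfig", "GroundTruth", "nearest_psd"]


def nearest_psd(matrix: np.ndarray) -> np.ndarray:
    """Nearest (in eigenvalue clipping sense) PSD matrix with unit diagonal kept."""
    sym = (matrix + matrix.T) / 2
    vals, vecs = np.linalg.eigh(sym)
    repaired = vecs @ np.diag(np.clip(vals, 0, None)) @ vecs.T
    d = np.sqrt(np.clip(np.diag(repaired), 1e-12, None))
    repaired = repaired / np.outer(d, d)
    np.fill_diagonal(repaired, 1.0)
    return repaired


@dataclass
class GenConfig:
    """All knobs of the synthetic cohort, defaulting to the published tables.

    ``fixed_effects`` are the reaction-time model coefficients (ms),
    ``l2_means_sds`` the marginal (mean, sd, min, max) of each cognitive
    measure, ``l2_spearman`` their rank-correlation matrix, and
    ``tau``/``sigma2`` the random-effect covariance and residual variance.
    ``negative_rt`` chooses how impossible (negative) generated RTs are
    handled: 're-draw' (default) or 'floor' at 1 ms.
    """

    n_participants: int = defaults.N_PARTICIPANTS
    trials_per_participant_range: tuple[int, int] = defaults.TRIALS_PER_PARTICIPANT
    fixed_effects: dict[str, float] = field(default_factory=lambda: dict(defaults.FIXED_EFFECTS))
    l2_means_sds: dict[str, tuple] = field(default_factory=lambda: dict(defaults.L2_MARGINALS))
    l2_spearman: np.ndarray = field(default_factory=lambda: defaults.L2_SPEARMAN.copy())
    tau: np.ndarray = field(default_factory=lambda: defaults.TAU.copy())
    sigma2: float = defaults.SIGMA2
    seed: int = 0
    negative_rt: str = "re-draw"        # or "floor"
    repair_non_psd: bool = True          # nearest-PSD repair vs. rejection

    def __post_init__(self) -> None:
        lo, hi = self.trials_per_participant_range
        if not (1 <= lo <= hi <= 160):
            raise ValueError("trial range must lie within [1, 160]")
        if self.negative_rt not in ("re-draw", "floor"):
            raise ValueError("negative_rt must be 're-draw' or 'floor'")
        self.l2_spearman = np.asarray(self.l2_spearman, dtype=float)
        if not np.allclose(self.l2_spearman, self.l2_spearman.T):
            raise ValueError("l2_spearman must be symmetric")
        if not np.allclose(np.diag(self.l2_spearman), 1.0):
            raise ValueError("l2_spearman must have unit diagonal")
        self.tau = np.asarray(self.tau, dtype=float)
        if np.linalg.eigvalsh(self.tau).min() < -1e-8 * max(1.0, np.abs(self.tau).max()):
            if not self.repair_non_psd:
                raise ValueError("tau is not positive semi-definite")
            warnings.warn("tau not PSD; clipping negative eigenvalues")
            vals, vecs = np.linalg.eigh((self.tau + self.tau.T) / 2)
            self.tau = vecs @ np.diag(np.clip(vals, 0, None)) @ vecs.T
        if self.sigma2 < 0:
            raise ValueError("sigma2 must be nonnegative")


@dataclass
class GroundTruth:
    """Generating parameters plus realized latent quantities, for recovery tests."""

    config: GenConfig
    random_effects: Optional[np.ndarray] = None      # n_participants x 4 (u0,u3,u4,u5)
    participant_ids: Optional[list] = None
    planted_partition: Optional[np.ndarray] = None
    n_redrawn_rts: int = 0
    n_floored_rts: int = 0

    def to_json(self, path) -> None:
        payload = {
            "config": {
                k: (v.tolist() if isinstance(v, np.ndarray) else v)
                for k, v in asdict(self.config).items()
            },
            "random_effects": None if self.random_effects is None else self.random_effects.tolist(),
            "participant_ids": self.participant_ids,
            "planted_partition": None if self.planted_partition is None else self.planted_partition.tolist(),
            "n_redrawn_rts": self.n_redrawn_rts,
            "n_floored_rts": self.n_floored_rts,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)
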