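"""Correlated Gaussian samples for correlation / dependent-correlation tests."""

from __future__ import annotations

import numpy as np

__all__ = ["generate_brain_behavior_pairs", "generate_trivariate"]


def generate_brain_behavior_pairs(n: int, true_r: float, seed: int = 0) -> np.ndarray:
    """n x 2 bivariate standard-normal draws with correlation ``true_r``."""
    if not abs(true_r) <= 1:
        raise ValueError("|true_r| must be <= 1")
    cov = np.array([[1.0, true_r], [true_r, 1.0]])
    rng = np.random.default_rng(seed)
    chol = np.linalg.cholesky(cov + 1e-15 * np.eye(2))
    return rng.standard_normal((n, 2)) @ chol.T


def generate_trivariate(n: int, corr: np.ndarray, seed: int = 0) -> np.ndarray:
    """n x 3 standard-normal draws with the requested correlation matrix."""
    corr = np.asarray(corr, dtype=float)
    if corr.shape != (3, 3) or not np.allclose(corr, corr.T):
        raise ValueError("corr must be a symmetric 3x3 matrix")
    if np.linalg.eigvalsh(corr).min() < -1e-10:
        raise ValueError("requested correlation matrix is not PSD")
    vals, vecs = np.linalg.eigh(corr)
    root = vecs @ np.diag(np.sqrt(np.clip(vals, 0, None)))
    rng = np.random.default_rng(seed)
    return rng.standard_normal((n, 3)) @ root.T
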