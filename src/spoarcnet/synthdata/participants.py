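"""Synthetic participant profiles: copula-correlated cognitive measures.

The seven cognitive measures are drawn from a Gaussian copula whose normal
scores carry the published rank correlations (Spearman rho mapped to the
latent Pearson scale via r = 2 sin(pi * rho / 6)), with each marginal a
truncated normal on the measure's observed [min, max].  The parent (mu,
sigma) of each truncated marginal is solved numerically so the *truncated*
distribution matches the published mean/SD; sampling goes through the
truncated inverse CDF, which keeps the copula's rank structure exact.
"""

from __future__ import annotations

import warnings
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .. import defaults
from .config import GenConfig, nearest_psd

__all__ = ["generate_participants", "matched_parent_params"]


@lru_cache(maxsize=64)
def matched_parent_params(mean: float, sd: float, lo: float, hi: float) -> tuple[float, float]:
    """Parent (mu, sigma) whose [lo, hi]-truncation has the target mean/SD.

    Solved by least squares on (mu, log sigma); for targets slightly
    outside the truncated-normal family (heavy skew against a nearby
    bound) the best attainable fit is returned.
    """

    def moments(mu: float, sigma: float) -> tuple[float, float]:
        a, b = (lo - mu) / sigma, (hi - mu) / sigma
        d = stats.truncnorm(a, b, loc=mu, scale=sigma)
        return d.mean(), d.std()

    def resid(p):
        m, s = moments(p[0], np.exp(p[1]))
        return [(m - mean) / sd, (s - sd) / sd]

    sol = optimize.least_squares(resid, [mean, np.log(sd)], xtol=1e-12, ftol=1e-12)
    return float(sol.x[0]), float(np.exp(sol.x[1]))


def _latent_correlation(spearman: np.ndarray, repair: bool) -> np.ndarray:
    latent = 2 * np.sin(np.pi * spearman / 6)
    np.fill_diagonal(latent, 1.0)
    if np.linalg.eigvalsh(latent).min() < -1e-10:
        if not repair:
            raise ValueError("latent correlation matrix is not positive semi-definite")
        warnings.warn("latent correlation not PSD; applying nearest-PSD repair")
        latent = nearest_psd(latent)
    return latent


def generate_participants(config: GenConfig | None = None) -> pd.DataFrame:
    """Simulate a cohort of participant profiles.

    Returns a DataFrame indexed by ``participant_id`` with the seven
    cognitive measures and the demographic covariates ``handedness``
    (1 left / 2 right), ``altL`` (0/1), ``school`` (1/2),
    ``education_years`` and ``gender`` (1 male / 2 female).
    """
    config = config or GenConfig()
    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(1)[0])
    n = config.n_participants
    measures = list(config.l2_means_sds)

    latent = _latent_correlation(config.l2_spearman, config.repair_non_psd)
    z = rng.multivariate_normal(np.zeros(len(measures)), latent, size=n,
                                method="cholesky")
    u = stats.norm.cdf(z)

    cols = {}
    for j, name in enumerate(measures):
        mean, sd, lo, hi = config.l2_means_sds[name]
        if sd == 0:
            cols[name] = np.full(n, mean)
            continue
        mu, sigma = matched_parent_params(mean, sd, lo, hi)
        a, b = (lo - mu) / sigma, (hi - mu) / sigma
        cols[name] = stats.truncnorm.ppf(u[:, j], a, b, loc=mu, scale=sigma)

    demo = defaults.DEMOGRAPHICS
    edu = np.rint(rng.normal(demo["education_mean"], demo["education_sd"], n))
    edu = np.clip(edu, *demo["education_range"])
    cols.update(
        handedness=np.where(rng.random(n) < demo["p_right_handed"], 2, 1),
        altL=(rng.random(n) < demo["p_altL"]).astype(int),
        school=np.where(rng.random(n) < demo["p_school2"], 2, 1),
        education_years=edu,
        gender=np.where(rng.random(n) < demo["p_female"], 2, 1),
    )
    profiles = pd.DataFrame(cols, index=pd.RangeIndex(1, n + 1, name="participant_id"))
    return profiles
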