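"""Brain-behavior correlations and dependent-correlation (Steiger) comparisons.

Across participants, the SPoARC magnitude is correlated with the
modularity of networks at several scales, and the correlations at
different scales are compared with Steiger's Z for two dependent
correlations sharing one variable (the behavior).  Sign convention: a
*positive* modularity-magnitude correlation means lower modularity goes
with a more negative (i.e. larger) SPoARC effect.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["SteigerResult", "pearson_r", "steiger_test", "scale_comparison"]


def pearson_r(x, y) -> tuple[float, float]:
    """Sample Pearson correlation with its two-sided t-test p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("x and y must be equal-length with n >= 3")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("inputs must be finite")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance input")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


@dataclass
class SteigerResult:
    z: float
    p: float
    n: int
    r_jk: float
    r_jh: float
    r_kh: float
    alternative: str = "two-sided"


def steiger_test(r_jk: float, r_jh: float, r_kh: float, n: int,
                 *, alternative: str = "two-sided") -> SteigerResult:
    """Steiger's Z for H0: rho_jk = rho_jh with a shared variable j.

    Tests whether variable j (here: behavior) correlates differently with k
    and h (here: modularity at two scales) using Fisher-z transforms with
    the dependent-correlation covariance correction evaluated at the
    pooled correlation (Z1* variant).  ``alternative`` is 'two-sided',
    'greater' (rho_jk > rho_jh) or 'less'.
    """
    for r in (r_jk, r_jh):
        if not abs(r) < 1:
            raise ValueError("compared correlations must satisfy |r| < 1")
    if not abs(r_kh) <= 1:
        raise ValueError("|r_kh| must be <= 1")
    if n < 4:
        raise ValueError("n must be >= 4")
    corr = np.array([[1, r_jk, r_jh], [r_jk, 1, r_kh], [r_jh, r_kh, 1]])
    if np.linalg.eigvalsh(corr).min() < -1e-10:
        raise ValueError("correlation triplet is not positive semi-definite")

    z_jk, z_jh = np.arctanh(r_jk), np.arctanh(r_jh)
    r_bar = (r_jk + r_jh) / 2.0
    # covariance between the two dependent correlations at the pooled value
    psi = r_kh * (1 - 2 * r_bar**2) - 0.5 * r_bar**2 * (1 - 2 * r_bar**2 - r_kh**2)
    s = min(psi / (1 - r_bar**2) ** 2, 1.0 - 1e-12)
    z = 0.0 if z_jk == z_jh else (z_jk - z_jh) * np.sqrt((n - 3) / (2 - 2 * s))

    if alternative == "two-sided":
        p = 2 * stats.norm.sf(abs(z))
    elif alternative == "greater":
        p = stats.norm.sf(z)
    elif alternative == "less":
        p = stats.norm.cdf(z)
    else:
        raise ValueError("alternative must be 'two-sided', 'greater' or 'less'")
    return SteigerResult(float(z), float(p), int(n), r_jk, r_jh, r_kh, alternative)


def scale_comparison(spoarc: pd.Series, modularity_by_scale: dict[str, pd.Series],
                     *, alternative: str = "two-sided") -> dict[str, pd.DataFrame]:
    """Correlate behavior with modularity per scale and compare scales pairwise.

    All inputs are participant-indexed Series; indices must align exactly
    (a missing participant in any vector raises).  Returns
    ``{'correlations': ..., 'comparisons': ...}`` DataFrames.
    """
    index = spoarc.index
    for name, values in modularity_by_scale.items():
        if not index.sort_values().equals(values.index.sort_values()):
            raise ValueError(f"participants misaligned between behavior and scale '{name}'")

    behavior = spoarc.sort_index()
    n = len(behavior)
    aligned = {k: v.sort_index() for k, v in modularity_by_scale.items()}

    corr_rows = []
    for name, values in aligned.items():
        r, p = pearson_r(behavior.to_numpy(), values.to_numpy())
        corr_rows.append({"scale": name, "r": r, "p": p, "n": n})
    correlations = pd.DataFrame(corr_rows)

    comp_rows = []
    names = list(aligned)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            r_jk, _ = pearson_r(behavior.to_numpy(), aligned[a].to_numpy())
            r_jh, _ = pearson_r(behavior.to_numpy(), aligned[b].to_numpy())
            r_kh, _ = pearson_r(aligned[a].to_numpy(), aligned[b].to_numpy())
            res = steiger_test(r_jk, r_jh, r_kh, n, alternative=alternative)
            comp_rows.append(
                {"scale_a": a, "scale_b": b, "r_a": r_jk, "r_b": r_jh,
                 "r_ab": r_kh, "z": res.z, "p": res.p}
            )
    comparisons = pd.DataFrame(comp_rows)
    return {"correlations": correlations, "comparisons": comparisons}
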