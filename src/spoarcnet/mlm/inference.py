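"""Probing cross-level moderation: Johnson-Neyman regions and simple slopes.

For a moderator w, the conditional (simple) Hand x Position effect is
``g_f + g_c w`` with sampling variance ``var(g_f) + 2w cov + w^2 var(g_c)``
from the fixed-effect covariance.  The Johnson-Neyman boundaries are the
real roots of ``(g_f + g_c w)^2 = t_crit^2 var(w)`` — a quadratic in w —
and the pick-a-point approach evaluates per-hand Position slopes and
their right-minus-left difference at chosen moderator levels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .fit import FitResult

__all__ = ["JNRegion", "johnson_neyman", "simple_slopes", "default_levels"]

FOCAL = "hand:position"


def _cli_column(moderator: str) -> str:
    return f"{moderator}_c:hand:position"


@dataclass
class JNRegion:
    moderator: str
    boundaries: tuple[float, ...]     # sorted, on the centered moderator scale
    significant: str                  # 'everywhere' | 'nowhere' | 'below' | 'above' | 'outside' | 'between'
    alpha: float
    t_crit: float

    def is_significant(self, w) -> np.ndarray:
        """Vectorized membership test on the centered moderator scale."""
        w = np.asarray(w, dtype=float)
        if self.significant == "everywhere":
            return np.ones_like(w, dtype=bool)
        if self.significant == "nowhere":
            return np.zeros_like(w, dtype=bool)
        if self.significant == "below":
            return w <= self.boundaries[0]
        if self.significant == "above":
            return w >= self.boundaries[0]
        lo, hi = self.boundaries
        inside = (w >= lo) & (w <= hi)
        return inside if self.significant == "between" else ~inside


def johnson_neyman(fit: FitResult, moderator: str, *, alpha: float = 0.05,
                   focal: str = FOCAL, dist: str = "t") -> JNRegion:
    """Region of moderator values where the simple focal effect is significant.

    The critical value uses the t distribution at the cross-level
    coefficient's Satterthwaite df (``dist='normal'`` for the z version).
    Boundaries are reported on the centered moderator scale used in the
    fit; callers restrict to the observed range when probing.
    """
    cli = _cli_column(moderator)
    for col in (focal, cli):
        if col not in fit.params.index:
            raise ValueError(f"fit lacks required coefficient '{col}'")
    gf, gc = fit.params[focal], fit.params[cli]
    vf = fit.cov_params.loc[focal, focal]
    vc = fit.cov_params.loc[cli, cli]
    cfc = fit.cov_params.loc[focal, cli]
    if vf <= 0 or vc < 0:
        raise ValueError("nonpositive coefficient variances")
    if dist == "t":
        t_crit = float(stats.t.ppf(1 - alpha / 2, fit.df[cli]))
    elif dist == "normal":
        t_crit = float(stats.norm.ppf(1 - alpha / 2))
    else:
        raise ValueError("dist must be 't' or 'normal'")

    # (gc^2 - t^2 vc) w^2 + 2 (gf gc - t^2 cfc) w + (gf^2 - t^2 vf) = 0
    a = gc**2 - t_crit**2 * vc
    b = 2 * (gf * gc - t_crit**2 * cfc)
    c = gf**2 - t_crit**2 * vf
    disc = b**2 - 4 * a * c

    def sig_at(w: float) -> bool:
        var = vf + 2 * w * cfc + w**2 * vc
        return abs(gf + gc * w) > t_crit * np.sqrt(var)

    if abs(a) < 1e-300:
        roots = () if abs(b) < 1e-300 else (-c / b,)
    elif disc < 0:
        roots = ()
    else:
        sq = np.sqrt(disc)
        roots = tuple(sorted(((-b - sq) / (2 * a), (-b + sq) / (2 * a))))

    if len(roots) == 0:
        significant = "everywhere" if sig_at(0.0) else "nowhere"
    elif len(roots) == 1:
        significant = "below" if sig_at(roots[0] - 1.0) else "above"
    else:
        mid = (roots[0] + roots[1]) / 2
        significant = "between" if sig_at(mid) else "outside"
    return JNRegion(moderator=moderator, boundaries=tuple(float(r) for r in roots),
                    significant=significant, alpha=alpha, t_crit=t_crit)


def default_levels(mean: float, sd: float) -> tuple[float, float, float]:
    """Pick-a-point levels: (mean - SD, mean, mean + SD)."""
    return (mean - sd, mean, mean + sd)


def simple_slopes(fit: FitResult, moderator: str, levels, *,
                  moderator_mean: float = 0.0, task_value: float = 1.5,
                  region: JNRegion | None = None,
                  observed_range: tuple[float, float] | None = None) -> pd.DataFrame:
    """Per-hand Position slopes and their difference at moderator levels.

    `levels` are on the raw moderator scale; ``moderator_mean`` converts
    them to the centered scale of the fit.  The Position slope for hand h
    is ``g20 + h*(g30 + g50*task + g_c w)`` with other moderators at their
    grand mean (0 on the centered scale); the SPoARC magnitude at level w
    is the right-minus-left difference ``2*(g30 + g50*task + g_c w)`` with
    a delta-method SE.  Levels outside `region` or `observed_range` are
    flagged, not silently dropped.
    """
    cli = _cli_column(moderator)
    names = ["position", FOCAL, "task:hand:position", cli]
    for col in names:
        if col not in fit.params.index:
            raise ValueError(f"fit lacks required coefficient '{col}'")
    g20 = fit.params["position"]

    rows = []
    for level in levels:
        w = level - moderator_mean
        # contrast for the conditional Hand x Position effect
        contrast = pd.Series(0.0, index=fit.params.index)
        contrast[FOCAL] = 1.0
        contrast["task:hand:position"] = task_value
        contrast[cli] = w
        eff = float(contrast @ fit.params)
        var_eff = float(contrast @ fit.cov_params @ contrast)
        in_region = bool(region.is_significant(w)) if region is not None else True
        in_range = (observed_range is None
                    or observed_range[0] <= level <= observed_range[1])
        rows.append({
            "level": float(level),
            "slope_left": float(g20 - eff),
            "slope_right": float(g20 + eff),
            "difference": 2 * eff,
            "se_difference": 2 * np.sqrt(var_eff),
            "in_jn_region": in_region,
            "in_observed_range": in_range,
        })
    return pd.DataFrame(rows)
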