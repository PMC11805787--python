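"""Gaussian linear mixed model with one grouping factor.

The marginal model is ``y_i = X_i gamma + Z_i u_i + eps_i`` per
participant i, with ``u_i ~ N(0, tau)`` (unstructured q x q covariance)
and ``eps_i ~ N(0, sigma2 I)``.  Estimation profiles both gamma and
sigma2 out of the (restricted) deviance and optimizes the relative
random-effect Cholesky factor Lambda (tau = sigma2 * Lambda Lambda') on
the log-Cholesky scale, so tau stays positive semi-definite including at
the boundary.  Only the per-group cross-product matrices enter the
criterion, which makes every evaluation O(G q^2 (p + q)) regardless of
trial counts.

Satterthwaite degrees of freedom use the delta method: for each
coefficient, df = 2 f^2 / (grad f' Vtheta grad f) with f the coefficient's
sampling variance as a function of the variance parameters, the gradient
taken numerically, and Vtheta = 2 H^-1 from the numerical Hessian of the
restricted deviance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .design import ModelSpec, build_design, SYMBOL_BY_COLUMN

__all__ = ["FitResult", "fit_lmm", "icc", "compare_models"]


@dataclass
class FitResult:
    params: pd.Series
    se: pd.Series
    tstat: pd.Series
    df: pd.Series                # Satterthwaite denominator df
    pvalues: pd.Series
    cov_params: pd.DataFrame
    sigma2: float
    tau: pd.DataFrame
    loglik: float
    deviance: float              # -2 * loglik on the fit's own criterion
    aic: float
    bic: float
    n_params: int
    method: str                  # 'REML' or 'FIML'
    converged: bool
    n_obs: int
    n_groups: int
    spec: ModelSpec
    dropped: list[str] = field(default_factory=list)
    optimizer_message: str = ""

    @property
    def gamma(self) -> dict[str, tuple]:
        """Published-symbol view: symbol -> (estimate, se, t, df, p)."""
        out = {}
        for name in self.params.index:
            sym = SYMBOL_BY_COLUMN.get(name)
            if sym:
                out[sym] = (self.params[name], self.se[name], self.tstat[name],
                            self.df[name], self.pvalues[name])
        return out

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame({"estimate": self.params, "se": self.se,
                             "t": self.tstat, "df": self.df, "p": self.pvalues})


class _Profile:
    """Profiled deviance machinery over per-group cross-products."""

    def __init__(self, X, y, Z, groups):
        self.n, self.p = X.shape
        self.q = Z.shape[1]
        self.G = groups.max() + 1
        W = np.column_stack([X, y])
        # per-group cross-products
        self.E = np.zeros((self.G, self.q, self.q))
        self.D = np.zeros((self.G, self.q, self.p + 1))
        C = np.zeros((self.p + 1, self.p + 1))
        for g in range(self.G):
            idx = groups == g
            Zg, Wg = Z[idx], W[idx]
            self.E[g] = Zg.T @ Zg
            self.D[g] = Zg.T @ Wg
            C += Wg.T @ Wg
        self.C = C
        self.I_q = np.eye(self.q)

    def n_theta(self) -> int:
        return self.q * (self.q + 1) // 2

    def lam(self, theta: np.ndarray) -> np.ndarray:
        """Lower-triangular Lambda; diagonal on the log scale."""
        L = np.zeros((self.q, self.q))
        il = np.tril_indices(self.q)
        L[il] = theta
        d = np.exp(np.clip(np.diag(L), -15.0, 15.0))
        L[np.diag_indices(self.q)] = d
        return L

    def theta_of_lam(self, L: np.ndarray) -> np.ndarray:
        L = L.copy()
        d = np.clip(np.diag(L), 1e-6, None)
        L[np.diag_indices(self.q)] = np.log(d)
        return L[np.tril_indices(self.q)]

    def _pieces(self, theta):
        """(XtVX, XtVy, yty_v, logdetVstar) for V* = I + Z Lam Lam' Z'."""
        if self.q == 0:
            A = self.C
            return A[: self.p, : self.p], A[: self.p, self.p], A[self.p, self.p], 0.0
        Lam = self.lam(theta)
        M = self.I_q + Lam.T @ self.E @ Lam        # (G, q, q)
        Lc = np.linalg.cholesky(M)
        S = Lam.T @ self.D                         # (G, q, p+1)
        T = np.linalg.solve(Lc, S)
        A = self.C - np.einsum("gip,giq->pq", T, T)
        logdet = 2.0 * np.log(np.diagonal(Lc, axis1=1, axis2=2)).sum()
        return A[: self.p, : self.p], A[: self.p, self.p], A[self.p, self.p], logdet

    def gls(self, theta):
        XtVX, XtVy, yty, logdet = self._pieces(theta)
        beta = np.linalg.solve(XtVX, XtVy)
        rss = max(yty - beta @ XtVy, 1e-12)
        return XtVX, beta, rss, logdet

    def criterion(self, theta, reml: bool) -> float:
        """Profiled -2 log (restricted) likelihood."""
        try:
            XtVX, beta, rss, logdet = self.gls(theta)
        except np.linalg.LinAlgError:
            return 1e12
        n, p = self.n, self.p
        if reml:
            s2 = rss / (n - p)
            sign, ld_x = np.linalg.slogdet(XtVX)
            if sign <= 0:
                return 1e12
            return (n - p) * np.log(2 * np.pi * s2) + logdet + ld_x + (n - p)
        s2 = rss / n
        return n * np.log(2 * np.pi * s2) + logdet + n

    def criterion_unprofiled(self, eta, reml: bool) -> float:
        """-2 log (restricted) likelihood at eta = (theta, log sigma2)."""
        theta, s2 = eta[:-1], np.exp(eta[-1])
        try:
            XtVX, beta, rss, logdet = self.gls(theta)
        except np.linalg.LinAlgError:
            return 1e12
        n, p = self.n, self.p
        if reml:
            sign, ld_x = np.linalg.slogdet(XtVX)
            return (n - p) * np.log(2 * np.pi * s2) + logdet + ld_x + rss / s2
        return n * np.log(2 * np.pi * s2) + logdet + rss / s2

    def cov_beta_at(self, eta) -> np.ndarray:
        theta, s2 = eta[:-1], np.exp(eta[-1])
        XtVX, _, _, _ = self._pieces(theta)
        return s2 * np.linalg.inv(XtVX)


def _numdiff_grad(f, x, h=1e-5):
    g = np.zeros((len(x),) + np.shape(f(x)))
    for k in range(len(x)):
        e = np.zeros_like(x)
        e[k] = h
        g[k] = (np.asarray(f(x + e)) - np.asarray(f(x - e))) / (2 * h)
    return g


def _numdiff_hess(f, x, h=1e-4):
    k = len(x)
    H = np.zeros((k, k))
    f0 = f(x)
    for i in range(k):
        for j in range(i, k):
            ei = np.zeros(k); ei[i] = h
            ej = np.zeros(k); ej[j] = h
            if i == j:
                H[i, i] = (f(x + ei) - 2 * f0 + f(x - ei)) / h**2
            else:
                H[i, j] = H[j, i] = (
                    f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej) + f(x - ei - ej)
                ) / (4 * h**2)
    return H


def _satterthwaite_df(prof: _Profile, eta_hat: np.ndarray, reml: bool) -> np.ndarray:
    """Per-coefficient denominator df; falls back to residual df on failure."""
    resid_df = prof.n - prof.p
    try:
        H = _numdiff_hess(lambda e: prof.criterion_unprofiled(e, reml), eta_hat)
        # eigenvalue-thresholded pseudo-inverse: variance parameters at the
        # boundary contribute no sampling variability instead of blowing up
        vals, vecs = np.linalg.eigh((H + H.T) / 2)
        tol = 1e-8 * max(vals.max(), 1.0)
        inv_vals = np.where(vals > tol, 1.0 / np.where(vals > tol, vals, 1.0), 0.0)
        v_eta = 2.0 * (vecs * inv_vals) @ vecs.T
        grads = _numdiff_grad(lambda e: np.diag(prof.cov_beta_at(e)), eta_hat)
        f0 = np.diag(prof.cov_beta_at(eta_hat))
        denom = np.einsum("kp,kl,lp->p", grads, v_eta, grads)
        with np.errstate(divide="ignore", invalid="ignore"):
            df = 2.0 * f0**2 / denom
        df = np.where(np.isfinite(df) & (df > 1.0), np.minimum(df, resid_df), resid_df)
        return df
    except np.linalg.LinAlgError:
        warnings.warn("ill-conditioned variance Hessian; using residual df")
        return np.full(prof.p, float(resid_df))


def _start_values(prof: _Profile, y, groups) -> np.ndarray:
    """Method-of-moments-flavored start: intercept ratio from group means."""
    grand = y.mean()
    resid = y - grand
    s2 = max(resid.var(), 1e-8)
    means = np.array([resid[groups == g].mean() for g in range(prof.G)])
    sizes = np.bincount(groups)
    vb = max(means.var() - s2 / max(sizes.mean(), 1.0), 0.01 * s2)
    lam_diag = np.full(prof.q, 0.1)
    lam_diag[0] = np.sqrt(vb / s2)
    L0 = np.diag(lam_diag)
    return prof.theta_of_lam(L0)


def fit_lmm(trials: pd.DataFrame, profiles: pd.DataFrame | None = None,
            spec: ModelSpec = ModelSpec(), *, satterthwaite: bool = True,
            max_restarts: int = 2) -> FitResult:
    """Fit the mixed model for `spec` on long-format trials.

    REML is used for coefficient estimates/SEs; FIML for the deviance and
    information criteria used in nested model comparison.  Degenerate
    random structures (tau -> 0) are reported as boundary fits rather
    than errors.
    """
    design = build_design(trials, profiles, spec)
    prof = _Profile(design.X, design.y, design.Z, design.groups)
    reml = spec.estimation == "REML"

    if prof.n_theta() == 0:
        # no random terms: the model is plain Gaussian OLS
        theta_hat = np.empty(0)
        converged, message = True, "OLS (no random terms)"
    else:
        x0 = _start_values(prof, design.y, design.groups)
        best = None
        rng = np.random.default_rng(0)
        for attempt in range(max_restarts + 1):
            start = x0 if attempt == 0 else x0 + rng.normal(0, 0.5, size=x0.size)
            res = optimize.minimize(prof.criterion, start, args=(reml,),
                                    method="L-BFGS-B",
                                    options={"maxiter": 500, "ftol": 1e-12, "gtol": 1e-7})
            if best is None or res.fun < best.fun - 1e-9:
                best = res
            if best.success:
                break
        theta_hat = best.x
        converged, message = bool(best.success), str(best.message)

    XtVX, beta, rss, _ = prof.gls(theta_hat)
    n, p = prof.n, prof.p
    s2 = rss / (n - p) if reml else rss / n
    Lam = prof.lam(theta_hat)
    tau = s2 * Lam @ Lam.T
    cov_beta = s2 * np.linalg.inv(XtVX)
    se = np.sqrt(np.diag(cov_beta))
    tval = beta / se

    eta_hat = np.append(theta_hat, np.log(s2))
    if satterthwaite and prof.n_theta() > 0:
        dfs = _satterthwaite_df(prof, eta_hat, reml)
    else:
        dfs = np.full(p, float(n - p))
    pvals = 2 * stats.t.sf(np.abs(tval), dfs)

    crit = prof.criterion(theta_hat, reml)
    loglik = -0.5 * crit
    k = p + prof.n_theta() + 1
    deviance = crit
    aic = crit + 2 * k
    bic = crit + k * np.log(n)

    names = design.x_names
    znames = design.z_names
    return FitResult(
        params=pd.Series(beta, index=names),
        se=pd.Series(se, index=names),
        tstat=pd.Series(tval, index=names),
        df=pd.Series(dfs, index=names),
        pvalues=pd.Series(pvals, index=names),
        cov_params=pd.DataFrame(cov_beta, index=names, columns=names),
        sigma2=float(s2),
        tau=pd.DataFrame(tau, index=znames, columns=znames),
        loglik=float(loglik),
        deviance=float(deviance),
        aic=float(aic),
        bic=float(bic),
        n_params=k,
        method=spec.estimation,
        converged=converged,
        n_obs=n,
        n_groups=prof.G,
        spec=spec,
        dropped=design.dropped,
        optimizer_message=message,
    )


def icc(null_fit: FitResult) -> float:
    """Intraclass correlation tau00 / (tau00 + sigma2) from the null model."""
    if tuple(null_fit.tau.index) != ("intercept",):
        raise ValueError("ICC requires an intercept-only random structure")
    tau00 = float(null_fit.tau.iloc[0, 0])
    return tau00 / (tau00 + null_fit.sigma2)


def compare_models(fit_reduced: FitResult, fit_full: FitResult) -> tuple[float, int, float]:
    """Likelihood-ratio chi-squared test for nested FIML fits.

    Returns (chi2, df, p) with chi2 = D_reduced - D_full and df the
    difference in estimated-parameter counts.
    """
    for f in (fit_reduced, fit_full):
        if f.method != "FIML":
            raise ValueError("model comparison requires FIML fits")
    df = fit_full.n_params - fit_reduced.n_params
    if df < 0:
        raise ValueError("models are not nested in the expected direction")
    chi2 = fit_reduced.deviance - fit_full.deviance
    if chi2 < -1e-6:
        raise ValueError("negative chi2: a fit likely failed to converge")
    chi2 = max(chi2, 0.0)
    p = 1.0 if df == 0 else float(stats.chi2.sf(chi2, df))
    return float(chi2), int(df), p
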