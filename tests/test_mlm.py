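"""Mixed-model estimation, model comparison, and moderation probing."""

import warnings

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from spoarcnet import defaults
from spoarcnet.mlm import (ModelSpec, compare_models, default_levels, fit_lmm,
                           grand_mean_center, icc, johnson_neyman,
                           simple_slopes)
from spoarcnet.mlm.design import build_design
from spoarcnet.mlm.fit import FitResult
from spoarcnet.synthdata import GenConfig, generate_participants, generate_probe_trials


def _null_fe(g00=800.0):
    fe = {k: 0.0 for k in defaults.FIXED_EFFECTS}
    fe["g00"] = g00
    return fe


def test_grand_mean_center():
    assert grand_mean_center([1, 2, 3]).tolist() == [-1, 0, 1]
    assert np.allclose(grand_mean_center([7.0] * 5), 0.0)
    x = np.random.default_rng(0).normal(0.65, 0.18, 200)
    c = grand_mean_center(x)
    assert abs(c.mean()) < 1e-12 and np.isclose(c.std(), x.std())


class TestFit:
    def test_no_random_terms_reduces_to_ols(self, small_cohort):
        _, profiles, trials, _ = small_cohort
        spec = ModelSpec(random_terms=(), estimation="FIML")
        fit = fit_lmm(trials, profiles, spec)
        d = build_design(trials, profiles, spec)
        beta = np.linalg.lstsq(d.X, d.y, rcond=None)[0]
        assert np.max(np.abs(fit.params.values - beta)) < 1e-6
        s2 = ((d.y - d.X @ beta) ** 2).mean()
        ll_ols = -0.5 * len(d.y) * (np.log(2 * np.pi * s2) + 1)
        assert fit.loglik == pytest.approx(ll_ols, abs=1e-6)

    @pytest.mark.parametrize("estimation", ["FIML", "REML"])
    def test_loglik_agrees_with_statsmodels_likelihood_at_our_optimum(self, estimation):
        # evaluate statsmodels' (restricted) likelihood function at our
        # variance estimates: the two criteria must coincide, and our
        # optimum must be at least as good as statsmodels' own fit
        import statsmodels.formula.api as smf
        from statsmodels.regression.mixed_linear_model import MixedLMParams

        cfg = GenConfig(n_participants=40, trials_per_participant_range=(40, 40), seed=9)
        profiles = generate_participants(cfg)
        trials, _ = generate_probe_trials(profiles, cfg)
        ours = fit_lmm(trials, profiles, ModelSpec.full(estimation), satterthwaite=False)

        t = trials.merge(profiles.reset_index(), on="participant_id")
        for m in defaults.COGNITIVE_MEASURES:
            t[m + "_c"] = t[m] - profiles[m].mean()
        t["hp"] = t["hand"] * t["position"]
        t["thp"] = t["task"] * t["hp"]
        demos = [d for d in ("handedness", "altL", "school", "education_years", "gender")
                 if t[d].nunique() > 1]
        fixed = ("rt_ms ~ hand + position + hp + task + thp + "
                 + " + ".join(m + "_c" for m in defaults.COGNITIVE_MEASURES)
                 + " + " + " + ".join(demos) + " + "
                 + " + ".join(m + "_c:hp" for m in defaults.COGNITIVE_MEASURES)
                 + " + siwm_c:ssowm_c:hp")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            md = smf.mixedlm(fixed, t, groups=t["participant_id"],
                             re_formula="1 + hp + task + thp")
            md.reml = estimation == "REML"
            md.cov_pen = None
            params = MixedLMParams.from_components(cov_re=ours.tau.values / ours.sigma2)
            ll_at_ours = md.loglike(params, profile_fe=True)
            mf = md.fit(reml=md.reml, maxiter=300)
        assert ours.loglik == pytest.approx(ll_at_ours, abs=1e-6)
        assert ours.loglik >= mf.llf - 1e-4

    def test_reml_matches_statsmodels_random_intercept_model(self, small_cohort):
        import statsmodels.formula.api as smf
        _, _, trials, _ = small_cohort
        ours = fit_lmm(trials, None, ModelSpec.null())
        md = smf.mixedlm("rt_ms ~ 1", trials, groups=trials["participant_id"])
        mf = md.fit(reml=True)
        assert ours.loglik == pytest.approx(mf.llf, abs=1e-6)
        assert ours.tau.iloc[0, 0] == pytest.approx(mf.cov_re.iloc[0, 0], rel=1e-3)
        assert ours.sigma2 == pytest.approx(mf.scale, rel=1e-4)

    def test_estimates_invariant_to_trial_order(self, small_cohort):
        _, profiles, trials, _ = small_cohort
        fit_a = fit_lmm(trials, profiles, ModelSpec.full("REML"), satterthwaite=False)
        perm = trials.sample(frac=1.0, random_state=1).reset_index(drop=True)
        fit_b = fit_lmm(perm, profiles, ModelSpec.full("REML"), satterthwaite=False)
        # identical up to the optimizer's stopping precision
        assert np.allclose(fit_a.params.values, fit_b.params.values,
                           rtol=1e-3, atol=0.2)

    def test_tau_is_positive_semidefinite(self, small_cohort):
        _, profiles, trials, _ = small_cohort
        fit = fit_lmm(trials, profiles, ModelSpec.full("REML"), satterthwaite=False)
        assert np.linalg.eigvalsh(fit.tau.values).min() >= -1e-8
        assert fit.sigma2 > 0
        assert fit.deviance == pytest.approx(-2 * fit.loglik)

    def test_vsowm_moderation_sign_recovered_at_published_scale(self):
        # at the published cohort size the planted negative vsowm moderation
        # should carry the right sign in nearly every replicate
        neg = 0
        reps = 12
        for r in range(reps):
            cfg = GenConfig(seed=3000 + r)
            prof = generate_participants(cfg)
            trials, _ = generate_probe_trials(prof, cfg)
            fit = fit_lmm(trials, prof, ModelSpec.full("REML"), satterthwaite=False)
            neg += fit.params["vsowm_c:hand:position"] < 0
        assert neg >= reps - 1


class TestIccAndComparison:
    def test_icc_formula(self, small_cohort):
        _, _, trials, _ = small_cohort
        null = fit_lmm(trials, None, ModelSpec.null())
        tau00 = null.tau.iloc[0, 0]
        assert icc(null) == pytest.approx(tau00 / (tau00 + null.sigma2))

    def test_icc_requires_null_random_structure(self, small_cohort):
        _, profiles, trials, _ = small_cohort
        fit = fit_lmm(trials, profiles, ModelSpec.full("REML"), satterthwaite=False)
        with pytest.raises(ValueError):
            icc(fit)

    def test_planted_icc_recovered(self):
        target = 0.293
        tau = np.zeros((4, 4))
        tau[0, 0] = target / (1 - target) * defaults.SIGMA2
        estimates = []
        for s in range(5):
            cfg = GenConfig(n_participants=160, fixed_effects=_null_fe(1000.0),
                            tau=tau, seed=40 + s)
            prof = generate_participants(cfg)
            trials, _ = generate_probe_trials(prof, cfg)
            estimates.append(icc(fit_lmm(trials, None, ModelSpec.null())))
        assert abs(np.mean(estimates) - target) < 0.03

    def test_identical_models_give_zero_chi2(self, small_cohort):
        _, _, trials, _ = small_cohort
        fit = fit_lmm(trials, None, ModelSpec(l1_terms=False, l2_cognitive=False,
                                              l2_controls=False, cross_level=False,
                                              random_terms=("intercept",),
                                              estimation="FIML"), satterthwaite=False)
        chi2, df, p = compare_models(fit, fit)
        assert (chi2, df, p) == (0.0, 0, 1.0)

    def test_comparison_requires_fiml(self, small_cohort):
        _, _, trials, _ = small_cohort
        fit = fit_lmm(trials, None, ModelSpec.null())
        with pytest.raises(ValueError):
            compare_models(fit, fit)

    def test_lrt_calibrated_under_null_and_powerful_under_alternative(self):
        reduced_spec = ModelSpec(l1_terms=False, l2_cognitive=False, l2_controls=False,
                                 cross_level=False, random_terms=("intercept",),
                                 estimation="FIML")
        full_spec = ModelSpec(l1_terms=True, l2_cognitive=False, l2_controls=False,
                              cross_level=False, random_terms=("intercept",),
                              estimation="FIML")
        rej_null = rej_alt = 0
        reps = 150
        for r in range(reps):
            cfg = GenConfig(n_participants=30, trials_per_participant_range=(20, 20),
                            fixed_effects=_null_fe(), tau=np.diag([20000.0, 0, 0, 0]),
                            seed=500 + r)
            prof = generate_participants(cfg)
            trials, _ = generate_probe_trials(prof, cfg)
            red = fit_lmm(trials, None, reduced_spec, satterthwaite=False)
            full = fit_lmm(trials, None, full_spec, satterthwaite=False)
            rej_null += compare_models(red, full)[2] < 0.05
        for r in range(40):
            fe = _null_fe()
            fe["g30"] = defaults.FIXED_EFFECTS["g30"]
            cfg = GenConfig(n_participants=30, trials_per_participant_range=(20, 20),
                            fixed_effects=fe, tau=np.diag([20000.0, 0, 0, 0]),
                            sigma2=10000.0, seed=900 + r)
            prof = generate_participants(cfg)
            trials, _ = generate_probe_trials(prof, cfg)
            red = fit_lmm(trials, None, reduced_spec, satterthwaite=False)
            full = fit_lmm(trials, None, full_spec, satterthwaite=False)
            rej_alt += compare_models(red, full)[2] < 0.05
        # ~3 SE binomial band around 0.05 at 150 replicates
        assert 0.0 <= rej_null / reps <= 0.11
        assert rej_alt / 40 > 0.9


def _toy_fit(gf, gc, vf, vc, cfc, df=120.0, g20=-37.0, g50=11.0):
    names = ["position", "hand:position", "task:hand:position",
             "vsowm_c:hand:position"]
    params = pd.Series([g20, gf, g50, gc], index=names)
    cov = np.diag([1.0, vf, 0.5, vc])
    cov[1, 3] = cov[3, 1] = cfc
    covd = pd.DataFrame(cov, index=names, columns=names)
    se = pd.Series(np.sqrt(np.diag(cov)), index=names)
    return FitResult(params=params, se=se, tstat=params / se,
                     df=pd.Series(df, index=names),
                     pvalues=pd.Series(0.5, index=names), cov_params=covd,
                     sigma2=1.0,
                     tau=pd.DataFrame([[1.0]], index=["intercept"], columns=["intercept"]),
                     loglik=0.0, deviance=0.0, aic=0.0, bic=0.0, n_params=4,
                     method="REML", converged=True, n_obs=2000, n_groups=100,
                     spec=ModelSpec.null())


class TestModerationProbes:
    def test_no_moderation_significant_everywhere(self):
        # moderation pinned to zero (coefficient and its variance) with a
        # focal effect well past the critical ratio
        fit = _toy_fit(gf=-23.0, gc=0.0, vf=4.0, vc=0.0, cfc=0.0)
        region = johnson_neyman(fit, "vsowm")
        assert region.boundaries == ()
        assert region.significant == "everywhere"

    def test_alpha_near_one_makes_entire_range_significant(self):
        fit = _toy_fit(gf=-1.0, gc=2.0, vf=25.0, vc=25.0, cfc=0.0)
        region = johnson_neyman(fit, "vsowm", alpha=0.999)
        # significant on the whole range apart from the measure-zero point
        # where the simple effect crosses zero exactly
        w = np.linspace(-5, 5, 100)
        assert region.is_significant(w).mean() >= 0.99

    def test_jn_region_agrees_with_dense_grid(self):
        fit = _toy_fit(gf=-23.27, gc=-19.37, vf=16.0, vc=60.0, cfc=2.0)
        region = johnson_neyman(fit, "vsowm")
        w = np.linspace(-4, 4, 200001)
        tstat = np.abs(fit.params["hand:position"] + fit.params["vsowm_c:hand:position"] * w)
        tstat /= np.sqrt(16.0 + 2 * w * 2.0 + w**2 * 60.0)
        assert np.array_equal(region.is_significant(w), tstat > region.t_crit)

    def test_zero_cli_gives_identical_slope_differences(self):
        fit = _toy_fit(gf=-23.0, gc=0.0, vf=4.0, vc=9.0, cfc=0.0)
        out = simple_slopes(fit, "vsowm", levels=[0.4, 0.6, 0.8], moderator_mean=0.6)
        assert out["difference"].nunique() == 1

    def test_negative_cli_makes_difference_strictly_decreasing(self):
        fit = _toy_fit(gf=-23.0, gc=-19.0, vf=4.0, vc=9.0, cfc=0.0)
        out = simple_slopes(fit, "vsowm", levels=[0.4, 0.6, 0.8], moderator_mean=0.6)
        diffs = out["difference"].to_numpy()
        assert np.all(np.diff(diffs) < 0)
        assert np.allclose(out["slope_right"] - out["slope_left"], diffs)

    def test_default_levels_reproduce_published_probe_points(self):
        # the published probe levels 0.48 / 0.65 / 0.82 correspond to
        # mean +- 0.17 around the vsowm mean of 0.65
        levels = default_levels(0.65, 0.17)
        assert np.allclose(levels, (0.48, 0.65, 0.82))
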