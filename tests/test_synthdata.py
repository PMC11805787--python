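"""Synthetic cohort generators: determinism, moment matching, structure."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from spoarcnet import defaults
from spoarcnet.synthdata import (GenConfig, generate_attention_and_wm_trials,
                                 generate_brain_behavior_pairs,
                                 generate_modular_timeseries,
                                 generate_participants, generate_probe_trials,
                                 generate_trivariate)


class TestParticipants:
    def test_deterministic_given_seed(self):
        a = generate_participants(GenConfig(seed=5))
        b = generate_participants(GenConfig(seed=5))
        pd.testing.assert_frame_equal(a, b)
        assert a.to_csv() == b.to_csv()

    def test_marginal_moments_match_published_tables(self):
        prof = generate_participants(GenConfig(seed=1))
        for name, (mean, sd, lo, hi) in defaults.L2_MARGINALS.items():
            x = prof[name]
            assert abs(x.mean() - mean) < 3 * sd / np.sqrt(len(x)), name
            assert (x >= lo).all() and (x <= hi).all(), name

    def test_zero_correlation_config_gives_independent_measures(self):
        cfg = GenConfig(n_participants=4000, l2_spearman=np.eye(7), seed=3)
        prof = generate_participants(cfg)
        cols = list(defaults.COGNITIVE_MEASURES)
        corr = prof[cols].corr(method="spearman").to_numpy()
        off = corr[~np.eye(7, dtype=bool)]
        assert np.abs(off).max() < 0.08

    def test_rank_correlations_recover_published_matrix(self):
        cfg = GenConfig(n_participants=4000, seed=4)
        prof = generate_participants(cfg)
        cols = list(defaults.COGNITIVE_MEASURES)
        rho = prof[cols].corr(method="spearman").to_numpy()
        assert np.abs(rho - defaults.L2_SPEARMAN).max() < 0.06

    def test_demographic_codings(self):
        prof = generate_participants(GenConfig(seed=2))
        assert set(prof["handedness"]) <= {1, 2}
        assert set(prof["gender"]) <= {1, 2}
        assert set(prof["altL"]) <= {0, 1}


class TestProbeTrials:
    def test_degenerate_config_rt_equals_intercept(self):
        fe = {k: 0.0 for k in defaults.FIXED_EFFECTS}
        fe["g00"] = 750.0
        cfg = GenConfig(n_participants=5, fixed_effects=fe,
                        tau=np.zeros((4, 4)), sigma2=0.0, seed=0)
        prof = generate_participants(cfg)
        trials, _ = generate_probe_trials(prof, cfg)
        assert np.allclose(trials["rt_ms"], 750.0)

    def test_trial_counts_within_configured_range(self):
        cfg = GenConfig(n_participants=40, seed=6)
        prof = generate_participants(cfg)
        trials, _ = generate_probe_trials(prof, cfg)
        counts = trials.groupby("participant_id").size()
        assert counts.between(44, 79).all()
        assert 40 * 44 <= len(trials) <= 40 * 79

    def test_floor_mode_records_floored_rts(self):
        fe = {k: 0.0 for k in defaults.FIXED_EFFECTS}
        fe["g00"] = 10.0  # most draws land below zero
        cfg = GenConfig(n_participants=5, fixed_effects=fe, tau=np.zeros((4, 4)),
                        sigma2=10000.0, seed=0, negative_rt="floor")
        prof = generate_participants(cfg)
        trials, truth = generate_probe_trials(prof, cfg)
        assert truth.n_floored_rts > 0
        assert (trials["rt_ms"] > 0).all()
        assert (trials["rt_ms"] == 1.0).any()  # floored draws

    def test_redraw_mode_yields_positive_rts_and_counts(self, small_cohort):
        _, _, trials, truth = small_cohort
        assert (trials["rt_ms"] > 0).all()
        assert truth.n_floored_rts == 0

    def test_realized_random_effect_covariance_near_tau(self):
        cfg = GenConfig(n_participants=2000, trials_per_participant_range=(1, 1), seed=8)
        prof = generate_participants(cfg)
        _, truth = generate_probe_trials(prof, cfg)
        sample_cov = np.cov(truth.random_effects.T)
        rel = np.linalg.norm(sample_cov - defaults.TAU) / np.linalg.norm(defaults.TAU)
        assert rel < 0.15


class TestTaskTrials:
    def test_exactly_twenty_catch_trials_per_participant(self):
        cfg = GenConfig(n_participants=3, seed=1)
        prof = generate_participants(cfg)
        tasks = generate_attention_and_wm_trials(prof, cfg)
        catch = tasks["exo"].groupby("participant_id")["trial_type"] \
            .apply(lambda s: (s == "catch").sum())
        assert (catch == 20).all()
        assert len(tasks["exo"]) == 3 * 168

    def test_noiseless_cueing_effect_recovers_profile_value(self):
        cfg = GenConfig(n_participants=2, seed=1)
        prof = generate_participants(cfg)
        prof = prof.assign(exo=50.0, endo=20.0)
        tasks = generate_attention_and_wm_trials(prof, cfg, cueing_noise_sd=0.0)
        t = tasks["exo"][tasks["exo"]["participant_id"] == prof.index[0]]
        effect = (t.loc[t.trial_type == "invalid", "rt_ms"].mean()
                  - t.loc[t.trial_type == "valid", "rt_ms"].mean())
        assert effect == pytest.approx(50.0, abs=1e-9)

    def test_perfect_wm_capacity_gives_all_correct(self):
        cfg = GenConfig(n_participants=2, seed=1)
        prof = generate_participants(cfg)
        prof = prof.assign(viwm=1.0, vsowm=1.0)
        tasks = generate_attention_and_wm_trials(prof, cfg)
        t = tasks["verbal_wm"]
        nonident = t[t["trial_type"] != "identical"]
        assert nonident["correct"].all()


class TestTimeseries:
    def test_deterministic_given_seed(self):
        a = generate_modular_timeseries(10, np.arange(10) % 2, 1.0, 0.2, seed=3)
        b = generate_modular_timeseries(10, np.arange(10) % 2, 1.0, 0.2, seed=3)
        assert np.array_equal(a.values, b.values)

    def test_shape_and_default_runs(self):
        p = generate_modular_timeseries(8, np.zeros(8, int), 1.0, 0.0, timepoints=50)
        assert (p.runs, p.nodes, p.timepoints) == (3, 8, 50)

    def test_partition_must_cover_nodes(self):
        with pytest.raises(ValueError):
            generate_modular_timeseries(8, np.zeros(5, int), 1.0, 0.0)

    def test_equal_weak_couplings_leave_no_planted_structure(self):
        # when couplings are equal and weak, the thresholded network is
        # ranking noise and the planted partition scores near zero
        from spoarcnet.netmod import (average_networks,
                                      connectivity_from_timeseries, modularity,
                                      threshold_binarize)
        ms = []
        for s in range(10):
            p = generate_modular_timeseries(20, np.arange(20) % 2, 0.15, 0.15,
                                            timepoints=100, seed=s)
            net = average_networks(connectivity_from_timeseries(p.values))
            g = threshold_binarize(net, 0.25)
            ms.append(modularity(g, p.planted_partition))
        assert abs(np.mean(ms)) < 0.1

    def test_planted_partition_recovered_from_strong_structure(self):
        from spoarcnet.netmod import (average_networks,
                                      connectivity_from_timeseries,
                                      optimize_partition, threshold_binarize)
        hits = 0
        for s in range(100):
            p = generate_modular_timeseries(20, np.repeat([0, 1], 10), 1.5, 0.1,
                                            timepoints=150, seed=s)
            net = average_networks(connectivity_from_timeseries(p.values))
            # density chosen so the retained edges nearly saturate the
            # within-block pairs, making the planted split the clear optimum
            res = optimize_partition(threshold_binarize(net, 0.45), seed=s)
            same = (res.partition.max() == 1
                    and len(set(zip(res.partition, p.planted_partition))) == 2)
            hits += same
        assert hits >= 95


class TestPairs:
    def test_perfect_correlation(self):
        x = generate_brain_behavior_pairs(50, 1.0, seed=0)
        assert np.corrcoef(x.T)[0, 1] == pytest.approx(1.0, abs=1e-12)

    def test_power_matches_fisher_z_closed_form(self):
        # one-sample correlation test at n=25, rho=0.47
        n, rho, reps = 25, 0.47, 2000
        rej = 0
        for s in range(reps):
            x = generate_brain_behavior_pairs(n, rho, seed=s)
            r, p = stats.pearsonr(x[:, 0], x[:, 1])
            rej += p < 0.05
        power_z = stats.norm.sf(stats.norm.ppf(0.975)
                                - np.sqrt(n - 3) * np.arctanh(rho))
        assert abs(rej / reps - power_z) < 0.05

    def test_trivariate_requires_psd(self):
        bad = np.array([[1, 0.9, -0.9], [0.9, 1, 0.9], [-0.9, 0.9, 1]])
        with pytest.raises(ValueError):
            generate_trivariate(10, bad)
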