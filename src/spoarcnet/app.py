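"""End-to-end orchestration of the two experiments on synthetic cohorts.

``run_experiment1`` chains cohort generation, the behavioral-measure and
exclusion machinery, and the multilevel moderation analysis.
``run_experiment2`` chains per-participant time-series panels, the network
modularity pipeline at several scales, the single-level SPoARC statistic,
and the brain-behavior correlation report.  Both are deterministic given
``RunConfig.seed`` and optionally persist every intermediate table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import defaults, io
from .brainbehavior import scale_comparison
from .measures import (TrimRule, apply_exclusions, binomial_chance_threshold,
                       compute_boa, compute_cueing_effect, compute_wm_capacities,
                       exclusion_table, trim_rts)
from .mlm import (ModelSpec, default_levels, fit_lmm, icc, johnson_neyman,
                  simple_slopes)
from .netmod import expected_edge_count, network_pipeline
from .spoarc import group_spoarc_summary, spoarc_table
from .synthdata import (GenConfig, generate_attention_and_wm_trials,
                        generate_modular_timeseries, generate_participants,
                        generate_probe_trials)

__all__ = ["RunConfig", "run_experiment1", "run_experiment2", "measured_profiles"]


@dataclass
class RunConfig:
    """Seed plus the stage-level parameters of both experiments."""

    seed: int = 0
    n_participants: int = defaults.N_PARTICIPANTS
    # experiment 2
    n_imaging_participants: int = 25
    n_nodes: int = defaults.NETWORK_SIZES["whole_brain"]
    n_subnetwork_nodes: int = defaults.NETWORK_SIZES["vsowm_attention"]
    density: float = defaults.EDGE_DENSITY
    runs: int = 3
    timepoints: int = 200
    n_modules: int = 4
    coupling_within: float = 1.0
    coupling_between_base: float = 0.35
    brain_behavior_slope: float = 0.12   # between-coupling shift per SD of SPoARC
    # inference settings
    alpha: float = 0.05
    moderators: tuple[str, ...] = ("vsowm", "siwm", "ssowm")
    outdir: str | None = None

    def gen_config(self, **overrides) -> GenConfig:
        kw = dict(n_participants=self.n_participants, seed=self.seed)
        kw.update(overrides)
        return GenConfig(**kw)


def measured_profiles(profiles: pd.DataFrame, tasks: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Recompute the seven cognitive measures from raw task trials.

    Returns a profile table whose cognitive columns come from the
    measures machinery (trimming included) rather than the generator's
    latent values; demographics are carried over.
    """
    boa_rule = TrimRule.for_task("boa")
    cue_rule = TrimRule.for_task("cueing")
    rows = {}
    for pid in profiles.index:
        row = {}
        boa_t = tasks["boa"][tasks["boa"]["participant_id"] == pid]
        keep = trim_rts(boa_t["rt_ms"].to_numpy(), boa_rule)
        row["boa"] = compute_boa(boa_t[keep])
        for task, name in (("exo", "exo"), ("endo", "endo")):
            t = tasks[task][(tasks[task]["participant_id"] == pid)
                            & (tasks[task]["trial_type"] != "catch")
                            & tasks[task]["correct"]]
            keep = trim_rts(t["rt_ms"].to_numpy(), cue_rule)
            t = t[keep]
            row[name] = compute_cueing_effect(
                t.loc[t["trial_type"] == "valid", "rt_ms"],
                t.loc[t["trial_type"] == "invalid", "rt_ms"])
        for task, (item, order) in (("verbal_wm", ("viwm", "vsowm")),
                                    ("spatial_wm", ("siwm", "ssowm"))):
            t = tasks[task][(tasks[task]["participant_id"] == pid)
                            & (tasks[task]["trial_type"] != "identical")]
            keep = trim_rts(t["rt_ms"].to_numpy(), TrimRule.for_task("wm"))
            row[item], row[order] = compute_wm_capacities(t[keep])
        rows[pid] = row
    measured = pd.DataFrame.from_dict(rows, orient="index")
    measured.index.name = profiles.index.name
    for col in ("handedness", "altL", "school", "education_years", "gender"):
        measured[col] = profiles[col]
    return measured


def _task_summaries(profiles: pd.DataFrame, tasks: dict[str, pd.DataFrame]) -> pd.DataFrame:
    rows = []
    for pid in profiles.index:
        row = {"participant_id": pid}
        for task in ("exo", "endo"):
            t = tasks[task][tasks[task]["participant_id"] == pid]
            catch = t[t["trial_type"] == "catch"]
            row[f"{task}_catch_response_rate"] = float(catch["responded"].mean())
            row[f"{task}_accuracy"] = float(t["correct"].mean())
        for task, col in (("verbal_wm", "verbal_wm"), ("spatial_wm", "spatial_wm")):
            t = tasks[task][tasks[task]["participant_id"] == pid]
            row[f"{col}_accuracy"] = float(t["correct"].mean())
            row[f"{col}_mean_rt"] = float(t["rt_ms"].mean())
        rows.append(row)
    return pd.DataFrame(rows)


def run_experiment1(config: RunConfig | None = None) -> dict:
    """Cohort -> behavioral measures -> exclusions -> moderation model."""
    config = config or RunConfig()
    gen = config.gen_config()
    profiles = generate_participants(gen)
    tasks = generate_attention_and_wm_trials(profiles, gen)
    summaries = _task_summaries(profiles, tasks)
    reports = apply_exclusions(summaries, alpha=config.alpha)
    kept = [r.participant_id for r in reports if r.kept]
    profiles_kept = profiles.loc[kept]

    trials, truth = generate_probe_trials(profiles_kept, config.gen_config(
        n_participants=len(profiles_kept)))

    null_fit = fit_lmm(trials, None, ModelSpec.null())
    fit = fit_lmm(trials, profiles_kept, ModelSpec.full("REML"))
    fiml_fit = fit_lmm(trials, profiles_kept, ModelSpec.full("FIML"),
                       satterthwaite=False)

    jn_reports = {}
    slope_reports = {}
    for moderator in config.moderators:
        region = johnson_neyman(fit, moderator, alpha=config.alpha)
        mean = float(profiles_kept[moderator].mean())
        sd = float(profiles_kept[moderator].std(ddof=1))
        levels = default_levels(mean, sd)
        obs = (float(profiles_kept[moderator].min()), float(profiles_kept[moderator].max()))
        jn_reports[moderator] = region
        slope_reports[moderator] = simple_slopes(
            fit, moderator, levels, moderator_mean=mean, region=region,
            observed_range=obs)

    artifacts = {
        "profiles": profiles,
        "tasks": tasks,
        "summaries": summaries,
        "exclusions": exclusion_table(reports),
        "trials": trials,
        "ground_truth": truth,
        "null_fit": null_fit,
        "icc": icc(null_fit),
        "fit": fit,
        "fiml_fit": fiml_fit,
        "jn": jn_reports,
        "simple_slopes": slope_reports,
    }
    if config.outdir:
        out = Path(config.outdir)
        io.write_table(profiles.reset_index(), out / "profiles.csv")
        io.write_table(trials, out / "trials.csv")
        io.write_table(artifacts["exclusions"], out / "exclusions.csv")
        io.write_table(fit.summary().reset_index(names="term"), out / "fit_summary.csv")
        io.write_json({"icc": artifacts["icc"],
                       "deviance": fiml_fit.deviance, "aic": fiml_fit.aic,
                       "bic": fiml_fit.bic, "n_params": fiml_fit.n_params,
                       "seed": config.seed}, out / "fit_indices.json")
        truth.to_json(out / "ground_truth.json")
    return artifacts


def run_experiment2(config: RunConfig | None = None) -> dict:
    """Panels -> modularity per scale -> SPoARC magnitudes -> correlations.

    The synthetic link between brain and behavior is planted in the
    function-specific subnetwork only: its between-module coupling
    increases with the participant's (standardized, sign-flipped) SPoARC
    magnitude, so a larger effect yields a less modular subnetwork; the
    whole-brain panel is generated without any behavioral link.
    """
    config = config or RunConfig()
    n = config.n_imaging_participants
    gen = config.gen_config(n_participants=n)
    profiles = generate_participants(gen)
    trials, _ = generate_probe_trials(profiles, gen)
    magnitudes = spoarc_table(trials).set_index("participant_id")["magnitude"]
    summary = group_spoarc_summary(magnitudes)

    z = -(magnitudes - magnitudes.mean()) / magnitudes.std(ddof=1)  # larger effect -> +z
    rng_seeds = np.random.SeedSequence((config.seed, 0xB7A1)).spawn(n)

    labels_whole = np.arange(config.n_nodes) % config.n_modules
    labels_sub = np.arange(config.n_subnetwork_nodes) % config.n_modules
    modularity_by_scale: dict[str, dict] = {"whole_brain": {}, "subnetwork": {}}
    edges_by_scale: dict[str, int] = {}
    for k, pid in enumerate(magnitudes.index):
        child = np.random.default_rng(rng_seeds[k])
        s_whole, s_sub, s_opt = child.integers(0, 2**31 - 1, size=3)
        panel_whole = generate_modular_timeseries(
            config.n_nodes, labels_whole, config.coupling_within,
            config.coupling_between_base, runs=config.runs,
            timepoints=config.timepoints, seed=int(s_whole))
        cb = max(config.coupling_between_base + config.brain_behavior_slope * float(z[pid]), 0.0)
        panel_sub = generate_modular_timeseries(
            config.n_subnetwork_nodes, labels_sub, config.coupling_within,
            cb, runs=config.runs, timepoints=config.timepoints, seed=int(s_sub))
        for scale, panel in (("whole_brain", panel_whole), ("subnetwork", panel_sub)):
            res = network_pipeline(panel.values, config.density, seed=int(s_opt))
            modularity_by_scale[scale][pid] = res.M
            edges_by_scale[scale] = res.n_edges

    mod_series = {k: pd.Series(v).rename_axis("participant_id")
                  for k, v in modularity_by_scale.items()}
    report = scale_comparison(magnitudes, mod_series)

    artifacts = {
        "profiles": profiles,
        "trials": trials,
        "spoarc": magnitudes,
        "spoarc_summary": summary,
        "modularity": mod_series,
        "report": report,
        "edges_by_scale": edges_by_scale,
        "edge_counts": {name: expected_edge_count(nn, config.density)
                        for name, nn in defaults.NETWORK_SIZES.items()},
    }
    if config.outdir:
        out = Path(config.outdir)
        io.write_table(magnitudes.reset_index(), out / "spoarc.csv")
        for scale, series in mod_series.items():
            io.write_table(series.reset_index(name="modularity"), out / f"modularity_{scale}.csv")
        io.write_table(report["correlations"], out / "correlations.csv")
        io.write_table(report["comparisons"], out / "comparisons.csv")
        io.write_json({"spoarc_summary": summary, "seed": config.seed,
                       "edge_counts": artifacts["edge_counts"]},
                      out / "experiment2.json")
    return artifacts
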