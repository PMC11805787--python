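# spoarcnet

Simulation and analysis tools for individual differences in the **SPoARC
effect** (Spatial Position Association of Response Codes): when people
respond to probes about a memorized verbal list, the left hand is faster
for early list positions and the right hand for late positions, as if the
sequence were laid out left-to-right on a "mental whiteboard". The package
implements, with fully seeded synthetic data standing in for unavailable
human RT and fMRI recordings, the two analysis arms such a study needs:

1. **Behavioral moderation (experiment 1).** Per-participant item-probe
   reaction times `RT_ij` are modeled with a two-level mixed-effects model

   ```
   RT_ij = γ00 + γ10·Hand + γ20·Pos + γ30·Hand·Pos + γ40·Task + γ50·Task·Hand·Pos
           + Σ_k γ0k·x_k(i) + Σ_k γ3k·x_k(i)·Hand·Pos + γ347·siwm·ssowm·Hand·Pos
           + u0i + u3i·Hand·Pos + u4i·Task + u5i·Task·Hand·Pos + ε_ij
   ```

   with `u_i ~ N(0, τ)` (unstructured 4×4), `ε ~ N(0, σ²)`, REML estimates
   with Satterthwaite *t*-tests, FIML deviance/AIC/BIC for nested
   comparisons, Johnson–Neyman regions of significance and pick-a-point
   simple slopes for the cross-level interactions. The seven level-2
   moderators (`boa`, `exo`, `endo`, `viwm`, `vsowm`, `siwm`, `ssowm`) are
   computed from task trials after two-stage RT trimming (absolute window,
   then Q1 − 3·IQR / Q3 + 3·IQR fences), with exact-binomial chance-level
   exclusion rules.

2. **Network modularity (experiment 2).** Multi-run node time series are
   turned into Pearson-correlation connectivity matrices, run-averaged,
   thresholded to the strongest 11.47% of edges (`k = ceil(density·C(n,2))`),
   binarized, and partitioned by Newman-style modularity maximization,

   `M = (1/2e) Σ_modules Σ_{i,j} (A_ij − a_i a_j / 2e)`,

   using greedy agglomeration with Kernighan–Lin refinement and seeded
   restarts (validated against exhaustive partition enumeration on small
   graphs). The per-participant single-level SPoARC magnitude (right-hand
   minus left-hand slope of RT on probe position) is then correlated with
   modularity at different network scales, and scales are compared with
   Steiger's test for dependent correlations.

The synthetic-data module (`spoarcnet.synthdata`) generates every input:
copula-correlated participant profiles matching the documented marginal
moments and rank correlations, probe trials from the two-level RT model,
attention/WM task trials, modular time-series panels with planted
communities, and correlated pairs for calibration studies. All generators
are deterministic given a seed, and each returns the ground truth used to
generate it for parameter-recovery testing.

## Worked example

```python
from spoarcnet.mlm import ModelSpec, fit_lmm, icc, johnson_neyman
from spoarcnet.synthdata import GenConfig, generate_participants, generate_probe_trials

cfg = GenConfig(n_participants=80, seed=6)
profiles = generate_participants(cfg)
trials, truth = generate_probe_trials(profiles, cfg)

print(icc(fit_lmm(trials, None, ModelSpec.null())))      # 0.290
fit = fit_lmm(trials, profiles, ModelSpec.full("REML"))
print(fit.gamma["g30"][:2])                               # (-27.75, 5.92)
print(fit.gamma["g36"][:2])                               # (-24.49, 8.89)
print(johnson_neyman(fit, "vsowm").significant)           # 'outside'
```

About 29% of RT variance lies between participants (hence the multilevel
model); the fitted Hand × Position coefficient of −27.7 ms/position (SE
5.9) recovers the generating SPoARC term of −23.27 within sampling error,
and the negative `vsowm` × Hand × Position interaction means participants
with higher verbal serial-order WM capacity show steeper right-minus-left
slope differences — a larger SPoARC effect. The `examples/` directory
holds one short narrative script per capability (cohort simulation,
behavioral measures, moderation model, network modularity, brain–behavior
comparison); each prints the numbers it computes and what they mean.

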