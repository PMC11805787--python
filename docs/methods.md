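# Methods

This note records the statistical models the package implements, the
choices made where the design was genuinely open, and what the synthetic
benchmarks do and do not establish.

## Synthetic cohort generator

**Level-2 profiles.** The seven cognitive measures are drawn from a
Gaussian copula. Latent normal scores carry the documented Spearman rank
correlations, converted to the latent Pearson scale by
`r = 2·sin(π·ρ/6)`; scores are mapped through truncated-normal inverse
CDFs so each marginal is supported exactly on the measure's observed
[min, max]. The truncated distribution — not its parent — must match the
documented mean/SD, so the parent (μ, σ) of each marginal is solved
numerically from the truncated moments. For `boa` (breadth of attention,
cm) the documented moments sit slightly outside the truncated-normal
family (the mean lies close to the upper bound with a large SD); the
least-squares fit attains mean 76.80 / SD 10.83 against targets
77.15 / 11.31, within one third of a cohort standard error at n = 160.
Mapping through the inverse CDF (rather than accept–reject re-drawing)
keeps the copula's rank structure exact and remains efficient even when
the fitted parent is extreme, as it is for `boa`.

Demographic covariates mirror the documented cohort: handedness
right with probability 149/160, gender female 87/160, exposure to
right-to-left or spatially expressed languages (`altL`) 6/160. The
school code (two recruitment sites) and education years are not
documented; we use P(site 2) = 0.30 and education ≈ round(N(13.5, 1.5²))
clipped to 12–18 years, realistic for 18–23-year-old undergraduates.
These enter only the control terms of the model.

**Probe trials.** Each participant contributes a uniform 44–79 correct
positive-probe trials with responding hand ±1, probe position 1–5 and a
fair-coin task code ∈ {1, 2}. RT is the fixed-effect linear predictor
(cognitive moderators grand-mean-centered, demographics raw) plus the
participant's realized random effects over (intercept, Hand × Position,
Task, Task × Hand × Position) drawn from the documented unstructured τ
(verified positive definite; eigenvalues 19.0–1.2·10⁵ ms²), plus a
Gaussian residual with variance σ² = 76 098.4 ms². The residual
distribution is not documented beyond the model's Gaussian assumption;
the generator is Gaussian (an ex-Gaussian option was considered and left
out of scope). Negative draws are re-drawn by default — flooring would
bias the mean upward — with the count recorded in the ground truth; a
`floor` mode (at 1 ms) exists for stress tests. All randomness descends
from one seed through per-participant substreams.

**Task trials.** Breadth-of-attention trials use 33 tested cluster
distances and 4 trials per distance (132 trials); accuracy falls off
logistically with distance, crossing the 75% criterion exactly at the
profile's `boa`, with a 2 cm logistic slope. The documented 0.5 cm step
for the 33 distances is incompatible with the measure's 0–86.8 cm range,
so the grid spans the full range (step ≈ 2.63 cm); the `boa` estimator is
accurate to one grid step on average. Cueing tasks use the documented
168-trial mix (126 valid / 22 invalid / 20 catch) with the profile's
cueing effect added to invalid-trial RTs and 50 ms trial noise;
sequence-matching WM tasks use 120 trials in equal thirds (identical /
item-change / order-swap; the per-type split is not documented) with
Bernoulli accuracy at the profile's capacity and 0.90 on identical
trials.

**Time-series panels.** Node series are
`w·s_module(t) + b·g(t) + ε(t)` with independent unit-normal module
signals, one global signal, and unit noise; three runs by default. The
within/between covariance gap is `w²` regardless of `b`, so planted
structure disappears only when that gap falls below correlation sampling
noise — weak couplings or strong global drive. This matters for how the
benchmarks are read (below).

## Trimming, measures, exclusions

Two-stage trimming: an absolute task window (100–3000 ms; 100–1200 ms
for cueing detection), then fences Q1 − 3·IQR and Q3 + 3·IQR computed on
the window-surviving trials only. Quartiles use linear interpolation
between order statistics (the documented analysis does not state a
convention; ours is configurable). The rule is idempotent and
order-invariant.

Chance-level accuracy for n trials is `k*/n` with
`k* = max{k : P(X ≥ k) > α}`, `X ~ Binomial(n, ½)` — the largest
accuracy still consistent with guessing at one-sided level α. At
α = 0.05 this gives 70% (n = 20), 58.75% (n = 80), 57.5% (n = 120),
and 56.55% at n = 168 (95/168; the analysis we follow reports 56.6%,
which the exact rule does not produce — we keep the exact value).
Exclusion applies, in order: the catch-trial rule (responding on more
than 30% of 20 catch trials), task-accuracy rules at the task's exact
threshold, and for WM tasks a *conjunction* of sub-threshold accuracy
and a mean RT below the group-level Q1 − 3·IQR fast fence, so slow but
inaccurate participants are kept.

`boa` is the largest tested distance with accuracy above 75%. For
non-monotonic accuracy profiles this literal reading is ambiguous; the
default takes the largest qualifying distance, and a `monotone=True`
variant stops at the first dip.

## Mixed model

One grouping factor (participant). The marginal criterion is profiled:
with τ = σ²ΛΛᵀ and Λ a lower-triangular factor with log-parameterized
diagonal, both γ and σ² are profiled out, leaving a 10-parameter
(q = 4) optimization solved by L-BFGS with seeded restarts from a
method-of-moments start; convergence tolerance 1e-12 on the relative
criterion. Only per-group cross-product matrices enter each evaluation,
so cost is independent of trial counts. REML supplies estimates and SEs;
FIML supplies the deviance, AIC and BIC used for nested model comparison
(χ² on the deviance difference; the parameter count of the full model is
26 fixed effects + 10 covariance parameters + σ² = 37). An empty random
structure reduces the fit exactly to OLS (used by the reduction tests).

Satterthwaite df per coefficient: `df = 2f²/(∇fᵀ V_η ∇f)` with
`f(η) = Var(γ̂_j)` as a function of the variance parameters
η = (θ, log σ²), gradient and Hessian by central differences, and
`V_η = 2H⁻¹` from the restricted deviance Hessian. Boundary fits make H
singular in the collapsed directions; an eigenvalue-thresholded
pseudo-inverse treats those directions as fixed rather than inflating
the df, with the residual df as an upper bound and fallback.

Validation: our REML optimum on a full 4-slope model agrees with lme4
(bobyqa) to four decimals in loglik, estimates and SEs, and our REML/ML
criteria agree with statsmodels' `MixedLM.loglike` evaluated at our
estimates to 1e-11 (statsmodels' own optimizer does not reliably
converge on this model family, so the likelihood-value check is the
oracle, plus the requirement that our optimum is never worse than
theirs).

Johnson–Neyman boundaries are the real roots of
`(γ_f + γ_c w)² = t²·(v_f + 2w·c_fc + w²·v_c)`; the critical value uses
the t distribution at the interaction coefficient's Satterthwaite df
(configurable to normal; the documented analysis is silent). Boundary
classification (significant below/above/between/outside/everywhere/
nowhere) is decided by evaluating the t-ratio at probe points. When the
moderation coefficient is pinned to zero *with zero variance*, the
simple effect is significant everywhere iff |γ_f|/SE exceeds the
critical value; if the interaction variance is positive, significance
always dies at extreme moderator values because the conditional SE grows
linearly in |w|. Pick-a-point slopes default to mean ± SD of the
moderator, restricted (by flagging, not dropping) to the JN region and
observed range; the right-minus-left Position-slope difference is
`2(γ30 + γ50·task + γ_c·w)` with a delta-method SE, task fixed at the
midpoint 1.5 by default.

The experiment-1 runner fits the model on the generated (latent)
profile table, so the moderators match the values that generated the
RTs; task-derived estimates (`measured_profiles`) are produced alongside
for comparison. Feeding measured estimates instead would attenuate the
cross-level interactions by the tasks' measurement noise, which is a
property of the tasks, not of the estimator under test.

## Network pipeline

Connectivity is the per-run Pearson correlation of node time series;
runs are combined by the arithmetic mean of raw correlations (no Fisher
transform — matching the documented averaging; a z-average flag exists).
Thresholding keeps the `k = ceil(density·n(n−1)/2)` largest off-diagonal
weights and binarizes; ceiling is the only rounding consistent with all
seven documented retained-edge counts (400/3486, 247/2145, 294/2556,
153/1326, 177/1540, 171/1485, 119/1035 at 11.47%). "Strongest" defaults
to the signed correlation, with an |r| option (the source analysis is
ambiguous); ties at the cut break lexicographically and are logged.

Modularity follows the printed formula exactly, summing over ordered
within-module pairs including i = j, so the singleton partition scores
−Σa_i²/(2e)² and a single module scores 0; for binary graphs this equals
the standard Newman measure (networkx's implementation is the
independent oracle in tests). The optimizer is greedy pairwise
agglomeration on the modularity-gain matrix, single-node move refinement
(moves to an empty module permitted, so splits are reachable), and a
Kernighan–Lin pass (move-lock-revert with best-prefix acceptance),
cycled to a fixed point, with 20 seeded restarts from random partitions
of random granularity. On 100 random graphs with n ≤ 8 it matches
exhaustive enumeration over all set partitions exactly.

## Brain–behavior statistics

Pearson r uses the exact t-test. Steiger's Z compares two dependent
correlations sharing the behavior variable (Z1* variant): Fisher-z
difference scaled by `sqrt((n−3)/(2−2s))` where s is the
dependent-correlation covariance evaluated at the pooled correlation.
Two-sided by default; one-sided exposed, since the documented z = 1.51,
p = 0.06 pattern is one-sided. Sign convention: a positive
modularity–magnitude correlation means lower modularity accompanies a
more negative (larger) SPoARC effect. The documented pick-a-point levels
0.48/0.65/0.82 correspond to mean ± 0.17; the separately documented SD
of 0.65 ± 0.18 would give 0.47/0.83, so the probe-level helper is tested
at the rounding that reproduces the documented levels.

## Benchmark problem sizes and what they show

All simulated checks run at scales chosen for a single CPU:

- **Parameter recovery**: 300 replicates of 60 participants × 30 trials
  at the documented generating values; 95% Wald coverage for the
  Hand × Position and vsowm-interaction coefficients within 95% ± 3%,
  and mean γ̂30 within 2 Monte-Carlo SEs of −23.27. Sign recovery of the
  vsowm interaction is checked at the full 160-participant scale (12
  replicates), where its power is near 1.
- **Modularity oracle**: exhaustive enumeration for n ≤ 8 on 50 random
  graphs, plus hand-derived fixtures (two disjoint triangles → 0.5).
- **Johnson–Neyman**: quadratic roots vs. a 1e-4-step grid on 50
  randomized coefficient/covariance draws.
- **Calibration**: 10 000 null replicates at n = 25 for both the Pearson
  and Steiger tests (5% ± 0.7% rejection; Steiger null p-values pass a
  KS uniformity check at α = 0.01).
- **Monotonicity**: 10 between-coupling levels × 50 seeds on 24-node,
  3-module panels (w = 0.5, T = 60, 3 runs) thresholded at density 0.30.
  At the 11.47% density a 24-node graph keeps only 32 edges — fewer than
  the within-module pair count — so the binary topology is insensitive
  to coupling; 0.30 exercises the identical pipeline in a regime where
  between-module edges compete for the edge budget, and the coupling
  sweep extends to b = 2 because the within/between correlation gap
  (w²/(w²+b²+1)) must fall to the sampling-noise scale before planted
  structure degrades.

What passing these benchmarks does **not** show: the generator draws
exchangeable Gaussian trials with no sequential effects, no RT skew, no
speed–accuracy trade-off, and time series with no autocorrelation,
hemodynamics or motion artifacts; real-data coefficient values,
correlations (e.g. any observed modularity–behavior r) and exclusion
counts are properties of unavailable human data and are not reproduced,
only the machinery that would estimate them.
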