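# Methods

## Task generator

`task_design` draws a schedule of `n_games` games (default 162). Condition
counts follow the configured proportions exactly — 50% Unequal Information;
50% Equal Reward, with the Unequal-Reward remainder split 25% High / 75% Low
— using largest-remainder rounding when `n_games` does not divide evenly
(the allocation is logged). Condition order is shuffled by the schedule
seed.

Generative means are built as base ∈ {30, 50} plus a signed adjustment
∈ ±{0, 4, 12, 20}, giving the integer support 10–70 by construction (no
re-rounding is ever needed). Equal-Reward games share one mean; in
Unequal-Reward games two distinct adjustments around a common base are
drawn and the pair/odd roles follow the High/Low label. In Unequal-Info ×
Unequal-Reward games the twice-sampled deck is assigned a mean lower or
higher than its rivals with equal probability (stratified assignment), so
the payoff of the partially-informative option is balanced across games;
elsewhere means are laid onto decks by a uniform random permutation.

Outcomes are Gaussian with SD 8 around the deck mean, redrawn until inside
[1, 100], then rounded to the nearest integer. Redrawing (rather than
clipping) preserves the truncated-Gaussian shape; at SD 8 and means 10–70
the truncation is negligible in practice. `outcome_sd = 0` degenerates to
the rounded mean, which the tests use as a noise-free limit.

The free horizon is drawn from weights ∝ exp(λ·h), h = 1…6, λ = 0.5 —
an increasing ("inverse-exponential") profile with its mode at 6 and mean
≈ 4.8 free trials/game. Only the mode is pinned by the design; λ is
configurable.

## Choice models

All models share the delta rule `Q ← Q + α(r − Q)` applied to the chosen
deck on forced and free trials alike, with `q0 = 50` (the midpoint of the
outcome range; configurable) as the initial expectation. Value functions:

| model       | value of deck c                              | free parameters |
|-------------|----------------------------------------------|-----------------|
| sRL         | Q(c)                                         | α, β            |
| kRL         | Q(c) + k·n(c)                                | α, β, k         |
| nkRL        | Q(c) + k·n(c) + ν·1_novel(c)                 | α, β, k, ν      |
| leaky_nkRL  | Q(c) + k·ñ(c) + ν·1_novel(c)                 | α, β, k, ν, λ_leak |
| gnkRL       | Q(c) + k·n(c)^γ + ν·1_novel(c)               | α, β, k, ν, γ   |

`n(c)` is the within-game sample count; `ñ(c)` is the leaky accumulator
(all decks decay by `λ_leak` each trial, then the chosen deck gains +1).
The novelty indicator is additive and drops to zero permanently after the
deck's first sample — it is not implemented as a ν-inflated `q0` decaying
through the delta rule; the two diverge after the first update and the
additive form is the one adopted here. "Sampled" means an outcome was
observed; mere on-screen presence does not remove novelty. `k` is
deliberately unconstrained in sign (the knowledge term cannot distinguish
attraction to accumulated knowledge from aversion to incremental
information gain). Counts and novelty reset at every game start.

Choices are softmax with inverse temperature β ≥ 0, computed with
max-subtraction; β = 0 is the exact uniform policy. Free-trial simulation
breaks greedy ties implicitly through the softmax sampling stream; one RNG
stream per simulated subject keeps cohorts reproducible and
order-independent.

The likelihood engine propagates beliefs through forced and free trials in
order and sums −log P only over free choices. Because games are
conditionally independent given the parameters, the recursion runs
vectorized across games (padded to the longest game); the test suite checks
it to 1e-10 against a scalar brute-force replay written independently.
Log-probabilities are floored at log(1e-300); the floor is unreachable at
finite β on this value scale.

## Fitting

`ModelEstimator` is a scikit-learn estimator: bounded L-BFGS-B from
`n_starts` uniform random initial points (default 10) within per-parameter
boxes (α ∈ [0.001, 1], β ∈ [0.001, 2], k ∈ [−10, 10], ν ∈ [−50, 50],
leak ∈ [0, 1], γ ∈ [0.1, 3]; all configurable). Start points are drawn
sequentially from one seeded stream, so the start set for m starts is a
prefix of the set for n > m and the returned best-of-starts NLL is monotone
non-increasing in `n_starts`. The returned NLL is additionally floored at
the best initial point, and convergence failures are flagged rather than
hidden. Function tolerance 1e-8; ties between starts go to the first found.

BIC = 2·NLL + p·ln(n) with n = the number of free-choice trials (the
fitted observations). `compare_models` fits the models in nesting order and
hands each richer model the embedded optimum of its fitted nested relatives
as extra warm starts, so fitted NLLs respect nkRL ≤ kRL ≤ sRL up to
optimizer tolerance by construction rather than by luck.

### Parameter recovery

`recovery_study` draws generating parameters uniformly over
α ∈ [0.05, 0.95], β ∈ [0.05, 0.5], k ∈ [−2, 4], ν ∈ [−5, 30] — the box the
fitted human-scale estimates plausibly occupy — simulates each set on a
fresh 162-game schedule and refits *within the same box*, the conventional
simulate-and-refit design in which generating and fitting supports
coincide. This matters for one known degeneracy: as α → 0 the Q-values
freeze and β trades off against k along a likelihood ridge, so a refit with
a much wider β box can escape to the β bound on a few percent of subjects.
Within the matched box all four parameters recover with Pearson r > 0.95
at 62 subjects × 162 games in our runs (minimum r is the quantity
`scripts/acceptance.py` reports).

## Behavioral metrics

First free choices are classified from the forced history alone. In
Unequal-Information games: the never-sampled deck is *novelty-seeking*;
otherwise the experienced deck (2- or 4-times) with the strictly higher
within-game empirical mean is *reward-seeking* regardless of its sample
count, and the lower one is *general-information-seeking* (2×) or
*familiar* (4×). In Equal-Information games the strictly highest empirical
mean is reward-seeking and the strictly lowest is *undirected exploration*.
Empirical-mean ties are excluded (UNCLASSIFIED) rather than randomly
assigned, so the reported frequencies are deterministic. The three relative
frequencies use the denominators novelty+reward, novelty+general-info, and
classifiable Equal-Info trials respectively; empty denominators yield NaN
with the denominator reported, never a silent zero.

The novelty–familiarity shift is the frequency of choosing the currently
least-sampled deck on the first minus the last free trial of
Unequal-Information games with ≥ 2 free trials (positions where all decks
are equally sampled are excluded). Performance Π is the sum of free-trial
points across games — forced-trial rewards never enter. The per-subject
parameter distance is d_ν-k = |ν − k|, computed per subject and averaged,
not taken between group means.

Group prediction is an ordinary logistic regression (statsmodels) of group
on fitted k and ν; severity is an OLS on the same predictors; correlation
of parameters with Π applies Benjamini–Hochberg FDR across the tested
pairs. Degenerate designs (single group, separation) are rejected or
flagged, not silently fit.

## Synthetic cohorts

`cohort_synthesis` samples per-subject nkRL parameters from truncated
normal group distributions (rejection sampling — exact at this scale):
ν ~ N(12.43, 12.91²) for HC-like and N(5.58, 12.11²) for PG-like subjects;
k ~ N(0.43, 1.04²) and N(1.38, 2.01²) respectively; α ~ N(0.3, 0.15²) on
[0.01, 1] and β ~ N(0.3, 0.15²) on [0.01, 2] shared across groups (the
groups are built not to differ on either). Default sizes are 40 PG-like and
22 HC-like subjects. A gambling-severity score accompanies each subject
(HC fixed at 0; PG ~ N(8.8, 6.1²) truncated to [1, 27]). Every subject
plays an independently seeded schedule; the manifest records the master
seed, every derived per-subject seed and the generating parameters, so the
dataset and its closed-loop recovery are reproducible from the manifest
alone.

What the generator emulates — group-level parameter separation, the task
structure, trial counts — supports testing the *pipeline*: directional group
contrasts (less novelty-seeking, more general-information-seeking, smaller
novelty–familiarity shift in knowledge-driven agents; no difference in
Equal-Information games), sign structure of the group-prediction
regression, and recovery. What it does not emulate: within-subject
correlation between ν and k (draws are independent), session effects,
lapses, response times, or any questionnaire structure beyond the severity
score. Passing tests therefore validate the machinery and the qualitative
group structure, not quantitative claims about real populations.

## Performance landscape

`performance_landscape` simulates nkRL agents over a (ν, k) grid at fixed
α, β (defaults 0.3, 0.3, the cohort means) and reports mean Π per cell over
`n_reps` fresh schedules. All cells replay the same schedules with the same
outcome RNG seed (common random numbers), so cell-to-cell contrasts are not
drowned by Monte-Carlo noise and the surface is bit-reproducible. Local
maxima are cells that dominate their 8-neighborhood, with equal-valued
adjacent plateau cells merged into a single mode.

A finding worth stating plainly: at high replication (300–800 reps/cell)
the *expected* surface under this task is unimodal — a single broad mode
near (ν ≈ 0–5, k ≈ 2–3), with Π declining gently (≈ 0.4% in total) toward
high ν at every k and for every (α, β) we probed (α 0.1–0.9,
β 0.1–2, and a horizon-always-6 variant). A distinct high-ν/low-k optimum
appears in 50-rep maps only as a noise-made local maximum on this near-flat
plateau, on some seeds and not others. The corresponding end-to-end test
asserts the two-mode structure at the 25×25/50-rep scale with a fixed seed
and is expected to fail on seeds where the plateau's noise maximum falls
outside the high-ν region; we report this rather than smoothing the surface
or re-seeding, because the honest conclusion is that the two-mode structure
is not a robust property of the model at these settings.

## Problem sizes and numerical choices

Default study sizes (162 games, 62 subjects, 10 starts, 25×25 grid at 50
reps) run in about a minute to a few minutes each on one CPU thanks to the
game-vectorized engine; the heavier end-to-end checks (20-replication model
recovery, cohort refits) use 3–6 starts and 4-subject cohorts, sizes chosen
to keep the full suite in the minutes range while preserving the
qualitative outcomes. Monetary conversion floors points/60 to cents.
Derived seeds are 31-bit integers produced by a documented arithmetic hash
of (master seed, stage, index), recorded in manifests.

## Known limitations

- The ARTool-style aligned-rank two-way ANOVA is not provided; the package
  reproduces sign/direction structure, not published test statistics.
- Real-data quantities (regression coefficients, summed BICs, Wilcoxon
  p-values from human subjects) are out of reach by construction; only
  their directional structure is checked on synthetic cohorts.
- The β–k ridge at α ≈ 0 is a genuine identifiability limit of nkRL; any
  application to data with near-zero learning rates should interpret β and
  k jointly, not separately.
- The "inverse-exponential" horizon profile is one parametric choice
  (exp(0.5·h)) consistent with a mode at 6; other shapes with the same mode
  would perturb absolute Π but none of the directional results.
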