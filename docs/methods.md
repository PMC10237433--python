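# Methods

## Task and data model

The orthogonalized go/no-go task crosses required action with outcome
valence: cue 1 *go-to-win* (reward domain, correct = go), cue 2
*go-to-avoid* (punishment, go), cue 3 *no-go-to-win* (reward, no-go), cue 4
*no-go-to-avoid* (punishment, no-go). A session has 180 trials, 45 per
condition, in a uniformly shuffled order. The optimal action earns the
domain's beneficial outcome (+1 in the reward domain, 0 — shock avoided —
in the punishment domain) with probability 0.7; the other action reverses
the probabilities. Feedback is coded r ∈ {−1, 0, +1}, and by construction
reward cues never yield −1 and punishment cues never yield +1 — the
validator enforces this.

Trial tables are tidy data frames with columns `subjID, trial, cue,
keyPressed, outcome` (a common convention for this task; a `dialect`
argument remaps other column names). Trials must be gap-free and ordered
within subject; missing responses are not representable and rows without a
binary action are rejected. Subjects whose proportion of go responses on
go-to-win cues is strictly below 0.1 are excluded: failure in the easiest,
Pavlovian-congruent condition signals disengagement, not a learning style.

## Choice model

Action weights and choice rule, per trial:

    W(go, s)   = Q(go, s) + b + π_dom V(s)
    W(nogo, s) = Q(nogo, s)
    P(go | s)  = σ(W_go − W_nogo)(1 − ξ) + ξ/2

The two-option softmax is implemented as a logistic of the weight
difference (algebraically identical, numerically stable). Updates after
feedback r:

    Q(a, s) += ε (ρ_dom r − Q(a, s))
    V(s)    += ε (ρ_dom r − V(s))

V updates on every trial regardless of the action — it is the Pavlovian
stimulus value. Domain-split parameters (ρ_rew/ρ_pun in M2 and M3,
π_rew/π_pun in M3) are selected by the cue's domain; because reward cues
only ever deliver r ∈ {0, +1} and punishment cues r ∈ {−1, 0}, selecting by
outcome sign would be numerically identical in this task (asserted in a
test).

Parameter ranges: ξ, ε ∈ [0, 1]; ρ-family > 0; b and the π-family are
unconstrained reals. Allowing negative π is deliberate: group-level
posterior means of π can plausibly be negative (a slight anti-Pavlovian
coupling), and constraining π ≥ 0 would push such mass onto a boundary.
Q and V start at zero, the convention for this model family; the
first-trial choice probability then depends only on b and ξ.

## Hierarchy, priors and sampling

Individual unconstrained parameters use the non-centered parameterization
θ_ik = μ_k + σ_k z_ik with z_ik ~ N(0, 1). Constraining transforms: probit
(standard-normal CDF) for ξ and ε, exp for the ρ-family, identity for b and
π. Priors are weakly informative and config-exposed:

| quantity | prior | default scale |
|---|---|---|
| μ_k (ξ, ε, ρ-family) | Normal(0, 1) | unconstrained scale |
| μ_k (b, π-family) | Normal(0, 10) | natural = unconstrained |
| σ_k | half-Normal(0, 1), log-scale sampling with Jacobian | |
| z_ik | Normal(0, 1) | |

Sampling uses an adaptive Hamiltonian Monte Carlo sampler written for this
package: leapfrog integration with a diagonal mass matrix, dual-averaging
step-size adaptation to a 0.8 target acceptance statistic, Stan-style
windowed variance estimation for the metric during warmup, and jittered
trajectory lengths (nominal integration time 1.2, multiplier U(0.5, 1.5))
to avoid resonances. Gradients of the log posterior are exact: forward-mode
derivatives of Q and V with respect to the seven natural-scale parameters
are propagated through the trial recursion in a numba-compiled kernel, then
chain-ruled through the constraining transforms and the non-centered
hierarchy. The gradient is validated against central finite differences,
and the sampler against the exact moments of Gaussian targets; the kernel's
likelihood is validated against the pure-Python forward pass and an
independently coded trial-by-trial reference.

Defaults retain 4 chains × 2000 draws after 2000 warmup iterations each
(8000 retained draws). Convergence is certified when every sampled
quantity's split-Rhat (arviz) is ≤ 1.1 and divergent transitions are below
5% of draws; failures warn and flag the result rather than hard-failing, so
pipelines can distinguish "ran" from "trustworthy". Each group is fitted
separately, sharing no hyperparameters — the group comparison then contrasts
two independent posteriors.

Probabilities in the gradient kernel are clamped at 1e−300 before taking
logs so that the extreme parameter values probed during step-size search
remain differentiable; at any parameter value visited post-warmup the clamp
is inactive.

## Model comparison and prediction

The pointwise unit for PSIS-LOO is the **subject** (session log-likelihood
summed over trials, evaluated for every retained draw): subjects are the
exchangeable units of the hierarchy. LOOIC = −2·elpd_loo; PSIS smoothing is
delegated to arviz and checked against the closed-form leave-one-out
predictive density of a conjugate normal-mean model. Pareto-k diagnostics
are reported, not refit. With few subjects and long, informative sessions
the importance weights can be heavy-tailed (Pareto-k > 0.7): in that regime
PSIS-LOO drifts optimistic relative to exact leave-one-subject-out
refitting — it stays bounded between the exact elpd and the in-sample lpd,
and the k diagnostics flag it (asserted in the test suite). Trust the
ranking, not the absolute elpd, when k values are high. Models are ranked
per group by LOOIC; when a
single best model must be carried forward for the group comparison, the
default is the lowest LOOIC summed across groups (overridable).

One-step-ahead prediction rolls each subject's latent state forward
conditioning on their *actual* actions and feedback, so the predicted p(go)
for trial t uses trials 1..t−1 only; predictions are averaged over all
retained draws. The summary correlation is computed per subject across the
four condition-level (mean predicted p(go), observed go frequency) pairs
and then averaged over subjects; a `trial_bin` alternative correlates over
consecutive within-condition bins instead, for users who want more than
four points per subject. Subjects with a flat profile in either variable
have an undefined correlation and are excluded from the cohort mean.

## Group comparison and behavioral indices

A parameter's group difference is formed on the natural scale from the two
fits' group-mean draws (transform of μ_k). Separately fitted groups have no
natural draw pairing, so draws are paired after a seeded permutation of
each fit's pooled draws — the arbitrary pairing made explicit and
reproducible. The difference is credible when its 95% HDI excludes zero.
The HDI is the shortest contiguous interval containing ⌈mass·n⌉ sorted
draws (verified against a brute-force window search and against arviz).

Behavioral indices from per-condition accuracies:

    overall    = (go_to_win + nogo_to_avoid) − (nogo_to_win + go_to_avoid)
    reward     =  go_to_win − nogo_to_win
    punishment =  nogo_to_avoid − go_to_avoid

The overall index is parenthesized congruent-minus-incongruent, so it
decomposes exactly into the two domain indices. Group tests on the indices
use Student's unpaired pooled-variance t by default (df = n₁ + n₂ − 2); a
paired mode exists, with the caveat that within-group condition contrasts
on the same subjects are arguably paired — both are provided and the
default follows the unpaired-df convention for this analysis. No
multiple-testing correction is applied; per-test p-values are reported.

## Synthetic studies

The generator runs the choice model forward. All randomness descends from
one seed through a `numpy.random.SeedSequence` hierarchy
(study → group → subject → schedule/trials), so every cohort is
bit-reproducible; schedules are independent across subjects. The default
two-group template (17 vs 14 subjects) encodes realistic group structure:
a "sham-like" group B with noticeable noise (ξ ≈ 0.10), learning rate
≈ 0.33, a positive go bias (b ≈ 1.0 unconstrained mean), a positive
punishment-domain Pavlovian bias (π_pun mean 0.5) and outcome sensitivities
ρ_rew ≈ 12, ρ_pun ≈ 7; and an "active-like" group A with lower ξ, b and
π_pun and identical ε and ρ. Between-subject SDs are 0.3 on the
probit/log-scaled parameters and 0.5 on b and π — moderate individual
differences that keep simulated cohorts heterogeneous without producing
degenerate responders.

What the generator does *not* emulate: reaction times, missed responses,
attention lapses that drift over time, practice effects across repeated
sessions, or any mechanistic effect of brain stimulation. Passing recovery
tests therefore show that the pipeline is self-consistent — data generated
by the model are correctly re-estimated at these sample sizes — not that
the model is true of any human dataset.

## Desk-scale settings and numerical choices

The shipped tests and the acceptance script use reduced but honest problem
sizes chosen as the package's default desk scale: convergence checks fit 15
subjects × 180 trials with 4 chains × (1000 + 1000); parameter recovery
uses 20 subjects with 2 chains × (1000 + 1000) and requires ≥ 6 of 7
group-mean 95% HDIs to cover the generating truth; model recovery (data
from M3 with π_rew = 0, π_pun = 1.5 selecting M3 over M1 by LOOIC) and the
two-group π_pun effect (group means differing by 1.0 at n = 20/group) use
the same chain settings. A full-defaults fit (4 × 2000 + 2000) of one
15-subject group takes well under a minute on one CPU.

Ties in model ranking keep input order; LOOIC units must match across
compared models; pointwise log-likelihood columns that are constant across
draws raise a degenerate-weights error rather than silently producing
infinite Pareto weights. HDI computation requires at least 100 draws.
Empty condition cells make accuracy undefined and raise.

## Known limitations

- The sampler is static-trajectory HMC, not NUTS; pathological posteriors
  (e.g. near-zero group SDs with few subjects at very short warmup) can
  show elevated Rhat — such fits are flagged, and more warmup or more
  subjects is the remedy.
- Group SD priors (half-Normal(0, 1)) mildly regularize heterogeneity; with
  fewer than ~5 subjects the group-level posterior is prior-dominated.
- LOO at the subject level estimates predictive accuracy for a *new
  subject*; trial-level LOO would answer a different question and is not
  provided.
- The one-step-ahead condition-level correlation uses only four points per
  subject and is accordingly coarse; the binned variant trades variance for
  resolution.
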