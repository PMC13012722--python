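# Methods

This note documents the models implemented in `socdec`, their conventions,
the synthetic-data generator's assumptions, and the design choices made
where more than one reasonable implementation existed.  Nothing here states
an empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Task model

A session has 60 trials: 20 *gain* (safe amount from {10, 15, 20, 25, 30}
cents versus a lottery of 0 or the safe amount times a multiplier from
{1.68, 1.82, 2, 2.22, 2.48, 2.8, 3.16, 3.6, 4.2, 5}), 20 *loss* (the exact
mirror with negated amounts), and 20 *mixed* (safe 0 versus a lottery of a
gain from {15, 25, 40, 55, 75} and that gain times a multiplier from
{−0.2, −0.34, −0.5, −0.64, −0.77, −0.89, −1, −1.1, −1.35, −2}).  Lottery
outcomes are equiprobable and, in two-player conditions, resolved
independently per player.  Non-integer products are rounded half away from
zero to integer cents, so loss trials mirror gain trials exactly.

Conditions (*solo*, *social*, *partner*) appear 20 times each per session in
a random order constrained to runs of at most two; the sequencer
rejection-samples permutations and fails loudly on infeasible configurations
rather than relaxing the constraint.  Amount and multiplier draws are
i.i.d. uniform over their sets, and trial class is randomised independently
of condition, since no balancing scheme is specified for either.  The
partner policy is deterministic expected-value maximisation with strict
inequality: lottery iff EVdiff > 0, safe on exact ties.  Happiness probes
follow every second trial; a probe after trial *t* incorporates events of
trials 1…t.  Screen side of the safe option is randomised and recorded but
unused.  Display timing and inter-stimulus intervals are out of scope.

## Happiness models

All five models express Z-scored momentary happiness as weighted,
exponentially decaying sums of per-trial events, with no intercept (the
ratings are Z-scored per participant, pooled over sessions, sample-SD
convention).  Events for unchosen options are zero; per trial at most one of
CR (safe chosen) and EV (lottery chosen) is non-zero.  The partner's RPE is
split by decision-maker: `social_pRPE` on participant-chosen lotteries in
the social condition, `partner_pRPE` on partner-chosen lotteries, never both
non-zero.  Inequality terms use realised rewards S and P; the
absolute-inequality regressor is |S − P| (an outer max with zero would be
vacuous), and advantageous/disadvantageous inequality are its two halves,
so abs_ineq ≡ adv_ineq + disadv_ineq.  Solo trials contribute no
partner-dependent events.  CR/EV/sRPE accrue in partner-condition trials as
well — the model equations condition on the chosen option, not on the
chooser.

Decayed sums use the convention γ⁰ = 1 even at γ = 0 (γ = 0 reduces to
current-trial events, γ = 1 to cumulative sums).  Decay does **not** carry
across session boundaries by default — sessions are separated in time — and
this is toggleable in the block-builder.

### Fitting

Given γ the model is linear, so fitting profiles γ: weights are solved by
no-intercept OLS at every point of a [0, 1] grid with step 0.001 (solved for
all grid points at once via batched normal equations with a pseudoinverse,
which also handles sessions where a regressor never occurs), followed by a
bounded local refinement within one grid step.  The returned SSE is
guaranteed ≤ the best grid SSE; the profile is deterministic, with no random
restarts.  Rank deficiency at the optimum is flagged on the fit.

### Fit metrics

* R² = 1 − SSE/SST with SST = Σy² (y is Z-scored, mean 0, so centred and
  uncentred SST coincide).  A no-intercept fit of zero-mean data cannot do
  worse than the zero model, so R² ∈ [0, 1].
* adjusted R² = 1 − (1 − R²)(n − 1)/(n − k_w − 1) with k_w the number of
  weights (γ not counted).
* Log-likelihood is full Gaussian with σ̂² = SSE/n.  The primary AIC/BIC
  fields count k = k_w + 2 parameters (weights + γ + residual variance).
  Because published comparison tables in this literature often use the
  least-squares form n·log(SSE/n) + penalty with k = k_w + 1 (γ but not
  σ²), the fit also carries `aic_ls`/`bic_ls` in that convention; model
  *rankings* are what matter and both conventions are reported by
  `compare_cohort`.
* The likelihood-ratio statistic is the conventional non-negative
  2·(logL_full − logL_nested) with df equal to the extra weight count,
  referred to the χ² upper tail.  (A printed form with the opposite sign
  appears in parts of the literature; it is the same quantity up to sign
  and the non-negative convention is used throughout.)
* `count_weights` reports the weight-only parameter count (3/4/5/5/4 for
  basic/inequality/guilt-envy/responsibility/responsibility-redux), the
  convention of published model-comparison tables.

### Parameter recovery

Per participant: fit the model, generate noise-free predictions at the same
probes from the fitted (w, γ), add Gaussian noise with SD equal to the SD of
those predictions ("one SD of noise"), refit, repeat 10 times; regress mean
recovered values on generating values per parameter.  The refit treats the
synthetic ratings as already standardized: they are generated from
parameters that were estimated on the Z-scored scale, and re-Z-scoring would
shrink every recovered weight by the synthetic ratings' SD, biasing slopes
away from 1 even in the noiseless limit (where recovery is exact by
construction).

## Risk preferences

**Risk premium.**  A per-participant, per-condition logistic fit of risky
choice on EVdiff; the premium is −β₀/β₁, the EVdiff of 50% risky choice,
positive under risk aversion.  Undefined (and flagged) when β₁ ≤ 0, the fit
fails, or choices are one-sided.

**CARA.**  The printed exponential utility U(x) = 1 − e^(−ρx) is
inconsistent with the certainty-equivalent formula CE = log(1 − ρ·EU)/(−ρ);
that formula is exact for the *normalized* utility U(x) = (1 − e^(−ρx))/ρ,
which is what this package adopts — it makes the estimator self-consistent
and scale-correct, and CE → EV analytically as ρ → 0.  Choice probabilities
follow a probit in (CE − safe)/σ with Fechner noise σ; (ρ, σ) minimise
squared residuals between observed 0/1 choices and those probabilities
(multi-start non-linear least squares).  ρ is bounded in [−0.1, 0.1] per
cent, which keeps 1 − ρ·EU positive over the task's payoff range; a fit is
flagged unreliable when trials are too few or one-sided, the optimiser ends
on the ρ bounds, or SE(ρ) > |ρ| + 0.02 (Gauss–Newton SE; thresholds
configurable).  Gain and loss trials are pooled by default; stratified
fitting is available via the underlying function.

**Condition comparisons** are two-tailed paired t-tests with Cohen's
d = mean(diff)/SD(diff).  Identical vectors give t = 0, p = 1; a non-zero
constant difference has zero variance and is flagged invalid rather than
reported.

**Manipulation check.**  The mixed-effects logistic regression of risky
choice on mean-centred EVdiff, condition (solo = 1, social = 2) and their
interaction, with per-participant random intercepts and uncorrelated random
slopes, is fitted by lme4's `glmer` (maximum likelihood, Laplace
approximation) through an Rscript bridge; no maintained frequentist GLMM
exists in the Python stack used here.  Boundary-singular fits are flagged
but not treated as convergence failures.

## Guilt-effect stage

Each probe is assigned to the single most recent trial's outcome (probes
occur every two trials; the intervening older trial is not used).  The
post-lottery table keeps probes whose assigned trial was a chosen lottery in
the social or partner condition, with dummies sHigh/pHigh (participant /
partner received the high outcome) and sDec (participant chose, i.e. the
social condition).  The mixed model has the three main effects and all
two-way interactions, participant random intercepts, REML estimation
(statsmodels MixedLM); reported t statistics use the residual-df convention
(n − fixed-effects), matching how such models' t(·) values are usually
printed; Satterthwaite-style df are not computed.  Because ratings are
Z-scored per participant, between-participant mean differences are largely
removed and the random-intercept variance often estimates at zero; this is
flagged as a warning, not an error.

The stratified guilt contrast is, per participant and self-outcome stratum,
mean z-happiness after partner-low outcomes in the social condition minus
the partner condition; strata use disjoint trial sets by construction.
Participants with an empty cell are dropped with a flag; if more than 20%
are missing the computation aborts with diagnostics.  Tests are two-tailed
paired t-tests with Cohen's d and a JZS Bayes factor — Cauchy(0, √2/2)
prior on the standardized effect, marginal likelihood by adaptive
quadrature (relative accuracy 1e-8; the independent cross-check in the test
suite is pingouin's implementation).

The agency effect regresses all Z-scored ratings on a dummy for
"participant chose the assigned trial" (social + solo vs partner) with
participant random intercepts.

Sample-size planning uses the exact noncentral-t power of a two-tailed
paired t-test, returning the smallest n whose power reaches the request.

## Synthetic cohorts: what they emulate and what they do not

The generator reproduces the study geometry (40 participants × 3 sessions
of 60 trials; the two-session variant of the second study is a parameter),
the task's amount sets, condition sequencing, partner policy, independent
lottery resolution, and probe schedule.  Agents' choices follow logistic
policies whose population slope on EVdiff is centred on 0.074 per cent (the
scale of the cohort-level choice coefficient) with a mean risk premium of
2 cents (SD 4); happiness follows the responsibility-redux model with
γ ~ N(0.42, 0.06) (the published medians range 0.39–0.46) and weights
ordered sRPE (0.020 /cent) > CR (0.015) ~ EV (0.012) > social_pRPE (0.010)
> partner_pRPE (0.005), inequality weights small and negative — the
orderings reported for the human cohorts.  Across-participant weight SDs
are 40% of the mean magnitude.  Rating noise SD equals the SD of the
noise-free predictions (noise_scale = 1), giving model R² near 0.5 — the
same order as, slightly above, the human values — and making the recovery
procedure's re-fitting scale-neutral.

Synthetic agents do **not** emulate: reaction times, learning or drift
across sessions, rating-scale truncation or discreteness (ratings are
generated on the latent scale; the analysis Z-scores per participant either
way), partner emotional responses, or any dependence of choices on past
outcomes.  Passing tests therefore demonstrate that the estimators recover
the generative structure the analysis assumes, not that human data satisfy
those assumptions.

## Problem sizes and numerical choices

The test suite runs the full property checks at study geometry: parameter
recovery uses 40 agents × 180 trials with 10 repetitions; the end-to-end
guilt check uses a 40 × 3-session cohort; the type-I calibration of the
pHigh×sDec test uses 300 null cohorts of 16 agents × 2 sessions (a
deliberately reduced replicate size with a pre-specified binomial 3σ band,
0.01–0.09, around the nominal 5%).  The γ grid step is 0.001; decayed-sum
oracle equivalence is asserted to 1e-10 against a brute-force double loop;
noise-free generative round trips recover weights to 1e-6.  All simulations
are seeded; identical configurations reproduce outputs bit-identically.

## Known limitations

* The CARA estimator is least-squares on choice indicators, not binomial
  maximum likelihood; this follows the established econometric recipe it
  implements but is statistically less efficient.
* Mixed-model p-values use residual df; with few participants they are
  anti-conservative relative to Satterthwaite/Kenward–Roger.
* The guilt LMM's random-intercept variance is weakly identified after
  per-participant Z-scoring (see above).
* Real-data import is supported through the documented CSV schema only; no
  BIDS adapter is included.
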