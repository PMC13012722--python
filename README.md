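# socdec

Simulation and analysis of **risky social decisions and their emotional
consequences**: a complete, tested pipeline for studying interpersonal guilt
and responsibility with momentary-happiness computational models.

## The problem

In the underlying experimental paradigm, a participant repeatedly chooses
between a safe amount and a two-outcome lottery (equiprobable outcomes) under
three conditions: *solo* (their choice pays only themselves), *social* (their
choice pays both themselves and a partner), and *partner* (an
expected-value-maximising algorithm chooses for both).  When a lottery is
chosen in a two-player condition it is played out **independently** for each
player, so the partner can lose while the participant wins.  Every two trials
the participant reports momentary happiness on a 100-point scale.

The scientific question: does *responsibility* change how another person's
outcomes affect us?  Operationally, the **guilt effect** is the extra drop in
happiness after the partner receives the low lottery outcome when the
participant — rather than the partner — made the choice.

`socdec` provides, for each stage of this analysis:

* **Task generation** (`socdec.task`) — 60-trial sessions with 20 mixed, 20
  gain and 20 loss trials drawn from the study's amount/multiplier sets, no
  more than two consecutive trials of one condition, probes every two trials.
* **Synthetic agents** (`socdec.agents`) — choice policies (logistic on the
  expected-value difference, or CARA expected utility with Fechner noise)
  and generative happiness ratings, with recorded ground truth.
* **Risk preferences** (`socdec.risk`) — risk premium −β₀/β₁ from a logistic
  choice fit; CARA ρ and Fechner σ from a certainty-equivalent probit,
  CE = log(1 − ρ·EU)/(−ρ); paired condition comparisons; a mixed-effects
  logistic manipulation check (lme4 `glmer` under the hood).
* **Happiness models** (`socdec.happiness`) — five nested models of
  Z-scored happiness built from exponentially decaying event sums,

  `happiness(t) = Σ_k w_k Σ_{j≤t} γ^(t−j) X_k[j]`,

  with regressors for certain reward (CR), chosen-lottery expected value
  (EV), the participant's reward prediction error (sRPE), inequality terms,
  and the partner's RPE split by who chose (social_pRPE vs partner_pRPE).
  Fitting profiles γ on a grid with exact OLS for the weights; model
  comparison (R², adjusted R², AIC/BIC, likelihood-ratio tests) and
  parameter recovery are included.
* **Guilt inference** (`socdec.guilt`) — the post-lottery mixed model with
  the pHigh×sDec interaction, stratified per-participant guilt contrasts
  with Cohen's d and default-prior (JZS) Bayes factors, the agency effect,
  and noncentral-t power / sample-size computation for paired designs.

## Worked example

The numbered scripts under `analysis/` run the whole study on a synthetic
cohort (40 participants × 3 sessions, responsibility-redux truth):

```bash
cd analysis
python 01_simulate.py && python 05_guilt_effects.py
```

prints (abridged):

```
simulated 40 participants x 3 sessions (7200 trials, 3600 happiness probes)
1195 post-lottery probes from 40 participants
pHigh x sDec interaction: beta = 0.668, t(1188) = 6.20, p = 7.98e-10 — partner outcomes matter more after own choices
guilt effect [self_high]: -0.343 z-units, t(37) = -2.21, p = 0.0337, d = -0.36, BF10 = 1.5
guilt effect [self_low]: -0.465 z-units, t(38) = -3.85, p = 0.0004, d = -0.62, BF10 = 63.5
```

The positive pHigh×sDec coefficient says the partner's lottery outcome
moves happiness more when the participant chose; the negative stratified
contrasts say that after partner-low outcomes the participant feels worse
when they themselves were responsible — the guilt effect.  `02` fits risk
preferences, `03` compares the five happiness models (the generating model
family wins on every criterion), and `04` verifies parameter recovery
(slopes ≈ 1).

The same stages are available as a CLI (`socdec simulate-cohort`,
`socdec risk-prefs`, `socdec fit-happiness`, `socdec guilt`,
`socdec recover`, `socdec run-all`) for use on any dataset directory in the
documented CSV schema, including imported real data.

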