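# Methods

## The valuation problem

EQ-5D-5L describes health by five dimensions — mobility (MO), self-care (SC),
usual activities (UA), pain/discomfort (PD), anxiety/depression (AD) — each at
one of five levels, giving 5^5 = 3,125 states written as five-digit codes.  A
value set assigns each state a societal utility anchored at 1 (full health,
11111) and 0 (dead).  Utilities are elicited for a subset of states by
composite time trade-off (cTTO) interviews — responses on [-1, 1] in 0.05
steps — and by discrete choice experiments (DCE), then a parametric model
interpolates to all 3,125 states.

## Structural models

The modelled quantity is the disutility `du(s) = 1 - u(s)`.  Two forms:

* **additive20**: `du = alpha + sum_{d,l>=2} beta_{d,l} x_{d,l}`, one
  coefficient per dimension-level dummy (20 free parameters).
* **multiplicative8**: `du = alpha + sum_d beta_d L_{l(d)}`, a dimension
  weight times a shared level multiplier, with `L_1 = 0`, `L_5 = 1` fixed
  (5 + 3 = 8 free parameters).

The optional intercept `alpha` applies to every state except 11111, the usual
valuation convention; without it `u(11111) = 1` exactly.  A coefficient set
is *logically consistent* when worsening any dimension never raises utility;
for the multiplicative form this is exactly "all `beta_d > 0` and
`0 < L2 < L3 < L4 < 1`".  For a complete value set, consistency over all
dominance pairs is equivalent to monotonicity over the 12,500 single-level
worsening moves, since any dominance relation is a chain of such moves; the
checker exploits this.

## Observation models

**cTTO.**  For respondent *i* valuing state *s*:

    du*_is = v_s + a_i + eps_is,   a_i ~ N(0, tau^2),   eps_is ~ N(0, sigma_s^2)
    sigma_s = sigma_a + sigma_b * v_s

with `v_s` the structural disutility of the *current* parameter iterate
(self-consistent heteroscedasticity, not a first-stage plug-in).  The
response scale truncates what can be expressed: nothing below -1 (disutility
above 2) or above 1 (disutility below 0).  Observations at -1 therefore
contribute `P(du* >= 2 | a_i)` and — by default — observations at 1
contribute `P(du* <= 0 | a_i)`; interior observations contribute the normal
density.  The ceiling term (`ModelSpec.ceiling_censored`) is this package's
design choice: the floor-only model is biased whenever the residual SD is
non-negligible at mild states, because their values pile up at 1 — in
simulation at the default noise level the floor-only model overstates `L2`
by about +0.05 (three SEs at n = 1,237) and understates `beta_AD`; with the
ceiling term all structural biases fall below 0.01.  Set
`ceiling_censored=False` to reproduce the floor-only convention.

The respondent random intercept is integrated out with non-adaptive
Gauss-Hermite quadrature, 31 nodes by default.  At the noise magnitudes seen
in valuation data the 31-node value is within 1e-9 of the 61-node value (a
property test enforces < 1e-6).  Non-adaptive quadrature degrades when
`tau` is far above the residual scale — the integrand becomes a spike between
nodes and the likelihood plateaus; the tau starting value is therefore capped
at half the OLS residual SD.

**DCE.**  Conditional logit on the same structural disutilities:
`P(choose A) = logistic(theta * (du_B - du_A))` with `theta > 0` the scale
bridging the two response formats.  The sign convention (disutility
differences) is fixed and documented; it is equivalent to the utility-
difference convention up to relabelling.

**Hybrid.**  The weighted sum of cTTO and DCE log-likelihoods with shared
structural coefficients; respondent weights multiply each respondent's whole
contribution, so the log-likelihood is exactly linear in the weights.

## Estimation

Parameters are optimised on an unconstrained scale: log for `tau` and
`theta`, identity for everything else; `sigma_s > 0` is enforced by rejection
(-inf log-likelihood) so `sigma_a`, `sigma_b` stay interpretable.  All
gradients are analytic and checked against central finite differences by a
property test.

L-BFGS-B maximises the objective normalised by total respondent weight (the
mean per-respondent negative log-likelihood), so the convergence criterion —
projected gradient below `gtol = 1e-5` — does not depend on sample size.
The deterministic start is OLS of the uncensored disutilities on the 20
dummies (collapsed to the multiplicative form via the level-5 dummies and the
mean level ratios), `tau = min(0.1, 0.5 * OLS residual SD)`, `sigma_a` at the
OLS residual SD, `sigma_b = 0`, `theta = 3`.  `fit_model` runs 3 starts by
default (the base start plus 2 seeded perturbations); warm-started refits
(cross-validation folds, bootstrap replicates) use a single start.
Non-convergence is warned about and recorded, never silently returned.

## Reference means, fit metrics, selection

The reference for all fit metrics is the set of **Tobit censored state
means**: one mean per directly valued state with a shared residual SD,
right-censored at disutility 2, fitted jointly by ML and reported on the
value scale.  States whose observations are all censored are flagged and
reported at the floor.  Metrics (RMSE, MAE, Lin's CCC with 1/n variances,
ICC(A,1) two-way absolute agreement, Pearson r) are computed over the
directly valued states only.

Model selection uses leave-one-cTTO-block-out cross-validation: each of the
10 blocks is held out, the model is refitted on the remaining 9 (DCE data
always included for hybrid variants, since DCE blocks are not aligned with
cTTO blocks), and the held-out block's states are predicted and compared to
censored means computed from the *full* data — those means are the best
available per-state target; a flagged alternative computing them from
training folds only is deliberately not the default.  Logically inconsistent
or non-converged candidates are discarded; the minimum pooled CV-RMSE wins.

## Weighting

Only marginal population totals are published, so the default re-weighting is
iterative proportional fitting (raking) on age group, sex, education and
region (a flag restricts to any subset), converged when every weighted margin
is within 1e-6 of target, normalised to mean 1, trimmed at 5.  Sample
categories missing from the margins (e.g. gender "other") keep their weighted
share and the listed targets are rescaled into the remaining mass, so no
respondent receives zero weight.  A logistic-propensity variant (sample vs. a
margin-expanded pseudo-population under independence) is available behind
`method="logistic"`; with independent margins it agrees with raking up to
sampling noise.

## Bootstrap

Uncertainty comes from resampling respondents with replacement, each carrying
their full cTTO and DCE records.  Weights are re-derived inside every
replicate when a weighting procedure is supplied, so weight uncertainty
propagates (default on; the alternative is a one-line change).  Replicates
refit from the full-data optimum with a single start; non-converged
replicates are dropped and counted, with a hard error above 5%.  SE = SD of
replicate estimates; 95% CI = 2.5/97.5 percentiles.  Production default is
B = 1,000 (B is a parameter everywhere); the analysis scripts use B = 200.

## What the generator does and does not emulate

`simulate_study` reproduces the design structure (10 cTTO blocks x 10 states
with one very mild state and 55555 each, 86-state universe; 28 DCE blocks x 7
pairs), the latent censored heteroscedastic random-intercept model, the 0.05
response grid, block randomization, demographics drawn from population
margins, interview durations, and injectable protocol violations (fast
interviews, misvalued worst state, feedback flags).

It does **not** emulate deliberate, internally coherent response behaviour:
noise is independent across a respondent's states (beyond the shared random
intercept).  One visible consequence: the worst-state QC rule ("55555 valued
at least 0.5 above the respondent's minimum") has a 15-20% false-positive
rate on fully compliant simulated data at the default noise level, because
censoring piles several severe states at -1 — whereas real interviews flag
only ~2%, respondents being far more rank-coherent than independent noise.
Passing QC tests therefore demonstrate the rules fire exactly as defined, not
that the simulated flag *rate* matches field rates.  A knock-on effect: on
simulated data those false-positive exclusions are correlated with the noise
draws, so running the full pipeline (which applies QC) shifts some
coefficients by a few hundredths relative to fitting the uncleaned data —
visible in the analysis scripts, and absent from the parameter-recovery
study, which simulates compliant data and skips QC.  Interviewer effects,
interview modes and the feedback-module interaction itself are out of scope
(only the resulting flag is represented).

The 0.05 grid is reproduced in simulation, but the likelihood treats interior
observations as continuous, matching standard practice; the quantisation
noise (SD ~0.014) is absorbed into `sigma_a`.

## Numerical and test-design choices

* Coefficients are stored at full precision; published-number checks feed the
  3-d.p. printed table in and round outputs to the printed precision.
* The single-level transition statistic is defined over all 12,500 worsening
  moves (move-weighted); its closed form under the multiplicative model is
  `(sum_d beta_d)/20`, which reproduces the printed mean to within rounding.
  The published SD for that statistic is computed under an undocumented
  definition and is not targeted.
* Dominance ties count as consistent; state order is everywhere lexicographic
  by code.
* Degenerate inputs: empty data tables raise; all-censored states are flagged
  at the boundary; `theta <= 0` raises; `sigma_s <= 0` anywhere on the data
  rejects the iterate.
* Simulation-based tests run at deliberately chosen reduced scales (e.g.
  selection consistency at n = 600 over 20 replicates, bootstrap coverage at
  n = 250 with B = 50 over 8 replicates, quadrature checks at 9-15 nodes)
  with fixed seeds; parameter recovery runs at the full n = 1,237 over 20
  replicates.  Bootstrap SEs used in the recovery check are computed once
  (B = 40) on the first replicate — the SE is a property of the design and
  sample size, not of the replicate.

## Known limitations

* No interval-censored likelihood for the response grid.
* No analytic (sandwich/delta) standard errors; bootstrap only.
* No probit DCE variant and no DCE-only anchoring.
* Raking matches marginal totals only; joint population tables are not
  supported (none are published).
* The exact published coefficient estimates can only be reproduced from the
  deposited interview data, which is neither bundled nor downloaded; with
  simulated data the pipeline reproduces the *structure* of those results
  (model choice, ranking, consistency), not the digits.
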