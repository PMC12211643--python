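# Methods

## The estimation problem

A two-stage SMART randomises each participant twice: to a stage-1
treatment `A1 ∈ {−1, +1}` given a binary baseline covariate
`O1 ∈ {−1, +1}`, and — after the binary responder status
`O2 ∈ {−1, +1}` is observed — to a stage-2 treatment `A2 ∈ {−1, +1}`.
A single continuous outcome `Y` is measured at the end of stage 2.
The target of inference is the optimal dynamic treatment regimen, i.e.
decision rules mapping history to treatment at each stage, estimated by
two-stage Q-learning:

1. **Stage 2.** OLS of `Y` on the working model
   `Q2(H2, A2) = β20 + β21 O1 + β22 A1 + β23 O1A1 + (ψ20 + ψ21 O2 + ψ22 A1) A2`.
2. **Pseudo-outcome.** Each record's best attainable stage-2 value,
   `Ŷ1 = β̂2ᵀH2 + |ψ̂2ᵀH2|` (the stage-1 reward is identically zero when
   only one end-of-study outcome exists).
3. **Stage 1.** OLS of `Ŷ1` on
   `Q1(H1, A1) = β10 + β11 O1 + (ψ10 + ψ11 O1) A1`.

`ψ10`, the stage-1 treatment main effect, is the primary estimand;
`ψ20` is the secondary, stage-2 estimand.  Optimal rules are
`d̂k(h) = sign(ψ̂kᵀh)`; an exact zero means no unique optimal action
(*non-regularity*).  We break ties deterministically towards `+1` and
flag them; no non-regularity correction (shrinkage, thresholding,
m-out-of-n bootstrap) is applied — the package studies plain Q-learning
on purpose.

## Generative model and the five treatment-effect settings

`O1`, `A1`, `A2` are fair ±1 coins; responder status follows
`P(O2 = 1 | O1, A1) = expit(δ1 O1 + δ2 A1)`; the outcome is
`Y = γ1 + γ2 O1 + γ3 A1 + γ4 O1A1 + γ5 A2 + γ6 O2A2 + γ7 A1A2 + ε`,
`ε ∼ N(0, 1)`.  Stage-2 randomisation is fair within every `(A1, O2)`
stratum, so a single per-record fair draw is identical in distribution
to stratified randomisation; blocked assignment is deliberately not
implemented.

The five presets all use `δ1 = δ2 = 0.5` and differ only in `γ`:

| setting | γ3 | γ5 | γ7 | regularity | true ψ10 |
|---|---|---|---|---|---|
| 1 | 0 | 0 | 0 | fully non-regular | 0 |
| 2 | −0.5 | 0 | 1 | fully regular | −0.5 |
| 3 | −0.5 | 0.5 | 0.5 | non-regular | 0 |
| 4 | −0.5 | 0.5 | 0.49 | regular, close to non-regular | −0.01 |
| 5 | −0.5 | 1 | 1 | non-regular | 0.5 |

(all other γ are zero).  The stage-2 effect for a participant is
`γ5 + γ6 O2 + γ7 A1`; settings where this vanishes for some or all
participants are the non-regular ones.

## Analytic truth

With the true stage-2 coefficients, the population pseudo-outcome mean
in baseline cell `(o1, a1)` is

    f(o1, a1) = γ1 + γ2 o1 + γ3 a1 + γ4 o1 a1
                + p |γ5 + γ6 + γ7 a1| + (1 − p) |γ5 − γ6 + γ7 a1|,
    p = expit(δ1 o1 + δ2 a1).

Projecting `f` onto the orthogonal stage-1 design over the four
equiprobable cells gives `ψ10 = ¼ Σ a1 f(o1, a1)` and
`ψ11 = ¼ Σ o1 a1 f(o1, a1)`; the stage-2 truths are `(γ5, γ6, γ7)`
directly.  `derive_truth` implements this closed form; the tests verify
it against an independent simulation + least-squares oracle both at the
five presets and at random parameter draws.  When `γ6 = 0` the
responder probability cancels, so ψ10 is then independent of
`(δ1, δ2)` — asserted as a regression test.

## Missingness mechanisms and calibration

Seven m-DAG scenarios impose missingness on `O2`, `A2`, `Y` (`O1`, `A1`
always complete), each a set of logistic models on the complete,
pre-deletion values; indicators `[X = 1]` are 0/1-coded and `Y` enters
untransformed.  Non-intercept coefficients are `log(1.6)` (weak) or
`log(3)` (strong).  Monotone propagation encodes the m-DAG's thick
arrows: missing `O2` hides `A2` and `Y` (scenarios 2–3); missing `A2`
hides `Y` (scenario 4).  In scenario 1 the `O2` and `Y` mechanisms are
drawn independently with no propagation (the m-DAG shows independent
mechanisms and fully observed `A2`).

Each model's intercept is calibrated by bisection so that the mean
missingness probability over a fresh simulated trial of 200,000 records
equals the target proportion (0.2 or 0.4); covariate-free models use
the closed form `logit(target)`.  "20%/40% missingness" is interpreted
as the marginal proportion for each scenario's primary model (`M_O2`
for scenarios 1–3, `M_A2` for scenario 4); where a scenario has a second
model (the `Y`-mechanism in scenarios 1–2) it is calibrated to the same
marginal proportion separately, so the *any-variable* incomplete-case
fraction can exceed the per-model target through overlap.  Intercepts
are frozen once per (setting, scenario, strength, proportion) with a
calibration seed derived from those factors, not re-estimated per
replicate.

## Missing-data handling

**Complete-case analysis** drops every record with any missing analysis
variable.

**Multiple imputation** is by chained equations with univariate models
built for compatibility with the Q-learning analysis model:

* `Y` — Bayesian linear regression on `O1, A1, O2, A2, O1A1, O2A2, A1A2`;
* `O2` — logistic regression on `O1, A1, A2, Y, O1A1, A1A2, YA2`;
* `A2` — logistic regression on `O1, A1, O2, Y, O1A1, YO2, YA1`.

Main effects of all other analysis variables accompany the listed
interaction terms so every univariate model nests the analysis model's
dependence structure; no auxiliary variables are used.  Imputation is
*proper*: for `Y` the error variance is drawn from its scaled
inverse-χ² posterior and the coefficients from their conditional
normal; for the binary variables coefficients are drawn from the
asymptotic normal of the logistic MLE and values sampled from the drawn
probabilities (mapped to ±1) — not predictive mean matching.
Interactions are recomputed passively from current values.  Defaults:
visit order `(O2, A2, Y)`, 10 sweeps per imputation, initial fill by
sampling each variable's observed values.  The logistic fits use
Newton–Raphson; separation or singularity falls back to a
ridge-stabilised fit (penalty 1e−2·n) with a warning.  The number of
imputations follows "m ≥ percentage incomplete": 20 at 20%, 40 at 40%,
overridable.

Per-imputation Q-learning estimates are combined by Rubin's rules:
pooled point = mean, total variance = within + (1 + 1/m)·between,
degrees of freedom `(m − 1)(1 + W/((1 + 1/m)B))²`, 95% t-interval.

## Standard errors and coverage

The naive stage-1 OLS variance of ψ̂10 is degenerate: the
pseudo-outcome is a deterministic function of `(O1, A1, O2)`, and with
`γ6 = 0` of `(O1, A1)` alone, so stage-1 residuals are near zero.  The
model-based SE therefore propagates the stage-2 coefficient covariance
by the delta method through `β̂2ᵀH2 + |ψ̂2ᵀH2|` (gradient
`(H2hist, sign(ψ̂2ᵀH2)·H2)`), plus the (negligible) stage-1 residual
term.  The absolute value is non-differentiable at `ψ̂2ᵀH2 = 0`, so
this SE is anti-conservative in exactly non-regular configurations;
the nonparametric bootstrap is the robust alternative and is what the
coverage evaluation uses.

Bootstrap SEs resample records with replacement at the original size
and re-run the full handling pipeline (complete-case subsetting, or —
for MI — a fresh bootstrap of the Q-learning fit within each completed
dataset) on every resample; B = 200 by default.  Confidence intervals:
complete-case `point ± t(0.975, B−1)·SE_boot`; MI uses the Rubin
t-interval with per-imputation bootstrap variances when coverage is
evaluated and model-based (delta) variances otherwise, switchable by
configuration.  Because of cost, bootstrap/coverage default to the
designated subset of cells (settings 1, 2, 4 under scenarios S1 and
S2a); a flag widens this.

## Performance measures

Over `n_reps` replicates: signed bias (figures report its absolute
value), empirical SE (divisor `n_reps − 1`), MSE = variance + bias²
(holds to numerical identity by construction), mean bootstrap SE,
coverage of 95% intervals, and the Monte Carlo standard error of the
mean estimate, `empirical SE / √n_reps`.

## Study orchestration and reproducibility

The grid is 5 settings × (S1 × {20%, 40%} + 6 scenarios × {weak,
strong} × {20%, 40%}) = 130 cells; defaults are n = 500 and
n_reps = 1000.  Every replicate draws four sub-streams (trial,
missingness, imputation, bootstrap) from
`SeedSequence([cell_root_seed, replicate_index])`, so any single
replicate is reconstructible and aggregate results are invariant to
execution order.  Identical configuration and seeds reproduce the
results table byte-for-byte; per-cell result files make interrupted
runs resumable.  Figures are a convenience; the long-format CSV is the
authoritative artifact.

## Problem sizes used by the test suite

Consistency and calibration checks use single simulations of 100,000 –
200,000 records.  Replicated pipeline checks use 200 replicates of
n = 500 (the unbiasedness and MI-vs-CCA pattern checks) and 1000
replicates for the complete-case Monte Carlo error bound; these sizes
give Monte Carlo errors of ~0.002–0.006 on ψ10, small enough to resolve
the directional effects being tested.

## What the generator does and does not emulate

The synthetic trials match the study conditions exactly: binary
covariate and responder status, fair randomisation, linear outcome with
unit Gaussian noise, logistic missingness.  Real SMARTs differ in ways
the generator does not represent: continuous or multivariate baseline
covariates, response-dependent stage-2 randomisation probabilities,
non-Gaussian or heteroscedastic outcomes, more than two stages, and
missingness driven by unmeasured variables beyond the mechanisms
modelled here.  Passing tests therefore certify the estimators and the
simulation machinery under these stylised conditions, not performance
on any particular real trial.

## Known limitations

* Plain Q-learning is biased in (near-)non-regular settings at trial
  sizes — e.g. setting 4 at n = 500 carries an intrinsic bias of about
  −0.03 in ψ̂10 for both handling methods; the comparison of interest is
  the *additional* bias from missing-data handling.
* The delta-method SE underestimates in exactly non-regular settings
  (see above).
* The MI within-imputation variance on the fast path is the
  delta-method variance, which shares that caveat.
* Only two stages, binary treatments/covariates, and a single terminal
  outcome are supported.
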