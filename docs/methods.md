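# Methods

## Model and estimand

One child per record.  Confounders `C` measured in childhood (ages 8–12):
three binary parental adversity flags, a six-category family-stability
classification derived from five annual household states, three-level
parental education, sex and birth year (1990–1995).  Exposure `A` is the
quintile of mean equivalised disposable family income over ages 8–12
(quintile 1 = lowest).  Mediators `M` measured at ages 13–17: seven binary
"ever during adolescence" indicators (self-harm, psychiatric disorder,
substance abuse, violent victimization, violent crime, out-of-home
placement, NEET) plus the GPA quartile at the end of compulsory school
(quartile 1 = highest; the ~3% of children with no registered GPA are placed
in the lowest quartile).  Outcome `Y`: any hospital-presenting self-harm at
ages 18–22.

The hypothetical intervention sets `A = 2` for children observed in `A = 1`,
leaving confounders untouched.  The parametric g-formula estimates the
counterfactual outcome distribution by fitting logistic models
`P(M_k | C, A)` (each mediator on confounders, sex, birth year and income
quintile dummies) and `P(Y | C, A, M)` (adding all mediator dummies), then
simulating mediators and outcome record by record.  GPA is modelled by a
sequential series of three logistic splits ordered from the lowest quartile
upward: `P(lowest)`, `P(3rd | not lowest)`, `P(2nd | upper half)`; the
implied four-vector of category probabilities sums to one by construction.

Scenario definitions: natural course (NC; no intervention, everything
simulated), counterfactual (CF; exposure and all mediators see the
intervened quintile), total-direct-effect scenario (TDE; exposure intervened,
mediators copied from the paired NC draws of the same inner repetition), and
per-mediator scenarios in which exactly one mediator responds while the rest
keep their NC draws (that mediator's pathway is thereby absorbed into the
direct effect).  Within one inner repetition all scenarios share uniform
draw streams (common random numbers), so an identity intervention reproduces
NC exactly and paired contrasts carry minimal Monte-Carlo variance.

Effects: `TE_abs = CF − NC`, `TDE_abs = TDE_scen − NC`,
`NIE_abs = TE_abs − TDE_abs` (the decomposition is an exact identity at
every granularity), with relative versions `1 − scenario/NC` signed so that
a beneficial intervention is a positive percentage reduction.  Population
effects average over all records; ATT restricts to records observed in the
intervened-from quintile.  Percentage mediated uses the ratio of
across-iteration averages `100·mean(NIE)/mean(TE)`: the outcome is rare, the
per-iteration TDE fluctuates around zero, and per-iteration ratios are
therefore unstable while the ratio of averages is not.  Its normal CI uses
the delta method with the empirical covariance of the two means; a Fieller
interval is computed from the same moments (the two agree except when the
denominator's t-statistic nears the critical value, where Fieller correctly
widens or becomes unbounded).

Defaults mirror the study configuration: 100 inner Monte-Carlo repetitions,
250 bootstrap iterations (resample with replacement, refit all models,
simulate; percentile confidence intervals), binomial draw mode.  Bootstrap
simulation standardizes over the *original* cohort rather than the resample,
so resampling perturbs only the fitted models; iterations are seeded by
spawning from the master seed, making results identical for any worker
count.  An *expectation* draw mode replaces the outcome's Bernoulli draw by
its probability (mediators are still drawn, since they enter the outcome
model nonlinearly); it is identical in expectation and removes the largest
Monte-Carlo noise term, and the test-suite and acceptance script use it.

## Synthetic registry generator

The generator emits raw register-style records — five annual incomes, five
annual family-structure states, parental flags and education, annual
adolescent episode flags, a numeric GPA with a missing fraction, the
outcome, and four sequential exclusion flags — from the same causal
structure the analysis assumes: mediators are conditionally independent
given `(C, A)` (mirroring the model layer, which fits each mediator without
the other mediators), and `Y` follows a logistic model in `(C, A, M)` whose
odds ratios are the published adjusted estimates.  Income enters mediator
generation as a linear-in-quintile log-odds slope (quintile 5 reference);
the outcome uses the published per-quintile odds ratios directly.

Per-child income is log-normal (location `log 25,000` EUR, scale 0.40 —
realistic for Finnish equivalised disposable income) with a downward
location shift proportional to an additive adversity score over the
confounders, so quintile membership correlates with adversity; five annual
incomes add 5% log-normal year-to-year noise, and the generator assigns
quintiles with the same empirical-fifths algorithm the cohort builder uses,
so generated and rebuilt exposure agree record by record.  Family sequences
are emitted so the six-category classifier recovers the drawn category
exactly; "ever without family" takes precedence over transition counting.
GPA is drawn as a quartile category via the sequential splits, then given a
numeric value uniform within disjoint per-category score bands, so the
builder's empirical quartiles reproduce the category up to the binomial
wobble of realized shares (the wobble reassigns only boundary records whose
within-band position is random, a negligible attenuation).  The outcome is
generated from the *rebuilt* GPA quartile (missing folded to lowest),
matching the variable the analysis models.  Exclusion flags are assigned by
exact count quotas on a seeded permutation, disjoint by construction, so
printed exclusion arithmetic can be reproduced exactly.

Confounder effects on mediators (odds-ratio maps) and the sex effect on the
outcome have no published values; the defaults are realism choices — all
adversities raise all adolescent risks, out-of-home placement most strongly
(e.g. 6.0 for "ever without family"), low parental education dominates the
GPA gradient — fixed once and documented here.  The GPA confounder log-odds
are damped by 0.5 in the two conditional splits above the lowest quartile.

## Calibration

Because confounders are discrete (288 strata) and latent income is a normal
mixture, every marginal and scenario mean has a closed form by enumerating
strata × quintiles × all 2⁷ × 4 mediator combinations.  Calibration is
one-dimensional root-finding on that enumeration, nested as follows:

* mediator and GPA-split intercepts → published marginal prevalences
  (GPA targets are exact quarters of the non-missing 97%, i.e. rebuilt
  shares 24.25/24.25/24.25/27.25 — continuous synthetic grades have no ties,
  so the builder's empirical quartiles are exact fifths of each quarter);
* income slopes for substance abuse (7%), violent victimization (21%),
  violent crime (17%), out-of-home placement (21%) and NEET (20%) → the
  published treated-group (ATT) reductions under the quintile-1→2 shift;
  adolescent self-harm and psychiatric disorder slopes are zero (published
  null responses);
* the GPA slope → the published "50% mediated when GPA is absorbed into the
  direct effect" row;
* the outcome intercept → 0.9% overall prevalence;
* the adversity→income scale → 1.4% crude prevalence in the lowest quintile
  (outermost loop; everything above is re-solved at each trial scale).

With only these published targets calibrated, the analytic model implies
ATT ≈ 7.3%, population TE ≈ 2.3%, percentage mediated ≈ 68%, and per-mediator
absorbed rows (placements 43%, NEET 53%, violent crime 58%, others 66–68%) —
emergent, not fitted, and close to the published pattern throughout.

## Headline estimation by cohort replication

A single finite cohort pins the fitted quintile coefficients to one noisy
realisation: with ~560 vs ~450 outcome cases in the two lowest quintiles at
n = 200,000, the direct-effect contrast has SE ≈ 0.06 on the log-odds scale,
i.e. ≈ 5–6 percentage points on the relative ATT and tens of points on the
mediated share.  Bootstrap averaging cannot reduce this (it centres on the
cohort's own MLE).  The study-level checks therefore run the full pipeline
on independent cohort realisations (default 120 in the acceptance script,
100 in the test-suite, 200,000 children each, n_mc = 20, expectation mode)
and pool NIE and TE by ratio of averages across replicates.  The pooled
estimates are unbiased for what the calibrated data-generating process
implies; their residual standard errors are ≈ 0.006 pp (NC prevalence),
≈ 0.7 pp (ATT), ≈ 0.2 pp (TE) and ≈ 7 points (percentage mediated — the
direct-effect noise floor; materially tightening it would need on the order
of 10⁸ simulated children).  Bootstrap confidence intervals are omitted in
these replicate runs because only point estimates are compared; the
`gfmed run` pipeline performs the full 250 × 100 bootstrap.

## Numerical choices

* Logistic fits: Newton–Raphson on the exact score/Hessian with step
  halving, intercept-only start (warm starts across replicate cohorts),
  convergence at score sup-norm < 1e-8; agrees with statsmodels' IRLS to
  ~1e-14 while avoiding its per-iteration SVD.  Empty response strata are
  reported with the model's name; separation is declared when converged
  coefficients exceed |15| on the logit scale (runaway guard at |40|).
  With 0.3%-prevalence mediators, bootstrap resamples of small cohorts can
  legitimately separate (zero cases in a 1%-share family category); such
  iterations are recorded and the run fails only if more than 5% fail.
* Quantile assignment (income quintiles, GPA quartiles) is rank-based with
  the stable child-id tie-break, so group sizes never differ by more than
  one and assignment is permutation-invariant; at the published sample size
  384,121 the extra record lands in the lowest quintile, matching the
  published Ns.  Children flagged by several exclusion rules are attributed
  to the first rule in listing order (overlap handling is unstated in the
  source; printed counts are treated as disjoint).
* The robustness grid (outcome prevalence 0.1/0.5/1% × n 50k/200k) runs in a
  test world where every category and mediator is common, isolating outcome
  rarity as the only stressor; with the registry's own sparse cells a
  0.1%-outcome model at 50k separates for legitimate reasons.

## What the synthetic cohorts do and do not show

The generator reproduces the registry's marginal structure, the adjusted
outcome odds-ratio pattern, the income-adversity correlation and the
intervention responses, under exactly the conditional-independence and
no-unmeasured-confounding assumptions the estimator itself makes.  Passing
tests therefore demonstrate that the pipeline estimates correctly *when the
models are correctly specified*; they cannot speak to unmeasured
confounding, to mediator-mediator dependence given `(C, A)`, to
registry-measurement artefacts (ICD coding, linkage error), or to
effect-modification structure beyond what main-effects logistic models
induce.  Real grade data also carry ties that make published GPA quartile
shares deviate slightly from exact quarters; the synthetic grades do not.

## Known limitations

Time-varying exposures and dynamic interventions are out of scope.  The
generator has no explicit exposure-confounder interactions, so subgroup
contrasts differ only through prevalence and non-collapsibility effects.
The GPA sequential-split ordering (from the lowest quartile upward) is a
design choice; the source does not specify one.  Whether the original
mediator models included the exposure is unstated; income-quintile terms are
included here, since the intervention can only propagate to mediators
through them.
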