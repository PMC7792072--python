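# Methods

This note records the statistical model behind `multiarm`, the defaults and
why they were chosen, the numerical choices, and what the simulations do and
do not establish.

## The design being modelled

A staged platform trial: stage 1 randomises FCR vs IR 1:1; stage 2 opens I
(a second control) and I+V, randomising 1:1:1:1; stage 3 drops IR and
continues 1:1:1.  Three powered hypotheses: IR vs FCR on PFS (HR 0.75,
medians 4.5 → 6 years, 379 events, one interim at half the events), I+V vs
FCR on PFS (medians 4.5 → 6.5 years, HR ≈ 0.69, 232 events, interim at
116), and I+V vs I on MRD negativity at 24 months (90% power at ~260
evaluable per arm for 20% → 32.5%).  Analyses pool over stages and include
trial stage, Binet stage, age group and sex as covariates; centre, although
a minimisation factor, is excluded from regression (about 100 levels would
destabilise the fits).

Stage transitions in the bundled config are recruitment-count triggers:
stage 1 ends at 316 IR patients, stage 2 when IR reaches its 377 target,
stage 3 when 274 FCR patients have been randomised concurrently with I+V.
The 316 threshold makes stage 2 contribute the remaining ~61 patients per
original arm, so the ~61 stage-2 FCR patients serve both PFS comparisons —
the design's shared controls.  Summing the per-comparison targets gives
754 + 822 − 61 = 1515 while the protocol's headline total is 1516; the
printed numbers are not exactly self-consistent, and the config reproduces
the per-comparison targets (simulated totals ≈ 1515).

## Sample size

* `required_events` implements Schoenfeld (default) and Freedman.  The
  default is Schoenfeld because its unrounded value at HR 0.75 (379.35)
  reproduces the 379-event target, and at the exact median ratio 4.5/6.5 it
  gives 232.2, matching the 232-event target of the added comparison.
  Freedman exceeds Schoenfeld for HR < 1 (property-checked).  Events are
  ceiled after any group-sequential inflation; the two-look O'Brien–Fleming
  maximum-information inflation is only 1.0078, and the printed event
  targets are consistent with no inflation, so `gsd_inflation` defaults
  to 1 with the plan's factor available explicitly.
* `event_probability` assumes exponential event times and entry uniform
  over the accrual window, analysed at accrual + minimum follow-up.  The
  expression is evaluated in an `expm1` form stable for very long medians.
* `required_n` divides events by the allocation-weighted mean event
  probability, inflates by 1/(1 − dropout) and rounds up to a whole
  allocation block.  With the stated design inputs this yields 734 total
  (vs the protocol's 754) and 270 per arm (vs 274): the protocol's exact
  software/formula is unpublished, and agreement within ~3% is as close as
  the stated inputs allow.
* `binary_power` defaults to the pooled-variance normal approximation,
  which gives 0.894 and 0.902 for the two design scenarios — the "90%
  power" statements.  Exact enumeration of the pooled z-test over the joint
  binomial distribution (`exact_enum`) gives 0.901 and 0.907; the normal
  approximation understates exact power by ~0.007 at this n.  `exact_sim`
  estimates the same exact power by Monte Carlo and agrees with the
  enumeration to MC precision.

## Group-sequential boundaries

Under standard survival asymptotics the interim and final log-rank
statistics behave as Brownian motion in information time (events).  On the
score scale `S_k = Z_k √t_k` the classic O'Brien–Fleming rule is a constant
boundary `C`; crossing probabilities are computed by the recursive
integration of the sub-density over the continuation region (trapezoid
quadrature, 801 points per look by default, boundary stable to < 1e-5 under
refinement — checked in the tests), and `C` is solved by Brent's method so
the total two-sided null crossing probability equals alpha.  For looks at
(0.5, 1.0) and alpha 0.05 this gives z-bounds (2.7965, 1.9774), i.e.
nominal two-sided p-thresholds 0.00517 and 0.04799 — the 0.005/0.048 pair.
A Monte-Carlo oracle (simulated Brownian score paths) confirms the null
crossing probability.  Stopping is for efficacy only; no futility bound.
The Lan–DeMets O'Brien–Fleming-like spending function is available as
`shape="ld_spending"`; the classic shape is the default because it is what
the printed threshold pair corresponds to.  The reported inflation factor
solves for the drift achieving the target power by the same recursion with
a mean-shifted process.

## Randomisation

Minimisation with a random element, range variant: an arm's score for a new
patient is the summed (allocation-weight-normalised) count of same-level
patients the arm would hold after the assignment, over all factors; the
minimising arm is selected with probability p (ties broken uniformly first)
and one of the remaining arms uniformly otherwise.  p defaults to 0.8 —
the published variant value is not stated, so p is an explicit config field.
Factor weights are equal (including centre).  The state is reset at every
stage transition: a newly added arm would otherwise start from zero counts
and distort the scores.  Simple randomisation is provided as a comparator;
at n = 800 minimisation's mean per-factor-level imbalance is strictly
smaller (simulation property).

## Cohort simulation

Entry is a homogeneous Poisson process at the configured accrual rate
(250/year by default, a rate consistent with the design's pooled multi-centre
recruitment); factor levels are independent draws, uniform by default —
actual prevalences affect balance bookkeeping but not the null/alternative
calibration of the comparisons, which is what the simulations measure.  PFS
is exponential with each arm's median; dropout is an independent exponential
process calibrated so P(dropout ≤ 8 years) equals the 5% design allowance;
MRD negativity is Bernoulli, independent of PFS, assessed at 24 months
(patients dropping out before then are not evaluable).

Randomness is split into named substreams (entry, profile, assignment,
outcome) derived from one master seed, with outcome uniforms indexed by
entry position, so a patient's latent outcomes do not depend on how many
arms are open.  Identical seeds reproduce a run byte-for-byte.

Deliberately not modelled: the MRD-guided treatment stop/restart rule (MRD
is a plain binary endpoint here, so PFS–MRD dependence is absent), centre-
level recruitment heterogeneity, secular trends in the patient mix (stage
effects exist in the analysis model but the generator draws stages
exchangeably), and non-proportional hazards.  Consequently the simulations
demonstrate the *design's* frequentist properties under its own assumptions;
they do not validate those assumptions against real accrual or survival
data.

## Trial engine and concurrency

"Concurrent" is operationalised as: randomised while both of a comparison's
arms were open to allocation.  Triggers are evaluated after every
randomisation (recruitment never pauses); event-count analysis cutoffs are
computed on the comparison's own concurrent events, and the cutoff calendar
date is the date of the defining event (compared on the calendar scale, so
the cutting event is always included).  Stage boundaries are counted by
randomisation order.

## Analyses

The Cox fitter maximises the Breslow partial likelihood by Newton–Raphson
with step-halving, tolerance 1e-9 on the gradient max-norm; ties are
grouped (simulated times are continuous, but imported data may tie — the
Breslow fixture is verified against an independent survival implementation).
Non-convergence and monotone likelihood (|log HR| > 10) are flagged, never
silently returned.  The global score statistic at β = 0 equals the log-rank
chi-square for a single binary covariate (asserted to 1e-10).  Multi-level
integer covariates are expanded to indicators against the first level;
continuous covariates enter linearly.  The log-rank test is implemented
directly from risk-set counts, not through the Cox path.  Logistic
regression uses IRLS with the same separation policy; the two-proportion
test uses the pooled null variance, matching the power formula.

## Operating characteristics

Each replicate runs the full pipeline (recruit → minimise → stage
transitions → concurrent sets → per-look analyses → boundary decisions).
The per-replicate analysis defaults to the log-rank / two-proportion score
tests; the covariate-adjusted regressions are available via
`use_regression` (≈30× slower, agreeing with the score path in ~95% of
replicates under the alternative).  The FWER family defaults to the two
PFS comparisons sharing FCR controls; the report also carries the
independent-trials reference `1 − Π(1 − rate_h)` and the empirical
correlation of the two final statistics.

Simulation sizes: the acceptance-level checks use 10⁴ replicates for the
global-null calibration and FWER (MC SE ≈ 0.0022 on a 5% rate) and 5×10³
for the partial-null intersection-union check; module-level behavioural
tests use a few hundred replicates.  With the bundled design's overlap of
~61 shared controls out of ~590 FCR patients, the induced statistic
correlation is ≈ 0.07 and the true family-wise error sits ≈ 0.097, only
marginally below the independent-trials bound 1 − 0.95² = 0.0975 — the
reduction is real but small at this degree of sharing, and a 10⁴-replicate
estimate resolves it only barely.

## Known limitations

* Exponential PFS and exponential dropout are design conveniences; real
  PFS in this population has non-constant hazard.
* The binary endpoint ignores the confounding between MRD-guided therapy
  duration and PFS acknowledged in the design.
* The required-participant calculations reproduce the published totals only
  to ~3% because the original calculation's software and rounding are not
  published.
* Minimisation uses equal factor weights and the range imbalance score;
  other variants exist and would change balance (not error rates).
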