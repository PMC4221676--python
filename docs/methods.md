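# Methods

`pacea` models the long-term health and cost consequences of offering a
behavioural physical-activity (PA) intervention to a population aged 50+.
It chains four components: a synthetic clustered trial, trial-effect
estimation, a Markov-type cohort chronic-disease model driven by
MET-hours/week of leisure-time PA, and a health-economic layer (ICERs,
willingness-to-pay decisions, probabilistic sensitivity analysis).

## Synthetic trial generator

The generator emulates a five-arm clustered RCT (waiting-list control plus
{print, web} x {basic, environmental add-on}) so that every downstream
stage is testable without the original micro-data.

* **Baseline PA** per arm is drawn from a normal truncated at zero whose
  *truncated* mean and SD equal the configured per-arm values (the
  underlying location/scale are solved by moment matching; a coefficient of
  variation >= 1 is infeasible for this family and rejected).  Defaults are
  the trial's arm-level moments (41.5–45.4 MET-h/week, SD 32–41).
* **Follow-up** is `baseline + true_effect + noise`, with noise SD implied
  by a configurable within-person correlation (default 0.7, a typical
  one-year test–retest value for self-reported PA).  Follow-up is
  deliberately *not* clipped at zero: clipping near the zero boundary
  inflates change scores by several MET-hours and would break the exact
  change-score structure that estimators are tested against.  Default true
  effects are +3.06, +2.94, +0.73, −0.22 MET-h/week for the four
  intervention arms against a control drift of −2.20.
* **Dropout** follows a logistic model in the environmental add-on
  (log-odds +0.398), web delivery (+0.614) and age (−0.016/year).  The
  intercept is a free parameter; the default 0.40 makes the overall
  12-month availability come out near the observed 58% given ages uniform
  on 50–90.  With only these three coefficients the generator cannot
  reproduce the full arm-wise completer pattern (real print arms dropped
  out more than control); this is a known limitation of the published
  model form.
* **Clusters** carry an additive random intercept with configurable
  variance, default 0 (the trial's multilevel analyses found no cluster
  effects).
* **Minutes/week** is derived from MET-hours at a constant intensity of
  4 MET (15 min per MET-hour) purely so the 6,720-minutes/week reliability
  filter is exercisable; questionnaire item structure is out of scope.

What passing tests on these data do *not* show: robustness to skewed or
zero-inflated PA distributions, item-level measurement error, informative
(outcome-dependent) dropout, or real cluster effects — none of which the
generator emulates.

## Effect estimation

Records with baseline PA above 6,720 minutes/week (active > 16 h/day,
7 days/week) are excluded; the boundary itself is retained ("more than" is
strict).  Dropouts are singly imputed: a non-responder's follow-up equals
their own baseline plus the mean change of *control-arm completers* in the
matching age-band ({50–64, >64}) x sex subgroup.  This reading of
"effect equal to the control group" preserves the participant's baseline
and is deliberately conservative — intervention-arm dropouts inherit the
control decline, attenuating intention-to-treat effects.  An alternative
"level" mode (impute the control subgroup's mean follow-up level) is
selectable.  A subgroup with fewer than two control completers falls back
to the overall control mean with a warning, which keeps small fixtures
runnable.

Within-arm changes use a paired t (two-sided 95% CI).  The between-arm
comparison is OLS of 12-month PA on intervention dummies (control
reference), age, sex and baseline PA.  Dropout is refit by maximum-
likelihood logistic regression.  Scenario effects pool two arms per
implementation scenario (printed, web_based, basic, environmental) by
n-weighted mean, with CIs propagated assuming independence.

## Cohort disease model

A deterministic expected-value cohort model over annual cycles, stratified
by integer age (50 to a configurable maximum, top age absorbing), sex, and
a discretised PA class in MET-hours/week (default 5 classes).  Five
diseases — diabetes, colon cancer, breast cancer (women only by default),
acute myocardial infarction, stroke — evolve as independent marginal
two-state (free/prevalent) processes on the shared alive population: the
state keeps the probability of each disease, not comorbidity.

Per cycle and stratum, in order:

1. **Incidence.**  Disease-free mass acquires disease *d* with probability
   `inc_d(age, sex) * exp(beta_d * (met − met_ref))`.  The log-linear
   dose-response is the simplest form consistent with meta-regression on
   relative risks; slopes are configuration parameters because the original
   meta-regression values are not public.  Default slopes (−0.002 to
   −0.006 per MET-h/week) give active-vs-inactive relative risks of
   ~0.7–0.9 over a 30–40 MET-h/week contrast, the meta-analytic order of
   magnitude.  A transition probability above 1 after risk scaling raises
   an error unless capping is explicitly enabled (then capped with a
   warning).
2. **Mortality.**  Survival multiplies background mortality with each
   disease's excess mortality: `S = (1−m) * prod_d (1 − e_d * pi_d)`, the
   exact expectation under independent statuses; the prevalence share
   among survivors updates in closed form to `pi (1−e) / (1 − e pi)`.
3. **Outputs.**  Person-years use a half-cycle correction (deaths
   contribute half a year).  QALYs are the *exact* expectation of
   person-years x utility over joint disease statuses, which factorises
   across diseases; utilities combine disutilities multiplicatively
   (`prod (1 − u_d)`), with an additive rule selectable.  Healthcare costs
   are prevalent cases x per-case annual cost plus a per-capita annual
   cost of being alive (default €4,000) that carries the cost of added
   life years.
4. **Ageing and drift.**  Everyone ages one year; a configurable fraction
   of PA-class mass (default 0.5%/year) moves one class down, emulating
   the age-related decline of PA.

**Exactness.**  With one disease, or with several diseases as long as
strata never pool, the marginal recursion reproduces an explicit
joint-state enumeration to numerical precision (the test suite asserts
1e-10 relative).  When PA drift or the absorbing top age pools strata with
different prevalence, disease statuses become correlated within the pooled
stratum while the state space retains only marginals; the induced
deviation is ~1e-7 relative on test instances and is inherent to the
marginal state-space design.

**Inputs are illustrative.**  Incidence levels and age gradients, excess
mortalities, disutilities and costs are plausible-magnitude defaults for a
north-west-European population, not register estimates; absolute
population results (incidence reductions, QALY totals, cost signs) depend
on them.  In particular whether lifetime total costs of an effective
scenario come out positive (costs in added life years dominate) or
negative (disease-cost savings dominate) is input-dependent; the bundled
defaults yield net lifetime savings.

## Scenarios

A scenario is a one-off population-wide offer: an uptake fraction times a
participant-level effect gives the population-average MET-hour shift per
(age band x sex); the first-year shift steps down once to 72% from cycle 2
onward and is then held constant (behaviour treated as a habit; geometric
decay selectable).  Real-world uptake multiplies the trial response rate
by an odds ratio for a shorter real-life questionnaire (printed:
1.48 x 19% ≈ 28%; web: 1.73 x 12% ≈ 21%).  That literal product is the
default for fidelity to the source computation; a mathematically exact
odds-scale transform is available by flag.  The pooled basic/environmental
scenarios mix one printed and one web condition and use the mean of the
two delivery-mode rates.

## Economics

Costs discount at 4%/year and QALYs at 1.5%/year (differential
discounting), independently configurable; the first model cycle is t = 0
and the one-off intervention cost falls entirely in it.  Intervention
costs average the two pooled conditions' fixed and variable components
(e.g. printed: €3,785 fixed, €19.50 per participant).  ICERs follow
`(C_i − C_c)/(E_i − E_c)` with two variants (intervention-cost-only and
total cost) and a cost-effectiveness-plane quadrant; a zero effect
difference is flagged undefined, never printed as infinity.  Decisions at
a willingness-to-pay (default €20,000/QALY): NE — cost-effective iff
ICER <= WTP; SE — dominant; NW — dominated; SW — the cheaper, less
effective option is preferred only if savings per QALY forgone >= WTP.
ICERs are reported unrounded.

## Uncertainty

The PSA samples participant-level effects from a normal with the point
estimate as mean and SD = CI width / 3.92 (the source varies effects over
their 95% CI without naming a distribution; the symmetric normal is the
minimal choice), reruns the deterministic pipeline per draw (default 100
draws, seeded), and summarises draws as CE-plane points and CEACs.  A CEAC
gives, per WTP, the share of draws in which an option has the highest net
monetary benefit `WTP x dE − dC` among all compared options jointly
(reference included; ties split equally) — well-defined in every quadrant,
unlike pairwise ICER thresholding.  Deterministic sweeps rerun the
pipeline with common 4%/4% and 0%/0% discounting and with participation at
the odds-ratio CI bounds (printed 1.06–2.07, web 1.40–2.13), the latter
also moving the per-participant intervention cost since fixed costs
amortise over participants.

## Numerical and design notes

* Determinism: every stage is seedable; identical configuration and seed
  reproduce byte-identical CSV outputs (hashed in the run manifest).
* "Lifetime" horizon runs to cohort extinction (alive < 1e-9 of initial)
  with a hard cap of 150 cycles; 5- and 10-year results slice the same
  trajectory, so horizons are mutually consistent.
* Monotonicity caveat: with protective dose-response, a uniformly higher
  PA distribution lowers every individual's risk, but per-cycle *case
  counts* can cross the reference late in a run because more disease-free
  people survive to remain at risk; cumulative counts and cycle-wise QALYs
  stay ordered.
* Default problem sizes (430 participants/arm; ages 50–100; 5 PA classes;
  100 PSA draws) keep a full analysis under a minute on one CPU; all sizes
  scale up by configuration.
* Known limitations: no comorbidity, no disease remission or case-fatality
  phase structure, no work-related PA, one-off intervention delivery only,
  and effect uncertainty is the only parameter varied in the PSA.
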