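# Methods

## Model structure

The analysis compares two strategies for offering low-intensity CBT (a
6–8-session structured self-help program) to university students with mild
depressive symptoms: therapist-guided delivery over an internet platform
versus conventional in-person sessions. It is an expectation model — a
cohort of identical students — with two stages.

**Decision tree (time zero).** A student offered strategy *s* accepts with
probability *a_s* and, if accepting, completes the program with probability
*c_s*. The treated fraction *a_s·c_s* receives the program outcome
probabilities (recovery to well 0.639, deterioration to moderate–severe
0.053); decliners and non-completers both receive the no-intervention
outcomes (recovery 0.25, deterioration 0.091). In the internet arm the
treated recovery probability is scaled by a relative-effectiveness
multiplier (base 1.00, capped so probabilities stay in [0, 1]).
Deteriorated mass splits moderate : severe by `prop_moderate_among_modsev`;
all non-recovered, non-deteriorated mass stays mild. The tree is resolved
instantaneously: the program window is short relative to the 5-year
horizon, and spreading its costs/outcomes over 2–3 months changes totals
only through two to three months of discounting (< 1%).

**Markov cohort (60 monthly cycles).** Occupancy states are well/remission,
mild, moderate, severe, and dead (absorbing). From well: relapse
(0.0244/month) and mortality (2.5 × 10⁻⁵/month). From any symptomatic
state: remission (0.0054/month) and mortality times a relative risk of
1.81. The severity composition of the symptomatic mass is redistributed
every cycle to the fixed relapse mix — mild 0.243, moderate and severe
(1 − 0.243)/2 each — i.e. severity is a proportional differentiation of a
single symptomatic macro-state rather than a persistent sub-state. This is
the `severity_mix="relapse_proportions"` default; a `"tree"` mode in which
tree-assigned severities persist without lateral moves is retained as an
alternative, but it holds the entry cohort's mild-heavy composition for
years and materially overstates total QALYs relative to the reference
results.

**School dropout.** Permanent university dropout is a parallel monthly
hazard (0.00124 from well, 0.00193 while symptomatic, none when dead). The
engine tracks the exact joint (health state × enrolment) occupancy — ten
slots — rather than multiplying a state-averaged survival factor into the
accruals; the joint chain is required for the microsimulation oracle to
agree without a systematic bias, because dropout is correlated with the
symptomatic (costly, low-utility) states. By default dropout stops cost and
QALY accrual (the student leaves the service provider's remit) but does not
alter health-state dynamics; a switch makes accrual continue in both
engines simultaneously.

**Accrual.** Each cycle accrues its end-of-cycle occupancy at the
end-of-cycle discount factor (`accrual_timing="cycle_end"`, the common
discrete-time convention that counts state membership after each
transition); cycle-start and half-cycle-corrected variants are switches.
Costs per cycle: monthly psychiatric outpatient cost (US $231) for every
enrolled symptomatic student (mild included — stepped-up care applies to
everyone who "did not achieve remission"; restricting it to
moderate/severe is a switch), plus expected hospitalization cost for
severe students (0.0178 × US $1,500). A separate one-off high-intensity
CBT course charge per entry into the stepped-up states (18 × 1 h × US $54
= US $972) is available but **off** by default: the outpatient cost is an
empirical claims-based per-patient-month figure and is taken to subsume
stepped-up psychotherapy; adding the explicit course charge on top pushes
total costs well above the reference results. QALYs per cycle: occupancy ·
utility / 12, with utilities 0.80 (well/remission — the remission utility;
the age-specific population utility 0.92 is a documented alternative
source), 0.62/0.48/0.33 (mild/moderate/severe), 0 (dead). Program cost is
charged at time zero to accepters (resources committed at enrollment;
charging completers only is a switch): US $189 per in-person course
(7 × 0.5 h × US $54), US $41.44 per internet course (9.23% of the
therapist time plus US $24 platform overhead). Both costs and QALYs are
discounted at (1.03)^(−t/12).

## Decision rule

Δcost and ΔQALY are internet minus in-person. The internet strategy is
*dominant* if Δcost < 0 and ΔQALY > 0. It is accepted as cost-effective at
willingness-to-pay λ (US $48,119/QALY, a GDP-per-capita threshold) if
dominant, or if more costly and more effective with ICER = Δcost/ΔQALY < λ.
The south-west quadrant (cheaper, less effective), which the two-branch
rule does not cover, is decided by the sign of the net monetary benefit
ΔQALY·λ − Δcost, so every PSA draw has a verdict. Exact NMB ties go to the
in-person comparator. Negative ICERs are reported as numbers with the
dominance flag alongside.

## Parameters and sampling

All inputs live in `data/default_parameters.yaml` (probabilities as
fractions): name, base value, sensitivity range, distribution family,
scale. Ranges are the published 95% CI / high–low / IQR figures. For the
PSA, triangular families use (low, mode = base, high); beta and gamma are
fitted by method of moments with mean = base and sd = (high − low)/3.92,
reading the range as an approximate 95% interval (the outpatient-cost IQR
is treated the same way; the construction is isolated in `make_sampler` and
swappable). Fixed inputs (no range) are degenerate. Strict-mode overrides
must stay inside the envelope; permissive mode admits the extended
sensitivity ranges (platform overhead to US $2,000, therapist time share to
50%).

The acceptance pair (*a*<sub>in-person</sub>, *a*<sub>internet</sub>) and
the compliance pair are each estimated in a single source study, so their
uncertainties are shared rather than independent; the PSA therefore samples
each pair **comonotonically** (one shared uniform quantile mapped through
both marginals; `psa_paired_quantiles` switches this off). Independent
pairs would make the between-arm contrast far noisier than the reference
Monte Carlo dispersion (per-draw ΔQALY sd ≈ 0.020 instead of ≈ 0.01, and
only ~93–95% of draws gaining QALYs), because the common between-study
uncertainty would be double-counted as a between-arm difference. Each draw
uses one spawned substream of the master seed, so the first *k* draws are
identical whatever the requested total.

## Sensitivity analyses

*One-way*: both strategies re-run at each parameter's range endpoints, all
else at base; tornado ordering by ICER swing (NMB swing is a more robust
alternative when ΔQALY approaches zero — with the default inputs ΔQALY
stays well away from zero at every endpoint). *Two-way*: the preferred
strategy on a compliance grid (default step 0.005 over [0.50, 1.00]²),
evaluated as one vectorized batch. *Threshold*: coarse scan plus bisection
on the acceptance verdict (tolerance US $1 for money scales, 10⁻³
otherwise), reporting every crossing if the verdict is non-monotone.

## Microsimulation oracle

`microsim` simulates individual students through the same tree, the same
transition matrix, the same dropout hazards and the same accrual
conventions (hospitalization as a per-cycle Bernoulli event with matching
expectation), reading the identical `ModelConfig` — so any structural
switch moves both engines together. Cohort expectations must equal
microsim sample means up to Monte Carlo error; the suite checks cost,
QALYs, dropout and terminal state frequencies at 200,000 individuals for
the default configuration, across 20 randomly perturbed parameter sets at
40,000 individuals each (with a no-systematic-bias check on the pooled
z-scores), and under a fully reconfigured switch set. These sizes give
standard errors of roughly US $11 / 0.0016 QALYs at 200k, comfortably
resolving sub-percent engine disagreements while keeping the suite fast.

What the simulator does *not* emulate: between-individual heterogeneity in
parameter values (second-order uncertainty lives in the PSA), within-month
event timing, and any behavioural feedback between dropout and symptom
course. Agreement between the two engines validates the cohort arithmetic,
not the model's fidelity to real students.

## Numerical conventions and edge cases

Occupancy conservation is asserted every cycle (10⁻⁹); transition rows must
sum to one within 10⁻¹²; a negative residual stay-probability (e.g. relapse
+ mortality > 1 after an extreme override) raises immediately. ΔQALY = 0
yields an undefined ICER sentinel, never a division error. A zero-month
horizon leaves only program costs. The mortality input (printed as
0.0025 under a percent header) is read as 0.0025% = 2.5 × 10⁻⁵/month,
consistent with all-cause mortality at age 21; both readings are so small
that the choice is immaterial to every reported quantity. A single monthly
mortality value is used across the horizon (mortality at ages 21–26 is
nearly flat). The cohort age input is carried in the registry as a
descriptive covariate; no age-dependence enters the transitions.

## Known limitations

- The severity mix, step-up costing, accrual timing and dropout-accrual
  conventions are structural choices the source material leaves open; the
  defaults are the calibrated reference configuration, and every
  alternative is one `ModelConfig` switch away.
- Indirect costs (productivity, quality-of-life impact of dropping out)
  are outside the service-provider perspective and not modelled.
- The outpatient cost does not vary with symptom severity.
- No efficiency frontier beyond the two strategies; no EVPI.
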