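# Methods

## Model structure

The model evaluates expected discounted lifetime cost and
quality-adjusted life years (QALYs) for one treatment strategy as the
composition of two parts.

**Short-run model (first 30 days).** Treatment happens at time 0. A
first session achieves complete resection/ablation with probability
`p_success_first`; otherwise a second session — assumed always successful
— is performed, repeating the full treatment cost
(`acute_procedure_cost + hospital_days × cost_per_hospital_day`). The
expected acute cost is therefore `total_cost × (2 − p_success_first)`,
accrued undiscounted at time 0. All patients enter the long-run model
treatment-complete.

**Long-run model.** A four-state Markov cohort model with one-year
cycles runs from `age_start` to `age_max` (horizon
`N = age_max − age_start` cycles). States: no recurrence, hepatic-only
recurrence, any other recurrence, death. From the recurrence-free state
the per-cycle competing transitions are death, hepatic recurrence and
other recurrence, with the residual probability staying; the outgoing sum
is validated, never silently renormalised. Recurrence states do not
transition to each other and never return to the recurrence-free state.
Death is absorbing. Cohort occupancy is propagated by left-multiplication
with the cycle's row-stochastic 4×4 matrix.

**Mortality.** In cycle 1 the strategy's observed all-cause 1-year
mortality replaces background mortality (it is an observed all-cause
figure, so compounding it with the life table would double-count). From
cycle 2 onward, the recurrence-free state uses the life-table annual
death probability `qx` at the attained age `age_start + cycle − 1`.
Queries above the table's last age return 1, which makes the horizon
finite regardless of `age_max`.

**Rewards.** Cycle `t` (t = 1..N) is discounted by `(1+r)^−(t−1)`; state
costs are `cost_no_recurrence_per_cycle` in the recurrence-free state,
`cost_recurrence_per_cycle` in either recurrence state and 0 when dead;
utilities are the state utilities, with the first cycle's recurrence-free
utility replaced by the post-treatment quality of life (below).

## Convention choices

Three reward-accrual conventions in annual-cycle Markov models are
genuinely open, and the model exposes each as a `ModelSettings` field.
The defaults are the combination under which the model reproduces the
published base-case totals for this comparison (all six values within
6%, costs within 2.3%, and the dominance pattern exactly); the
alternatives remain implemented and tested.

1. **Recurrence-state mortality**
   (`recurrence_mortality_compounds_background`, default `False`). The
   sourced annual death probabilities with hepatic (0.12) and non-hepatic
   (0.05) recurrence are used flat, exactly as tabulated. The alternative
   compounds them with background `qx` as independent competing risks,
   `1 − (1−qx)(1−q_state)`, which avoids recurrence patients outliving
   the background population at very old ages but is not what the source
   tables state; under the flat convention the `age_max = 100` horizon
   still terminates every trajectory.

2. **First-cycle utility** (`first_cycle_utility`, default
   `"full_year"`). The "quality of life one month after treatment"
   (0.70 surgery, 0.95 ablation) is applied as the recurrence-free
   utility for the whole first annual cycle — in a model with one-year
   cycles, the utility measured at one month is the natural reward weight
   for the recovery year, and a one-month sliver cannot be represented
   without sub-cycling. The `"one_month_blend"` alternative accrues 1/12
   of the year at the post-treatment utility and 11/12 at the
   recurrence-free utility.

3. **Half-cycle correction** (`half_cycle_correction`, default `True`).
   Rewards accrue on the average of start- and end-of-cycle occupancy,
   the standard correction for transitions occurring throughout the year
   (and the convention common in decision-analytic software). With
   `False`, rewards accrue on start-of-cycle membership.

Empirically (the base-case reproduction test exercises this), the flat
recurrence mortality is what moves lifetime costs onto the published
values, and the full-year first-cycle utility is what makes MWA — not
surgery — the most effective strategy, as published; with the blend
convention the surgery arm's lower hepatic-recurrence rate outweighs its
higher 1-year mortality and the published dominance pattern cannot be
reproduced.

## Parameters

Strategy-specific (surgery / RFA / MWA): first-session success 0.99 /
0.93 / 0.97; procedure cost USD 2,421 / 1,493 / 1,493; hospital days
7 / 4 / 4; 1-month post-treatment utility 0.70 / 0.95 / 0.95; 1-year
mortality 0.0825 / 0.06 / 0.055; annual hepatic recurrence 0.025 /
0.077 / 0.04; annual non-hepatic recurrence 0.05 (shared source).

Shared: hospital day USD 2,424; per-cycle cost USD 855 recurrence-free
and USD 3,935 with recurrence; utilities 1 / 0.65 / 0.19 / 0; annual
death probability 0.12 (hepatic) and 0.05 (other recurrence); discount
rate 3%/year; starting age 73; maximum age 100; WTP USD 100,000/QALY.
The tabulated long-term cost sources label the amounts "monthly", but
accruing USD 855/3,935 every month is irreconcilable with the published
lifetime totals (it would give six-figure lifetime costs); they are
treated as per-annual-cycle amounts, which is consistent with those
totals. Currency is nominal 2018 USD throughout; no inflation adjustment.

## Probabilistic sensitivity analysis

Each uncertain parameter gets a method-of-moments distribution: gamma for
costs (`shape = (mean/se)², scale = se²/mean`), beta for probabilities
and utilities (`ν = mean(1−mean)/se² − 1, α = mean·ν, β = (1−mean)·ν`).
Spreads are not reported with the source estimates, so the relative
spread is a modelling choice, default `se = 0.2 × mean` for gamma and
`se = 0.2 × min(mean, 1−mean)` for beta — the `min` form is symmetric
under recoding a probability as its complement and always feasible
(a flat 20% of the mean violates `se² < mean(1−mean)` for means near 1,
e.g. a 0.99 success probability), and coincides with 20% of the mean for
all means ≤ 0.5. Acceptability results are additionally checked at 10%
and 30% spreads.

Per iteration, shared parameters (hospital-day cost, state costs and
utilities, recurrence-state mortality, the non-hepatic recurrence
probability) are drawn once and used by all three strategies — common
random numbers keep the comparison tight — while strategy-specific
parameters (success probability, procedure cost, 1-month utility, 1-year
mortality, hepatic recurrence) are drawn per strategy. All draws are
independent across parameters; no correlation structure is imposed.
Structural constants are never drawn: discount rate, ages, WTP,
second-session success, hospital-day counts (integer resource counts with
no reported uncertainty), and any parameter whose mean sits on the
boundary of its support (the recurrence-free utility of exactly 1 is a
degenerate beta and stays fixed). First-session success probabilities are
drawn by default and can be excluded (`draw_success=False`).

An iteration is "won" at a given WTP by the strategy with maximal net
monetary benefit; exact ties go to the cheaper strategy, then to input
order. The CEAC reports win fractions on a WTP grid; they form a
probability partition at every grid point by construction.

Reproducibility: iteration `i` uses the `i`-th child of
`numpy.random.SeedSequence(seed)`, so results are bit-identical for a
given `(seed, n, config)` and independent of evaluation order.

## Synthetic life table

No machine-readable background-mortality table ships with the source
data, so the bundled table (`synthetic_us2014_lifetable.csv`) is
generated from a Gompertz hazard, `qx(age) = 1 − exp(−a·e^{b·age})`,
with `b = 0.085` (a typical adult log-hazard slope) and
`a = 6.065×10⁻⁵` calibrated once so that remaining life expectancy at
age 73 is ≈13.0 years — the ballpark of the 2014 US all-sex period
table at the model's base-case starting age. It is a synthetic stand-in,
not transcribed vital statistics: it has no infant-mortality hump, no
accident plateau in early adulthood, and no old-age hazard deceleration.
Consequently the base-case reproduction is approximate by construction
(the tests assert a ±10% band plus exact orderings, not equality), and
passing tests validate the model mechanics and the comparison's
structure, not a specific country's vital statistics. Any real period
life table in the same two-column CSV format can be substituted.

## Verification strategy

* **Microsimulation oracle.** A patient-level simulation
  (`microsim_oracle`) applies the identical transition matrices and
  reward conventions by sampling individual trajectories (one random
  stream per patient). Its means must agree with the cohort engine
  within 3 Monte Carlo standard errors — run at 100,000 patients on a
  10-cycle horizon, and under the alternative convention settings too.
  A disagreement localises a bug to either reward accrual or transition
  construction.
* **Closed forms.** With recurrence switched off and constant mortality,
  the discounted QALY sum collapses to a geometric series; the engine
  must match it to 1e-9 (tested under both half-cycle conventions).
* **Structural invariants.** Transition rows sum to 1 (1e-12); occupancy
  is conserved (1e-9); death occupancy is monotone; QALYs are monotone
  non-increasing in the discount rate and in each recurrence
  probability; randomly generated valid configurations (`random_config`)
  are fuzzed through the engine.
* **Brute-force CEA check.** Dominance classification is compared
  against a direct pairwise enumeration on 1,000 random cost/QALY
  triples, and the frontier is checked to be input-order invariant with
  strictly increasing ICERs.

## Problem sizes in the shipped runs

The test suite runs the PSA at 3,000 iterations (the acceptability
headline is insensitive to n well below that; the full-size run lives in
`scripts/acceptance.py`, which uses the complete 30,000 iterations at
all three spreads) and the microsim oracle at 100,000 patients on a
10-cycle horizon in the acceptance suite and 20,000 elsewhere.

## Known limitations

* Recurrence hazards are constant over time (no truncation after a
  disease-free interval) and recurrences are not re-treated; there are
  no tunnel states.
* The second session's cost is assumed to repeat the full first-session
  resource use; the sources state its success (100%) but not its cost.
* Only the starting age varies in the age sweep; treatment parameters,
  including 1-year mortality, are age-invariant, so the sweep isolates
  background-mortality effects only.
* The comparison applies only to patients amenable to all three
  modalities, under US payer-level 2018 costs; no other health system,
  chemotherapy combination, or alternative local therapy is modelled.
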