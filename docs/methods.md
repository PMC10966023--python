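# Methods

## Model structure

The model is a two-arm state-transition (Markov) cohort model of
primary angle-closure disease with yearly cycles. Both arms share the
irreversible chain

PACS → PAC → PACG → unilateral blindness → bilateral blindness,

where PACS is primary angle-closure suspect (narrow angle, no damage),
PAC adds angle pathology and triggers lens extraction on entry, PACG is
primary angle-closure glaucoma, and the blindness states are absorbing
endpoints of glaucomatous damage (bilateral blindness is the single
absorbing state; unilateral blindness can still progress). Only PACG
feeds the blindness states. There is no dead state: the model is meant
for middle-aged cohorts whose background mortality is low enough to
cancel out of an incremental comparison between arms that share it.

Arm differences:

- **LPI arm** (7 states): the prophylactic laser is performed in the
  first year, folded into the first-year PACS cost. Progression
  probabilities are the post-iridotomy ones.
- **Observation arm** (9 states): higher progression probabilities, plus
  an acute angle-closure crisis (AACC) hazard from PACS. AACC lasts
  exactly one cycle (emergency iridotomy, cost 107,167 JPY, utility
  0.99) and resolves with certainty into an open-angle PACS state
  ("PACS, LPI open") that pays the iridotomy-arm follow-up cost and
  progresses at the iridotomy-arm rate, with no residual crisis risk.

First-year **tunnel states** (`PACS_y1`, `PAC_y1`) carry one-off
first-year costs and are left after exactly one cycle: they exit to
their established twin with the twin's own clinical transition
probabilities, so switching every clinical probability to zero still
drains the tunnels (a cohort cannot pay a first-year cost twice).

A patient in either arm occupies exactly one state per cycle and makes
at most one clinical transition per cycle; state-skipping (PACS to PACG
in one year) is impossible by construction.

## Rewards and discounting

Each cycle, the cohort accrues `occupancy · cost` and
`occupancy · utility` evaluated at the attained age (entry age + cycle
index). Discounting is **annuity-due**: cycle *t* is weighted by
`(1+r)^−t`, so the first cycle is undiscounted and an always-healthy
20-year cohort at r = 2% accrues 16.6785 QALYs — the closed-form
annuity-due sum that anchors the engine's unit tests. No half-cycle
correction is applied; occupancy is measured at cycle start.

**Trabeculectomy** is not a separate state. Within PACG the surgery is a
memoryless expected-value event: cycle cost includes
`p_trab(age) × 697,008` JPY and cycle utility is
`(1 − p_trab)·0.75 + p_trab·0.74`. A cohort model without memory cannot
express "at most one surgery per lifetime"; the patient-level simulator
can, and re-simulating 200,000 observation-arm patients with a
once-only surgery flag under common random numbers moves the 20-year
mean cost by on the order of 0.002% (`analysis/05_validate_oracle.py`
prints the measured value; the test suite asserts < 0.1%), so the
memoryless simplification is numerically irrelevant at these surgery
probabilities (0.88%/0.63% per PACG-year).

The surgery-year utility is the tabulated 0.74. The separate 0.007
utility decrement for glaucoma surgery is exposed as
`trab_utility_loss` for users who prefer `u_PACG − 0.007 = 0.743`, but
0.74 is the default.

## Parameters

All inputs live in `lpi_cea.parameters` as a registry of named values
with validation (probabilities and utilities in [0, 1], costs ≥ 0, exit
probabilities from any state summing to ≤ 1, sensitivity ranges
bracketing the default). Units: probabilities are annual fractions,
utilities are QALY weights per year, costs are JPY per year (or per
event for the surgery), the discount rate is an annual fraction.
Headline defaults: PACS→PAC 1.17%/2.18% per year (LPI/observation),
PAC→PACG 0.146%/0.34%, PACG→unilateral blindness 0.46%, unilateral→
bilateral 3.87%, AACC incidence 0.097%/year (observation only);
utilities 1.0 (PACS, PAC), 0.99 (AACC year), 0.75 (PACG), 0.74
(surgery year), 0.47/0.26 (uni-/bilateral blindness); first-year costs
98,393 (PACS with laser) vs 19,560 (PACS observed) and 171,259 JPY (PAC
with lens extraction); follow-up costs 23,780 (post-iridotomy and PAC)
vs 22,180 JPY (observed PACS); trabeculectomy 697,008 JPY. Analysis
constants: discount 2%, willingness to pay 5,000,000 JPY/QALY, 160 JPY
per pound sterling.

**Age brackets.** PACG/blindness costs and the trabeculectomy
probability come in 40–49 and 50–59 brackets, indexed by the *attained*
age, with half-open convention [40, 50) and [50, ∞): age 50 belongs to
the upper bracket, and ages 60+ reuse the 50–59 values because no older
bracket exists. Indexing by attained age (rather than years since
entry) is the natural clinical reading; with near-identical bracket
values the alternative changes results only in the fourth significant
digit, so no configuration switch is provided.

**Societal perspective.** The engine accepts an optional user-supplied
block: annual indirect cost of bilateral blindness, a per-state visit
schedule priced at 4,547 JPY of travel per visit, and the convention
that unilateral blindness incurs 30% of the bilateral indirect cost.
Because the indirect-cost values themselves are not part of the
built-in payer-perspective set, the CLI refuses a societal run without
this block rather than silently assuming zeros.

## Deterministic sensitivity analysis

The scenario sweep re-runs both arms for seven entry/exit-age
configurations (entry 40 or 50; horizons 10, 15, 20 and 60 years). The
one-way analysis moves one input at a time to its range bounds — ±30%
for probabilities, ±8% for utilities, ±20% for costs, 0–4% for the
discount rate — holding everything else at default; a cost shared by
both arms (e.g. the PAC follow-up) moves in both arms simultaneously,
while the arm-specific probability pairs are separate entries. Entries
are ranked by ICER span (descending, ties resolved by registry order)
and the tornado keeps the top 12 by default. Excursions are pure
functions: the default set is never mutated. If an excursion flips the
comparison into dominance the entry is flagged and its span falls back
to the net-monetary-benefit scale; this does not occur at the default
ranges.

## Probabilistic sensitivity analysis

"SD equal to 10% (5%) of the mean" is implemented literally:
probabilities get beta distributions with SD = 0.10 × mean, utilities
beta with SD = 0.05 × mean, costs gamma with SD = 0.10 × mean, all fit
by the method of moments (for the gamma this gives shape 100 exactly).
Inputs printed without a distribution — the utilities fixed at 1.0 and
0.99, the certain AACC resolution, the discount rate and the analysis
constants — never vary. Draws are independent across parameters (no
correlation structure is specified) and shared within an iteration:
one draw per parameter applied to both arms, so the incremental results
reflect parameter uncertainty rather than between-arm sampling noise.

Reproducibility contract: a single PCG64 generator seeded with the
user's seed; draws are taken parameter-by-parameter in registry order,
`n_iterations` values per parameter. Iterations in which sampled exit
probabilities from any state sum above 1 are redrawn and counted
(vanishingly rare at these means — the beta for the largest
probability, 3.87%, has essentially no mass near 1). The default run is
10,000 iterations, which takes a few seconds and puts a binomial
standard error of about 0.5 percentage points on the cost-effectiveness
probability. The acceptability curve reports, for each willingness-to-
pay value, the fraction of iterations with strictly positive net
monetary benefit; its 50% crossing is read off a 10,000-JPY grid.

## Microsimulation oracle and synthetic trajectories

`lpi_cea.microsim` simulates individual patients through the identical
transition graph with per-cycle multinomial draws, reusing the cohort
engine's reward and discounting code so that any disagreement isolates
to the transition logic. It doubles as the package's synthetic-data
generator (per-patient, per-cycle state trajectories with surgery
events, exportable as a long-format table). The validation driver runs
200,000 patients per arm and requires agreement with the cohort engine
within 3 standard errors on total cost, total QALYs and every per-cycle
state occupancy (with a 1/n slack term so states whose expected count
is below one patient are compared honestly); CI-level tests use
20,000–50,000 patients, which takes seconds.

What the simulator emulates is exactly the model: it shares the
transition structure, rewards, and parameter values. Passing
equivalence tests therefore demonstrates internal consistency of the
cohort arithmetic — not that the model reflects any particular clinical
population. Real claims data would add inter-patient heterogeneity,
time-varying hazards, treatment discontinuation and mortality, none of
which the chain contains.

## Numerical choices

- Occupancy rows are required to sum to 1 within 1e−12 at every cycle;
  transition-matrix construction rejects any row violating this.
- ICERs are kept unrounded internally; reporting rounds to integer JPY
  and integer pounds (at 160 JPY/£).
- Degenerate inputs: a one-cycle horizon yields equal QALYs in both
  arms (both cohorts spend the single cycle in first-year PACS), so the
  ICER is undefined and reported as such rather than as ±inf; dominance
  uses exact zero comparisons, since the only way to hit zero increments
  with this model is exact structural equality.
- The beta moment fit rejects sd² ≥ mean(1−mean) with an explicit
  infeasible-moments error instead of clipping.

## Known limitations

- No mortality, no cataract-surgery pathway, no bilateral-eye
  bookkeeping beyond the two blindness states, no treatment
  discontinuation; these are structural choices of the model, not
  omissions of the implementation.
- Blindness is reachable only from PACG; a model in which long-standing
  PAC contributes directly would shift more weight onto the
  observation arm.
- PSA draws are independent; correlated uncertainty (e.g. between the
  two arms' progression probabilities, which share an evidence source)
  would narrow the incremental distributions.
- The cohort's memorylessness makes the post-crisis ("LPI open") PAC
  transition use the arm-level PAC→PACG probability; patients who
  reached PAC via a crisis are not distinguished.
- No expected-value-of-perfect-information analysis is provided.
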