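# lpi-cea

A Markov cohort cost-utility model comparing **prophylactic laser
peripheral iridotomy (LPI)** with **observation** for **primary
angle-closure suspects (PACS)** in Japan, from the healthcare payer's
perspective, with deterministic and probabilistic sensitivity analyses
and a patient-level microsimulation validator.

It is written for health-economics and ophthalmic-epidemiology
researchers who want a transparent, scriptable, fully tested
re-implementation of this class of decision model: every input is a
named parameter with an explicit sensitivity range and distribution,
every analysis is a library call, and a brute-force individual-level
simulator cross-checks the cohort arithmetic.

## The model

Patients enter at age 40 (configurable) in the PACS state and progress
irreversibly through

```
PACS  →  PAC  →  PACG  →  unilateral blindness  →  bilateral blindness
```

in yearly cycles with no death state. The LPI arm receives the laser in
the first year; the observation arm is additionally at risk of an acute
angle-closure crisis (AACC), a one-cycle state resolved by emergency
iridotomy into an open-angle PACS state that thereafter progresses at
the LPI-arm rate. First-year "tunnel" states carry one-off costs (the
laser itself; lens extraction on entry to PAC). Within PACG,
trabeculectomy is an expected-value event each cycle: with the
age-bracket probability `p_trab`, the cycle cost includes
`p_trab × c_trab` and the utility is `(1 − p_trab)·u_PACG + p_trab·u_trab`.

Discounted totals per arm use annuity-due accrual (cycle *t* weighted by
`(1+r)^−t`, first cycle undiscounted, no half-cycle correction):

```
Cost  = Σ_t (1+r)^−t Σ_s occ[t,s] · c(s, age_t)
QALYs = Σ_t (1+r)^−t Σ_s occ[t,s] · u(s, age_t)
ICER  = ΔCost / ΔQALYs,    NMB = λ·ΔQALYs − ΔCost
```

with willingness to pay λ = 5,000,000 JPY/QALY and r = 2%/year by
default. One-way sensitivity ranges are ±30% (probabilities), ±8%
(utilities), ±20% (costs) and 0–4% (discount rate); the probabilistic
analysis draws probabilities/utilities from method-of-moments beta
distributions (SD = 10%/5% of the mean) and costs from gamma
distributions (SD = 10%), 10,000 iterations.

## Worked example

```bash
$ lpi-cea base-case
scenario          : 40-59 (20-year horizon, base-case)
LPI arm           : 496,174 JPY, 16.6749 QALYs
observation arm   : 416,730 JPY, 16.6638 QALYs
incremental cost  : 79,443 JPY
incremental QALYs : 0.01117
ICER              : 7,112,969 JPY/QALY (44,456 GBP/QALY)
NMB at 5,000,000: -23,599 JPY
```

Prophylaxis buys 0.011 discounted QALYs over 20 years for an extra
79,443 JPY, i.e. about 7.1 million JPY per QALY at these default
inputs. The equivalent library call:

```python
from lpi_cea import BASE_SCENARIO, default_parameters, run_comparison

lpi, obs, cea = run_comparison(default_parameters(), BASE_SCENARIO)
print(cea.icer)          # 7112969.38...
print(cea.dominance)     # 'tradeoff'
```

The numbered drivers under `analysis/` run the full study: `01` base
case, `02` the seven entry/exit-age scenarios, `03` the tornado diagram
(the PACS follow-up costs dominate the ranking), `04` the probabilistic
analysis with the acceptability curve, and `05` the 200,000-patient
microsimulation validation of the cohort engine. Each writes CSV (and
SVG) output under `results/`.

```bash
lpi-cea scenarios            # scenario table
lpi-cea dsa --top-k 12       # tornado
lpi-cea psa --iterations 10000 --seed 1
lpi-cea validate-oracle --patients 50000
```

Parameter overrides come from a YAML/JSON file (`--params my.yaml`);
the societal perspective additionally needs a `societal:` block with the
indirect cost of bilateral blindness and a visit schedule, since those
inputs are not part of the built-in payer-perspective set.

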