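# Methods

## The decision problem

Adults (> 18 years) with severe asthma that remains uncontrolled on
medium/high-dose inhaled corticosteroids plus a long-acting β₂-agonist
(ICS+LABA) may receive add-on tiotropium, a long-acting muscarinic
antagonist. The package compares lifetime costs (2023 US$, COP converted at
4,000/US$) and quality-adjusted life-years (QALYs) of the two strategies with
a Markov cohort model and evaluates cost-effectiveness at a willingness-to-pay
of US$5,180 per QALY.

## Model structure

The cohort occupies a single *alive, controlled-asthma* state plus an
absorbing *dead* state, on a two-week cycle. Exacerbations are modelled as
transient within-cycle events, not persistent states: each alive member may
experience at most one event per cycle — an OCS burst, an emergency-department
(ED) visit or a hospitalization — whose costs and one-cycle utility decrements
attach to the cycle in which they occur. A two-week cycle matches the length
of an exacerbation episode, so tunnel states would double-count time.

Within a cycle, competing risks are resolved in a fixed declared order:

1. background death, with per-cycle probability
   `1 − (1 − qx)^(14/365.25)` from the annual life-table probability `qx`
   at the cohort's current completed age;
2. at most one exacerbation event among survivors, channel `i` with
   probability `1 − exp(−split_i · rate · 14/365.25)` (channel probabilities
   are renormalized, with a warning, in the pathological case where they sum
   above 1);
3. asthma death, applied as a case fatality on the hospitalization channel
   only.

The annual exacerbation rate is 1.14 per person-year for the comparator; the
add-on strategy multiplies it by the relative risk 0.72 (95% CI 0.62–0.83) on
the *rate* scale before probability conversion.

### Adherence waning

28% of add-on patients discontinue after 16 weeks (8 cycles). The engine runs
two sub-cohorts — fully adherent (treated inputs throughout) and reverted
(treated inputs for cycles 0–7, comparator inputs, including no drug cost,
thereafter) — and blends them with weights 0.72/0.28. The blend is computed as
`adherent + f·(reverted − adherent)` so that identical sub-cohorts blend to
themselves bit-for-bit, which makes the zero-effect identity (RR = 1 and a
free drug ⇒ ΔC = ΔE = 0) hold exactly in floating point.

### Horizon, discounting, rewards

The horizon is lifetime: the run stops at the terminal life-table age (100),
at cohort extinction (alive mass < 1e-9), or at a user-set cycle count.
Costs and QALYs are discounted at 5%/year as `(1.05)^(−k·14/365.25)` for
cycle `k`, with half-cycle correction implemented as trapezoidal end-weights
(½, 1, …, 1, ½). Annual state cost (US$38) and utility (0.74) are prorated
by `14/365.25`; the drug cost, priced per 4-week pack (US$71), is prorated to
US$35.5 per model cycle for the on-treatment fraction of the alive mass.

## Parameters and uncertainty

Every quantity carries a base value and a lower/upper sensitivity range. For
sampling, ranges are read as central 95% intervals, `sd = (upper−lower)/3.92`
— exact for the relative risk (whose range is a published CI) and a uniform
convention for the ±25% ranges used elsewhere.

| parameter | base (range) | PSA family |
|---|---|---|
| drug cost / 4 wk | 71 (53–89) | gamma |
| controlled-state annual cost | 38 (28–47) | gamma |
| OCS burst / episode | 38 (28–47) | gamma |
| ED visit / episode | 2,648 (1,986–3,310) | gamma |
| hospitalization / episode | 230 (173–288) | gamma |
| controlled utility | 0.74 (0.56–0.93) | beta |
| decrements OCS / ED / hosp | 0.10 / 0.15 / 0.20 (±) | beta |
| relative risk | 0.72 (0.62–0.83) | beta |
| exacerbation rate /yr | 1.14 (±25%) | beta on cycle probability |
| discontinuation fraction | 0.28 (0.24–0.43) | beta |
| discount rate /yr | 0.05 (0–0.06) | fixed in PSA, varied in DSA |

Beta and gamma shapes come from method-of-moments fits that reproduce the
mean exactly and the sd to 1e-9 (verified analytically in the tests). The
annual exacerbation rate exceeds 1, so its beta parent is the per-cycle
probability, back-transformed to a rate after sampling; a relative risk whose
range touches 1 falls back to a moment-matched log-normal with a warning.

Declared assumptions where the published inputs are silent:

* **Event split** 0.40/0.35/0.25 (OCS burst/ED/hospitalization) of the 1.14
  total. The cost study's event rates (1.4 ED, 2.5 hospitalizations per year)
  are mutually inconsistent with the 1.14 total and cannot be used directly.
* **Asthma case fatality** 0.01 per hospitalized exacerbation (0 for the
  outpatient channels). An asthma-mortality path is structurally required;
  its magnitude is an explicit, configurable assumption.
* **Cohort**: enters at age 18, 50/50 sex mix, because the source models
  "general adults" without an age distribution.

The PSA is a second-order Monte Carlo with *common random parameters*: each
replication samples one parameter set and evaluates both strategies under it,
so incremental statistics are within-replication differences. Default 10,000
replications. Centiles use empirical quantiles with linear interpolation.
`P(cost-effective)` is the fraction of draws with `ΔE·λ − ΔC > 0`, the same
functional the acceptability curve evaluates, so the two agree exactly at λ.
The one-way DSA sets each ranged parameter to its lower and upper bound in
turn (all else at base) and orders the tornado by |NMB(high) − NMB(low)|.

## Synthetic life table

Background mortality uses a Gompertz–Makeham stand-in for national life
tables: annual hazard `a + b·exp(c·age)` with defaults `a = 5e-4, b = 3e-5,
c = 0.09`, giving e.g. qx(40) ≈ 0.0016 and qx(80) ≈ 0.04 — plausible
middle-income adult mortality. The terminal age (100) is forced to qx = 1 so
every cohort is extinguished. Under these defaults about 6.5% of the cohort
survives from 18 to the terminal age under background mortality alone;
extinction is guaranteed by the terminal closure, not by the hazard itself.
Sex-specific tables apply hazard multipliers (0.80 female, 1.25 male) and are
blended by the scenario's female fraction. The synthetic table reproduces the
*shape* of adult mortality, not any country's actual rates, so green tests
establish internal correctness of the engine and analytics, not calibration
to a real population.

## Numerical choices

* Extinction threshold 1e-9 of the cohort mass; 365.25-day year everywhere.
* Negative per-cycle QALYs (possible only under extreme sampled decrements)
  are clamped to zero with a warning.
* ICERs are computed from full-precision internals, never from rounded
  summaries; a zero QALY difference yields a dominance/equivalence label
  instead of a ratio, and the CE-plane quadrant is always reported.
* The engine is fully vectorized (cumulative products over the cycle grid),
  so a 10,000-replication PSA over a lifetime horizon runs in seconds on one
  CPU. A count-based individual-level microsimulation (exact for
  exchangeable individuals) serves as the test oracle, never as the
  production engine.

## Known limitations

* With the published drug cost (US$71/4 wk ≈ US$923/yr) and the declared
  event split, the exacerbation costs the relative risk can avert
  (≈ US$317/yr) fall far short of the drug cost, so this implementation
  finds the add-on strategy *more* costly over a lifetime — the published
  cost-saving direction (and its very small lifetime totals, ≈ US$100 and
  ≈ 0.17 QALYs) is not reproducible from the published inputs. The
  acceptance suite computes and records this discrepancy rather than hiding
  it; the tornado and PSA machinery are unaffected.
* Indirect costs are not separately modelled; the unit costs are taken as
  already societal.
* No post-exacerbation tunnel states, no third comparator, no expected value
  of perfect information.
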