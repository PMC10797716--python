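# asthma-cua

Markov cohort cost-utility model of **add-on tiotropium versus ICS+LABA in
severe asthma**, for health economists and modellers who want a tested,
scriptable re-implementation of a published decision model: cohort engine,
adherence waning, probabilistic sensitivity analysis (PSA), net-benefit
decision analytics, cost-effectiveness acceptability curves (CEAC) and
one-way tornado analysis.

## The model

Adults with severe asthma occupy a controlled-asthma state or death, on a
two-week cycle over a lifetime horizon. Alive members may experience at most
one exacerbation per cycle — OCS burst, emergency-department visit or
hospitalization, with per-cycle probability
`1 − exp(−split_i · rate · 14/365.25)` — plus background mortality from a
life table and an asthma case fatality on hospitalizations. Add-on therapy
multiplies the exacerbation rate by RR = 0.72 (0.62–0.83); 28% of patients
discontinue after 16 weeks and revert to comparator inputs. Costs and QALYs
are discounted at 5%/year with half-cycle correction, and decisions use net
monetary benefit,

```
NMB(strategy) = QALYs × λ − Cost,      λ = US$5,180 per QALY
```

The PSA samples utilities, the relative risk, event probabilities and the
discontinuation fraction from method-of-moments beta distributions and costs
from gamma distributions (ranges read as 95% intervals). See
`docs/methods.md` for the full model account and declared assumptions.

## Worked example

```python
from asthma_cua import CostUtilityModel

model = CostUtilityModel()          # packaged inputs + synthetic life table
print(model.run().summary())
```

```
Base-case cost-utility results (discounted, lifetime horizon)
==============================================================
                                    cost (US$)         QALYs
ICS+LABA                              21364.58       13.4141
tiotropium+ICS+LABA                   29772.87       13.5670
--------------------------------------------------------------
Incremental cost (US$):               8408.29
Incremental QALYs:                     0.1529
ICER:                          54,979.13 US$/QALY [trade-off (costlier, more effective)]
NMB at US$5180/QALY:    comparator 48120.38, add-on 40504.30
Incremental NMB:                     -7616.08
```

Read: over a lifetime the add-on strategy buys 0.153 extra QALYs (fewer
exacerbations, slightly longer survival) for US$8,408 extra cost — an ICER of
about US$55,000/QALY, far above the US$5,180 threshold, so under the packaged
inputs the add-on is **not** cost-effective. (The source publication reported
the opposite direction; `docs/methods.md` explains why that result is not
reachable from its published inputs.) Probabilistic uncertainty:

```python
psa = model.run_psa(n_runs=10_000, seed=1)
s = psa.summary()
s.p_cost_effective          # 0.0  — P(incremental NMB > 0 at λ=5180)
psa.ceac().to_frame()       # acceptability curve over λ ∈ [0, 15540]
model.one_way_dsa().table   # tornado: NMB at each parameter's range endpoints
```

Everything is also available from the shell:

```sh
asthma-cua --out results run-base
asthma-cua --out results run-psa --n 10000 --seed 1
asthma-cua --out results run-dsa
asthma-cua --out results ceac --lambda-max 15540 --points 101
```

Inputs are overridable with `--params overrides.yaml` (merged onto the
packaged base case) and `--life-table table.csv` (`age,sex,qx`).

## Acceptance script

`scripts/acceptance.py` re-runs the whole analysis from scratch — base case,
10,000-replication PSA, acceptability curve and one-way tornado, with report
consistency checks — and writes its JSON output to `--out`:

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

## Layout

- `src/asthma_cua/params.py` — parameter set, validation, beta/gamma fits, PSA sampling
- `src/asthma_cua/lifetable.py`, `fixtures.py` — synthetic life table, packaged inputs, scenario
- `src/asthma_cua/engine.py` — cohort propagation, adherence blending, microsimulation oracle
- `src/asthma_cua/outcomes.py` — discounting, half-cycle correction, ICER, NMB
- `src/asthma_cua/psa.py` — PSA, summaries, CEAC, one-way DSA
- `src/asthma_cua/report.py`, `plots.py`, `model.py`, `cli.py` — reporting, figures, facade, CLI
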