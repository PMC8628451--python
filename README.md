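# earlyhta

Early health-economic evaluation of clinical analytics.

Developers of data-driven clinical analytics (risk stratification, early
detection, decision support) face an investment decision long before any
trial exists: is this application worth building at all? `earlyhta`
implements the quantitative core of a staged answer, aimed at analytics
developers and health-economics analysts:

1. **Data-feasibility audit** — is the candidate development dataset
   large enough, followed long enough, complete enough? The auditor
   computes sample size, median follow-up, per-field missingness, site
   count and outcome capture, and gates them against user-supplied
   requirements.
2. **Scope and barrier ledger** — a PICO (Population, Intervention,
   Comparator, Outcomes) scope plus a graded barrier list; development
   proceeds to evaluation only when no insurmountable barrier remains.
3. **Early economic evaluation** — decision trees rolled back into
   Markov cohort state-transition models, producing discounted costs,
   life-years and QALYs per strategy arm, incrementals and ICERs, net
   monetary benefit and headroom, with a full uncertainty toolkit:
   one-way (tornado), scenario, probabilistic (PSA + cost-effectiveness
   plane + CEAC), threshold and parameter-sweep analyses.

## The model

A strategy arm is an optional decision tree feeding a Markov cohort
model. Tree rollback yields an entry distribution over health states and
an expected upfront cost; the cohort then evolves per cycle as
`x_{t+1} = x_t P_t` with row-stochastic transition matrices `P_t`
(optionally time-dependent). Discounted outcomes accumulate per cycle
with an optional half-cycle (trapezoid) correction:

```
Cost  = upfront + Σ_k (1+r_c)^(-t_k) Σ_s x_k[s] · c_s
QALY  =           Σ_k (1+r_e)^(-t_k) Σ_s x_k[s] · u_s · Δt
ICER  = ΔCost / ΔQALY        NMB = λ·ΔQALY − ΔCost
Headroom = N + λ·Q
```

where `N` is the saving with the technology cost set to zero, `λ` the
willingness-to-pay threshold and `Q` the health effects gained. Hazard
ratios apply to per-cycle probabilities on the rate scale,
`p' = 1 − (1−p)^HR`.

Two case models ship as editable config bundles (model YAML + parameter
CSV + scenario YAML); their state structures and all parameter values
not printed in published main-text tables are illustrative assumptions,
labelled as such in the files:

- `cll` — analytics-guided stratification of watch-and-wait chronic
  lymphocytic leukaemia patients with early ibrutinib for the high-risk
  fraction (monthly cycles, 40-year horizon);
- `crbsi` — early detection of catheter-related bloodstream infections
  in the ICU, priced per bed (weekly cycles, decision tree + four-state
  Markov model).

## Worked example

```python
import earlyhta as e

case = e.load_case("crbsi")
res = case.base_case()
print(f"Δcost {res.delta_cost:,.0f} EUR, ΔQALY {res.delta_qaly:.3f}")
# Δcost 66 EUR, ΔQALY 0.061

free = e.scenario(case.builder, case.params, {"price_per_bed": 0.0})
print(f"at zero price: Δcost {free.delta_cost:,.0f} EUR ({free.dominance_label})")
# at zero price: Δcost -434 EUR (dominant)

thr = e.threshold_search(case.builder, case.params, "price_per_bed",
                         lambda r: r.delta_cost < 0, lo=0, hi=40_000)
print(f"cost-saving below {thr.value:,.0f} EUR per bed")
# cost-saving below 8,688 EUR per bed
```

At the base price the analytics add €66 per patient while gaining
0.061 QALYs; with the technology free they *save* €434 per patient and
dominate current care. The price threshold is the headroom to
cost-neutrality: the per-patient saving times the bed's annual patient
throughput (20), about €8,700 per bed per year — the budget available
for licensing, validation and integration before the technology stops
paying for itself.

The same surface drives the CLL case, where the conclusion reverses:
analytics plus early treatment add ≈€129,000 per patient for ≈0.13
QALYs (ICER far above European willingness-to-pay thresholds), and the
tornado analysis attributes most of that to the per-cycle drug cost.

A CLI mirrors the library:

```bash
earlyhta run --case cll --scenario best_case
earlyhta psa --case crbsi --n 1000 --seed 7 --plot
earlyhta threshold --case crbsi --param price_per_bed --criterion cost_saving
earlyhta audit --data patients.csv --spec roles.yaml --requirements reqs.yaml
earlyhta synth patients --n 2000 --seed 1 --out patients.csv
```

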