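# Methods

## Cohort engine

The engine simulates a closed cohort over discrete cycles. A model is a
set of labelled health states — each carrying a per-cycle cost (currency
units) and a utility weight in [0, 1] per year-equivalent — plus a
row-stochastic transition matrix, optionally a sequence of matrices for
time-dependent transitions (e.g. per-cycle probabilities digitised from
a time-to-event curve); when the horizon outruns the sequence, the final
matrix is reused. At least one absorbing state must exist and absorbing
rows must be identity rows. Absorbing states default to utility 0 and
cost 0 unless explicitly overridden.

Row sums are validated to 1 within 1e-9; deviations below that tolerance
are renormalised away (so downstream occupancy sums are exact), larger
ones raise with the offending row named. Entry distributions and
decision-tree branch probabilities are validated the same way.

**Cycle accounting.** A trace over `T` cycles has `T + 1` occupancy rows
(row 0 = entry). Payoffs for cycle `k` (k = 0..T−1) accrue on the
start-of-cycle occupancy, or on the trapezoid `(x_k + x_{k+1})/2` when
the half-cycle correction is enabled (the default — membership changes
are better approximated as mid-cycle events); either way they are
discounted at `t_k = k·Δt` with annual factors `(1+r)^(−t)`, separately
for costs and effects. Life-years count only non-absorbing occupancy.
The correction can be disabled per plan, which is also how the engine is
compared against its step-by-step oracle in tests.

**Decision-tree rollback.** Trees are finite and acyclic; each branch
carries a probability, a payoff cost and either a child node or a
terminal entry distribution over the Markov states. Rollback returns the
probability-weighted mixture of terminal distributions and the expected
path cost, which becomes the arm's upfront cost.

**Hazard ratios.** A hazard ratio applies to a per-cycle probability on
the rate scale, `p' = 1 − (1−p)^HR`, assuming a constant hazard within
the cycle. `HR = 1` is short-circuited to return `p` unchanged: the
naive expression `1 − (1−p)^1.0` rounds away from `p` in floating point,
and the exact fixed point is what makes null-intervention comparisons
exactly zero. `p = 1` with `HR ≠ 1` is a domain error (the underlying
rate is infinite).

## Economic outcomes

Incrementals are exact subtractions (intervention minus comparator).
ICERs are computed only when the incremental effect is nonzero;
otherwise they are *undefined* (`None`), never ±infinity, and the
dominance label (dominant / dominated / trade-off) carries the
interpretation. Headroom follows `N + λ·Q` with `N` the savings at zero
technology cost, `λ` the willingness to pay and `Q` the health gain; at
`λ = 0` it collapses to the cost-neutrality budget. Net monetary benefit
is `λ·ΔQALY − ΔCost`.

Parameters live in a `ParameterSet`: name, kind (probability, utility,
cost, hazard-ratio, rate, count), base, low/high range, optional
sampling distribution, source tag (literature / guideline / expert /
assumption). Kind supports are enforced (probabilities and utilities in
[0, 1], costs non-negative, hazard ratios strictly positive). The table
round-trips through CSV.

## Uncertainty toolkit

All analyses re-evaluate a *model builder* — a callable from a parameter
vector to a comparison — so they work identically for any case model.

- **One-way (tornado)**: each parameter to its low and high bound, all
  others at base; bars sorted by width descending around the base-case
  outcome.
- **Scenario**: a named override map applied simultaneously; the base
  table is never mutated.
- **PSA**: joint independent draws, one stream per parameter in fixed
  declaration order from a single seeded generator, so results are
  bit-reproducible under a seed. Parameters without a distribution are
  held at base (or rejected, per flag). Draws are clipped into the
  kind's support. Default draw count 1,000; correlations between
  parameters are not modelled — a documented limitation.
- **Default distributions** by kind, derived from base and range
  interpreted as a ≈95% interval: beta (method of moments, mean = base)
  for probabilities/utilities, gamma (mean = base) for costs and counts,
  lognormal (median = base) for hazard ratios, uniform fallback.
  Degenerate ranges fall back to a vanishingly narrow uniform.
- **CEAC**: fraction of draws with *strictly* positive NMB per λ; a tie
  at exactly zero counts as not cost-effective. Default λ grid 0 to
  200,000 in steps of 1,000.
- **Threshold search**: bisection for the value of one parameter at
  which a boolean criterion flips, default tolerance 0.01 currency
  units; same truth value at both bounds returns a "no threshold in
  range" result rather than raising; monotonicity can be checked
  empirically on a grid first.
- **Parameter sweep**: full re-evaluation over a grid, all other
  parameters at base.

## Case models

Cases are config bundles: `model.yaml` (states, cycle plan, per-arm
transition edge lists, payoff bindings, trees), `parameters.csv`,
`scenarios.yaml`. Transition and payoff values are expressions resolved
against the parameter vector: numbers, parameter names, or combinators
(`hr_adjust`, `sum`, `product`, `ratio`, `complement`, `mix`, `lerp`).
Unspecified diagonal entries get the residual stay probability. The
`lerp` combinator (`a + w(b−a)`) expresses "a treated fraction `w`
behaves like `b`, the rest like `a`" and collapses *bit-exactly* to `a`
when the endpoints coincide, which is what makes null interventions give
exactly zero incrementals.

**CLL.** Four states: watch-and-wait, treatment (next line),
subsequent-line, dead; monthly cycles, 40-year horizon (a lifetime
proxy: the cohort is effectively extinct), 3%/3% annual discounting.
Both arms are identical except the watch-and-wait row: the intervention
flags a high-risk fraction `f_highrisk` at entry (one-off analytics +
testing cost) and treats them early with ibrutinib — their per-cycle
probability of progressing to the next treatment line is hazard-ratio
adjusted, their per-cycle cost adds the drug, their utility is the
treated-state utility. Published anchor values: best-case HR 0.11,
half-price ibrutinib €2,542 and venetoclax €2,731 per cycle (hence base
prices of twice those), analytics+testing €100, early-treatment utility
0.78. Everything else is an assumption flagged in the parameter table.
The packaged `null_intervention` scenario sets HR = 1, zero analytics
and early-drug cost *and* equalises the early-treatment utility with
watch-and-wait — the natural definition of an intervention with no
effect and no cost.

**CRBSI.** Four states: ICU, post-ICU ward, discharged, dead; weekly
cycles (the ICU/ward phase is short), 40-year horizon for discharged
survivors. Per arm a decision tree splits on infection (prevalence
`p_crbsi`): infected patients incur extra ICU days times the per-day
cost plus antibiotics (a tree payoff) and an attributable ICU mortality
applied as a shift of the entry distribution toward dead before the
Markov phase; early detection lowers both. The Markov phase is shared
between arms, so arm differences are exactly the tree differences plus
the technology price, which enters per patient as
`price_per_bed / patients_per_bed` (the per-bed/per-patient conversion
is an explicit parameter, not a hard-coded constant). With base values
the tree mortality difference is prevalence × (0.25 − 0.20) = 0.5
percentage points.

## Feasibility audit and scope gate

The auditor computes descriptive metrics only; every threshold comes
from the user's requirements (the package encodes no clinical
judgement). Follow-up is (last contact − enrolment)/365.25 in years;
rows with a missing or unparseable date are excluded from the median and
reported as a separate follow-up-unknown fraction, so missing dates can
never flatter the median. Unparseable dates count as missing, never
fatal. Site heterogeneity is reported as per-site stratification only —
no formal heterogeneity statistic — and bias/representativeness is
explicitly "not assessed". The overall verdict is not-feasible iff any
requirement fails.

The scope gate requires all four PICO fields non-empty and blocks iff
any barrier is graded insurmountable; surmountable barriers are echoed
so the evaluation can carry them as scenarios. The blocking verdict is
"re-scope-or-cease": choosing between those is a developer decision, not
a computation.

## Synthetic data

The parameter generator draws base values uniformly within per-kind
ranges, brackets them with ±25% bounds clipped to the kind support and
attaches the kind-matched default distribution, so every generated table
passes downstream validation unchanged. The patient-table generator
draws enrolment dates uniformly over a window, exponential follow-up
censored at an administrative cutoff, site labels, and demographic/
outcome fields, then masks each configured field independently
(missing-completely-at-random). Both are bit-reproducible under a seed.

What the generator does *not* emulate: informative missingness,
correlated covariates, site-specific case mix, real date semantics
(deaths vs losses to follow-up). Passing audits on synthetic tables
therefore demonstrates that the metrics and gates are computed
correctly, not that any real dataset is feasible.

## Numerical choices and limitations

- Validation tolerance 1e-9 on probability sums; sub-tolerance noise is
  renormalised, larger deviations raise.
- The engine's trace equals naive step-by-step multiplication to 1e-12
  over 100 cycles (tested against an independent double-loop oracle).
- Problem sizes: the packaged cases run 480 (CLL) and 2,080 (CRBSI)
  cycles per arm; PSA defaults to 1,000 draws, and calibration tests use
  10,000 draws on closed-form toy models where the Monte-Carlo error is
  known.
- Absolute case-model totals are illustrative: the packaged parameter
  tables are assumptions around a handful of published anchor values,
  and the package makes directional and structural claims (signs,
  monotonicities, exact accounting identities), not reproductions of any
  published totals.
- Out of scope: patient-level microsimulation, continuous-time models,
  parametric survival fitting (curves arrive as per-cycle
  probabilities), value-of-information analysis, correlated PSA,
  budget-impact and societal-perspective costing.
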