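# Methods

## Model structure and assumptions

The analysis is a decision tree — appropriate because uncomplicated acute
appendicitis resolves quickly and the only long-horizon dynamic, recurrence
after nonoperative management (NOM), is modelled as at most one recurrence
per patient within the 5-year horizon (no Markov cycling, no half-cycle
correction). The decision root compares open appendectomy (OA),
laparoscopic appendectomy (LA) and NOM.

Each appendectomy (index operation, post-failure operation, interval or
immediate operation after a complicated recurrence) branches into a
four-way, mutually exclusive short-term outcome: no complication,
surgical-site infection (SSI), intra-abdominal abscess, or postoperative
ileus. LA complication probabilities are derived as
`min(p_OA × RR, 1)`; a clamp at 1 is logged, never silent. NOM branches
into durable success, failure within the initial admission (a distinct
branch with its own probability, 0 by default), or recurrence in year
1..5; recurrences are uncomplicated (→ appendectomy, open with probability
`p_choose_oa`) or complicated (→ medical management with percutaneous
drainage plus interval appendectomy, with probability
`p_complicated_medical`, else immediate surgery).

Structural exclusions, asserted by the tree validator: death, incisional
hernia, enteric fistula and abdominal sepsis do not appear anywhere in the
model (all are negligibly rare in uncomplicated appendicitis). Ileus is
cost-only: it resolves within the index admission without a
quality-of-life decrement.

Branch probabilities are stored *symbolically* (expressions over the
parameter set), so deterministic sweeps and probabilistic draws re-evaluate
one compiled tree rather than rebuilding it; an expected-value rollback and
an exhaustive path enumeration are interchangeable, and the test suite
holds them to within 1e−9 of each other.

## Timing and discounting conventions

Event timing is not uniquely determined by a tree alone, so the package
fixes one convention: all surgical-strategy costs (packages plus
complication management) and NOM initial-management costs occur at year 0;
recurrence costs occur at their schedule year; utilities accrue as
continuous streams tiling the whole horizon (episode windows chained
back-to-back from their event year, background "healthy" utility filling
the gaps). This is the only convention under which a surgical strategy's
discounted and undiscounted costs coincide, as in the source analysis'
deterministic table.

Costs at year *t* are discounted by `(1+r)^−t`. QALY streams are split
into calendar-year slices; the slice in year *k* is discounted at
`(1+r)^−(k+1)` (end-of-year annuity) by default, with mid-year
(`k+0.5`) and start-of-year (`k`) conventions selectable via
`qaly_convention`. The source analysis' TreeAge accrual rule could not be
recovered from its printed tables — its discounted 5-year QALY implies a
discount ratio matching neither convention — so the convention is explicit
and switchable rather than forced to agree; the same irrecoverability
applies to its PSA QALY scale (mean ≈ 3.33 against a deterministic ≈ 4.10),
which is why probabilistic QALY levels are treated as configuration-
dependent and only orderings are asserted.

## Parameters, units, defaults

All tariffs are COP; `USD = COP × inflation_factor / exchange_rate` with
the guideline +30% inflation adjustment and 3,478 COP/USD (January 2021),
applied once at event level with no intermediate rounding. Key defaults
(full provenance table in `appendix_cea.parameters.PROVENANCE`):

| parameter | default | why |
|---|---|---|
| `p_nom_success` | 0.727 | five-year antibiotic success, APPAC trial |
| `recurrence_schedule` | derived | 27% cumulative failure at year 1, linear to `1−p_nom_success` at year 5 |
| `p_choose_oa` | 0.929 | national share of open appendectomies |
| `rr_la_ssi / abscess / ileus` | 0.35 / 1.77 / 0.40 | meta-analytic scale (LA protects against SSI/ileus, raises abscess risk) |
| `discount_rate` | 0.05 | national EE guideline |
| `wtp` | \$6,667/QALY | 1 GDP per capita |
| `horizon_years` | 5 | captures late NOM recurrences |

The recurrence schedule stores conditional per-year hazards; validation
enforces that the implied overall success equals `p_nom_success` to 1e−9.
When a sweep or PSA draw moves `p_nom_success`, the cumulative-failure
curve is rescaled, keeping its shape.

## Second-order distributions

Families follow standard practice for each parameter type: beta for
binomial probabilities and utilities (moment-matched at an effective
sample size of 100, configurable), Dirichlet jointly over the four-way
complication split (concentration = probability × ESS, the standard
construction when only marginals are known), Poisson for resource
quantities, uniform for unit tariffs (±25% when no bounds are known) and
for relative risks over their 95% CIs. The assumed RR intervals are
symmetric about the point estimates so that every second-order
distribution is mean-centred on the deterministic base case — without
this, PSA mean orderings would drift from the base case for no substantive
reason. Draws violating any parameter-set invariant (e.g. a complication
simplex overflow) are redrawn and counted, never clamped.

## Monte Carlo design

All randomness flows from a single integer seed through named
`numpy.random` substreams (`psa`, `microsim`, `population`, `synthetic`),
so runs are bitwise reproducible and the three simulation levels never
share a stream.

*First order* (`microsimulate`): each trial samples its terminal path from
the compiled path distribution — distributionally identical to walking the
tree branch by branch — and draws its utility values per trial;
`utilities_only=True` keeps branch outcomes expectation-weighted so only
utilities vary, matching the narrower reading of patient-level variability.

*Second order* (`psa_run`): per iteration one joint parameter draw, then
expected-value rollback of all three strategies under that same draw
(recorded with a draw digest). The CEAC reports, per willingness-to-pay,
the fraction of iterations in which each strategy attains the maximal
absolute NMB (`λ·E − C`); exact ties — measure-zero under continuous
draws — go to the cheapest tying strategy for determinism.

*Population* (`population_simulation`): each second-order iteration
simulates the whole population first-order via a multinomial over terminal
paths and sums costs. With 100,000 patients the spread of totals is
dominated by parameter uncertainty (sampling error shrinks with √n), which
is the regime the published ±millions standard deviations imply; with one
patient it degenerates to a single microsimulation trial.

Deterministic sensitivity analysis evaluates a strategy's absolute NMB (or
a pairwise ICER) on an even grid over one input (tornado entries sorted by
span); threshold analysis checks empirical monotonicity of the NMB
difference on the grid and then brackets the crossing with Brent's method
to 1e−6 relative tolerance, returning a declared no-crossing result when
the sign never changes. A virtual target `scale.cost_items.<event>`
multiplies every tariff of an event, supporting questions like "how much
cheaper must NOM become?".

## What the synthetic baseline does and does not show

The exact resource quantities, tariffs, probabilities, utilities and
distribution parameters behind the original analysis are not publicly
deposited. The shipped baseline is therefore a *synthetic* configuration:
internally consistent, tariff-scale realistic, anchored to the publicly
stated facts (NOM success 72.7%, open-surgery share 92.9%, guideline
constants, LA package = OA package + one trocar) and calibrated so the
baseline reproduces the qualitative structure of the published results —
LA cheapest (deterministically and in PSA means), OA absolutely dominated,
NOM most effective by a fine margin, LA dominant in NMB probability at
1 GDP per capita. Passing tests therefore demonstrate that the *machinery*
is correct and that this structure is robust under the documented
uncertainty model; they do not validate the specific Colombian tariff
values, and absolute levels (e.g. PSA QALY means) will move when an analyst
transcribes primary-source tables into `configs/template.yaml`. The
synthetic generator couples scenarios through shared uniforms, so raising a
scenario scale (complications, costs) moves every affected parameter
monotonically — scenario-comparison properties are exact, not statistical.

## Numerical choices and edge cases

- Rounding only at presentation (console: USD 2 dp, QALYs 4 dp); full
  precision in all stored outputs.
- Incremental analysis sorts by ascending cost, breaking ties by
  descending QALYs then input order; `ΔE = 0` yields an explicit
  `undefined_zero_delta_e` verdict instead of a division.
- Absolute dominance is flagged against the cheapest dominating strategy;
  extended dominance (non-increasing successive ICERs) is pruned
  iteratively even though three-strategy analyses rarely need it.
- Degenerate (all-point) PSA reproduces the deterministic result exactly;
  a no-op rescale guard keeps those draws bitwise identical.
- Problem sizes used by the acceptance script — 10,000 PSA iterations,
  1,000 microsimulation trials, 1,000 × 100,000-patient budget iterations —
  are the package's defaults for a converged analysis; the whole script
  runs in well under a minute on one core.

## Known limitations

- One recurrence per patient; no events beyond year 5.
- No correlation structure between parameters (beyond the Dirichlet
  simplex), matching the independence assumption of the source analysis.
- No value-of-information (EVPI/EVPPI) analysis.
- Uniform tariff distributions are a coarse stand-in where a gamma or
  log-normal would be preferred if dispersion data existed.
- The baseline's absolute cost/QALY levels are synthetic; only the
  documented anchors carry external provenance.
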