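# appendix-cea

Decision-analytic cost-effectiveness analysis of the three ways uncomplicated
acute appendicitis is managed in practice — **open appendectomy (OA)**,
**laparoscopic appendectomy (LA)**, and **nonoperative management (NOM)**
(antibiotics with appendectomy reserved for failure or recurrence) — from the
perspective of the Colombian public payer. It is written for health
economists and HTA analysts who want a scriptable, testable alternative to
spreadsheet or TreeAge decision-tree models: the whole analysis (tree
rollback, incremental analysis, deterministic and probabilistic sensitivity
analysis, budget impact) is a Python library with a thin CLI.

## The model

A decision tree over a 5-year horizon. Surgical strategies branch into a
mutually exclusive short-term outcome — no complication, surgical-site
infection, intra-abdominal abscess, or postoperative ileus — where the LA
complication probabilities are derived from the OA ones via meta-analytic
relative risks, `p_LA = min(p_OA × RR, 1)`. NOM branches into durable
success, failure within the initial admission, or recurrence in year
*t* ∈ {1..5}; an uncomplicated recurrence goes to appendectomy (open with
probability `p_choose_oa`), a complicated one to medical management plus
interval appendectomy or to immediate surgery. Costs are Colombian tariff
(COP) packages and per-event resource sums, inflated 30% per the national
guideline and converted at 3,478 COP/USD; outcomes are QALYs
(utility × time). Both are discounted at 5%/year:

- present value of a cost at year *t*:  `C / (1+r)^t`
- QALYs from utility *u* held over years 1..T (end-of-year annuity):
  `u · (1 − (1+r)^−T) / r`
- `ICER = ΔC / ΔE`,  `NMB = ΔE·λ − ΔC` with λ = $6,667/QALY (1 GDP per capita)

Uncertainty is handled the standard two-level way: a first-order
microsimulation (patient-level sampling with per-trial utility draws) and a
second-order Monte Carlo PSA over beta (probabilities, utilities), Dirichlet
(the polytomous complication split), Poisson (resource quantities) and
uniform (tariffs, relative risks) distributions, summarized as a
cost-effectiveness acceptability curve, an incremental-NMB distribution, and
a 100,000-patient budget simulation.

The exact tariff/probability/utility tables behind the original analysis are
not publicly deposited, so the package ships a documented synthetic baseline
calibrated to the publicly stated anchors (72.7% five-year NOM success,
92.9% open-surgery share, guideline constants); `configs/template.yaml`
flags every field an analyst should transcribe from primary sources before
using the model for a real decision.

## Worked example

```bash
appendix-cea --out-dir results evaluate
```

prints (USD, QALYs; baseline configuration):

```
  strategy         block comparator   cost  qalys delta_cost delta_qalys               verdict       icer     nmb
0       LA  undiscounted       None 312.32 4.9793        NaN         NaN             reference        NaN     NaN
1       OA  undiscounted         LA 317.50 4.9640       5.19     -0.0153  absolutely_dominated        NaN -106.94
2      NOM  undiscounted         LA 418.69 4.9800     106.37      0.0008                  icer 136,474.19 -101.18
3       LA    discounted       None 312.32 4.3106        NaN         NaN             reference        NaN     NaN
4       OA    discounted         LA 317.50 4.2961       5.19     -0.0145  absolutely_dominated        NaN -102.10
5      NOM    discounted         LA 414.14 4.3117     101.83      0.0011                  icer  91,677.00  -94.42
```

Reading the discounted block: LA is the cheapest strategy and the reference;
OA costs $5.19 more per patient while yielding 0.0145 *fewer* QALYs, so it
is absolutely dominated and excluded from the efficiency frontier; NOM adds
0.0011 QALYs over LA at $101.83 extra, an ICER of ≈$92,000/QALY — far above
the λ = $6,667/QALY threshold, so LA is the cost-effective choice (the NOM
row's incremental NMB at λ is −$94). Surgical costs all fall at year 0,
which is why their discounted and undiscounted costs coincide while NOM's
recurrence costs shrink under discounting.

The same library calls are available programmatically:

```python
from appendix_cea import (baseline_parameter_set, build_appendicitis_tree,
                          rollback, incremental_analysis)
params = baseline_parameter_set()
tree = build_appendicitis_tree(params)
result = rollback(tree, params)
analysis = incremental_analysis(result, wtp=params.wtp)
print(analysis.frontier)          # ['LA', 'NOM']
```

Other subcommands: `psa` (Monte Carlo summary), `ceac`, `nmb-dist`,
`dsa` (tornado), `threshold`, `popsim`, `synth` (emit a synthetic config),
`tree` (outline + DOT export). For example, the threshold analysis

```bash
appendix-cea threshold
# scale.cost_items.nom_initial: NMB parity NOM vs LA at 0.709968 (-29.0% vs baseline)
```

says NOM would need a 29% reduction of its initial-management cost to tie
LA on net monetary benefit under the baseline configuration.

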