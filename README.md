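# osteomark

A Markov cohort cost-effectiveness model of osteoporosis treatment in
postmenopausal women, for health economists and modellers who want a tested,
scriptable implementation of the standard fracture-model architecture:
hierarchical health states, time-dependent treatment efficacy, real-world
persistence with offset decay after discontinuation, post-fracture excess
mortality, and payer-perspective cost/QALY accrual.

## The model

A cohort of women (default: age 72, femoral-neck T-score −2.5, 23.6% with a
prevalent vertebral fracture) moves through eight health states — well, four
acute fracture states (hip, vertebral, wrist, other), post-hip, post-vertebral
and dead — in 6-month cycles over a lifetime horizon. The per-cycle fracture
probability at each site composes three factors:

```
rate = (general-population incidence)
     × (disease RR: gradient^(mean population T-score − patient T-score),
        or the prior-fracture RR, adjusted down 10% to avoid double counting
        BMD, for women with a fracture history)
     × (treatment RR: 12/24/36-month trial endpoints, the 36-month value
        carried forward; after discontinuation a linear return to 1 over
        min(time on treatment, maximum offset time))

p_cycle = 1 − exp(−rate × 0.5)
```

Within a cycle the most severe fracture (hip > vertebral > wrist > other)
routes the patient; lower-hierarchy fractures sustained in hip/vertebral
states are counted as *downstream* events that accrue costs and a three-step
disutility without changing state. Excess mortality after hip/vertebral
fractures persists for 8 years (half-year tunnel compartments), with 30% of
the excess attributed to the fracture itself. Treatment persistence follows
observed 36-month curves (extrapolated geometrically) and spawns
discontinuation strata that carry their own offset clocks. Costs (2024 USD,
US third-party payer) and QALYs are discounted at 3%/year.

Strategies compared: 10-year denosumab (6-monthly injection, 1-year offset),
alendronate 5 years on / 2-year drug holiday / 3 years on (2-year offset),
and no treatment. Outputs: discounted lifetime cost by category, fracture
events by site, life-years, QALYs, and pairwise ICERs (Δcost/ΔQALY) or
dominance; plus a scenario grid over on-treatment/holiday durations, one-way
sensitivity analysis, and a probabilistic sensitivity analysis with
cost-effectiveness acceptability curves.

Published point estimates (relative risks, efficacy, persistence, unit costs,
utilities) ship as bundled defaults. Inputs that are not published in full —
the female life table, age-specific fracture incidence, mean population
T-score by age, post-fracture mortality RRs, nursing-home admission and stay
after hip fracture — are synthetic stand-ins generated by
`osteomark.synthetic` and clearly flagged as assumptions; absolute results on
the bundled inputs are therefore illustrative of the model mechanics, not a
reproduction of any published table. See `docs/methods.md`.

## Worked example

```python
import osteomark as om

params = om.default_parameters()
den  = om.evaluate(om.denosumab(), params)
alen = om.evaluate(om.alendronate(), params)
res = om.icer(den, alen)
print(f"denosumab:   cost ${den.total_cost:,.0f}  QALYs {den.qalys:.3f}")
print(f"alendronate: cost ${alen.total_cost:,.0f}  QALYs {alen.qalys:.3f}")
print(f"ICER: ${res.icer:,.0f} per QALY gained "
      f"(dCost ${res.delta_cost:,.0f}, dQALY {res.delta_qaly:.4f})")
```

prints, on the bundled inputs:

```
denosumab:   cost $53,215  QALYs 8.894
alendronate: cost $48,368  QALYs 8.813
ICER: $59,608 per QALY gained (dCost $4,847, dQALY 0.0813)
```

i.e. ten years of denosumab costs $4,847 more per patient than the
alendronate regimen over a lifetime and yields 0.081 additional
quality-adjusted life-years, so each QALY gained costs about $59,600 —
cost-effective at a $100,000/QALY willingness-to-pay threshold.

The command line mirrors the library:

```
osteomark synth --seed 0 --out bundle/        # write a parameter bundle
osteomark validate bundle/                    # schema + invariant checks
osteomark run --strategy-set base --out out/  # base-case CE table
osteomark run --strategy-set psa --seed 1 --out out/
osteomark oracle --strategy alendronate --n 200000 --seed 1
```

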