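# Methods

## Model structure

The cohort occupies an array indexed by (persistence stratum ×
vertebral-fracture flag × health state × time-in-state). Eight health states:
well; acute hip, vertebral, wrist and other fracture; post-hip;
post-vertebral; dead (tracked as cumulative mass). Cycles are 6 months; the
default horizon is lifetime, meaning age 100 (56 cycles from the default
starting age of 72).

Routing follows the severity hierarchy hip > vertebral > wrist > other,
resolved by a cascade: the probability of entering the hip state is the hip
marginal probability; vertebral is entered with probability
(1 − p_hip)·p_vert, and so on, so the within-cycle outcome distribution is
that of independent site-specific events with the most severe one winning.
From the acute hip state only a hip re-fracture changes the path (back to
acute hip, clock reset); otherwise survivors move to post-hip. From acute
vertebral/post-vertebral states a hip fracture routes upward and a vertebral
re-fracture resets; from post-hip only hip re-fractures route. Acute wrist and
other states route like the well state and return to well after two cycles.

Lower-hierarchy fractures sustained while in hip/vertebral states are
"downstream" events: in each cycle, occupancy of the acute-hip, post-hip,
acute-vertebral and post-vertebral compartments is multiplied by the lower
sites' per-cycle probabilities; the expected counts accrue the full year-1
fracture cost and a one-year disutility (see below) without changing state.
This corrects the undercounting a strict hierarchy otherwise causes.
Downstream events do not update the vertebral-fracture flag or trigger excess
mortality; they feed accounting only.

Time-in-state is tracked with half-year tunnel compartments in the post-hip
and post-vertebral states, deep enough to cover the excess-mortality window
(16 compartments for the 8-year base case; the depth follows the configured
window, with a capped "beyond" compartment that accrues year-2+ costs and
utilities indefinitely).

Event timing: fractures occurring during cycle k place the patient in the
acute state during cycle k+1, where the acute (year-1) effects accrue over
two cycles. Events generated by the final cycle's transition fall beyond the
horizon and are not counted — true identically in the cohort engine and the
microsimulation.

## Fracture risk

Per cycle and site: rate = general-population incidence × disease RR ×
treatment RR, converted by p = 1 − exp(−rate/2). The exponential conversion
keeps probabilities in [0, 1) under large RR products.

*Disease RR.* Fracture-naive patients (well state, no prevalent vertebral
fracture) use the BMD pathway: gradient-of-risk per SD raised to the deficit
of the patient T-score below the age-specific population mean. Patients with
any fracture history — a prevalent vertebral fracture, occupancy of a fracture
or post-fracture state — use the prior-fracture RR instead, adjusted downward
by 10%, precisely because that adjustment exists to remove the BMD overlap;
the two pathways are never multiplied. The hip gradient defaults to the
all-age value (2.60), with the age-specific alternative (2.89 at 65, 2.78 at
70) available as a config switch. Sparse age-anchored RR tables (hip prior-
fracture RR, age-specific hip gradient) hold their first anchor for younger
ages so that younger-cohort scenarios remain evaluable; dense tables (life
table, incidence) raise below support. Age-keyed lookups default to step
functions at the largest key ≤ age; linear interpolation is a config switch.

A structural limitation shared with the hierarchy: wrist/other fracture
history is forgotten once the patient returns to well, so those patients
revert to the BMD pathway.

*Treatment RR.* A step function of months on drug — the (0,12], (12,24] and
(24,36] intervals take the 12/24/36-month endpoint values, and the 36-month
value is carried forward. Patients discontinuing mid-interval keep the
interval's value (e.g. a 6-month discontinuer froze at the 12-month RR),
which slightly flatters early discontinuers in both arms.

*Offset.* After discontinuation the RR returns linearly to 1 over the
effective offset time min(months on treatment, maximum offset), so early
discontinuers lose their residual benefit sooner ("dynamic" offset). During a
scheduled drug holiday and after the final on-treatment segment the whole
current stratum follows the same residual decay with the treatment clock
frozen at the segment boundary.

## Persistence

Observed persistence at 6-month marks over 36 months; beyond that, geometric
decay at a per-6-month retention ratio: the final observed interval's ratio
("last value" / "last interval rate" — on a 36-month dataset the two published
framings coincide, so both names map to the same rule) or the overall ratio
p(36)^(1/6) ("overall rate"). The 6-monthly injectable evaluates persistence
at cycle starts, aligned with administration; the weekly oral at cycle
midpoints, linearly interpolated between marks (the interpolation rule is
ours; only the midpoint timing is prescribed). Each cycle's drop in the
persistent fraction spawns a discontinuation stratum with its own
time-on-treatment clock; a stratum whose offset has elapsed is
indistinguishable from never-treated mass and is merged, which bounds the
stratum count at 2 + (offset in cycles). On re-initiation after a holiday the
persistence clock resumes from its value at the holiday start (no reset to
100%) — conservative toward the oral regimen; a full reset would require a
re-initiation model the data do not support.

## Mortality

Baseline: q_cycle = 1 − (1 − q_annual)^0.5 from the female life table. Within
the window after a hip or vertebral fracture (default 8 years including the
acute cycle) the state's mortality RR applies as
q = q_cycle · (1 + a·(RR − 1)) with attribution a = 0.30 (alternatives 0,
0.18, 0.42, 1.0), clipped at 1. "Other" fractures carry their RR during the
two acute cycles only, because those patients return to well and the model
retains no clock for them; wrist fractures carry no excess (no published RR).
Death is applied before fracture within a cycle — the model text is silent on
within-cycle order, and death-first is the conservative choice.

Patients whose vertebral fracture occurred during the simulation carry a flag
(prevalent fractures are flagged separately and excluded, since the published
weighting counts only the *incremental* vertebral-fracture proportion).
In the hip and post-hip states the flag adds the vertebral excess to the
mortality RR additively (RR_hip + RR_vert − 1; additive stacking of excess
risks avoids the superlinear growth a product would create) while the hip
window is active, and multiplies the hip-state utility by the year-2+
vertebral multiplier for life. Because the engine tracks the joint
distribution of the flag and the states, this is the exact form of the
aggregate weighting quotient (incremental vertebral proportion divided by the
baseline proportion without vertebral fracture), which is still exposed and
tested as `prior_vf_weight`.

## Costs and QALYs

Third-party payer, 2024 USD, 3%/year discount, end-of-cycle factors
(1+r)^(−t). Drug and management (nurse/physician visits, DXA at annual
frequencies) accrue per cycle on the alive, persistent, on-treatment mass;
nothing accrues during holidays or after discontinuation. Year-1 fracture
costs split evenly over the two acute cycles — mirroring the two-cycle utility
treatment; the cost timing is not prescribed — and year-2+ costs accrue at
half the annual value per cycle in the post states. Downstream events accrue
the full year-1 cost in their cycle. Nursing-home costs apply only to hip
fractures, as a one-time expected lump sum (admission probability × mean stay
× per-day rate) at entry; the stay-duration profile is unpublished, and the
expected lump sum is order-correct and simplest. Age bands (50–64 / 65+ for
costs, decades for utilities) follow the cohort's age at the accrual cycle,
not at fracture — the simplest consistent rule; the default cohort enters at
72 so the 65+ band dominates.

QALYs: age-band baseline utility × state multiplier × 0.5 years per cycle.
Year-1 multipliers apply during the two-cycle acute window (hip 0.550,
vertebral 0.680, wrist/other 0.830), year-2+ multipliers in the post states
(hip 0.860, vertebral 0.850). Downstream disutility in three steps: the
lower-hierarchy utility is the higher state's utility times the lower site's
year-1 multiplier; the decrement is the difference; the cycle's QALYs are
adjusted down by one year of that decrement per event, taken in the event's
cycle.

## Synthetic stand-ins

Generated tables (flagged `ASSUMED` in every file header) replace inputs not
published in full:

* **Life table** — Gompertz–Makeham q(x) = min(1, 2e−4 + 1.7e−5·e^{0.095x}),
  female life expectancy at 72 ≈ 17 years (checked against a survival-product
  oracle), terminal q(110) = 1.
* **Post-fracture mortality RRs** — linear decline with age from 4.5/3.4/2.2
  (hip/vertebral/other) at 50, floored at 1.5/1.3/1.1.
* **Incidence** — exponential-in-age site rates (hip rising ~10× from 55 to
  85, vertebral comparable, wrist nearly flat), with levels set once so the
  untreated cohort sustains ~1.5 lifetime fractures with a realistic site mix;
  the levels were frozen after that single calibration.
* **Mean population T-score** — linear, −0.9 at 65 to −1.8 at 85.
* **Long-term care** — admission probability 0.20, mean stay 180 days.

These stand-ins reproduce the *structure* real inputs would have (shapes,
monotonicity, magnitudes), so passing tests demonstrate correct model
mechanics — accounting identities, hierarchy and offset behaviour, engine/
microsimulation equivalence, directional sensitivity — but the absolute
cost-effectiveness numbers on the bundled inputs are illustrative only.
Swapping in transcribed tables via a parameter bundle changes the numbers,
not the code paths.

## Sensitivity analyses

One-way variants are pure parameter overrides (dotted paths into the
serialized parameter tree) or strategy substitutions; the base-case inputs
are layered defaults, so every scenario is a diff. Implemented rows: start
age, prevalent fracture share, T-score, horizon, maximal treatment length,
both offsets, persistence extrapolation method and 100%-persistence,
discount rate, excess-mortality attribution and window. Alternative
network-meta-analysis efficacy sets and alternative persistence sources can
be supplied as bundles but are not built in (values unpublished here), and a
"5-year rate" extrapolation is not implemented (no published definition).

The PSA draws all uncertain inputs jointly: efficacy RRs lognormal
(moment-matched so the distribution *mean* equals the point estimate — the
inputs are stated as point estimates with standard errors, not medians),
persistence points, the nursing-home admission probability and utilities beta
(mean/SE moment matching, variance clipped to the feasible range), fracture
costs normal truncated at zero. Standard errors default to 10% of the point
estimate. Sampled persistence curves are forced nonincreasing by a running
minimum. All strategies are evaluated on the same draw (common random
numbers), which removes between-arm sampling noise from the incremental
distributions. CEACs use the net-benefit rule λ·ΔQALY − Δcost ≥ 0 on a
$0–$300,000 grid in $5,000 steps.

## Validation

An individual-level microsimulation (`osteomark.microsim`) implements the
same rules by sampling trajectories, with per-cycle discontinuation sampling
matching the cohort engine's proportional stratum transfer in distribution.
The acceptance suite requires every summary output (total cost, QALYs,
life-years, per-site and any-fracture counts) to agree within three
Monte-Carlo standard errors at n = 200,000 for all three base-case strategies
and for three randomized parameter sets drawn by the PSA sampler.

## Problem sizes and numerics

Default runs use 56 cycles, ≤ 6 persistence strata, 3 vertebral-flag levels,
7 alive states and 16 tunnel compartments (~2,000 compartments); one strategy
evaluation takes ~25 ms, the 1000-draw PSA about 80 s, and a 200,000-woman
microsimulation a few seconds. Mass conservation (occupancy + cumulative
deaths = 1) is asserted at 1e−10 every cycle. Negative occupancies are
asserted against at 1e−15. Death probabilities are clipped at 1 after excess
scaling. Ties in the fracture cascade cannot occur (probabilities are
composed, not compared).

## Known limitations

* No imminent-risk escalation by time since fracture, by design.
* Wrist/other fracture history is forgotten on return to well.
* Downstream events do not set the vertebral-fracture flag or excess
  mortality.
* Persistence is independent of health state (no post-fracture adherence
  response).
* The bundled epidemiology is synthetic; absolute ICERs on it are
  illustrative.
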