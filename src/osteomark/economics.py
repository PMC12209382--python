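"""Cost and QALY accrual over a cohort trace.

Costs (third-party payer, 2024 USD): drug acquisition and treatment
management (nurse/physician visits, DXA) while persistent on treatment;
fracture treatment costs with the year-1 cost split evenly over the two
acute cycles and the year-2+ annual cost accruing at half per cycle in the
post-hip/post-vertebral states; expected nursing-home costs as a lump sum at
hip-fracture entry; downstream fractures accrue their full year-1 cost in the
cycle they occur.

QALYs: age-band baseline utility times the state multiplier (year-1
multiplier during the two-cycle acute window, year-2+ multiplier thereafter
for hip/vertebral), half a year per cycle, with incident-vertebral history
additionally multiplying the hip-state utilities; downstream fractures
subtract a one-year disutility computed in three steps (lower-hierarchy
utility = higher-state utility x lower site's multiplier; the decrement is
the difference; cycle QALYs are adjusted downward by it).

Discounting is end-of-cycle at the annual rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict

import numpy as np
import pandas as pd

from .engine import (
    DOWNSTREAM_GROUPS,
    CohortTrace,
    HIP_FX,
    OTHER_FX,
    POST_HIP,
    POST_VERT,
    VERT_FX,
    WELL,
    WRIST_FX,
)
from .params import ParameterSet, TreatmentStrategy
from .states import SITES, VF_INCIDENT

COST_CATEGORIES = ("hip", "vertebral", "wrist", "other", "drug", "management")

#: utility multiplier applied to the higher-hierarchy state of each
#: downstream accrual group
_GROUP_MULT = {"hip_y1": ("hip", 1), "hip_y2": ("hip", 2),
               "vert_y1": ("vertebral", 1), "vert_y2": ("vertebral", 2)}


def discount_factor(rate_annual: float, cycle_index: int, cycle_length: float = 0.5) -> float:
    """End-of-cycle discount factor ``(1 + r)^(-t)`` with t in years."""
    if rate_annual < 0:
        raise ValueError("discount rate must be >= 0")
    return float((1.0 + rate_annual) ** (-cycle_index * cycle_length))


def cycle_drug_and_monitoring_cost(
    strategy: TreatmentStrategy, persistent_fraction: float, params: ParameterSet
) -> tuple[float, float]:
    """Per-cycle (drug, management) cost for the persistent fraction.

    Management covers nurse visits, physician visits and DXA scans at annual
    frequencies; both components are zero during a holiday and for
    no-treatment (persistent fraction 0).
    """
    if not 0.0 <= persistent_fraction <= 1.0:
        raise ValueError("persistent_fraction must be in [0,1]")
    uc = params.costs.unit_costs
    half = params.config.cycle_length
    drug = persistent_fraction * half * strategy.annual_drug_cost
    mgmt = persistent_fraction * half * (
        strategy.nurse_visits_per_year * uc["nurse_visit"]
        + strategy.physician_visits_per_year * uc["physician_visit"]
        + strategy.dxa_scans_per_year * uc["dxa"]
    )
    return drug, mgmt


def state_multiplier_matrix(params: ParameterSet, n_tunnel: int) -> np.ndarray:
    """Utility multipliers by (vf flag, state, time-in-state)."""
    m1 = params.utilities.multiplier_year1
    m2 = params.utilities.multiplier_year2plus
    mult = np.ones((3, 7, n_tunnel))
    mult[:, HIP_FX, 0] = m1["hip"]
    mult[:, POST_HIP, 0] = m1["hip"]
    mult[:, POST_HIP, 1:] = m2["hip"]
    mult[:, VERT_FX, 0] = m1["vertebral"]
    mult[:, POST_VERT, 0] = m1["vertebral"]
    mult[:, POST_VERT, 1:] = m2["vertebral"]
    mult[:, WRIST_FX, 0:2] = m1["wrist"]
    mult[:, OTHER_FX, 0:2] = m1["other"]
    # incident vertebral history blends the vertebral year-2+ multiplier into
    # the hip states for life
    mult[VF_INCIDENT, HIP_FX, :] *= m2["vertebral"]
    mult[VF_INCIDENT, POST_HIP, :] *= m2["vertebral"]
    return mult


def state_cost_matrix(params: ParameterSet, age: float, n_tunnel: int) -> np.ndarray:
    """Per-cycle fracture treatment cost by (state, time-in-state)."""
    band = params.cost_band(age)
    y1 = {s: params.costs.fracture_year1[s][band] for s in SITES}
    y2 = {s: params.costs.fracture_year2plus[s][band] for s in ("hip", "vertebral")}
    c = np.zeros((7, n_tunnel))
    c[HIP_FX, 0] = y1["hip"] / 2
    c[POST_HIP, 0] = y1["hip"] / 2
    c[POST_HIP, 1:] = y2["hip"] / 2
    c[VERT_FX, 0] = y1["vertebral"] / 2
    c[POST_VERT, 0] = y1["vertebral"] / 2
    c[POST_VERT, 1:] = y2["vertebral"] / 2
    c[WRIST_FX, 0:2] = y1["wrist"] / 2
    c[OTHER_FX, 0:2] = y1["other"] / 2
    return c


_STATE_SITE = {HIP_FX: "hip", POST_HIP: "hip", VERT_FX: "vertebral",
               POST_VERT: "vertebral", WRIST_FX: "wrist", OTHER_FX: "other"}


def ltc_cost_accrual(hip_events: float, params: ParameterSet) -> float:
    """Expected nursing-home cost for newly sustained hip fractures,
    delivered as a one-time expected cost at hip-fracture entry."""
    if hip_events < 0:
        raise ValueError("hip_events must be >= 0")
    c = params.costs
    return hip_events * c.ltc_admission_prob_after_hip * c.ltc_mean_stay_days * c.ltc_per_day


def downstream_disutility(
    higher_state_utility: float, lower_site: str, events: float, params: ParameterSet
) -> float:
    """One-year QALY decrement for downstream fractures.

    The lower-hierarchy utility is the higher-state utility times the lower
    site's year-1 multiplier; the decrement is the difference, applied over
    one year per event.
    """
    mult = params.utilities.multiplier_year1[lower_site]
    return events * higher_state_utility * (1.0 - mult)


@dataclass
class StrategyOutcome:
    """Discounted lifetime totals for one strategy."""

    strategy: str
    total_cost: float
    cost_by_category: Dict[str, float]
    events: Dict[str, float]
    life_years: float
    qalys: float
    ledger: pd.DataFrame = field(default_factory=pd.DataFrame, repr=False)


def accrue(trace: CohortTrace, params: ParameterSet) -> StrategyOutcome:
    """Accrue discounted costs, life-years and QALYs over a trace."""
    cfg = params.config
    strategy = trace.strategy
    n_tunnel = trace.records[0].occ.shape[-1] if trace.records else 3
    mult = state_multiplier_matrix(params, n_tunnel)

    rows = []
    cost_cat = {c: 0.0 for c in COST_CATEGORIES}
    ly = qaly = 0.0
    for rec in trace.records:
        df = discount_factor(cfg.discount_rate_annual, rec.cycle, cfg.cycle_length)
        u_base = params.baseline_utility(rec.age)

        drug, mgmt = cycle_drug_and_monitoring_cost(strategy, rec.on_mass, params)
        cost_sq = state_cost_matrix(params, rec.age, n_tunnel)
        state_costs = rec.occ.sum(axis=0) * cost_sq  # (state, t)
        site_cost = {s: 0.0 for s in SITES}
        for st, site in _STATE_SITE.items():
            site_cost[site] += float(state_costs[st].sum())
        # downstream fractures: full year-1 cost in the cycle they occur
        band = params.cost_band(rec.age)
        for i, site in enumerate(SITES):
            site_cost[site] += float(
                rec.downstream_by_site[i] * params.costs.fracture_year1[site][band]
            )
        site_cost["hip"] += ltc_cost_accrual(float(rec.events[0]), params)

        q_cycle = float((rec.occ * mult).sum()) * u_base * cfg.cycle_length
        for g, label in enumerate(DOWNSTREAM_GROUPS):
            hsite, year = _GROUP_MULT[label]
            m_h = (params.utilities.multiplier_year1[hsite] if year == 1
                   else params.utilities.multiplier_year2plus[hsite])
            u_h = u_base * m_h
            for i, site in enumerate(SITES):
                ev = float(rec.downstream[g, i])
                if ev:
                    q_cycle -= downstream_disutility(u_h, site, ev, params)

        l_cycle = rec.alive * cfg.cycle_length
        for s in SITES:
            cost_cat[s] += df * site_cost[s]
        cost_cat["drug"] += df * drug
        cost_cat["management"] += df * mgmt
        ly += df * l_cycle
        qaly += df * q_cycle
        rows.append(
            {"cycle": rec.cycle, "age": rec.age, "discount": df,
             **{f"cost_{s}": site_cost[s] for s in SITES},
             "cost_drug": drug, "cost_management": mgmt,
             "life_years": l_cycle, "qalys": q_cycle}
        )

    return StrategyOutcome(
        strategy=strategy.name,
        total_cost=float(sum(cost_cat.values())),
        cost_by_category=cost_cat,
        events=trace.cumulative_events(),
        life_years=float(ly),
        qalys=float(qaly),
        ledger=pd.DataFrame(rows),
    )
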