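"""Result surfaces: base-case table, scenario grid, one-way sensitivity, PSA.

``evaluate`` runs the cohort engine plus economic accrual for one strategy and
is deterministic given the parameters.  ``icer`` classifies a pairwise
comparison (incremental cost per QALY gained, or dominance).  ``scenario_grid``
varies the oral-bisphosphonate on-treatment and drug-holiday durations while
keeping the denosumab regimen constant.  ``owsa`` re-evaluates the comparison
under one-at-a-time input changes.  ``psa`` samples all uncertain inputs
jointly — relative risks lognormal, proportions and utilities beta, fracture
costs normal, with standard errors defaulting to 10% of the point estimate —
using common random numbers across strategies within each draw, and summarises
cost-effectiveness acceptability curves over a willingness-to-pay grid.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import strategies as strat
from .economics import StrategyOutcome, accrue
from .engine import run_trace
from .params import ParameterSet, TreatmentStrategy, apply_override
from .states import SITES

DEFAULT_THRESHOLDS = np.arange(0, 300_001, 5_000, dtype=float)


def evaluate(strategy: TreatmentStrategy, params: ParameterSet) -> StrategyOutcome:
    """Discounted lifetime costs, events, LYs and QALYs for one strategy."""
    return accrue(run_trace(strategy, params), params)


@dataclass
class ICERResult:
    """Pairwise incremental comparison (intervention vs comparator)."""

    delta_cost: float
    delta_qaly: float
    icer: Optional[float]
    classification: str  # "icer" | "dominant" | "dominated" | "indifferent"

    @property
    def label(self) -> str:
        if self.classification == "dominant":
            return "dominant"
        if self.classification == "dominated":
            return "dominated"
        if self.classification == "indifferent":
            return "indifferent"
        return f"{self.icer:,.0f}"


def icer(intervention: StrategyOutcome, comparator: StrategyOutcome,
         tol: float = 1e-12) -> ICERResult:
    """Incremental cost-effectiveness ratio or dominance classification.

    Dominant: cheaper and more effective.  Dominated: costlier and less
    effective.  A zero QALY difference is classified by cost alone, never
    divided through.
    """
    dc = intervention.total_cost - comparator.total_cost
    dq = intervention.qalys - comparator.qalys
    if abs(dq) <= tol:
        if abs(dc) <= tol:
            return ICERResult(dc, dq, None, "indifferent")
        return ICERResult(dc, dq, None, "dominated" if dc > 0 else "dominant")
    if dq > 0 and dc <= 0:
        return ICERResult(dc, dq, None, "dominant")
    if dq < 0 and dc >= 0:
        return ICERResult(dc, dq, None, "dominated")
    return ICERResult(dc, dq, dc / dq, "icer")


def base_case_table(params: ParameterSet,
                    strategy_list: Optional[Sequence[TreatmentStrategy]] = None
                    ) -> pd.DataFrame:
    """Cost-effectiveness table: totals per strategy plus incrementals of the
    first strategy vs each other one."""
    if strategy_list is None:
        strategy_list = strat.base_case_strategies()
    outcomes = [evaluate(s, params) for s in strategy_list]
    rows = []
    for oc in outcomes:
        rows.append({
            "strategy": oc.strategy,
            "total_cost": oc.total_cost,
            **{f"cost_{c}": v for c, v in oc.cost_by_category.items()},
            **{f"events_{s}": oc.events[s] for s in (*SITES, "any")},
            "life_years": oc.life_years,
            "qalys": oc.qalys,
        })
    df = pd.DataFrame(rows).set_index("strategy")
    ref = outcomes[0]
    for oc in outcomes[1:]:
        res = icer(ref, oc)
        df.loc[oc.strategy, "delta_cost_vs_first"] = res.delta_cost
        df.loc[oc.strategy, "delta_qaly_vs_first"] = res.delta_qaly
        df.loc[oc.strategy, "icer_vs_first"] = res.label
    return df


def scenario_grid(
    params: ParameterSet,
    on_durations: Sequence[float] = (3.0, 4.0, 5.0),
    holiday_durations: Sequence[float] = (1.0, 2.0, 3.0),
    total_window: float = 10.0,
    include_5v5: bool = True,
) -> pd.DataFrame:
    """ICER of 10-year denosumab vs oral-bisphosphonate regimen variants.

    Each variant spends ``on`` years on drug, takes a holiday, then resumes to
    fill the treatment window.  The special 5-vs-5 case caps both arms at five
    years with no holiday.
    """
    den = evaluate(strat.denosumab(), params)
    rows = []
    for on in on_durations:
        for hol in holiday_durations:
            resume = max(total_window - on - hol, 0.0)
            alen = strat.alendronate(on, hol, resume)
            res = icer(den, evaluate(alen, params))
            rows.append({"on_years": on, "holiday_years": hol, "resume_years": resume,
                         "delta_cost": res.delta_cost, "delta_qaly": res.delta_qaly,
                         "icer": res.icer, "classification": res.classification})
    if include_5v5:
        den5 = evaluate(strat.denosumab(years=5.0), params)
        res = icer(den5, evaluate(strat.alendronate(5.0, 0.0, 0.0), params))
        rows.append({"on_years": 5.0, "holiday_years": 0.0, "resume_years": 0.0,
                     "delta_cost": res.delta_cost, "delta_qaly": res.delta_qaly,
                     "icer": res.icer, "classification": res.classification,
                     "note": "both arms capped at 5 years"})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# one-way sensitivity analysis
# ---------------------------------------------------------------------------

@dataclass
class OWSAVariant:
    """A single one-way change: parameter overrides and/or strategy changes."""

    label: str
    overrides: Dict[str, object] = field(default_factory=dict)
    strategy_factory: Optional[Callable[[], List[TreatmentStrategy]]] = None


def default_owsa_variants() -> List[OWSAVariant]:
    """One-at-a-time input variations of the key drivers."""
    v: List[OWSAVariant] = [OWSAVariant("base_case")]
    for age in (50, 65, 80):
        v.append(OWSAVariant(f"start_age_{age}", {"config.start_age": float(age)}))
    for p in (0.0, 1.0):
        v.append(OWSAVariant(f"prevalent_vf_{p:g}", {"config.prevalent_vf_fraction": p}))
    for t in (-2.8, -3.0):
        v.append(OWSAVariant(f"t_score_{t}", {"config.t_score": t}))
    for h in (10.0, 15.0, 20.0):
        v.append(OWSAVariant(f"horizon_{h:g}y", {"config.horizon_years": h}))
    v.append(OWSAVariant(
        "max_treatment_5y",
        strategy_factory=lambda: [strat.denosumab(5.0), strat.no_treatment(),
                                  strat.alendronate(5.0, 0.0, 0.0)]))
    for off in (0.0, 2.0):
        v.append(OWSAVariant(
            f"denosumab_offset_{off:g}y",
            strategy_factory=(lambda o=off: [strat.denosumab(max_offset_years=o),
                                             strat.no_treatment(), strat.alendronate()])))
    for off in (1.0, 3.0, 5.0):
        v.append(OWSAVariant(
            f"alendronate_offset_{off:g}y",
            strategy_factory=(lambda o=off: [strat.denosumab(), strat.no_treatment(),
                                             strat.alendronate(max_offset_years=o)])))
    for method in ("last_interval_rate", "overall_rate"):
        v.append(OWSAVariant(
            f"persistence_extrapolation_{method}",
            {"persistence.denosumab.extrapolation": method,
             "persistence.alendronate.extrapolation": method}))
    full = {m: 1.0 for m in (0, 6, 12, 18, 24, 30, 36)}
    v.append(OWSAVariant(
        "persistence_100pct",
        {"persistence.denosumab.observed": full,
         "persistence.alendronate.observed": dict(full)}))
    for r in (0.0, 0.05):
        v.append(OWSAVariant(f"discount_{r:g}", {"config.discount_rate_annual": r}))
    for a in (0.0, 0.18, 0.42, 1.0):
        v.append(OWSAVariant(f"excess_mortality_attribution_{a:g}",
                             {"config.excess_mortality_attribution": a}))
    for w in (3.0, 5.0, 10.0, None):
        label = "lifetime" if w is None else f"{w:g}y"
        v.append(OWSAVariant(f"mortality_window_{label}",
                             {"config.excess_mortality_years": w}))
    return v


def owsa(variants: Sequence[OWSAVariant], params: ParameterSet) -> pd.DataFrame:
    """ICER of denosumab vs no treatment and vs alendronate per variant."""
    rows = []
    for var in variants:
        p = params
        for path, value in var.overrides.items():
            p = apply_override(p, path, value)
        strategy_list = (var.strategy_factory() if var.strategy_factory
                         else strat.base_case_strategies())
        den, notx, alen = (evaluate(s, p) for s in strategy_list)
        vs_notx = icer(den, notx)
        vs_alen = icer(den, alen)
        rows.append({
            "variant": var.label,
            "icer_vs_no_treatment": vs_notx.label,
            "icer_vs_alendronate": vs_alen.label,
            "icer_vs_no_treatment_value": vs_notx.icer,
            "icer_vs_alendronate_value": vs_alen.icer,
            "delta_cost_vs_alendronate": vs_alen.delta_cost,
            "delta_qaly_vs_alendronate": vs_alen.delta_qaly,
        })
    return pd.DataFrame(rows).set_index("variant")


# ---------------------------------------------------------------------------
# probabilistic sensitivity analysis
# ---------------------------------------------------------------------------

def _lognormal(rng: np.random.Generator, mean: float, se: float) -> float:
    """Lognormal draw moment-matched so the distribution mean equals the
    point estimate."""
    if se <= 0:
        return mean
    sigma2 = math.log(1.0 + (se / mean) ** 2)
    mu = math.log(mean) - sigma2 / 2
    return float(rng.lognormal(mu, math.sqrt(sigma2)))


def _beta(rng: np.random.Generator, mean: float, se: float) -> float:
    """Beta draw moment-matched by mean/SE; variance clipped to the feasible
    range for means near 0 or 1."""
    if se <= 0 or mean <= 0 or mean >= 1:
        return mean
    var = min(se**2, 0.99 * mean * (1 - mean))
    nu = mean * (1 - mean) / var - 1.0
    a, b = mean * nu, (1 - mean) * nu
    return float(rng.beta(a, b))


def _normal_nonneg(rng: np.random.Generator, mean: float, se: float) -> float:
    if se <= 0:
        return mean
    return float(max(rng.normal(mean, se), 0.0))


def sample_parameters(
    params: ParameterSet, rng: np.random.Generator, se_fraction: float = 0.10
) -> ParameterSet:
    """One joint draw of the uncertain inputs.

    Treatment-efficacy RRs are lognormal; persistence proportions, the
    long-term-care admission probability and utilities are beta; fracture
    costs are normal truncated at zero.  Standard errors default to
    ``se_fraction`` of the point estimate.  Sampled persistence curves are
    forced nonincreasing by a running minimum.
    """
    p = params.copy()
    for profile in p.efficacy.values():
        for site in SITES:
            for m, v in profile.rr[site].items():
                profile.rr[site][m] = min(_lognormal(rng, v, se_fraction * v), 1.5)
    for curve in p.persistence.values():
        running = 1.0
        for m in sorted(curve.observed):
            if m == 0:
                continue
            v = _beta(rng, curve.observed[m], se_fraction * curve.observed[m])
            running = min(running, v)
            curve.observed[m] = running
    c = p.costs
    c.ltc_admission_prob_after_hip = _beta(
        rng, c.ltc_admission_prob_after_hip, se_fraction * c.ltc_admission_prob_after_hip
    )
    for site in SITES:
        for band in c.fracture_year1[site]:
            v = c.fracture_year1[site][band]
            c.fracture_year1[site][band] = _normal_nonneg(rng, v, se_fraction * v)
    for site in c.fracture_year2plus:
        for band in c.fracture_year2plus[site]:
            v = c.fracture_year2plus[site][band]
            c.fracture_year2plus[site][band] = min(
                _normal_nonneg(rng, v, se_fraction * v),
                c.fracture_year1[site][band],
            )
    u = p.utilities
    for age in u.baseline_by_age:
        v = u.baseline_by_age[age]
        u.baseline_by_age[age] = _beta(rng, v, se_fraction * v)
    for site in u.multiplier_year1:
        v = u.multiplier_year1[site]
        u.multiplier_year1[site] = _beta(rng, v, se_fraction * v)
    for site in u.multiplier_year2plus:
        v = u.multiplier_year2plus[site]
        u.multiplier_year2plus[site] = _beta(rng, v, se_fraction * v)
    return p.validate()


@dataclass
class PSAResult:
    """Probabilistic sensitivity analysis output."""

    draws: pd.DataFrame           # one row per draw x strategy
    thresholds: np.ndarray
    ceac: pd.DataFrame            # P(cost-effective) per threshold, per comparison
    seed: Optional[int]
    n: int

    def prob_cost_effective(self, comparison: str, threshold: float) -> float:
        i = int(np.argmin(np.abs(self.thresholds - threshold)))
        return float(self.ceac[comparison].iloc[i])


def psa(
    params: ParameterSet,
    n: int = 1000,
    seed: Optional[int] = None,
    thresholds: np.ndarray = DEFAULT_THRESHOLDS,
    se_fraction: float = 0.10,
    strategy_list: Optional[Sequence[TreatmentStrategy]] = None,
) -> PSAResult:
    """Joint probabilistic sensitivity analysis with CEAC summaries.

    All strategies are evaluated on the same parameter draw (common random
    numbers), so incremental comparisons are not inflated by between-arm
    sampling noise.  The CEAC for strategy A vs B at threshold λ is the
    fraction of draws with ``λ·ΔQALY − Δcost >= 0``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if strategy_list is None:
        strategy_list = strat.base_case_strategies()
    rng = np.random.default_rng(seed)
    rows = []
    for draw in range(n):
        p = sample_parameters(params, rng, se_fraction)
        for s in strategy_list:
            oc = evaluate(s, p)
            rows.append({"draw": draw, "strategy": oc.strategy,
                         "cost": oc.total_cost, "qaly": oc.qalys})
    draws = pd.DataFrame(rows)
    wide_c = draws.pivot(index="draw", columns="strategy", values="cost")
    wide_q = draws.pivot(index="draw", columns="strategy", values="qaly")
    ref = strategy_list[0].name
    ceac_cols = {}
    for s in strategy_list[1:]:
        dc = wide_c[ref] - wide_c[s.name]
        dq = wide_q[ref] - wide_q[s.name]
        nmb = thresholds[None, :] * dq.values[:, None] - dc.values[:, None]
        ceac_cols[f"{ref}_vs_{s.name}"] = (nmb >= 0).mean(axis=0)
    ceac = pd.DataFrame(ceac_cols, index=thresholds)
    ceac.index.name = "threshold"
    return PSAResult(draws=draws, thresholds=np.asarray(thresholds, float),
                     ceac=ceac, seed=seed, n=n)
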