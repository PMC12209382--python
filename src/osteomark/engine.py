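"""Deterministic Markov cohort engine.

The cohort is advanced in 6-month cycles over an occupancy array indexed by

    (persistence stratum, vertebral-fracture flag, health state, time in state)

Within each cycle, in order: (1) persistence strata are rebalanced (newly
discontinued mass moves into an offset slot; fully-offset slots merge into the
untreated stratum); (2) all-cause death is applied, with post-fracture excess
mortality inside the configured window; (3) survivors transition according to
the site-specific fracture probabilities, resolved by the severity hierarchy
(hip > vertebral > wrist > other) — the most severe fracture occurring in a
cycle routes the patient to that acute state, a same-site re-fracture resets
the acute clock, and lower-hierarchy fractures sustained in hip/vertebral
states do not change state but are counted separately as downstream events
feeding cost and disutility accrual.

Time in the post-hip / post-vertebral states is tracked with half-year tunnel
compartments so the excess-mortality window (base case: 8 years after the
event) has the memory a plain 8-state chain lacks.  Excess mortality after a
wrist fracture is not modelled (no published relative risk); after an "other"
fracture it is applied during the two acute cycles only, because those
patients return to the well state and their fracture history is not retained —
a structural simplification shared with the hierarchy itself.

Patients whose vertebral fracture occurred during the simulation (as opposed
to a prevalent fracture at entry) carry a flag; in the hip-fracture and
post-hip states that flag adds the vertebral excess mortality (within the
mortality window) and the year-2+ vertebral utility multiplier (lifetime),
which is the joint-distribution form of the published aggregate weighting —
see :func:`prior_vf_weight` for the aggregate quotient itself.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional

import numpy as np
import pandas as pd

from .params import ParameterSet, TreatmentStrategy
from .risk import bmd_rr as _bmd_rr
from .risk import prior_fx_rr as _prior_fx_rr
from .schedule import ExposureSchedule, build_schedule
from .states import (
    SITES,
    HealthState,
    N_ALIVE_STATES,
    N_VF_FLAGS,
    VF_INCIDENT,
    VF_NONE,
    VF_PREVALENT,
)

WELL = HealthState.WELL
HIP_FX = HealthState.HIP_FX
VERT_FX = HealthState.VERT_FX
WRIST_FX = HealthState.WRIST_FX
OTHER_FX = HealthState.OTHER_FX
POST_HIP = HealthState.POST_HIP
POST_VERT = HealthState.POST_VERT

#: downstream accrual groups: (label, states involved, lower-hierarchy sites)
DOWNSTREAM_GROUPS = ("hip_y1", "hip_y2", "vert_y1", "vert_y2")
_DOWNSTREAM_SITES = {
    "hip_y1": (1, 2, 3),
    "hip_y2": (1, 2, 3),
    "vert_y1": (2, 3),
    "vert_y2": (2, 3),
}

_MASS_TOL = 1e-10


@dataclass
class CycleRecord:
    """State of the cohort during one cycle."""

    cycle: int
    age: float
    #: occupancy (vf flag, state, time-in-state) during the cycle, strata summed
    occ: np.ndarray
    #: alive mass on treatment (drug + monitoring cost applies)
    on_mass: float
    #: new routed fractures entering acute states this cycle, per site
    events: np.ndarray
    #: downstream (unrouted lower-hierarchy) events, per group x site
    downstream: np.ndarray
    alive: float
    deaths_cum: float

    @property
    def downstream_by_site(self) -> np.ndarray:
        return self.downstream.sum(axis=0)


@dataclass
class CohortTrace:
    """Per-cycle occupancy, events and accounting masses for one strategy."""

    strategy: TreatmentStrategy
    params: ParameterSet
    initial_occ: np.ndarray
    records: List[CycleRecord] = field(default_factory=list)

    @property
    def n_cycles(self) -> int:
        return len(self.records)

    def cumulative_events(self) -> Dict[str, float]:
        """Lifetime fracture events per patient by site (routed + downstream)."""
        totals = np.zeros(len(SITES))
        for rec in self.records:
            totals += rec.events + rec.downstream_by_site
        out = {site: float(totals[i]) for i, site in enumerate(SITES)}
        out["any"] = float(totals.sum())
        return out

    def incident_vf_proportion(self, cycle: int) -> float:
        """Proportion of the initial cohort with a simulation-incident
        vertebral fracture, alive or dead-after-event excluded (alive mass)."""
        rec = self.records[cycle]
        return float(rec.occ[VF_INCIDENT].sum())

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for rec in self.records:
            row = {
                "cycle": rec.cycle,
                "age": rec.age,
                "alive": rec.alive,
                "deaths_cum": rec.deaths_cum,
                "on_treatment": rec.on_mass,
            }
            for st in HealthState:
                if st == HealthState.DEAD:
                    continue
                row[f"state_{st.name.lower()}"] = float(rec.occ[:, st, :].sum())
            for i, site in enumerate(SITES):
                row[f"events_{site}"] = float(rec.events[i])
                row[f"downstream_{site}"] = float(rec.downstream_by_site[i])
            rows.append(row)
        return pd.DataFrame(rows)


def prior_vf_weight(incremental_vf_prop: float, baseline_no_vf_prop: float) -> float:
    """Aggregate weighting for vertebral-fracture consequences in hip states.

    The incremental proportion of patients with a vertebral fracture over the
    considered window, divided by the proportion without a prior vertebral
    fracture at the window's start; used to blend the vertebral excess into
    the post-hip mortality (and lifetime utility) when the joint distribution
    is not tracked.
    """
    if baseline_no_vf_prop <= 0:
        raise ZeroDivisionError("baseline proportion without vertebral fracture must be > 0")
    return incremental_vf_prop / baseline_no_vf_prop


def excess_mortality_window_cycles(params: ParameterSet) -> int:
    """Number of cycles (including the acute cycle) with excess mortality."""
    years = params.config.excess_mortality_years
    if years is None:
        return params.config.n_cycles + 1
    return int(round(years / params.config.cycle_length))


def _state_mortality_rr(params: ParameterSet, age: float, n_tunnel: int) -> np.ndarray:
    """Mortality RR by (vf flag, state, time-in-state) for one cycle."""
    rr = np.ones((N_VF_FLAGS, N_ALIVE_STATES, n_tunnel))
    win = excess_mortality_window_cycles(params)
    rr_hip = params.mortality_rr("hip", age)
    rr_vert = params.mortality_rr("vertebral", age)
    rr_other = params.mortality_rr("other", age)
    if win >= 1:
        rr[:, HIP_FX, 0] = rr_hip
        rr[:, VERT_FX, 0] = rr_vert
        rr[:, OTHER_FX, 0:1] = rr_other
    if win >= 2:
        rr[:, OTHER_FX, 1:2] = rr_other
    # post states: cycles since fracture = t + 1; excess while t <= win - 2
    t_max = min(win - 1, n_tunnel)
    if t_max > 0:
        rr[:, POST_HIP, 0:t_max] = rr_hip
        rr[:, POST_VERT, 0:t_max] = rr_vert
    # incident vertebral fracture adds its excess in the hip states
    # (additive stacking of excess risks)
    extra = rr_vert - 1.0
    if win >= 1:
        rr[VF_INCIDENT, HIP_FX, 0] += extra
    if t_max > 0:
        rr[VF_INCIDENT, POST_HIP, 0:t_max] += extra
    return rr


def death_prob(
    age: float,
    state: HealthState,
    cycles_since_fx: int,
    weighted_vf_rr: float,
    params: ParameterSet,
) -> float:
    """Per-cycle death probability for a compartment.

    ``q_cycle = 1 - (1 - q_annual)^0.5``; within the excess-mortality window
    after a hip/vertebral/other fracture, ``q = q_cycle * (1 + a*(RR - 1))``
    where ``a`` is the attribution share (base 30%).  ``weighted_vf_rr`` is an
    additional RR (>= 1) blended in for the hip states when the vertebral
    history weighting applies; pass 1.0 for none.
    """
    q_annual = params.q_annual(age)
    q_cycle = 1.0 - (1.0 - q_annual) ** params.config.cycle_length
    win = excess_mortality_window_cycles(params)
    rr = 1.0
    if state in (HIP_FX, POST_HIP) and cycles_since_fx < win:
        rr = params.mortality_rr("hip", age) + (weighted_vf_rr - 1.0)
    elif state in (VERT_FX, POST_VERT) and cycles_since_fx < win:
        rr = params.mortality_rr("vertebral", age)
    elif state == OTHER_FX and cycles_since_fx < min(win, 2):
        rr = params.mortality_rr("other", age)
    a = params.config.excess_mortality_attribution
    return float(np.clip(q_cycle * (1.0 + a * (rr - 1.0)), 0.0, 1.0))


def _disease_rr_matrix(params: ParameterSet, age: float) -> np.ndarray:
    """Disease RR by (vf flag, state, site): BMD gradient for fracture-naive
    compartments, adjusted prior-fracture RR otherwise."""
    cfg = params.config
    rrs = params.relative_risks
    bmd = np.array(
        [_bmd_rr(s, age, cfg.t_score, rrs, cfg.hip_gradient, cfg.age_interpolation) for s in SITES]
    )
    prior = np.array(
        [_prior_fx_rr(s, age, rrs, cfg.prior_fx_adjusted, cfg.age_interpolation) for s in SITES]
    )
    disease = np.empty((N_VF_FLAGS, N_ALIVE_STATES, len(SITES)))
    disease[:] = prior
    disease[VF_NONE, WELL, :] = bmd
    return disease


def cycle_probs(
    params: ParameterSet, age: float, rr_mult: np.ndarray
) -> np.ndarray:
    """Fracture probabilities (stratum, vf flag, state, site) for one cycle."""
    gen = np.array([params.incidence_rate(s, age) for s in SITES])
    disease = _disease_rr_matrix(params, age)
    rate = gen[None, None, :] * disease  # (F, states, sites)
    rate = rate[None, :, :, :] * rr_mult[:, None, None, :]
    return 1.0 - np.exp(-rate * params.config.cycle_length)


def n_tunnel_compartments(params: ParameterSet) -> int:
    win = excess_mortality_window_cycles(params)
    return max(3, min(win, params.config.n_cycles + 1))


def initial_occupancy(params: ParameterSet, n_strata: int, n_tunnel: int) -> np.ndarray:
    occ = np.zeros((n_strata, N_VF_FLAGS, N_ALIVE_STATES, n_tunnel))
    pvf = params.config.prevalent_vf_fraction
    occ[1, VF_NONE, WELL, 0] = 1.0 - pvf
    occ[1, VF_PREVALENT, WELL, 0] = pvf
    return occ


def step(
    occ: np.ndarray,
    q: np.ndarray,
    p: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Advance one cycle: death, fracture routing by hierarchy, clock advance.

    ``occ``: (strata, vf, state, t); ``q``: (vf, state, t) death probability;
    ``p``: (strata, vf, state, site) fracture probabilities.  Returns the new
    occupancy, routed fracture events per site, and deaths this cycle.
    """
    n_strata, n_vf, n_states, n_t = occ.shape
    new = np.zeros_like(occ)
    events = np.zeros(len(SITES))
    deaths = float((occ * q[None]).sum())
    surv = occ * (1.0 - q)[None]

    last_t = n_t - 1
    for s in range(n_strata):
        v = surv[s]
        ph = p[s, :, :, 0]
        pv = p[s, :, :, 1]
        pw = p[s, :, :, 2]
        po = p[s, :, :, 3]

        # -- states routing like "well": well, acute wrist, acute other ----
        for st in (WELL, WRIST_FX, OTHER_FX):
            mass = v[:, st, :]  # (vf, t)
            if not mass.any():
                continue
            hip_in = mass * ph[:, st, None]
            rem = mass - hip_in
            vert_in = rem * pv[:, st, None]
            rem = rem - vert_in
            wrist_in = rem * pw[:, st, None]
            rem = rem - wrist_in
            other_in = rem * po[:, st, None]
            rem = rem - other_in

            new[s, :, HIP_FX, 0] += hip_in.sum(axis=1)
            new[s, VF_INCIDENT, VERT_FX, 0] += vert_in.sum()  # flag promotes
            new[s, :, WRIST_FX, 0] += wrist_in.sum(axis=1)
            new[s, :, OTHER_FX, 0] += other_in.sum(axis=1)
            events[0] += hip_in.sum()
            events[1] += vert_in.sum()
            events[2] += wrist_in.sum()
            events[3] += other_in.sum()
            if st == WELL:
                new[s, :, WELL, 0] += rem.sum(axis=1)
            else:
                # acute wrist/other: t0 -> t1 (second half of year 1), t1 -> well
                new[s, :, st, 1] += rem[:, 0]
                new[s, :, WELL, 0] += rem[:, 1:].sum(axis=1)

        # -- acute hip: re-fracture stays, otherwise to post-hip -----------
        mass = v[:, HIP_FX, 0]
        hip_re = mass * ph[:, HIP_FX]
        new[s, :, HIP_FX, 0] += hip_re
        new[s, :, POST_HIP, 0] += mass - hip_re
        events[0] += hip_re.sum()

        # -- acute vertebral: hip routes up, re-fracture stays, else post --
        mass = v[:, VERT_FX, 0]
        hip_in = mass * ph[:, VERT_FX]
        rem = mass - hip_in
        vert_re = rem * pv[:, VERT_FX]
        new[s, :, HIP_FX, 0] += hip_in
        new[s, :, VERT_FX, 0] += vert_re
        new[s, :, POST_VERT, 0] += rem - vert_re
        events[0] += hip_in.sum()
        events[1] += vert_re.sum()

        # -- post-hip: hip re-fracture routes, otherwise tunnel advances ---
        mass = v[:, POST_HIP, :]
        hip_in = mass * ph[:, POST_HIP, None]
        rem = mass - hip_in
        new[s, :, HIP_FX, 0] += hip_in.sum(axis=1)
        new[s, :, POST_HIP, 1:] += rem[:, :-1]
        new[s, :, POST_HIP, last_t] += rem[:, last_t]
        events[0] += hip_in.sum()

        # -- post-vertebral: hip or vertebral routes, else tunnel advances -
        mass = v[:, POST_VERT, :]
        hip_in = mass * ph[:, POST_VERT, None]
        rem = mass - hip_in
        vert_in = rem * pv[:, POST_VERT, None]
        rem = rem - vert_in
        new[s, :, HIP_FX, 0] += hip_in.sum(axis=1)
        new[s, :, VERT_FX, 0] += vert_in.sum(axis=1)
        new[s, :, POST_VERT, 1:] += rem[:, :-1]
        new[s, :, POST_VERT, last_t] += rem[:, last_t]
        events[0] += hip_in.sum()
        events[1] += vert_in.sum()

    assert new.min() > -1e-15, "negative occupancy"
    return new, events, deaths


def downstream_fracture_events(occ: np.ndarray, p: np.ndarray) -> np.ndarray:
    """Downstream (unrouted lower-hierarchy) events by group x site.

    For mass occupying the hip / vertebral acute and post states, lower-
    hierarchy fractures do not change state; their expected counts — occupancy
    times the site's cycle probability — feed cost and disutility accrual.
    """
    out = np.zeros((len(DOWNSTREAM_GROUPS), len(SITES)))
    group_masses = {
        "hip_y1": occ[:, :, HIP_FX, 0].sum(axis=1) + occ[:, :, POST_HIP, 0].sum(axis=1),
        "hip_y2": occ[:, :, POST_HIP, 1:].sum(axis=(1, 2)),
        "vert_y1": occ[:, :, VERT_FX, 0].sum(axis=1) + occ[:, :, POST_VERT, 0].sum(axis=1),
        "vert_y2": occ[:, :, POST_VERT, 1:].sum(axis=(1, 2)),
    }
    group_states = {
        "hip_y1": (HIP_FX, POST_HIP),
        "hip_y2": (POST_HIP, POST_HIP),
        "vert_y1": (VERT_FX, POST_VERT),
        "vert_y2": (POST_VERT, POST_VERT),
    }
    for g, label in enumerate(DOWNSTREAM_GROUPS):
        state = group_states[label][0]
        # probabilities are flag-independent in fracture-history states; use
        # the prior-fracture row (vf flag 2)
        for i in _DOWNSTREAM_SITES[label]:
            out[g, i] = float((group_masses[label] * p[:, VF_INCIDENT, state, i]).sum())
    return out


def _rebalance_strata(occ: np.ndarray, phi: float) -> np.ndarray:
    """Age the discontinuation slots and move newly discontinued mass out of
    the current stratum.  Slot 2+j holds mass that discontinued j cycles ago;
    the oldest slot merges into the untreated stratum (index 0)."""
    n_strata = occ.shape[0]
    out = np.zeros_like(occ)
    out[0] = occ[0]
    if n_strata > 2:
        out[0] += occ[n_strata - 1]
        out[3:] = occ[2:-1]
    flow = occ[1] * phi
    out[1] = occ[1] - flow
    if n_strata > 2:
        out[2] = flow
    else:
        out[0] += flow
    return out


def run_trace(
    strategy: TreatmentStrategy,
    params: ParameterSet,
    schedule: Optional[ExposureSchedule] = None,
) -> CohortTrace:
    """Run the cohort to the horizon and return the full trace."""
    strategy.validate(params.config.cycle_length)
    n_cycles = params.config.n_cycles
    if schedule is None:
        schedule = build_schedule(strategy, params, n_cycles)
    n_tunnel = n_tunnel_compartments(params)
    occ = initial_occupancy(params, schedule.n_strata, n_tunnel)
    trace = CohortTrace(strategy, params, occ.sum(axis=0).copy())

    deaths_cum = 0.0
    pending_events = np.zeros(len(SITES))
    cfg = params.config
    for k in range(n_cycles):
        age = cfg.start_age + k * cfg.cycle_length
        occ = _rebalance_strata(occ, schedule.phi[k])
        p = cycle_probs(params, age, schedule.rr_mult[k])
        q = _death_prob_matrix(params, age, n_tunnel)
        downstream = downstream_fracture_events(occ, p)
        on_mass = float(occ[1].sum()) if schedule.is_on[k] else 0.0
        alive = float(occ.sum())
        trace.records.append(
            CycleRecord(
                cycle=k,
                age=age,
                occ=occ.sum(axis=0),
                on_mass=on_mass,
                events=pending_events,
                downstream=downstream,
                alive=alive,
                deaths_cum=deaths_cum,
            )
        )
        occ, pending_events, deaths = step(occ, q, p)
        deaths_cum += deaths
        total = occ.sum() + deaths_cum
        assert abs(total - 1.0) < _MASS_TOL, f"mass leak at cycle {k}: {total}"
    return trace


def _death_prob_matrix(params: ParameterSet, age: float, n_tunnel: int) -> np.ndarray:
    q_annual = params.q_annual(age)
    q_cycle = 1.0 - (1.0 - q_annual) ** params.config.cycle_length
    rr = _state_mortality_rr(params, age, n_tunnel)
    a = params.config.excess_mortality_attribution
    return np.clip(q_cycle * (1.0 + a * (rr - 1.0)), 0.0, 1.0)
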