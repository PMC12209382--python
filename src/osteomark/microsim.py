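"""Individual-level Monte Carlo simulator.

Implements the identical rules as the cohort engine — risk composition,
severity-hierarchy routing, persistence and offset dynamics, excess mortality,
cost/QALY accrual — by sampling one trajectory per individual instead of
propagating expectations.  It exists as an independent brute-force check of
the cohort bookkeeping: at large n its means converge to the cohort engine's
outputs within Monte-Carlo error.  It is vectorised over individuals, so a
run of a few hundred thousand women takes seconds.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional

import numpy as np

from .economics import state_cost_matrix, state_multiplier_matrix, discount_factor
from .engine import (
    HIP_FX,
    OTHER_FX,
    POST_HIP,
    POST_VERT,
    VERT_FX,
    WELL,
    WRIST_FX,
    _death_prob_matrix,
    _disease_rr_matrix,
    n_tunnel_compartments,
)
from .params import ParameterSet, TreatmentStrategy
from .schedule import build_schedule
from .states import SITES, VF_INCIDENT, VF_NONE, VF_PREVALENT


@dataclass
class MicrosimResult:
    n: int
    seed: Optional[int]
    mean: Dict[str, float]
    se: Dict[str, float]

    def agree_within(self, other: Dict[str, float], n_se: float = 3.0) -> Dict[str, bool]:
        """Whether each outcome matches a reference within n_se standard errors."""
        return {
            k: abs(self.mean[k] - other[k]) <= n_se * max(self.se[k], 1e-12)
            for k in self.mean
            if k in other
        }


def simulate(
    strategy: TreatmentStrategy,
    params: ParameterSet,
    n: int = 100_000,
    seed: Optional[int] = None,
) -> MicrosimResult:
    """Simulate n individual trajectories; return mean outcomes with SEs."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    cfg = params.config
    n_cycles = cfg.n_cycles
    n_tunnel = n_tunnel_compartments(params)
    sched = build_schedule(strategy, params, n_cycles)

    # rr[d, k, site]: treatment RR at cycle k for an individual who
    # discontinued at cycle d (row n_cycles = never discontinued): before d the
    # individual follows the current-stratum path, after d the offset decay of
    # the cohort that discontinued at d
    from .risk import residual_rr

    rr = np.ones((n_cycles + 1, max(n_cycles, 1), len(SITES)))
    profile = params.efficacy.get(strategy.drug) if strategy.drug else None
    for k in range(n_cycles):
        rr[:, k, :] = sched.rr_mult[k, 1, :]  # current-stratum path
    if profile is not None:
        cyc_months = 12.0 * cfg.cycle_length
        for d in range(n_cycles):
            if not sched.is_on[d]:
                continue
            m_disc = sched.months_on[d]
            for k in range(d, n_cycles):
                for i, site in enumerate(SITES):
                    rr[d, k, i] = residual_rr(
                        profile, site, m_disc, (k - d) * cyc_months, strategy.max_offset_years
                    )

    NEVER = n_cycles
    state = np.full(n, int(WELL), dtype=np.int16)
    tis = np.zeros(n, dtype=np.int16)
    vf = np.where(rng.random(n) < cfg.prevalent_vf_fraction, VF_PREVALENT, VF_NONE).astype(np.int16)
    alive = np.ones(n, dtype=bool)
    disc = np.full(n, NEVER, dtype=np.int32)

    cost = np.zeros(n)
    qaly = np.zeros(n)
    ly = np.zeros(n)
    events = np.zeros((n, len(SITES)), dtype=np.int32)

    mult = state_multiplier_matrix(params, n_tunnel)
    m1 = params.utilities.multiplier_year1
    m2 = params.utilities.multiplier_year2plus
    uc = params.costs
    ltc_lump = uc.ltc_admission_prob_after_hip * uc.ltc_mean_stay_days * uc.ltc_per_day

    gen_sites = np.empty(len(SITES))
    for k in range(n_cycles):
        age = cfg.start_age + k * cfg.cycle_length
        df = discount_factor(cfg.discount_rate_annual, k, cfg.cycle_length)
        u_base = params.baseline_utility(age)
        band = params.cost_band(age)

        # newly discontinued this cycle (proportional within the on stratum)
        if sched.phi[k] > 0:
            on_now = alive & (disc == NEVER)
            newly = on_now & (rng.random(n) < sched.phi[k])
            disc[newly] = k

        idx = np.nonzero(alive)[0]
        if idx.size == 0:
            break
        st_a = state[idx]
        tis_a = np.minimum(tis[idx], n_tunnel - 1)
        vf_a = vf[idx]

        # fracture probabilities per alive individual and site
        for i, site in enumerate(SITES):
            gen_sites[i] = params.incidence_rate(site, age)
        disease = _disease_rr_matrix(params, age)  # (vf, state, site)
        rr_ind = rr[disc[idx], k]  # (n_alive, sites)
        rate = gen_sites[None, :] * disease[vf_a, st_a, :] * rr_ind
        p = 1.0 - np.exp(-rate * cfg.cycle_length)

        # occupancy-based accrual (life-years, utility, fracture state costs)
        ly[idx] += df * cfg.cycle_length
        qaly[idx] += df * u_base * mult[vf_a, st_a, tis_a] * cfg.cycle_length
        cost_sq = state_cost_matrix(params, age, n_tunnel)
        cost[idx] += df * cost_sq[st_a, tis_a]
        on_mask = (disc[idx] == NEVER) & sched.is_on[k]
        if on_mask.any():
            half = cfg.cycle_length
            per_cycle = half * (
                strategy.annual_drug_cost
                + strategy.nurse_visits_per_year * uc.unit_costs["nurse_visit"]
                + strategy.physician_visits_per_year * uc.unit_costs["physician_visit"]
                + strategy.dxa_scans_per_year * uc.unit_costs["dxa"]
            )
            cost[idx[on_mask]] += df * per_cycle

        # downstream (unrouted lower-hierarchy) fractures in hip/vert states
        hipish = (st_a == HIP_FX) | (st_a == POST_HIP)
        vertish = (st_a == VERT_FX) | (st_a == POST_VERT)
        y1_bucket = tis_a == 0
        for i, site in enumerate(SITES):
            if site == "hip":
                continue
            eligible = hipish if site == "vertebral" else (hipish | vertish)
            hit = eligible & (rng.random(idx.size) < p[:, i])
            if not hit.any():
                continue
            events[idx[hit], i] += 1
            cost[idx[hit]] += df * params.costs.fracture_year1[site][band]
            # three-step disutility vs the higher-hierarchy state's utility
            hi_site = np.where(hipish[hit], 0, 1)
            hi_mult = np.where(
                y1_bucket[hit],
                np.where(hi_site == 0, m1["hip"], m1["vertebral"]),
                np.where(hi_site == 0, m2["hip"], m2["vertebral"]),
            )
            qaly[idx[hit]] -= df * u_base * hi_mult * (1.0 - m1[site])

        # death
        q = _death_prob_matrix(params, age, n_tunnel)
        dead = rng.random(idx.size) < q[vf_a, st_a, tis_a]
        alive[idx[dead]] = False
        keep = ~dead
        idx = idx[keep]
        if idx.size == 0:
            break
        st_a, tis_a, vf_a, p = st_a[keep], tis_a[keep], vf_a[keep], p[keep]

        # fracture routing by severity hierarchy (single cascade uniform)
        u = rng.random(idx.size)
        ph, pv = p[:, 0], p[:, 1]
        pw, po = p[:, 2], p[:, 3]
        new_state = st_a.copy()
        new_tis = tis_a + 1
        fx_site = np.full(idx.size, -1, dtype=np.int16)

        r_group = (st_a == WELL) | (st_a == WRIST_FX) | (st_a == OTHER_FX)
        t1 = ph
        t2 = t1 + (1 - ph) * pv
        t3 = t2 + (1 - ph) * (1 - pv) * pw
        t4 = t3 + (1 - ph) * (1 - pv) * (1 - pw) * po
        fx_site = np.where(r_group & (u < t1), 0, fx_site)
        fx_site = np.where(r_group & (u >= t1) & (u < t2), 1, fx_site)
        fx_site = np.where(r_group & (u >= t2) & (u < t3), 2, fx_site)
        fx_site = np.where(r_group & (u >= t3) & (u < t4), 3, fx_site)
        # no fracture: well stays, acute wrist/other advance then return well
        none_r = r_group & (u >= t4)
        new_state = np.where(none_r & (st_a == WELL), WELL, new_state)
        new_tis = np.where(none_r & (st_a == WELL), 0, new_tis)
        ret_well = none_r & ((st_a == WRIST_FX) | (st_a == OTHER_FX)) & (tis_a >= 1)
        new_state = np.where(ret_well, WELL, new_state)
        new_tis = np.where(ret_well, 0, new_tis)

        hip_state = st_a == HIP_FX
        fx_site = np.where(hip_state & (u < ph), 0, fx_site)
        new_state = np.where(hip_state & (u >= ph), POST_HIP, new_state)
        new_tis = np.where(hip_state & (u >= ph), 0, new_tis)

        vert_state = st_a == VERT_FX
        t2v = ph + (1 - ph) * pv
        fx_site = np.where(vert_state & (u < ph), 0, fx_site)
        fx_site = np.where(vert_state & (u >= ph) & (u < t2v), 1, fx_site)
        new_state = np.where(vert_state & (u >= t2v), POST_VERT, new_state)
        new_tis = np.where(vert_state & (u >= t2v), 0, new_tis)

        ph_state = st_a == POST_HIP
        fx_site = np.where(ph_state & (u < ph), 0, fx_site)

        pv_state = st_a == POST_VERT
        fx_site = np.where(pv_state & (u < ph), 0, fx_site)
        fx_site = np.where(pv_state & (u >= ph) & (u < t2v), 1, fx_site)

        fractured = fx_site >= 0
        new_state = np.where(fx_site == 0, HIP_FX, new_state)
        new_state = np.where(fx_site == 1, VERT_FX, new_state)
        new_state = np.where(fx_site == 2, WRIST_FX, new_state)
        new_state = np.where(fx_site == 3, OTHER_FX, new_state)
        new_tis = np.where(fractured, 0, new_tis)
        new_vf = np.where(fx_site == 1, VF_INCIDENT, vf_a)

        if k < n_cycles - 1:  # events are attributed to the cycle they enter
            df_next = discount_factor(cfg.discount_rate_annual, k + 1, cfg.cycle_length)
            for i in range(len(SITES)):
                hit = fx_site == i
                if hit.any():
                    events[idx[hit], i] += 1
            hip_hit = fx_site == 0
            if hip_hit.any():
                cost[idx[hip_hit]] += df_next * ltc_lump

        state[idx] = new_state
        tis[idx] = np.minimum(new_tis, n_tunnel - 1)
        vf[idx] = new_vf

    outcomes = {
        "total_cost": cost,
        "qalys": qaly,
        "life_years": ly,
        **{f"events_{site}": events[:, i].astype(float) for i, site in enumerate(SITES)},
        "events_any": events.sum(axis=1).astype(float),
    }
    mean = {k: float(v.mean()) for k, v in outcomes.items()}
    se = {k: float(v.std(ddof=1) / np.sqrt(n)) for k, v in outcomes.items()}
    return MicrosimResult(n=n, seed=seed, mean=mean, se=se)
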