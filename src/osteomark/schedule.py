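"""Per-cycle treatment exposure schedule.

Turns a treatment strategy (segments of on-treatment and drug-holiday time),
its persistence curve, and its efficacy profile into per-cycle quantities the
cohort engine and the microsimulation both consume:

* the persistent fraction during each on-treatment cycle;
* the fraction of the current stratum newly discontinuing each cycle;
* per-stratum, per-site treatment RR multipliers.

Strata layout (fixed width ``2 + J`` where ``J`` is the maximum offset in
cycles): index 0 holds never-treated and fully-offset mass (RR = 1); index 1
is the "current" stratum (on treatment, on scheduled holiday, or in terminal
offset after the final segment); indices ``2 + j`` hold cohorts that
discontinued ``j`` cycles ago and are still inside their offset window.  A
cohort whose offset has elapsed behaves identically to never-treated mass, so
the oldest slot merges into index 0 each cycle.

During a scheduled holiday the whole current stratum — and, at the end of the
final segment, all remaining persistent patients — uses the residual
(offset-decay) RR with the treatment clock frozen at the segment boundary.
The persistence clock pauses during a holiday and resumes on re-initiation
(no reset to 100%).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .params import ParameterSet, TreatmentStrategy
from .persistence import cycle_persistent_fraction
from .risk import residual_rr, treatment_rr
from .states import SITES


@dataclass
class ExposureSchedule:
    n_cycles: int
    n_strata: int
    #: persistent fraction during each cycle (0 outside on-segments)
    on_fraction: np.ndarray
    #: fraction of the current stratum newly moved to disc slot 0 each cycle
    phi: np.ndarray
    #: (n_cycles, n_strata, n_sites) treatment RR multipliers
    rr_mult: np.ndarray
    #: cycle lies in an on-treatment segment
    is_on: np.ndarray
    #: unconditional fraction of the cohort discontinuing at each cycle
    disc_weight: np.ndarray
    #: months on treatment at the start of each cycle (clock pauses off-drug)
    months_on: np.ndarray


def build_schedule(
    strategy: TreatmentStrategy, params: ParameterSet, n_cycles: int
) -> ExposureSchedule:
    n_sites = len(SITES)
    max_off_cycles = int(np.ceil(strategy.max_offset_years / params.config.cycle_length))
    n_strata = 2 + max_off_cycles

    on_fraction = np.zeros(n_cycles)
    phi = np.zeros(n_cycles)
    is_on = np.zeros(n_cycles, dtype=bool)
    rr_mult = np.ones((n_cycles, n_strata, n_sites))
    disc_weight = np.zeros(n_cycles)
    months_on = np.zeros(n_cycles)

    if strategy.drug is None:
        return ExposureSchedule(
            n_cycles, n_strata, on_fraction, phi, rr_mult, is_on, disc_weight, months_on
        )

    profile = params.efficacy[strategy.drug]
    curve = params.persistence[strategy.drug]
    cyc_months = 12.0 * params.config.cycle_length

    m = 0.0                 # treatment clock (months) at cycle start
    g_prev = 1.0            # persistent fraction in the previous on-cycle
    off_start: int | None = None   # cycle index when the current stratum went off
    # months-on clock of each cohort at its discontinuation cycle
    m_at_disc = np.full(n_cycles, np.nan)

    for k in range(n_cycles):
        t_years = k * params.config.cycle_length
        seg = strategy.segment_at(t_years)
        months_on[k] = m

        if seg == "on":
            off_start = None
            g = cycle_persistent_fraction(curve, strategy.persistence_timing, m)
            flow = max(g_prev - g, 0.0)
            phi[k] = flow / g_prev if g_prev > 0 else 0.0
            disc_weight[k] = flow
            m_at_disc[k] = m
            on_fraction[k] = g
            is_on[k] = True
            for i, site in enumerate(SITES):
                rr_mult[k, 1, i] = treatment_rr(profile, site, m + cyc_months)
            g_prev = g
            m += cyc_months
        else:  # holiday or off (past the end of all segments)
            if off_start is None:
                off_start = k
            months_off = (k - off_start) * cyc_months
            for i, site in enumerate(SITES):
                rr_mult[k, 1, i] = residual_rr(
                    profile, site, m, months_off, strategy.max_offset_years
                )

        # discontinuation slots: slot j holds the cohort that discontinued at
        # cycle k - j; its clock froze at m_at_disc[k - j]
        for j in range(max_off_cycles):
            d = k - j
            if d < 0 or not np.isfinite(m_at_disc[d]) or disc_weight[d] == 0.0:
                continue
            for i, site in enumerate(SITES):
                rr_mult[k, 2 + j, i] = residual_rr(
                    profile, site, m_at_disc[d], j * cyc_months, strategy.max_offset_years
                )

    return ExposureSchedule(
        n_cycles, n_strata, on_fraction, phi, rr_mult, is_on, disc_weight, months_on
    )
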