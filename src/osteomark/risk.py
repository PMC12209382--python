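"""Fracture risk composition.

Per-cycle fracture probability is composed multiplicatively:

    rate = (general-population rate) x (disease RR) x (treatment RR)
    p    = 1 - exp(-rate * 0.5)

The disease relative risk is either the BMD gradient raised to the patient's
deficit below the age-specific population mean T-score, or — for patients with
a fracture history — the prior-fracture RR (adjusted downward by 10% so the
BMD pathway is not double counted).  The treatment RR is a step function of
time on drug (12/24/36-month endpoints, 36-month value carried forward); after
discontinuation it decays linearly back to 1 over the effective offset time,
which is the shorter of time on treatment and the drug's maximum offset.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .params import EfficacyProfile, ParameterSet, RelativeRiskSet, age_lookup


@dataclass
class TreatmentStratum:
    """Exposure status of a persistence stratum."""

    status: str = "never_treated"  # never_treated | on_treatment | discontinued | holiday
    months_on: float = 0.0         # treatment clock at the status change
    months_since_off: float = 0.0  # for discontinued/holiday

    def __post_init__(self) -> None:
        if self.months_on < 0 or self.months_since_off < 0:
            raise ValueError("stratum clocks must be >= 0")
        if self.status == "on_treatment" and self.months_since_off != 0:
            raise ValueError("months_since_off must be 0 while on treatment")


def bmd_rr(
    site: str,
    age: float,
    t_score: float,
    rrs: RelativeRiskSet,
    hip_gradient: str = "overall",
    interpolation: str = "step",
) -> float:
    """RR of fracture due to low BMD: gradient ** (mean population T-score − patient T-score)."""
    if hip_gradient == "age_specific" and site == "hip":
        grad = age_lookup(rrs.rr_hip_per_sd_by_age, age, interpolation, clamp_low=True)
    else:
        grad = rrs.rr_per_sd[site]
    mean_t = age_lookup(rrs.mean_pop_tscore, age, interpolation)
    return grad ** (mean_t - t_score)


def prior_fx_rr(
    site: str,
    age: float,
    rrs: RelativeRiskSet,
    adjusted: bool = True,
    interpolation: str = "step",
) -> float:
    """RR of fracture given a history of prior fracture (hip is age-keyed)."""
    if site == "hip":
        rr = age_lookup(rrs.rr_prior_fx_hip_by_age, age, interpolation, clamp_low=True)
    else:
        rr = rrs.rr_prior_fx[site]
    return rr * rrs.bmd_adjustment_factor if adjusted else rr


def treatment_rr(profile: EfficacyProfile, site: str, months_on: float) -> float:
    """On-treatment RR vs placebo as a step function of months on drug."""
    if months_on < 0:
        raise ValueError("months_on must be >= 0")
    if months_on == 0:
        return 1.0
    if months_on <= 12:
        return profile.rr[site][12]
    if months_on <= 24:
        return profile.rr[site][24]
    return profile.rr[site][36]  # 36-month value carried forward


def residual_rr(
    profile: EfficacyProfile,
    site: str,
    months_on_at_disc: float,
    months_since_off: float,
    max_offset_years: float,
) -> float:
    """Post-discontinuation RR: linear return to 1 over the effective offset.

    The effective offset is min(time on treatment, maximum offset); a zero
    offset means efficacy is lost immediately.
    """
    if months_since_off < 0 or months_on_at_disc < 0:
        raise ValueError("durations must be >= 0")
    r0 = treatment_rr(profile, site, months_on_at_disc)
    t_offset = min(months_on_at_disc, 12.0 * max_offset_years)
    if t_offset <= 0:
        return 1.0
    frac = min(months_since_off / t_offset, 1.0)
    return r0 + (1.0 - r0) * frac


def stratum_rr(
    profile: EfficacyProfile | None,
    site: str,
    stratum: TreatmentStratum,
    max_offset_years: float,
) -> float:
    """Treatment-related RR for a persistence stratum."""
    if profile is None or stratum.status == "never_treated":
        return 1.0
    if stratum.status == "on_treatment":
        return treatment_rr(profile, site, stratum.months_on)
    return residual_rr(
        profile, site, stratum.months_on, stratum.months_since_off, max_offset_years
    )


def rate_to_cycle_prob(rate_per_year: float, cycle_length: float = 0.5) -> float:
    """Exponential conversion of an annual rate to a per-cycle probability."""
    if rate_per_year < 0:
        raise ValueError("rate must be >= 0")
    return 1.0 - math.exp(-rate_per_year * cycle_length)


def cycle_fracture_prob(
    site: str,
    age: float,
    stratum: TreatmentStratum,
    has_prior_fx: bool,
    params: ParameterSet,
    strategy_drug: str | None = None,
    max_offset_years: float = 0.0,
) -> float:
    """Per-cycle probability of fracture at a site for one stratum.

    Patients with a fracture history use the (adjusted) prior-fracture RR;
    patients without use the BMD gradient.  The composed annual rate is
    converted with the exponential formula so the probability stays in [0, 1).
    """
    cfg = params.config
    gen = params.incidence_rate(site, age)
    if has_prior_fx:
        disease = prior_fx_rr(
            site, age, params.relative_risks, cfg.prior_fx_adjusted, cfg.age_interpolation
        )
    else:
        disease = bmd_rr(
            site, age, cfg.t_score, params.relative_risks, cfg.hip_gradient, cfg.age_interpolation
        )
    profile = params.efficacy.get(strategy_drug) if strategy_drug else None
    treat = stratum_rr(profile, site, stratum, max_offset_years)
    rate = gen * disease * treat
    assert rate >= 0
    return rate_to_cycle_prob(rate, cfg.cycle_length)
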