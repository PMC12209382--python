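"""Base-case treatment strategies.

Denosumab: subcutaneous injection every 6 months, 10 years on treatment,
1-year efficacy offset after discontinuation.  Alendronate: weekly oral,
5 years on treatment, a 2-year drug holiday, then 3 more years on treatment,
2-year maximum offset.  Monitoring: 2 nurse visits/year for denosumab
(injection administration), 1 physician visit/year and 0.5 DXA scans/year
for any active treatment.
"""

from __future__ import annotations

from .params import TreatmentStrategy


def no_treatment() -> TreatmentStrategy:
    return TreatmentStrategy(name="no_treatment")


def denosumab(years: float = 10.0, max_offset_years: float = 1.0) -> TreatmentStrategy:
    return TreatmentStrategy(
        name=f"denosumab_{years:g}y",
        drug="denosumab",
        segments=[("on", years)],
        max_offset_years=max_offset_years,
        annual_drug_cost=2899.0,
        nurse_visits_per_year=2.0,
        physician_visits_per_year=1.0,
        dxa_scans_per_year=0.5,
        persistence_timing="cycle_start",
    )


def alendronate(
    on_years: float = 5.0,
    holiday_years: float = 2.0,
    resume_years: float = 3.0,
    max_offset_years: float = 2.0,
) -> TreatmentStrategy:
    segments = [("on", on_years)]
    if holiday_years > 0:
        segments.append(("holiday", holiday_years))
    if resume_years > 0:
        segments.append(("on", resume_years))
    label = f"alendronate_{on_years:g}+{holiday_years:g}h+{resume_years:g}y"
    return TreatmentStrategy(
        name=label,
        drug="alendronate",
        segments=segments,
        max_offset_years=max_offset_years,
        annual_drug_cost=44.0,
        nurse_visits_per_year=0.0,
        physician_visits_per_year=1.0,
        dxa_scans_per_year=0.5,
        persistence_timing="midpoint",
    )


def base_case_strategies() -> list[TreatmentStrategy]:
    """The three base-case arms, in comparison order."""
    return [denosumab(), no_treatment(), alendronate()]
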