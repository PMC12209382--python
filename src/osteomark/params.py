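"""Model parameters: containers, validation, layered loading and overrides.

All epidemiological, efficacy, persistence, cost and utility inputs live in a
single validated :class:`ParameterSet`.  Published point estimates (relative
risks, efficacy by treatment duration, persistence at 6-month intervals, unit
costs, fracture costs by age band, utilities and multipliers) are bundled as
in-code defaults; inputs that are only available as supplementary material or
not published at all (the female life table, general-population fracture
incidence by age, mean population T-score by age, post-fracture mortality
relative risks, nursing-home admission/stay after hip fracture) are generated
by :mod:`osteomark.synthetic` and are clearly flagged as assumptions.

Parameter files are layered: a YAML manifest (optionally referencing CSV
tables) is deep-merged over the bundled defaults, so sensitivity analyses and
scenarios are expressed as pure overrides.
"""

from __future__ import annotations

import copy
import difflib
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any, Dict, List, Optional, Tuple

import pandas as pd
import yaml

from .states import SITES


class ValidationError(ValueError):
    """A parameter value violates a model invariant."""


class SchemaError(ValueError):
    """A parameter bundle is structurally malformed (missing table/field)."""


# ---------------------------------------------------------------------------
# age-keyed lookups
# ---------------------------------------------------------------------------

def age_lookup(
    table: Dict[float, float], age: float, mode: str = "step", clamp_low: bool = False
) -> float:
    """Look up an age-keyed table.

    ``step`` returns the value at the largest key <= age; ``linear``
    interpolates between adjacent keys.  Ages beyond the last key hold the
    last value; ages below the first key raise unless ``clamp_low`` holds the
    first value (used for RR tables published at sparse age anchors only).
    """
    keys = sorted(table)
    if not keys:
        raise ValidationError("empty age-keyed table")
    if age < keys[0]:
        if clamp_low:
            return table[keys[0]]
        raise ValidationError(f"age {age} below table support (min {keys[0]})")
    if age >= keys[-1]:
        return table[keys[-1]]
    if mode == "step":
        lo = max(k for k in keys if k <= age)
        return table[lo]
    if mode == "linear":
        import bisect

        i = bisect.bisect_right(keys, age) - 1
        k0, k1 = keys[i], keys[i + 1]
        w = (age - k0) / (k1 - k0)
        return table[k0] * (1 - w) + table[k1] * w
    raise ValidationError(f"unknown age interpolation mode {mode!r}")


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class ModelConfig:
    start_age: float = 72.0
    cycle_length: float = 0.5
    max_age: float = 100.0
    #: fixed horizon in years, or None for lifetime (to max_age)
    horizon_years: Optional[float] = None
    discount_rate_annual: float = 0.03
    t_score: float = -2.5
    prevalent_vf_fraction: float = 0.236
    #: share of post-fracture excess mortality attributed to the fracture
    excess_mortality_attribution: float = 0.30
    #: duration of elevated mortality after hip/vertebral fracture; None = lifetime
    excess_mortality_years: Optional[float] = 8.0
    #: acute fracture effects (year-1 utility multiplier and cost) span 2 cycles
    fracture_effect_cycles: int = 2
    #: "overall" uses the all-age gradient of risk for hip; "age_specific"
    #: uses the age-keyed hip gradient instead
    hip_gradient: str = "overall"
    #: age-keyed table lookup: "step" or "linear"
    age_interpolation: str = "step"
    #: apply the 10% downward adjustment to prior-fracture RRs (avoids double
    #: counting the BMD pathway)
    prior_fx_adjusted: bool = True

    def validate(self) -> None:
        if self.start_age < 50:
            raise ValidationError(f"config.start_age must be >= 50, got {self.start_age}")
        if self.cycle_length != 0.5:
            raise ValidationError(f"config.cycle_length is fixed at 0.5, got {self.cycle_length}")
        if self.discount_rate_annual < 0:
            raise ValidationError("config.discount_rate_annual must be >= 0")
        for name in ("prevalent_vf_fraction", "excess_mortality_attribution"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"config.{name} must be in [0,1], got {v}")
        if self.excess_mortality_years is not None and self.excess_mortality_years <= 0:
            raise ValidationError("config.excess_mortality_years must be > 0 (or null for lifetime)")
        if self.fracture_effect_cycles != 2:
            raise ValidationError("config.fracture_effect_cycles is fixed at 2")
        if self.hip_gradient not in ("overall", "age_specific"):
            raise ValidationError(f"config.hip_gradient must be 'overall' or 'age_specific', got {self.hip_gradient!r}")
        if self.age_interpolation not in ("step", "linear"):
            raise ValidationError("config.age_interpolation must be 'step' or 'linear'")

    @property
    def horizon(self) -> float:
        if self.horizon_years is not None:
            return float(self.horizon_years)
        return float(self.max_age - self.start_age)

    @property
    def n_cycles(self) -> int:
        return int(round(self.horizon / self.cycle_length))


@dataclass
class RelativeRiskSet:
    """Disease-related relative risks of fracture."""

    #: gradient of fracture risk per SD of hip BMD, by site
    rr_per_sd: Dict[str, float] = field(default_factory=dict)
    #: age-keyed hip gradient (men+women combined)
    rr_hip_per_sd_by_age: Dict[float, float] = field(default_factory=dict)
    #: RR of fracture given a history of prior fracture (original values);
    #: hip is age-keyed, other sites are age-constant
    rr_prior_fx_hip_by_age: Dict[float, float] = field(default_factory=dict)
    rr_prior_fx: Dict[str, float] = field(default_factory=dict)
    #: downward adjustment applied to prior-fracture RRs to avoid double
    #: counting the BMD-mediated risk
    bmd_adjustment_factor: float = 0.90
    #: mean female population T-score by age (assumption, generated)
    mean_pop_tscore: Dict[float, float] = field(default_factory=dict)

    def validate(self) -> None:
        for site in SITES:
            if site not in self.rr_per_sd:
                raise SchemaError(f"relative_risks.rr_per_sd missing site {site!r}")
            if self.rr_per_sd[site] <= 0:
                raise ValidationError(f"relative_risks.rr_per_sd.{site} must be > 0")
        for site in ("vertebral", "wrist", "other"):
            if site not in self.rr_prior_fx:
                raise SchemaError(f"relative_risks.rr_prior_fx missing site {site!r}")
            if self.rr_prior_fx[site] <= 0:
                raise ValidationError(f"relative_risks.rr_prior_fx.{site} must be > 0")
        if not self.rr_prior_fx_hip_by_age:
            raise SchemaError("relative_risks.rr_prior_fx_hip_by_age is empty")
        if not 0 < self.bmd_adjustment_factor <= 1:
            raise ValidationError("relative_risks.bmd_adjustment_factor must be in (0,1]")
        if not self.mean_pop_tscore:
            raise SchemaError("relative_risks.mean_pop_tscore is empty")


@dataclass
class EfficacyProfile:
    """Treatment efficacy: RR of fracture vs placebo by site and time on drug.

    RRs are keyed by the 12/24/36-month endpoints; beyond 36 months the
    36-month value is carried forward.
    """

    drug: str = ""
    #: site -> {12: rr, 24: rr, 36: rr}
    rr: Dict[str, Dict[int, float]] = field(default_factory=dict)

    def validate(self) -> None:
        for site in SITES:
            if site not in self.rr:
                raise SchemaError(f"efficacy[{self.drug}].rr missing site {site!r}")
            for m in (12, 24, 36):
                if m not in self.rr[site]:
                    raise SchemaError(f"efficacy[{self.drug}].rr.{site} missing {m}-month value")
                v = self.rr[site][m]
                if not 0 < v <= 1.5:
                    raise ValidationError(
                        f"efficacy[{self.drug}].rr.{site}.{m} must be in (0, 1.5], got {v}"
                    )


@dataclass
class PersistenceCurve:
    """Observed proportion of patients persistent with therapy at 6-month marks."""

    drug: str = ""
    #: month (0, 6, ..., 36) -> proportion persistent
    observed: Dict[int, float] = field(default_factory=dict)
    #: extrapolation beyond the observed window:
    #: "last_value" | "last_interval_rate" | "overall_rate"
    extrapolation: str = "last_value"

    def validate(self) -> None:
        if 0 not in self.observed:
            raise SchemaError(f"persistence[{self.drug}].observed missing month 0")
        if self.observed[0] != 1.0:
            raise ValidationError(
                f"persistence[{self.drug}].observed[0] must be 1.0, got {self.observed[0]}"
            )
        months = sorted(self.observed)
        vals = [self.observed[m] for m in months]
        for m, v in zip(months, vals):
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"persistence[{self.drug}].observed[{m}] must be in [0,1]")
        for a, b in zip(vals, vals[1:]):
            if b > a + 1e-12:
                raise ValidationError(f"persistence[{self.drug}] must be nonincreasing")
        if self.extrapolation not in ("last_value", "last_interval_rate", "overall_rate"):
            raise ValidationError(
                f"persistence[{self.drug}].extrapolation unknown method {self.extrapolation!r}"
            )


@dataclass
class TreatmentStrategy:
    """A drug with a timeline of on-treatment / holiday segments.

    ``persistence_timing`` selects where within a cycle the persistent
    fraction is evaluated: at the cycle start (aligned with 6-monthly
    administration) or at the cycle midpoint (weekly oral dosing).
    """

    name: str = "no_treatment"
    drug: Optional[str] = None
    #: ordered (kind, duration-in-years); kind in {"on", "holiday"}
    segments: List[Tuple[str, float]] = field(default_factory=list)
    max_offset_years: float = 0.0
    annual_drug_cost: float = 0.0
    nurse_visits_per_year: float = 0.0
    physician_visits_per_year: float = 0.0
    dxa_scans_per_year: float = 0.0
    persistence_timing: str = "cycle_start"

    def validate(self, cycle_length: float = 0.5) -> None:
        for kind, dur in self.segments:
            if kind not in ("on", "holiday"):
                raise ValidationError(f"strategy {self.name}: segment kind {kind!r} unknown")
            if dur < 0:
                raise ValidationError(f"strategy {self.name}: negative segment duration")
            if abs(dur / cycle_length - round(dur / cycle_length)) > 1e-9:
                raise ValidationError(
                    f"strategy {self.name}: segment duration {dur} not a multiple of {cycle_length}"
                )
        if self.max_offset_years < 0:
            raise ValidationError(f"strategy {self.name}: max_offset_years must be >= 0")
        if self.drug is None and any(kind == "on" for kind, _ in self.segments):
            raise ValidationError(f"strategy {self.name}: on-segments require a drug")
        if self.persistence_timing not in ("cycle_start", "midpoint"):
            raise ValidationError(f"strategy {self.name}: unknown persistence_timing")

    def segment_at(self, years_from_start: float) -> str:
        """Return 'on', 'holiday' or 'off' (past the end of all segments)."""
        t = 0.0
        for kind, dur in self.segments:
            if years_from_start < t + dur - 1e-9:
                return kind
            t += dur
        return "off"

    @property
    def total_years(self) -> float:
        return sum(dur for _, dur in self.segments)


@dataclass
class CostTable:
    """Direct medical costs (2024 USD, third-party payer perspective)."""

    #: site -> {"50-64": USD, "65+": USD} incremental cost in the fracture year
    fracture_year1: Dict[str, Dict[str, float]] = field(default_factory=dict)
    #: hip/vertebral only: annual cost in year 2 and beyond
    fracture_year2plus: Dict[str, Dict[str, float]] = field(default_factory=dict)
    unit_costs: Dict[str, float] = field(default_factory=dict)
    ltc_per_day: float = 216.0
    #: probability of nursing-home admission after hip fracture (assumption)
    ltc_admission_prob_after_hip: float = 0.20
    #: mean nursing-home stay in days (assumption)
    ltc_mean_stay_days: float = 180.0

    def validate(self) -> None:
        for site in SITES:
            if site not in self.fracture_year1:
                raise SchemaError(f"costs.fracture_year1 missing site {site!r}")
            for band in ("50-64", "65+"):
                if band not in self.fracture_year1[site]:
                    raise SchemaError(f"costs.fracture_year1.{site} missing band {band!r}")
                if self.fracture_year1[site][band] < 0:
                    raise ValidationError(f"costs.fracture_year1.{site}.{band} must be >= 0")
        for site in ("hip", "vertebral"):
            if site not in self.fracture_year2plus:
                raise SchemaError(f"costs.fracture_year2plus missing site {site!r}")
            for band in ("50-64", "65+"):
                y2 = self.fracture_year2plus[site][band]
                if y2 < 0:
                    raise ValidationError(f"costs.fracture_year2plus.{site}.{band} must be >= 0")
                if y2 > self.fracture_year1[site][band]:
                    raise ValidationError(
                        f"costs: year-2+ cost exceeds year-1 cost for {site}/{band}"
                    )
        for key in ("dxa", "physician_visit", "iv_injection", "nurse_visit"):
            if key not in self.unit_costs:
                raise SchemaError(f"costs.unit_costs missing {key!r}")
            if self.unit_costs[key] < 0:
                raise ValidationError(f"costs.unit_costs.{key} must be >= 0")
        if self.ltc_per_day < 0 or self.ltc_mean_stay_days < 0:
            raise ValidationError("long-term care cost inputs must be >= 0")
        if not 0 <= self.ltc_admission_prob_after_hip <= 1:
            raise ValidationError("costs.ltc_admission_prob_after_hip must be in [0,1]")


@dataclass
class UtilityTable:
    """Age-specific baseline utilities and post-fracture multipliers."""

    #: decade band lower bound -> utility (women, general population)
    baseline_by_age: Dict[float, float] = field(default_factory=dict)
    #: site -> year-1 multiplier
    multiplier_year1: Dict[str, float] = field(default_factory=dict)
    #: hip/vertebral -> year-2+ multiplier
    multiplier_year2plus: Dict[str, float] = field(default_factory=dict)

    def validate(self) -> None:
        if not self.baseline_by_age:
            raise SchemaError("utilities.baseline_by_age is empty")
        for age, u in self.baseline_by_age.items():
            if not 0 < u <= 1:
                raise ValidationError(f"utilities.baseline_by_age[{age}] must be in (0,1]")
        for site in SITES:
            if site not in self.multiplier_year1:
                raise SchemaError(f"utilities.multiplier_year1 missing site {site!r}")
            if not 0 < self.multiplier_year1[site] <= 1:
                raise ValidationError(f"utilities.multiplier_year1.{site} must be in (0,1]")
        for site in ("hip", "vertebral"):
            if site not in self.multiplier_year2plus:
                raise SchemaError(f"utilities.multiplier_year2plus missing site {site!r}")
            if not 0 < self.multiplier_year2plus[site] <= 1:
                raise ValidationError(f"utilities.multiplier_year2plus.{site} must be in (0,1]")


@dataclass
class MortalityTable:
    """Female all-cause mortality and post-fracture mortality relative risks."""

    #: age -> annual probability of death
    q_female: Dict[float, float] = field(default_factory=dict)
    #: site in {hip, vertebral, other} -> age -> RR of death after fracture
    rr_post_fracture: Dict[str, Dict[float, float]] = field(default_factory=dict)

    def validate(self) -> None:
        if not self.q_female:
            raise SchemaError("mortality.q_female is empty")
        for age, q in self.q_female.items():
            if not 0 <= q <= 1:
                raise ValidationError(f"mortality.q_female[{age}] must be in [0,1]")
        for site in ("hip", "vertebral", "other"):
            if site not in self.rr_post_fracture:
                raise SchemaError(f"mortality.rr_post_fracture missing site {site!r}")
            for age, rr in self.rr_post_fracture[site].items():
                if rr < 1:
                    raise ValidationError(
                        f"mortality.rr_post_fracture.{site}[{age}] must be >= 1, got {rr}"
                    )


@dataclass
class IncidenceTable:
    """General-population fracture incidence rates (per person-year, women)."""

    #: site -> age -> rate
    rates: Dict[str, Dict[float, float]] = field(default_factory=dict)

    def validate(self) -> None:
        for site in SITES:
            if site not in self.rates:
                raise SchemaError(f"incidence.rates missing site {site!r}")
            for age, r in self.rates[site].items():
                if r < 0:
                    raise ValidationError(f"incidence.rates.{site}[{age}] must be >= 0")


@dataclass
class ParameterSet:
    """Single source of truth for all model inputs."""

    config: ModelConfig = field(default_factory=ModelConfig)
    relative_risks: RelativeRiskSet = field(default_factory=RelativeRiskSet)
    efficacy: Dict[str, EfficacyProfile] = field(default_factory=dict)
    persistence: Dict[str, PersistenceCurve] = field(default_factory=dict)
    costs: CostTable = field(default_factory=CostTable)
    utilities: UtilityTable = field(default_factory=UtilityTable)
    mortality: MortalityTable = field(default_factory=MortalityTable)
    incidence: IncidenceTable = field(default_factory=IncidenceTable)

    def validate(self) -> "ParameterSet":
        self.config.validate()
        self.relative_risks.validate()
        for profile in self.efficacy.values():
            profile.validate()
        for curve in self.persistence.values():
            curve.validate()
        self.costs.validate()
        self.utilities.validate()
        self.mortality.validate()
        self.incidence.validate()
        return self

    # -- lookups used across the model ------------------------------------

    def q_annual(self, age: float) -> float:
        return age_lookup(self.mortality.q_female, age, "step")

    def mortality_rr(self, site: str, age: float) -> float:
        return age_lookup(
            self.mortality.rr_post_fracture[site], age, self.config.age_interpolation
        )

    def incidence_rate(self, site: str, age: float) -> float:
        return age_lookup(self.incidence.rates[site], age, self.config.age_interpolation)

    def mean_pop_tscore(self, age: float) -> float:
        return age_lookup(
            self.relative_risks.mean_pop_tscore, age, self.config.age_interpolation
        )

    def baseline_utility(self, age: float) -> float:
        return age_lookup(self.utilities.baseline_by_age, age, "step")

    def cost_band(self, age: float) -> str:
        return "50-64" if age < 65 else "65+"

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> Dict[str, Any]:
        d = asdict(self)
        # asdict turns tuples into lists for segments; fine for YAML
        return d

    @classmethod
    def from_dict(cls, d: Dict[str, Any]) -> "ParameterSet":
        def num_keys(table: Dict) -> Dict:
            return {_coerce_key(k): v for k, v in table.items()}

        cfg = ModelConfig(**d["config"])
        rr_d = d["relative_risks"]
        rrs = RelativeRiskSet(
            rr_per_sd=dict(rr_d["rr_per_sd"]),
            rr_hip_per_sd_by_age=num_keys(rr_d["rr_hip_per_sd_by_age"]),
            rr_prior_fx_hip_by_age=num_keys(rr_d["rr_prior_fx_hip_by_age"]),
            rr_prior_fx=dict(rr_d["rr_prior_fx"]),
            bmd_adjustment_factor=rr_d["bmd_adjustment_factor"],
            mean_pop_tscore=num_keys(rr_d["mean_pop_tscore"]),
        )
        efficacy = {
            drug: EfficacyProfile(
                drug=p["drug"],
                rr={s: {int(m): v for m, v in t.items()} for s, t in p["rr"].items()},
            )
            for drug, p in d["efficacy"].items()
        }
        persistence = {
            drug: PersistenceCurve(
                drug=p["drug"],
                observed={int(m): v for m, v in p["observed"].items()},
                extrapolation=p["extrapolation"],
            )
            for drug, p in d["persistence"].items()
        }
        costs = CostTable(
            fracture_year1={s: dict(b) for s, b in d["costs"]["fracture_year1"].items()},
            fracture_year2plus={s: dict(b) for s, b in d["costs"]["fracture_year2plus"].items()},
            unit_costs=dict(d["costs"]["unit_costs"]),
            ltc_per_day=d["costs"]["ltc_per_day"],
            ltc_admission_prob_after_hip=d["costs"]["ltc_admission_prob_after_hip"],
            ltc_mean_stay_days=d["costs"]["ltc_mean_stay_days"],
        )
        utilities = UtilityTable(
            baseline_by_age=num_keys(d["utilities"]["baseline_by_age"]),
            multiplier_year1=dict(d["utilities"]["multiplier_year1"]),
            multiplier_year2plus=dict(d["utilities"]["multiplier_year2plus"]),
        )
        mortality = MortalityTable(
            q_female=num_keys(d["mortality"]["q_female"]),
            rr_post_fracture={
                s: num_keys(t) for s, t in d["mortality"]["rr_post_fracture"].items()
            },
        )
        incidence = IncidenceTable(
            rates={s: num_keys(t) for s, t in d["incidence"]["rates"].items()}
        )
        return cls(cfg, rrs, efficacy, persistence, costs, utilities, mortality, incidence)

    def copy(self) -> "ParameterSet":
        return copy.deepcopy(self)


def _coerce_key(k: Any) -> float:
    if isinstance(k, (int, float)):
        return float(k)
    return float(k)


# ---------------------------------------------------------------------------
# bundled defaults (published point estimates)
# ---------------------------------------------------------------------------

def _default_tables() -> Dict[str, Any]:
    """Published base-case inputs (US, 2024 USD)."""
    return {
        "config": asdict(ModelConfig()),
        "relative_risks": {
            "rr_per_sd": {"hip": 2.60, "vertebral": 1.80, "wrist": 1.40, "other": 1.60},
            "rr_hip_per_sd_by_age": {65.0: 2.89, 70.0: 2.78},
            "rr_prior_fx_hip_by_age": {65.0: 2.28, 70.0: 1.90},
            "rr_prior_fx": {"vertebral": 4.40, "wrist": 1.40, "other": 1.90},
            "bmd_adjustment_factor": 0.90,
            "mean_pop_tscore": {},  # filled from synthetic stand-in
        },
        "efficacy": {
            "alendronate": {
                "drug": "alendronate",
                "rr": {
                    "hip": {12: 0.86, 24: 0.51, 36: 0.52},
                    "vertebral": {12: 0.51, 24: 0.37, 36: 0.51},
                    "wrist": {12: 0.77, 24: 0.53, 36: 0.62},
                    "other": {12: 0.77, 24: 0.53, 36: 0.62},
                },
            },
            "denosumab": {
                "drug": "denosumab",
                "rr": {
                    "hip": {12: 0.55, 24: 0.47, 36: 0.28},
                    "vertebral": {12: 0.39, 24: 0.29, 36: 0.33},
                    "wrist": {12: 0.84, 24: 0.79, 36: 0.82},
                    "other": {12: 0.84, 24: 0.79, 36: 0.82},
                },
            },
        },
        "persistence": {
            "alendronate": {
                "drug": "alendronate",
                "observed": {0: 1.0, 6: 0.561, 12: 0.388, 18: 0.298,
                             24: 0.247, 30: 0.203, 36: 0.172},
                "extrapolation": "last_value",
            },
            "denosumab": {
                "drug": "denosumab",
                "observed": {0: 1.0, 6: 0.936, 12: 0.727, 18: 0.596,
                             24: 0.503, 30: 0.432, 36: 0.380},
                "extrapolation": "last_value",
            },
        },
        "costs": {
            "fracture_year1": {
                "hip": {"50-64": 67115.0, "65+": 51760.0},
                "vertebral": {"50-64": 33923.0, "65+": 23949.0},
                "wrist": {"50-64": 16279.0, "65+": 21731.0},
                "other": {"50-64": 16279.0, "65+": 21731.0},
            },
            "fracture_year2plus": {
                "hip": {"50-64": 11145.0, "65+": 7896.0},
                "vertebral": {"50-64": 8455.0, "65+": 5943.0},
            },
            "unit_costs": {
                "dxa": 38.95,
                "physician_visit": 90.87,
                "iv_injection": 62.58,
                "nurse_visit": 14.31,
            },
            "ltc_per_day": 216.0,
            "ltc_admission_prob_after_hip": 0.20,
            "ltc_mean_stay_days": 180.0,
        },
        "utilities": {
            "baseline_by_age": {50.0: 0.837, 60.0: 0.811, 70.0: 0.771, 80.0: 0.724},
            "multiplier_year1": {"hip": 0.550, "vertebral": 0.680,
                                 "wrist": 0.830, "other": 0.830},
            "multiplier_year2plus": {"hip": 0.860, "vertebral": 0.850},
        },
        "mortality": {"q_female": {}, "rr_post_fracture": {}},
        "incidence": {"rates": {}},
    }


def default_parameters(seed: int = 0) -> ParameterSet:
    """Bundled defaults: published point estimates plus synthetic stand-ins
    for the inputs that are not published (life table, incidence, mean
    population T-score, post-fracture mortality RRs, long-term care)."""
    from . import synthetic  # local import to avoid a cycle

    d = _default_tables()
    d["mortality"] = synthetic.gen_mortality_dict(seed)
    d["incidence"] = synthetic.gen_incidence_dict(seed)
    d["relative_risks"]["mean_pop_tscore"] = synthetic.gen_tscore_dict(seed)
    return ParameterSet.from_dict(d).validate()


# ---------------------------------------------------------------------------
# loading / layering / overrides
# ---------------------------------------------------------------------------

def _deep_update(base: Dict, override: Dict) -> Dict:
    for k, v in override.items():
        if isinstance(v, dict) and isinstance(base.get(k), dict):
            _deep_update(base[k], v)
        else:
            base[k] = v
    return base


_TABLE_FILES = {
    "life_table": ("mortality", "q_female"),
    "mortality_rr": ("mortality", "rr_post_fracture"),
    "incidence": ("incidence", "rates"),
    "tscore": ("relative_risks", "mean_pop_tscore"),
}


def load_parameters(path: Optional[str | Path] = None, seed: int = 0) -> ParameterSet:
    """Load a parameter bundle layered over the bundled defaults.

    ``path`` may be a YAML manifest or a directory containing ``manifest.yaml``.
    The manifest may reference CSV tables via a ``tables:`` mapping (keys:
    life_table, mortality_rr, incidence, tscore).  Omitted fields keep their
    default values; ``path=None`` returns the defaults unchanged.
    """
    base = default_parameters(seed).to_dict()
    if path is None:
        return ParameterSet.from_dict(base).validate()
    path = Path(path)
    if path.is_dir():
        path = path / "manifest.yaml"
    if not path.exists():
        raise SchemaError(f"parameter bundle not found: {path}")
    with open(path) as fh:
        manifest = yaml.safe_load(fh) or {}
    tables = manifest.pop("tables", {})
    _deep_update(base, manifest)
    for key, ref in tables.items():
        if key not in _TABLE_FILES:
            raise SchemaError(f"unknown table reference {key!r} in manifest "
                              f"(expected one of {sorted(_TABLE_FILES)})")
        csv_path = path.parent / ref
        if not csv_path.exists():
            raise SchemaError(f"table {key!r}: file not found: {csv_path}")
        df = pd.read_csv(csv_path, comment="#", float_precision="round_trip")
        section, fld = _TABLE_FILES[key]
        if key in ("life_table", "tscore"):
            value_col = [c for c in df.columns if c != "age"][0]
            base[section][fld] = {float(a): float(v) for a, v in zip(df["age"], df[value_col])}
        else:
            base[section][fld] = {
                c: {float(a): float(v) for a, v in zip(df["age"], df[c])}
                for c in df.columns
                if c != "age"
            }
    return ParameterSet.from_dict(base).validate()


def _leaf_paths(d: Any, prefix: str = "") -> List[str]:
    if isinstance(d, dict):
        out: List[str] = []
        for k, v in d.items():
            key = f"{prefix}.{k}" if prefix else str(k)
            out.extend(_leaf_paths(v, key))
        return out
    return [prefix]


def apply_override(params: ParameterSet, path: str, value: Any) -> ParameterSet:
    """Return a new ParameterSet with a single dotted field replaced.

    ``path`` addresses a scalar or table cell, e.g. ``config.discount_rate_annual``
    or ``relative_risks.rr_per_sd.hip``.  The original object is untouched.
    An unknown path raises a :class:`SchemaError` listing the nearest valid
    paths.
    """
    d = params.to_dict()
    parts = path.split(".")
    node: Any = d
    i = 0
    while True:
        if not isinstance(node, dict):
            _unknown_path(d, path)
        # numeric keys may themselves contain a dot ("72.0"): try the
        # two-part candidate first, then the single part
        match = None
        for j in (min(i + 2, len(parts)), i + 1):
            key = _match_key(node, ".".join(parts[i:j]))
            if key is not None and (j < len(parts) and isinstance(node[key], dict)
                                    or j == len(parts)):
                match = (key, j)
                break
        if match is None:
            _unknown_path(d, path)
        key, j = match
        if j == len(parts):
            node[key] = value
            break
        node = node[key]
        i = j
    return ParameterSet.from_dict(d).validate()


def _match_key(d: Dict, part: str) -> Any:
    if part in d:
        return part
    for cand in d:
        if str(cand) == part:
            return cand
    f = _try_float(part)
    if f is not None:
        for cand in d:
            if isinstance(cand, (int, float)) and float(cand) == f:
                return cand
    return None


def _try_float(s: str) -> Optional[float]:
    try:
        return float(s)
    except ValueError:
        return None


def _unknown_path(d: Dict, path: str) -> None:
    candidates = _leaf_paths(d)
    near = difflib.get_close_matches(path, candidates, n=5, cutoff=0.3)
    raise SchemaError(f"unknown parameter path {path!r}; nearest valid paths: {near}")


def save_parameters(params: ParameterSet, path: str | Path) -> None:
    """Serialize a full ParameterSet to a single YAML file (lossless)."""
    with open(path, "w") as fh:
        yaml.safe_dump(params.to_dict(), fh, sort_keys=True)


def read_parameters(path: str | Path) -> ParameterSet:
    """Read a YAML file written by :func:`save_parameters`."""
    with open(path) as fh:
        return ParameterSet.from_dict(yaml.safe_load(fh)).validate()
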