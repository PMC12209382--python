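"""Synthetic stand-ins for model inputs that are not published in full.

ASSUMED — these tables are not transcribed from any source.  They are
constructed to have the statistical structure the analysis assumes (shapes,
monotonicity, plausible magnitudes for US postmenopausal women), so that every
module is testable without a download, and they are replaced wholesale when a
bundle supplies real tables:

* female all-cause mortality: Gompertz–Makeham annual death probabilities
  ``q(x) = min(1, a + b*exp(c*x))`` calibrated so life expectancy at age 72 is
  roughly 15–17 years;
* post-fracture mortality relative risks: linear decline with age, floored
  above 1, hip > vertebral > other;
* general-population fracture incidence: exponential-in-age rates per site
  (hip rising ~10-fold from 55 to 85, vertebral comparable, wrist flatter),
  scaled so the untreated base-case cohort sustains on the order of 1–2
  fractures per patient over a lifetime;
* mean population T-score: linear decline with age (~ −0.9 at 65 to −1.8
  at 85).

Generation is deterministic given the seed (the default tables use fixed
analytic forms; the seed is threaded through for interface stability and for
bundle reproducibility checks).
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Dict

import yaml

from .params import (
    IncidenceTable,
    MortalityTable,
    ParameterSet,
    _default_tables,
)
from .states import SITES

#: Gompertz–Makeham parameters (ASSUMED): background rate, level, slope per year
_GM_A = 2.0e-4
_GM_B = 1.7e-5
_GM_C = 0.095

#: post-fracture mortality RR at age 50 and per-year decline (ASSUMED)
_MORT_RR = {
    "hip": (4.5, 0.030, 1.5),       # (RR at 50, decline/yr, floor)
    "vertebral": (3.4, 0.025, 1.3),
    "other": (2.2, 0.015, 1.1),
}

#: general-population fracture rates per person-year at age 72 and exponential
#: age slope per year (ASSUMED; calibrated to an untreated lifetime burden of
#: order 1 fracture/patient with a hip/vertebral-dominated site mix)
_INCIDENCE = {
    "hip": (0.0056, 0.077),
    "vertebral": (0.0060, 0.055),
    "wrist": (0.0118, 0.015),
    "other": (0.0098, 0.030),
}

#: mean population T-score: value at 65 and decline per year (ASSUMED)
_TSCORE_AT_65 = -0.9
_TSCORE_SLOPE = 0.045


def gen_mortality_dict(seed: int = 0, max_age: int = 110) -> Dict:
    q = {}
    for age in range(50, max_age + 1):
        q[float(age)] = min(1.0, _GM_A + _GM_B * math.exp(_GM_C * age))
    q[float(max_age)] = 1.0  # forced terminal
    rr = {
        site: {
            float(age): max(floor, rr50 - slope * (age - 50))
            for age in range(50, max_age + 1, 5)
        }
        for site, (rr50, slope, floor) in _MORT_RR.items()
    }
    return {"q_female": q, "rr_post_fracture": rr}


def gen_incidence_dict(seed: int = 0, max_age: int = 110) -> Dict:
    rates = {
        site: {
            float(age): r72 * math.exp(slope * (age - 72))
            for age in range(50, max_age + 1)
        }
        for site, (r72, slope) in _INCIDENCE.items()
    }
    return {"rates": rates}


def gen_tscore_dict(seed: int = 0, max_age: int = 110) -> Dict[float, float]:
    return {
        float(age): _TSCORE_AT_65 - _TSCORE_SLOPE * (age - 65)
        for age in range(50, max_age + 1)
    }


def gen_life_table(seed: int = 0, max_age: int = 110) -> MortalityTable:
    """Synthetic female life table plus post-fracture mortality RRs."""
    d = gen_mortality_dict(seed, max_age)
    t = MortalityTable(q_female=d["q_female"], rr_post_fracture=d["rr_post_fracture"])
    t.validate()
    return t


def gen_incidence_table(seed: int = 0) -> IncidenceTable:
    """Synthetic site- and age-specific general-population fracture rates."""
    t = IncidenceTable(rates=gen_incidence_dict(seed)["rates"])
    t.validate()
    return t


def gen_population_tscore(seed: int = 0) -> Dict[float, float]:
    """Synthetic mean female population T-score by age."""
    return gen_tscore_dict(seed)


def life_expectancy(q_female: Dict[float, float], age: float) -> float:
    """Remaining life expectancy by direct survival-product summation."""
    ages = sorted(a for a in q_female if a >= age)
    surv = 1.0
    le = 0.0
    for a in ages:
        q = q_female[a]
        le += surv * (1 - q / 2)  # deaths mid-year on average
        surv *= 1 - q
        if surv <= 0:
            break
    return le


_BANNER = "# ASSUMED — synthetic stand-in, not transcribed from any source\n"


def gen_bundle(seed: int, out_dir: str | Path) -> Path:
    """Write a complete parameter bundle (YAML manifest + CSV tables).

    The manifest carries the published point estimates verbatim; the CSV
    tables are the synthetic stand-ins, each flagged with an ASSUMED banner.
    Returns the manifest path.  Byte-identical for identical seeds.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    mort = gen_mortality_dict(seed)
    inc = gen_incidence_dict(seed)
    tsc = gen_tscore_dict(seed)

    with open(out / "life_table.csv", "w") as fh:
        fh.write(_BANNER)
        fh.write("age,q\n")
        for age in sorted(mort["q_female"]):
            fh.write(f"{age:g},{mort['q_female'][age]:.17g}\n")
    with open(out / "mortality_rr.csv", "w") as fh:
        fh.write(_BANNER)
        fh.write("age,hip,vertebral,other\n")
        ages = sorted(mort["rr_post_fracture"]["hip"])
        for age in ages:
            row = ",".join(
                f"{mort['rr_post_fracture'][s][age]:.17g}" for s in ("hip", "vertebral", "other")
            )
            fh.write(f"{age:g},{row}\n")
    with open(out / "incidence.csv", "w") as fh:
        fh.write(_BANNER)
        fh.write("age," + ",".join(SITES) + "\n")
        for age in sorted(inc["rates"]["hip"]):
            row = ",".join(f"{inc['rates'][s][age]:.17g}" for s in SITES)
            fh.write(f"{age:g},{row}\n")
    with open(out / "tscore.csv", "w") as fh:
        fh.write(_BANNER)
        fh.write("age,mean_tscore\n")
        for age in sorted(tsc):
            fh.write(f"{age:g},{tsc[age]:.17g}\n")

    manifest = _default_tables()
    # tables are shipped as CSV files, not inline
    del manifest["mortality"]
    del manifest["incidence"]
    manifest["relative_risks"]["mean_pop_tscore"] = {}
    manifest["relative_risks"].pop("mean_pop_tscore")
    manifest["tables"] = {
        "life_table": "life_table.csv",
        "mortality_rr": "mortality_rr.csv",
        "incidence": "incidence.csv",
        "tscore": "tscore.csv",
    }
    manifest_path = out / "manifest.yaml"
    with open(manifest_path, "w") as fh:
        fh.write(_BANNER)
        yaml.safe_dump(manifest, fh, sort_keys=True)
    return manifest_path
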