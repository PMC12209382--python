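"""Treatment persistence: observed curves, extrapolation and cycle timing.

Observed persistence is reported at 6-month marks over 36 months.  Beyond the
observed window the curve is extrapolated geometrically with a per-6-month
retention ratio chosen by method:

* ``last_value`` / ``last_interval_rate`` — hold the final observed interval's
  retention ratio constant (on a 0–36-month dataset the two published framings
  coincide; both names are accepted);
* ``overall_rate`` — the constant per-interval ratio implied by the 36-month
  value, i.e. ``p(36) ** (1/6)``.

Two cycle-timing conventions are supported: the persistent fraction for a
6-monthly injectable is evaluated at the cycle start (aligned with
administration), while a weekly oral is evaluated at the cycle midpoint,
linearly interpolated between adjacent observations.
"""

from __future__ import annotations

from .params import PersistenceCurve


def _observed_points(curve: PersistenceCurve):
    months = sorted(curve.observed)
    return months, [curve.observed[m] for m in months]


def extrapolation_ratio(curve: PersistenceCurve) -> float:
    """Per-6-month retention ratio applied beyond the observed window."""
    months, vals = _observed_points(curve)
    last = vals[-1]
    if curve.extrapolation in ("last_value", "last_interval_rate"):
        if len(vals) < 2:
            return 1.0
        prev = vals[-2]
        return last / prev if prev > 0 else 0.0
    if curve.extrapolation == "overall_rate":
        n_intervals = (months[-1] - months[0]) / 6.0
        return last ** (1.0 / n_intervals) if n_intervals > 0 else 1.0
    raise ValueError(f"unknown extrapolation method {curve.extrapolation!r}")


def persistence_at(curve: PersistenceCurve, month: float, interpolate: bool = False) -> float:
    """Proportion persistent at a given month on treatment.

    Within the observed window: the step value at the largest observed mark
    <= month, or a linear interpolation when ``interpolate`` is set.  Beyond
    the window: geometric decay at the method's retention ratio (stepwise per
    6 months, or continuously when interpolating).
    """
    if month < 0:
        raise ValueError(f"month must be >= 0, got {month}")
    months, vals = _observed_points(curve)
    last_m, last_v = months[-1], vals[-1]
    if month > last_m:
        ratio = extrapolation_ratio(curve)
        k = (month - last_m) / 6.0
        if not interpolate:
            k = int(k)  # step at 6-month marks
        return last_v * ratio**k
    if not interpolate:
        lo = max(m for m in months if m <= month)
        return curve.observed[lo]
    import bisect

    i = bisect.bisect_right(months, month) - 1
    if months[i] == month or i == len(months) - 1:
        return vals[i]
    m0, m1 = months[i], months[i + 1]
    w = (month - m0) / (m1 - m0)
    return vals[i] * (1 - w) + vals[i + 1] * w


def cycle_persistent_fraction(
    curve: PersistenceCurve, timing: str, months_on_at_cycle_start: float
) -> float:
    """Persistent fraction applied during a cycle of an on-treatment segment.

    ``timing`` is ``cycle_start`` (6-monthly administration) or ``midpoint``
    (weekly oral, evaluated 3 months into the cycle with linear
    interpolation).
    """
    if timing == "cycle_start":
        return persistence_at(curve, months_on_at_cycle_start)
    if timing == "midpoint":
        return persistence_at(curve, months_on_at_cycle_start + 3.0, interpolate=True)
    raise ValueError(f"unknown persistence timing {timing!r}")


def discontinuation_flow(
    curve: PersistenceCurve, cycle_index: int, timing: str = "cycle_start"
) -> float:
    """Proportion of the initial cohort newly discontinuing at a given cycle
    of an uninterrupted on-treatment timeline.

    Flow at cycle k is persistent(k-1) − persistent(k); each flow spawns a
    discontinuation stratum carrying its own time-on-treatment clock.
    """
    if cycle_index < 0:
        raise ValueError("cycle_index must be >= 0")
    if cycle_index == 0:
        g_prev = 1.0
    else:
        g_prev = cycle_persistent_fraction(curve, timing, 6.0 * (cycle_index - 1))
    g_now = cycle_persistent_fraction(curve, timing, 6.0 * cycle_index)
    flow = g_prev - g_now
    if flow < -1e-12:
        raise ValueError("persistence curve must be nonincreasing")
    return max(flow, 0.0)
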