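"""Independent brute-force re-implementation of the response definitions.

Deliberately written as plain loops over (day, relative-volume) pairs,
without importing the package's classification code, so the two routes can
be compared exhaustively. Keep this file dumb: clarity over speed.
"""

from __future__ import annotations

PD_LEVEL = 1.20
PR_LEVEL = 0.70


def oracle_eval_point(days, rel, target, window=3):
    """Nearest point within ±window (ties to the earlier day), else linear
    interpolation between bracketing points, else None."""
    candidates = [(abs(d - target), d, r) for d, r in zip(days, rel)
                  if abs(d - target) <= window]
    if candidates:
        _, d, r = min(candidates)  # tuple order: distance, then earlier day
        return d, r
    before = [(d, r) for d, r in zip(days, rel) if d < target]
    after = [(d, r) for d, r in zip(days, rel) if d > target]
    if before and after:
        d0, r0 = before[-1]
        d1, r1 = after[0]
        return target, r0 + (r1 - r0) * (target - d0) / (d1 - d0)
    return None


def oracle_confirmed_pd_day(days, rel, last_day=None):
    """Second day of the first consecutive pair both at/above +20%."""
    for i in range(len(days) - 1):
        if last_day is not None and days[i + 1] > last_day:
            return None
        if rel[i] >= PD_LEVEL and rel[i + 1] >= PD_LEVEL:
            return days[i + 1]
    return None


def oracle_classify(days, rel, baseline_volume, eval_day, cr_volume=0.0):
    """CR / PR / SD / PD per the printed definitions; None if unevaluable."""
    point = oracle_eval_point(days, rel, eval_day)
    pd_day = oracle_confirmed_pd_day(days, rel, last_day=eval_day)
    if point is None:
        return ("PD", pd_day) if pd_day is not None else None
    _, value = point
    if value * baseline_volume <= cr_volume:
        return ("CR", None)
    if pd_day is not None:
        return ("PD", pd_day)
    if value <= PR_LEVEL:
        return ("PR", None)
    return ("SD", None)


def oracle_resistance(days, rel, baseline_volume, eval_day, follow_up_end):
    call = oracle_classify(days, rel, baseline_volume, eval_day)
    if call is None:
        return None
    category, _ = call
    if category == "PD":
        return ("primary", None)
    if category in ("SD", "PR"):
        pd_day = oracle_confirmed_pd_day(days, rel, last_day=follow_up_end)
        if pd_day is not None and pd_day > eval_day:
            return ("secondary", pd_day)
    return ("none", None)


def oracle_ttp(days, rel, end_of_study):
    pd_day = oracle_confirmed_pd_day(days, rel)
    if pd_day is not None and pd_day <= end_of_study:
        return pd_day, False
    return end_of_study, True


def oracle_waterfall(days, rel, cutoff_day):
    eligible = [(d, r) for d, r in zip(days, rel) if d <= cutoff_day]
    if len(eligible) < 2:
        return None
    return 100.0 * (eligible[-1][1] - 1.0)
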