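"""Response grading, resistance detection, and arm-level aggregation.

The grading is a mouse-adapted RECIST analogue applied to baseline-relative
tumor volumes:

* **CR** — tumor undetectable at the evaluation day,
* **PR** — at least a 30% volume reduction at the evaluation day,
* **PD** — a ≥ 20% volume increase confirmed at two consecutive
  measurement days on or before the evaluation day,
* **SD** — everything else.

Progression must be confirmed at two consecutive caliper days so a single
noisy reading cannot trigger a PD call. *Primary* resistance is PD within
the initial 28-day treatment period; *secondary* resistance (SR) is
progression after initial disease control (SD or PR at day 28).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from fractions import Fraction
from typing import Iterable, Sequence

import numpy as np

from .config import ResponseThresholds
from .cohort import TumorCourse
from .growth import EvaluationError, RelativeGrowthCurve, relative_curve, value_at_day

logger = logging.getLogger(__name__)

CATEGORIES = ("CR", "PR", "SD", "PD")


@dataclass(frozen=True)
class ResponseCall:
    """Categorical response of one tumor or model-mean curve at one day."""

    subject: str
    basis: str  # "tumor" or "model_mean"
    evaluation_day: int
    category: str
    relative_change: float
    day_used: int
    pd_onset_day: int | None = None

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")
        if self.category == "PD" and self.pd_onset_day is None:
            raise ValueError("PD call requires pd_onset_day")


@dataclass(frozen=True)
class ResistanceCall:
    """Resistance status of one subject over the follow-up period."""

    subject: str
    kind: str  # "none", "primary", "secondary"
    sr_onset_day: int | None = None


@dataclass
class ArmSummary:
    """Category counts for one arm at one evaluation day."""

    arm: str
    evaluation_day: int
    counts: dict[str, int]
    n: int

    @property
    def disease_control_rate(self) -> Fraction:
        controlled = sum(self.counts.get(c, 0) for c in ("CR", "PR", "SD"))
        return Fraction(controlled, self.n)

    def fraction(self, *categories: str) -> Fraction:
        return Fraction(sum(self.counts.get(c, 0) for c in categories), self.n)

    def percent_display(self, *categories: str) -> int:
        """Percentage rounded to the nearest integer, halves away from zero."""
        return round_half_away(100.0 * float(self.fraction(*categories)))


def round_half_away(x: float) -> int:
    import math

    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def _curve_basis(curve: RelativeGrowthCurve) -> str:
    return "model_mean" if np.any(curve.n_at_day > 1) else "tumor"


def _confirmed_pd_onset(curve: RelativeGrowthCurve, pd_level: float,
                        last_day: int | None, confirm: bool = True) -> int | None:
    """First day at which progression is established.

    With confirmation (default) this is the second of the first pair of
    consecutive measurement days both at or above ``pd_level``; without,
    the first single day at or above it. ``last_day`` bounds the search.
    """
    rel = curve.relative_volume
    days = curve.days
    if confirm:
        for i in range(len(days) - 1):
            if last_day is not None and days[i + 1] > last_day:
                break
            if rel[i] >= pd_level and rel[i + 1] >= pd_level:
                return int(days[i + 1])
    else:
        for i in range(len(days)):
            if last_day is not None and days[i] > last_day:
                break
            if rel[i] >= pd_level:
                return int(days[i])
    return None


def classify(curve: RelativeGrowthCurve, evaluation_day: int,
             thresholds: ResponseThresholds | None = None) -> ResponseCall:
    """Grade a relative growth curve at an evaluation day.

    Precedence: CR (undetectable at evaluation), then PD (confirmed ≥ +20%
    on/before the evaluation day), then PR (≤ −30% at evaluation), else SD.
    An unevaluable curve raises :class:`EvaluationError` rather than
    silently defaulting to SD.
    """
    th = thresholds or ResponseThresholds()
    try:
        day_used, rel_eval = value_at_day(curve, evaluation_day, th.eval_window_days)
    except EvaluationError:
        # A course ending early (size-limit removal) with progression already
        # confirmed is PD even without a reading near the evaluation day.
        onset = _confirmed_pd_onset(curve, 1.0 + th.pd_increase, evaluation_day)
        if onset is None:
            raise
        last = int(np.nonzero(curve.days <= evaluation_day)[0][-1])
        return ResponseCall(
            subject=curve.subject, basis=_curve_basis(curve),
            evaluation_day=evaluation_day, category="PD",
            relative_change=float(curve.relative_volume[last]) - 1.0,
            day_used=int(curve.days[last]), pd_onset_day=onset,
        )
    change = rel_eval - 1.0
    basis = _curve_basis(curve)
    if rel_eval * curve.baseline_volume_mm3 <= th.cr_volume_mm3:
        category, onset = "CR", None
    else:
        onset = _confirmed_pd_onset(curve, 1.0 + th.pd_increase, evaluation_day)
        if onset is not None:
            category = "PD"
        elif change <= th.pr_decrease:
            category, onset = "PR", None
        else:
            category, onset = "SD", None
    return ResponseCall(
        subject=curve.subject,
        basis=basis,
        evaluation_day=evaluation_day,
        category=category,
        relative_change=change,
        day_used=day_used,
        pd_onset_day=onset,
    )


def detect_resistance(curve: RelativeGrowthCurve, day28_call: ResponseCall,
                      follow_up_end: int,
                      thresholds: ResponseThresholds | None = None,
                      confirm: bool = True) -> ResistanceCall:
    """Classify resistance over the follow-up period.

    Primary resistance is a PD call at the initial evaluation. Secondary
    resistance requires initial disease control (SD or PR at day 28)
    followed by progression — the same confirmed ≥ +20% criterion —
    established at some day in (28, ``follow_up_end``]. ``confirm=False``
    switches to a strict single-reading progression rule.
    """
    th = thresholds or ResponseThresholds()
    eval_day = day28_call.evaluation_day
    if follow_up_end <= eval_day:
        raise ValueError(f"follow_up_end must exceed {eval_day}, got {follow_up_end}")
    if day28_call.category == "PD":
        return ResistanceCall(subject=curve.subject, kind="primary")
    if day28_call.category in ("SD", "PR"):
        onset = _confirmed_pd_onset(curve, 1.0 + th.pd_increase, follow_up_end, confirm)
        if onset is not None and onset > eval_day:
            return ResistanceCall(subject=curve.subject, kind="secondary",
                                  sr_onset_day=onset)
    return ResistanceCall(subject=curve.subject, kind="none")


def time_to_progression(curve: RelativeGrowthCurve, end_of_study: int,
                        thresholds: ResponseThresholds | None = None
                        ) -> tuple[int, bool]:
    """Days to first confirmed progression, censored at end of study.

    Returns ``(day, censored)``: the first day at which the confirmed
    ≥ +20% criterion is met, or ``(end_of_study, True)`` for a tumor still
    responding at the end of observation.
    """
    th = thresholds or ResponseThresholds()
    onset = _confirmed_pd_onset(curve, 1.0 + th.pd_increase, None)
    if onset is not None and onset <= end_of_study:
        return onset, False
    return end_of_study, True


def waterfall_values(courses: Sequence[TumorCourse], cutoff_day: int = 59
                     ) -> list[tuple[str, float]]:
    """Per-tumor percent volume change for a waterfall plot.

    Uses the last measurement at or before ``cutoff_day`` (the end of the
    experiment or day 59, whichever comes first). Tumors with only a
    baseline reading are excluded with a warning.
    """
    out: list[tuple[str, float]] = []
    for course in courses:
        curve = relative_curve(course)
        eligible = np.nonzero(curve.days <= cutoff_day)[0]
        if eligible.size < 2:
            logger.warning("tumor %s: no post-baseline measurement at/before day %d; "
                           "excluded from waterfall", course.tumor_id, cutoff_day)
            continue
        last = int(eligible[-1])
        out.append((course.tumor_id, 100.0 * (float(curve.relative_volume[last]) - 1.0)))
    return out


def aggregate_arm(calls: Iterable[ResponseCall] | Iterable[str], arm: str = "",
                  evaluation_day: int | None = None) -> ArmSummary:
    """Tally category counts and the disease-control rate for one arm.

    Accepts either :class:`ResponseCall` objects (which must share an
    evaluation day) or bare category strings from a published summary
    column, where ``SR`` counts as progression and ``missing`` cells are
    dropped rather than imputed.
    """
    calls = list(calls)
    if not calls:
        raise ValueError("aggregate_arm: empty call list")
    categories: list[str] = []
    if isinstance(calls[0], ResponseCall):
        days = {c.evaluation_day for c in calls}  # type: ignore[union-attr]
        if len(days) > 1:
            raise ValueError(f"mixed evaluation days: {sorted(days)}")
        evaluation_day = calls[0].evaluation_day  # type: ignore[union-attr]
        categories = [c.category for c in calls]  # type: ignore[union-attr]
    else:
        for c in calls:
            if c == "missing":
                continue
            categories.append("PD" if c == "SR" else str(c))
        if not categories:
            raise ValueError("aggregate_arm: all calls missing")
    counts = {cat: categories.count(cat) for cat in CATEGORIES if categories.count(cat)}
    unknown = set(categories) - set(CATEGORIES)
    if unknown:
        raise ValueError(f"unknown categories {sorted(unknown)}")
    return ArmSummary(arm=arm, evaluation_day=evaluation_day or 0,
                      counts=counts, n=len(categories))
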