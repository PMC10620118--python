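"""Volume computation and baseline-relative growth curves.

Tumor volume follows the standard two-dimensional caliper estimate
V = L·W²/2 (mm³). Growth curves are expressed relative to the volume at
treatment start (day 0); model-level curves average the relative volumes of
all tumors still on study at each measurement day and carry SEM error bars.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .cohort import TumorCourse

#: Baseline search window: day 0 preferred, else latest day in [-3, 0].
BASELINE_WINDOW_DAYS = 3


class EvaluationError(ValueError):
    """A curve cannot be evaluated at the requested day."""


def volume_from_caliper(length_mm: float, width_mm: float) -> float:
    """Tumor volume in mm³ from a two-dimensional caliper reading.

    V = length × width² / 2, the standard ellipsoid approximation for
    subcutaneous xenografts. Both dimensions must be positive; the formula
    is evaluated as given (canonicalize length ≥ width upstream if the
    orientation convention matters).
    """
    if length_mm <= 0 or width_mm <= 0:
        raise ValueError(f"caliper dimensions must be > 0, got ({length_mm}, {width_mm})")
    return length_mm * width_mm * width_mm / 2.0


@dataclass
class RelativeGrowthCurve:
    """Volume series normalized to the baseline at treatment start.

    For single-tumor curves ``n_at_day`` is all ones and ``sem_at_day`` all
    zeros; model-mean curves record the per-day number of contributing
    tumors (non-increasing once removals begin) and the standard error of
    the mean (sample SD / √n; reported as 0 when n = 1).
    """

    subject: str
    days: np.ndarray
    relative_volume: np.ndarray
    baseline_volume_mm3: float
    n_at_day: np.ndarray = field(default=None)  # type: ignore[assignment]
    sem_at_day: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.days = np.asarray(self.days, dtype=int)
        self.relative_volume = np.asarray(self.relative_volume, dtype=float)
        if self.days.shape != self.relative_volume.shape:
            raise ValueError("days and relative_volume must align")
        if np.any(np.diff(self.days) <= 0):
            raise ValueError("days must be strictly increasing")
        if self.n_at_day is None:
            self.n_at_day = np.ones_like(self.days)
        if self.sem_at_day is None:
            self.sem_at_day = np.zeros_like(self.relative_volume)

    def __len__(self) -> int:
        return len(self.days)

    def volume_mm3(self) -> np.ndarray:
        """Absolute volumes, undoing the baseline normalization."""
        return self.relative_volume * self.baseline_volume_mm3


def _course_volumes(course: TumorCourse) -> tuple[np.ndarray, np.ndarray]:
    days = np.array(course.days, dtype=int)
    vols = np.array(
        [volume_from_caliper(m.length_mm, m.width_mm) for m in course.measurements]
    )
    return days, vols


def _baseline_index(days: np.ndarray, baseline_day: int, tumor_id: str) -> int:
    exact = np.nonzero(days == baseline_day)[0]
    if exact.size:
        return int(exact[0])
    window = np.nonzero(
        (days >= baseline_day - BASELINE_WINDOW_DAYS) & (days < baseline_day)
    )[0]
    if window.size:
        return int(window[-1])  # latest pre-treatment reading
    raise EvaluationError(
        f"tumor {tumor_id}: no baseline measurement at day {baseline_day} or in "
        f"[{baseline_day - BASELINE_WINDOW_DAYS}, {baseline_day}]"
    )


def relative_curve(course: TumorCourse, baseline_day: int = 0) -> RelativeGrowthCurve:
    """Normalize one tumor's volumes to its treatment-start baseline.

    The baseline is the day-0 measurement, or failing that the latest
    reading within 3 days before treatment start (enrollment precedes the
    first dose by at most a few days). The baseline point is exactly 1.0.
    """
    if not course.measurements:
        raise EvaluationError(f"tumor {course.tumor_id}: empty course")
    days, vols = _course_volumes(course)
    b = _baseline_index(days, baseline_day, course.tumor_id)
    baseline = vols[b]
    if baseline <= 0:
        raise EvaluationError(f"tumor {course.tumor_id}: nonpositive baseline volume")
    rel = vols / baseline
    rel[b] = 1.0
    return RelativeGrowthCurve(
        subject=course.tumor_id,
        days=days,
        relative_volume=rel,
        baseline_volume_mm3=float(baseline),
    )


def model_mean_curve(courses: list[TumorCourse], baseline_day: int = 0) -> RelativeGrowthCurve:
    """Mean relative growth curve over the tumors of one model and arm.

    Relative volumes are grouped by exact measurement day (the caliper
    schedule is a shared twice-weekly grid; no smoothing or interpolation).
    A removed tumor contributes through its removal day and then drops out
    of the mean — complete-case per day, no carry-forward. SEM uses the
    n−1 sample SD and is reported as 0 where only one tumor remains.
    """
    if not courses:
        raise ValueError("model_mean_curve requires at least one course")
    per_day: dict[int, list[float]] = {}
    baselines = []
    for course in courses:
        curve = relative_curve(course, baseline_day)
        baselines.append(curve.baseline_volume_mm3)
        for day, rel in zip(curve.days, curve.relative_volume):
            per_day.setdefault(int(day), []).append(float(rel))
    days = np.array(sorted(per_day), dtype=int)
    means = np.array([np.mean(per_day[d]) for d in days])
    ns = np.array([len(per_day[d]) for d in days])
    sems = np.array([
        np.std(per_day[d], ddof=1) / math.sqrt(len(per_day[d])) if len(per_day[d]) > 1 else 0.0
        for d in days
    ])
    model_id = courses[0].model_id
    arm = courses[0].arm
    return RelativeGrowthCurve(
        subject=f"{model_id}:{arm}",
        days=days,
        relative_volume=means,
        baseline_volume_mm3=float(np.mean(baselines)),
        n_at_day=ns,
        sem_at_day=sems,
    )


def value_at_day(curve: RelativeGrowthCurve, target_day: int,
                 window: int = 3) -> tuple[int, float]:
    """Relative volume at (or near) a target day.

    Caliper days rarely hit the evaluation day exactly, so the measured
    point nearest ``target_day`` within ±``window`` days is used, ties
    broken toward the earlier day. With no point in the window the value is
    linearly interpolated between the bracketing measurements; with no
    bracket either, the curve is unevaluable.
    """
    if len(curve) == 0:
        raise EvaluationError(f"{curve.subject}: empty curve")
    days = curve.days
    dist = np.abs(days - target_day)
    in_window = np.nonzero(dist <= window)[0]
    if in_window.size:
        best = min(in_window, key=lambda i: (dist[i], days[i]))
        return int(days[best]), float(curve.relative_volume[best])
    before = np.nonzero(days < target_day)[0]
    after = np.nonzero(days > target_day)[0]
    if before.size and after.size:
        i, j = int(before[-1]), int(after[0])
        x0, x1 = days[i], days[j]
        y0, y1 = curve.relative_volume[i], curve.relative_volume[j]
        value = y0 + (y1 - y0) * (target_day - x0) / (x1 - x0)
        return target_day, float(value)
    raise EvaluationError(
        f"{curve.subject}: no measurement within ±{window} days of day "
        f"{target_day} and no bracketing points to interpolate"
    )
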