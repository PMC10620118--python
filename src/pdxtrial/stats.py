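"""Arm-vs-arm inference and trial-level summaries."""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import stats as sps

from .cohort import ModelCohort
from .config import ResponseThresholds
from .growth import model_mean_curve, relative_curve
from .response import (
    ArmSummary,
    ResistanceCall,
    ResponseCall,
    aggregate_arm,
    classify,
    detect_resistance,
    time_to_progression,
)


@dataclass(frozen=True)
class ComparisonResult:
    """Two-sample comparison of relative volumes at one day."""

    day: int
    arm_a: str
    arm_b: str
    t_statistic: float
    p_value: float
    stars: str
    n_a: int
    n_b: int

    @property
    def significant(self) -> bool:
        return self.p_value < 0.05


def significance_stars(p: float) -> str:
    """Figure-legend convention: * p<0.05, ** p<0.01, *** p<0.001."""
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p-value out of range: {p}")
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def compare_arms(group_a: Sequence[float], group_b: Sequence[float],
                 day: int = 0, arm_a: str = "a", arm_b: str = "b",
                 welch: bool = False) -> ComparisonResult:
    """Two-sided unpaired Student's t-test between two arms' relative volumes.

    Pooled (equal-variance) by default; ``welch=True`` drops the
    equal-variance assumption. Each group needs at least two observations.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs n >= 2")
    t, p = sps.ttest_ind(a, b, equal_var=not welch)
    # identical groups: scipy reports nan; by convention no difference
    if np.isnan(t):
        t, p = 0.0, 1.0
    return ComparisonResult(day=day, arm_a=arm_a, arm_b=arm_b,
                            t_statistic=float(t), p_value=float(p),
                            stars=significance_stars(float(p)),
                            n_a=len(a), n_b=len(b))


def model_calls(cohorts: Sequence[ModelCohort], arm: str, evaluation_day: int,
                thresholds: ResponseThresholds | None = None
                ) -> list[ResponseCall]:
    """Model-level calls (mean curve over the arm's tumors) for each model."""
    calls = []
    for cohort in cohorts:
        courses = cohort.arm(arm)
        if not courses:
            continue
        curve = model_mean_curve(courses)
        calls.append(classify(curve, evaluation_day, thresholds))
    return calls


def tumor_resistance(cohorts: Sequence[ModelCohort], arm: str,
                     evaluation_day: int = 28, follow_up_end: int = 59,
                     thresholds: ResponseThresholds | None = None
                     ) -> list[ResistanceCall]:
    """Per-tumor resistance calls over the follow-up period."""
    out = []
    for cohort in cohorts:
        for course in cohort.arm(arm):
            curve = relative_curve(course)
            try:
                day28 = classify(curve, evaluation_day, thresholds)
            except Exception:
                continue
            out.append(detect_resistance(curve, day28, follow_up_end, thresholds))
    return out


def trial_report(cohorts: Sequence[ModelCohort], arm: str = "combination",
                 evaluation_days: tuple[int, int] = (28, 59),
                 end_of_study: int = 59,
                 thresholds: ResponseThresholds | None = None) -> dict:
    """Structured trial summary: arm tallies, per-model TTP, SR tumor list.

    Returns a JSON-serializable dict; render with :func:`format_report` or
    dump with :func:`write_report`.
    """
    report: dict = {"arm": arm, "n_models": 0, "arms": {}, "ttp": [], "sr_tumors": []}
    summaries: dict[int, ArmSummary] = {}
    for day in evaluation_days:
        calls = model_calls(cohorts, arm, day, thresholds)
        if not calls:
            continue
        summary = aggregate_arm(calls, arm=arm)
        summaries[day] = summary
        report["arms"][str(day)] = {
            "counts": summary.counts,
            "n": summary.n,
            "disease_control_rate": float(summary.disease_control_rate),
            "disease_control_percent": summary.percent_display("CR", "PR", "SD"),
        }
        report["n_models"] = summary.n
    for cohort in cohorts:
        courses = cohort.arm(arm)
        if not courses:
            continue
        curve = model_mean_curve(courses)
        days_to_pd, censored = time_to_progression(curve, end_of_study, thresholds)
        report["ttp"].append({"model_id": cohort.model_id,
                              "days": days_to_pd, "censored": censored})
    for call in tumor_resistance(cohorts, arm, evaluation_days[0],
                                 end_of_study, thresholds):
        if call.kind == "secondary":
            report["sr_tumors"].append({"tumor_id": call.subject,
                                        "sr_onset_day": call.sr_onset_day})
    return report


def format_report(report: dict) -> str:
    """Human-readable rendering of a trial report."""
    lines = [f"Trial summary — arm: {report['arm']} ({report['n_models']} models)"]
    for day, arm in sorted(report["arms"].items(), key=lambda kv: int(kv[0])):
        counts = ", ".join(f"{c} {n}" for c, n in sorted(arm["counts"].items()))
        lines.append(
            f"  day {day}: {counts}; disease control "
            f"{arm['disease_control_percent']}% "
            f"({round(arm['disease_control_rate'] * arm['n'])}/{arm['n']})"
        )
    censored = sum(1 for t in report["ttp"] if t["censored"])
    if report["ttp"]:
        lines.append(f"  time to progression: {len(report['ttp'])} models, "
                     f"{censored} still responding at end of study")
    lines.append(f"  secondary-resistant tumors: {len(report['sr_tumors'])}")
    return "\n".join(lines)


def write_report(report: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(report, indent=2) + "\n")
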