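"""Trial data model and delimited-text I/O.

The unit of observation is a single caliper measurement of one subcutaneous
tumor; tumors belong to a PDX model (all xenografts derived from one
patient's tumor) and are assigned to a treatment arm. Files are plain CSV
with a header; see :data:`MEASUREMENT_COLUMNS`.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

MEASUREMENT_COLUMNS = ("tumor_id", "model_id", "arm", "day", "length_mm", "width_mm")
REMOVAL_REASONS = ("max_size", "health", "end_of_study")

#: Response categories as they appear in published model-level summaries.
#: ``SR`` (secondary resistance) occurs only as a day-59 follow-up label;
#: ``missing`` marks models whose observation ended before the evaluation day.
FIXTURE_CATEGORIES = ("CR", "PR", "SD", "PD", "SR", "missing")


class SchemaError(ValueError):
    """A required column is absent or a cell cannot be parsed."""


@dataclass(frozen=True)
class CaliperMeasurement:
    """One two-dimensional caliper reading of one tumor.

    Day 0 is treatment start; negative days are pre-enrollment readings.
    Calipers are orientation-agnostic, so length/width are canonicalized
    to length ≥ width on construction.
    """

    tumor_id: str
    day: int
    length_mm: float
    width_mm: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "day", int(self.day))
        object.__setattr__(self, "length_mm", float(self.length_mm))
        object.__setattr__(self, "width_mm", float(self.width_mm))
        if self.length_mm <= 0 or self.width_mm <= 0:
            raise ValueError(
                f"caliper dimensions must be positive, got "
                f"({self.length_mm}, {self.width_mm}) for {self.tumor_id}"
            )
        if self.width_mm > self.length_mm:
            longer, shorter = self.width_mm, self.length_mm
            object.__setattr__(self, "length_mm", longer)
            object.__setattr__(self, "width_mm", shorter)


@dataclass
class TumorCourse:
    """Ordered measurement series for one tumor.

    ``removal_day`` marks a tumor taken off study early (size limit or
    animal health); measurements never extend past it.
    """

    tumor_id: str
    model_id: str
    arm: str
    measurements: list[CaliperMeasurement] = field(default_factory=list)
    removal_day: int | None = None
    removal_reason: str | None = None

    def __post_init__(self) -> None:
        self.measurements = sorted(self.measurements, key=lambda m: m.day)
        days = [m.day for m in self.measurements]
        if len(set(days)) != len(days):
            dupes = sorted({d for d in days if days.count(d) > 1})
            raise ValueError(f"duplicate measurement days {dupes} for tumor {self.tumor_id}")
        if self.removal_reason is not None and self.removal_reason not in REMOVAL_REASONS:
            raise ValueError(f"unknown removal_reason {self.removal_reason!r}")
        if self.removal_day is not None and days and max(days) > self.removal_day:
            raise ValueError(
                f"tumor {self.tumor_id}: measurement at day {max(days)} "
                f"after removal_day {self.removal_day}"
            )

    @property
    def days(self) -> list[int]:
        return [m.day for m in self.measurements]


@dataclass
class ModelCohort:
    """All tumors of one PDX model, across arms."""

    model_id: str
    kras_variant: str = ""
    uicc_stage: str | None = None
    tumors: list[TumorCourse] = field(default_factory=list)

    def __post_init__(self) -> None:
        bad = [t.tumor_id for t in self.tumors if t.model_id != self.model_id]
        if bad:
            raise ValueError(f"tumors {bad} do not belong to model {self.model_id}")
        if not self.tumors:
            raise ValueError(f"model {self.model_id} has no tumors")

    def arm(self, name: str) -> list[TumorCourse]:
        return [t for t in self.tumors if t.arm == name]

    @property
    def arms(self) -> dict[str, list[TumorCourse]]:
        out: dict[str, list[TumorCourse]] = {}
        for t in self.tumors:
            out.setdefault(t.arm, []).append(t)
        return out


def _parse_row(row: dict, lineno: int) -> tuple[str, str, str, CaliperMeasurement]:
    try:
        day = int(row["day"])
        length = float(row["length_mm"])
        width = float(row["width_mm"])
    except (TypeError, ValueError) as exc:
        raise SchemaError(f"line {lineno}: non-numeric value ({exc})") from exc
    if width > length:
        logger.warning(
            "line %d: width %.3g > length %.3g for tumor %s; swapped",
            lineno, width, length, row["tumor_id"],
        )
    m = CaliperMeasurement(tumor_id=row["tumor_id"], day=day, length_mm=length, width_mm=width)
    return row["tumor_id"], row["model_id"], row["arm"], m


def read_measurements(path: str | Path, delimiter: str = ",") -> list[TumorCourse]:
    """Read a caliper-measurement table into tumor courses.

    The file must carry a header with at least the columns in
    :data:`MEASUREMENT_COLUMNS`; optional ``removal_day`` / ``removal_reason``
    columns are honored (constant per tumor). Width > length readings are
    swapped and logged. Duplicate (tumor, day) pairs are an error.
    """
    path = Path(path)
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh, delimiter=delimiter)
        header = reader.fieldnames or []
        missing = [c for c in MEASUREMENT_COLUMNS if c not in header]
        if missing:
            raise SchemaError(f"{path}: missing column(s) {missing}")
        has_removal = "removal_day" in header
        grouped: dict[str, dict] = {}
        for lineno, row in enumerate(reader, start=2):
            tumor_id, model_id, arm, m = _parse_row(row, lineno)
            rec = grouped.setdefault(
                tumor_id,
                {"model_id": model_id, "arm": arm, "measurements": [],
                 "removal_day": None, "removal_reason": None},
            )
            if any(prev.day == m.day for prev in rec["measurements"]):
                raise SchemaError(
                    f"line {lineno}: duplicate day {m.day} for tumor {tumor_id}"
                )
            rec["measurements"].append(m)
            if has_removal and row.get("removal_day") not in (None, "", "NA"):
                rec["removal_day"] = int(row["removal_day"])
                rec["removal_reason"] = row.get("removal_reason") or None
    return [
        TumorCourse(
            tumor_id=tid,
            model_id=rec["model_id"],
            arm=rec["arm"],
            measurements=rec["measurements"],
            removal_day=rec["removal_day"],
            removal_reason=rec["removal_reason"],
        )
        for tid, rec in grouped.items()
    ]


def write_measurements(courses: Iterable[TumorCourse], path: str | Path,
                       delimiter: str = ",") -> None:
    """Write tumor courses as a flat measurement CSV (inverse of reading)."""
    path = Path(path)
    cols = list(MEASUREMENT_COLUMNS) + ["removal_day", "removal_reason"]
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter=delimiter)
        writer.writerow(cols)
        for course in courses:
            for m in course.measurements:
                writer.writerow([
                    course.tumor_id, course.model_id, course.arm, m.day,
                    repr(m.length_mm), repr(m.width_mm),
                    "" if course.removal_day is None else course.removal_day,
                    course.removal_reason or "",
                ])


def write_cohort(cohorts: Sequence[ModelCohort], measurements_path: str | Path,
                 manifest_path: str | Path | None = None) -> None:
    """Write a cohort as a measurement CSV plus an optional model manifest."""
    courses = [t for c in cohorts for t in c.tumors]
    write_measurements(courses, measurements_path)
    if manifest_path is not None:
        with Path(manifest_path).open("w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["model_id", "kras", "uicc", "arm", "tumor_id",
                             "removal_day", "removal_reason"])
            for c in cohorts:
                for t in c.tumors:
                    writer.writerow([
                        c.model_id, c.kras_variant, c.uicc_stage or "", t.arm,
                        t.tumor_id,
                        "" if t.removal_day is None else t.removal_day,
                        t.removal_reason or "",
                    ])


def read_cohort(measurements_path: str | Path,
                manifest_path: str | Path | None = None) -> list[ModelCohort]:
    """Assemble model cohorts from a measurement CSV (+ optional manifest)."""
    courses = read_measurements(measurements_path)
    meta: dict[str, dict] = {}
    if manifest_path is not None:
        manifest = pd.read_csv(manifest_path, dtype=str).fillna("")
        for _, row in manifest.iterrows():
            meta[row["model_id"]] = {"kras": row.get("kras", ""),
                                     "uicc": row.get("uicc", "") or None}
    grouped: dict[str, list[TumorCourse]] = {}
    for course in courses:
        grouped.setdefault(course.model_id, []).append(course)
    return [
        ModelCohort(
            model_id=mid,
            kras_variant=meta.get(mid, {}).get("kras", ""),
            uicc_stage=meta.get(mid, {}).get("uicc"),
            tumors=ts,
        )
        for mid, ts in grouped.items()
    ]


def load_table1_fixture() -> pd.DataFrame:
    """Load the packaged model-level response summary of the 19-model trial.

    Columns: ``model_id``, ``uicc``, ``kras``, and the day-28/day-59 calls
    under the combination (``combo_d28``, ``combo_d59``) and under
    trametinib monotherapy (``tram_d28``, ``tram_d59``). Cells are one of
    CR/PR/SD/PD, ``SR`` (day-59 secondary resistance under monotherapy), or
    ``missing`` where observation ended before the evaluation day. Missing
    cells are never imputed.
    """
    with resources.files("pdxtrial.data").joinpath("table1.csv").open() as fh:
        df = pd.read_csv(fh, dtype=str)
    bad = set(df.iloc[:, 3:].to_numpy().ravel()) - set(FIXTURE_CATEGORIES)
    if bad or len(df) != 19:
        raise RuntimeError(f"packaged summary fixture is corrupt: {sorted(bad)}, n={len(df)}")
    return df


def rescale_course(course: TumorCourse, factor: float) -> TumorCourse:
    """Return a copy with every caliper reading scaled by ``factor**(1/3)``
    (so volumes scale by ``factor``); used in invariance checks."""
    cube = factor ** (1.0 / 3.0)
    return replace(
        course,
        measurements=[
            CaliperMeasurement(m.tumor_id, m.day, m.length_mm * cube, m.width_mm * cube)
            for m in course.measurements
        ],
    )
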