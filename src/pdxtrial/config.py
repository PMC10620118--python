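"""Run configuration: grading thresholds, protocol constants, I/O settings.

All thresholds are expressed as *relative volume change* from baseline
(e.g. ``+0.20`` means a 20% increase), except ``cr_volume_mm3`` which is an
absolute detectability cut-off in mm³.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml


@dataclass(frozen=True)
class ResponseThresholds:
    """Cut-offs for the mouse-adapted RECIST-like grading.

    pd_increase
        Relative increase defining progressive disease. Inclusive: a change
        of exactly +20% counts as PD. The boundary is configurable because
        published conventions disagree on whether +20% itself progresses.
    pr_decrease
        Relative decrease defining partial response (inclusive, ≤ −30%).
    cr_volume_mm3
        Absolute volume at or below which a tumor counts as undetectable
        (complete response). "Undetectable by inspection" has no numeric
        definition, so the default is a recorded volume of 0.
    eval_window_days
        Half-width of the search window around an evaluation day; with a
        twice-weekly caliper schedule a measurement always falls within
        3–4 days of any target day.
    """

    pd_increase: float = 0.20
    pr_decrease: float = -0.30
    cr_volume_mm3: float = 0.0
    eval_window_days: int = 3

    def __post_init__(self) -> None:
        if not 0.0 < self.pd_increase < 5.0:
            raise ValueError(f"pd_increase out of range: {self.pd_increase}")
        if not -1.0 < self.pr_decrease < 0.0:
            raise ValueError(f"pr_decrease out of range: {self.pr_decrease}")
        if self.cr_volume_mm3 < 0:
            raise ValueError("cr_volume_mm3 must be >= 0")
        if self.eval_window_days < 0:
            raise ValueError("eval_window_days must be >= 0")


@dataclass(frozen=True)
class ProtocolConfig:
    """Constants of the intermittent long-term treatment schedule.

    The schedule pauses dosing once a tumor has clearly responded and
    re-treats on regrowth: pause at partial response by day 59; resume when
    the tumor regrows to ``resume_threshold_mm3`` (the enrollment size);
    pause again after ``control_streak_days`` of disease control within a
    cycle; resume when the volume reaches ``doubling_factor`` times the
    volume at the end of the previous treatment cycle; at most
    ``max_cycles`` treatment cycles.
    """

    resume_threshold_mm3: float = 200.0
    doubling_factor: float = 2.0
    control_streak_days: int = 30
    max_cycles: int = 3
    pause_eval_day: int = 59

    def __post_init__(self) -> None:
        if self.resume_threshold_mm3 <= 0:
            raise ValueError("resume_threshold_mm3 must be > 0")
        if self.doubling_factor <= 1.0:
            raise ValueError("doubling_factor must exceed 1")
        if self.control_streak_days <= 0 or self.max_cycles < 1:
            raise ValueError("invalid protocol constants")


@dataclass
class RunConfig:
    """Top-level configuration for a pipeline run; round-trips to YAML."""

    measurements_path: str | None = None
    manifest_path: str | None = None
    output_dir: str = "results"
    seed: int = 0
    log_level: str = "INFO"
    thresholds: ResponseThresholds = field(default_factory=ResponseThresholds)
    protocol: ProtocolConfig = field(default_factory=ProtocolConfig)

    def to_yaml(self, path: str | Path) -> None:
        payload = dataclasses.asdict(self)
        Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        payload = yaml.safe_load(Path(path).read_text()) or {}
        thresholds = ResponseThresholds(**payload.pop("thresholds", {}))
        protocol = ProtocolConfig(**payload.pop("protocol", {}))
        return cls(thresholds=thresholds, protocol=protocol, **payload)
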