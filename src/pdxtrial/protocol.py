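"""State machine for the intermittent long-term treatment schedule.

The schedule alternates dosing and drug holidays driven by the tumor's own
behavior: a tumor that reaches partial response by day 59 has its treatment
paused; treatment resumes when the tumor regrows to the enrollment size
(200 mm³); if disease control (PR/SD relative to the cycle's own start
volume) is then held for at least 30 days the treatment pauses again, and a
third cycle starts when the tumor roughly doubles the volume it had at the
end of the previous cycle. Two to three cycles are run in total.

The machine is fed absolute-volume observations in day order; it can audit
a recorded course or drive the simulator closed-loop. Progression confirmed
while *on* treatment in a re-treatment cycle flags secondary resistance
under the intermittent schedule.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import ProtocolConfig, ResponseThresholds
from .cohort import TumorCourse
from .growth import RelativeGrowthCurve
from .response import ResponseCall, classify

PHASES = ("on_treatment", "paused", "finished")


@dataclass(frozen=True)
class ProtocolEvent:
    day: int
    action: str  # start | pause | resume | stop
    trigger: str


@dataclass
class ProtocolState:
    """Mutable protocol bookkeeping for one tumor."""

    phase: str = "on_treatment"
    cycle_index: int = 1
    cycle_start_day: int = 0
    cycle_start_volume_mm3: float | None = None
    last_cycle_end_volume_mm3: float | None = None
    control_streak_start: int | None = None
    pending_pd_day: int | None = None
    sr_flag: bool = False
    last_day: int | None = None
    started: bool = False


def step(state: ProtocolState, day: int, volume_mm3: float,
         config: ProtocolConfig | None = None,
         thresholds: ResponseThresholds | None = None,
         ) -> tuple[ProtocolState, ProtocolEvent | None]:
    """Advance the protocol by one observation.

    Observations must arrive in strictly increasing day order. Returns the
    (mutated) state and the event emitted at this observation, if any.
    """
    cfg = config or ProtocolConfig()
    th = thresholds or ResponseThresholds()
    if state.last_day is not None and day <= state.last_day:
        raise ValueError(f"observations out of order: day {day} after {state.last_day}")
    state.last_day = day
    event: ProtocolEvent | None = None

    if not state.started:
        state.started = True
        state.cycle_start_day = day
        state.cycle_start_volume_mm3 = volume_mm3
        return state, ProtocolEvent(day=day, action="start", trigger="treatment_start")

    if state.phase == "finished":
        return state, None

    rel = volume_mm3 / state.cycle_start_volume_mm3

    if state.phase == "on_treatment":
        pd_level = 1.0 + th.pd_increase
        if rel >= pd_level:
            if state.pending_pd_day is not None:
                # confirmed progression while on treatment
                if state.cycle_index > 1:
                    state.sr_flag = True
                    state.phase = "finished"
                    return state, ProtocolEvent(day=day, action="stop",
                                                trigger="pd_on_treatment")
                # cycle 1 progression: tumor never becomes pause-eligible
                state.phase = "finished"
                return state, ProtocolEvent(day=day, action="stop",
                                            trigger="pd_on_treatment")
            state.pending_pd_day = day
            state.control_streak_start = None
            return state, None
        state.pending_pd_day = None

        if state.cycle_index == 1:
            # pause-eligibility: partial response held at the day-59 evaluation
            if day >= cfg.pause_eval_day and rel <= 1.0 + th.pr_decrease:
                state.phase = "paused"
                state.last_cycle_end_volume_mm3 = volume_mm3
                return state, ProtocolEvent(day=day, action="pause",
                                            trigger="pr_at_day59")
            return state, None

        # re-treatment cycle: count days of continuous disease control
        if state.control_streak_start is None:
            state.control_streak_start = day
        if day - state.control_streak_start >= cfg.control_streak_days:
            state.last_cycle_end_volume_mm3 = volume_mm3
            if state.cycle_index >= cfg.max_cycles:
                state.phase = "finished"
                return state, ProtocolEvent(day=day, action="stop",
                                            trigger="max_cycles_reached")
            state.phase = "paused"
            return state, ProtocolEvent(day=day, action="pause",
                                        trigger="disease_control_30d")
        return state, None

    # paused: wait for regrowth
    if state.cycle_index == 1:
        threshold = cfg.resume_threshold_mm3
        trigger = "regrowth_to_enrollment_size"
    else:
        threshold = cfg.doubling_factor * state.last_cycle_end_volume_mm3
        trigger = "volume_doubled"
    if volume_mm3 >= threshold:
        if state.cycle_index >= cfg.max_cycles:
            state.phase = "finished"
            return state, ProtocolEvent(day=day, action="stop",
                                        trigger="max_cycles_reached")
        state.cycle_index += 1
        state.cycle_start_day = day
        state.cycle_start_volume_mm3 = volume_mm3
        state.control_streak_start = None
        state.pending_pd_day = None
        state.phase = "on_treatment"
        return state, ProtocolEvent(day=day, action="resume", trigger=trigger)
    return state, None


@dataclass
class ProtocolResult:
    events: list[ProtocolEvent]
    per_cycle_calls: list[ResponseCall]
    sr_under_intermittent: bool
    state: ProtocolState
    cycles_completed: int = field(init=False)

    def __post_init__(self) -> None:
        self.cycles_completed = self.state.cycle_index


def _cycle_windows(events: list[ProtocolEvent], last_day: int
                   ) -> list[tuple[int, int, int]]:
    """(cycle_index, start_day, end_day) for each on-treatment period."""
    windows = []
    cycle = 0
    start: int | None = None
    for ev in events:
        if ev.action in ("start", "resume"):
            cycle += 1
            start = ev.day
        elif ev.action in ("pause", "stop") and start is not None:
            windows.append((cycle, start, ev.day))
            start = None
    if start is not None:
        windows.append((cycle, start, last_day))
    return windows


def run_protocol(course: TumorCourse | list[tuple[int, float]],
                 config: ProtocolConfig | None = None,
                 thresholds: ResponseThresholds | None = None) -> ProtocolResult:
    """Audit a full course under the intermittent schedule.

    Accepts a recorded :class:`TumorCourse` or raw ``(day, volume_mm3)``
    pairs. Returns the event log, a response call for each on-treatment
    cycle (graded against that cycle's own start volume), and whether
    secondary resistance emerged under the schedule.
    """
    from .growth import volume_from_caliper

    cfg = config or ProtocolConfig()
    th = thresholds or ResponseThresholds()
    if isinstance(course, TumorCourse):
        obs = [(m.day, volume_from_caliper(m.length_mm, m.width_mm))
               for m in course.measurements]
        subject = course.tumor_id
    else:
        obs = list(course)
        subject = "course"
    if not obs:
        raise ValueError("run_protocol: empty course")

    state = ProtocolState()
    events: list[ProtocolEvent] = []
    for day, vol in obs:
        state, event = step(state, int(day), float(vol), cfg, th)
        if event is not None:
            events.append(event)
    if state.phase != "finished":
        state.phase = "finished"

    days = np.array([d for d, _ in obs], dtype=int)
    vols = np.array([v for _, v in obs], dtype=float)
    calls: list[ResponseCall] = []
    for cycle, start, end in _cycle_windows(events, int(days[-1])):
        mask = (days >= start) & (days <= end)
        cdays, cvols = days[mask], vols[mask]
        if len(cdays) < 2:
            continue
        curve = RelativeGrowthCurve(
            subject=f"{subject}:cycle{cycle}",
            days=cdays,
            relative_volume=cvols / cvols[0],
            baseline_volume_mm3=float(cvols[0]),
        )
        calls.append(classify(curve, int(cdays[-1]), th))
    return ProtocolResult(events=events, per_cycle_calls=calls,
                          sr_under_intermittent=state.sr_flag, state=state)
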