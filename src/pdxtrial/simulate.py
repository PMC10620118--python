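"""Seeded two-subclone tumor-growth simulator.

The generator produces caliper-level cohorts with the statistical structure
the analysis assumes, so every downstream stage can be exercised without
animal data. Each tumor is a mixture of a drug-sensitive and a resistant
compartment, both growing exponentially; treatment adds a kill rate to the
sensitive compartment only:

    dV_s/dt = (g_s − k·on(t)) · V_s        dV_r/dt = g_r · V_r

solved exactly piecewise over treatment on/off intervals. The total volume
is back-converted to a caliper pair (L, W) with a fixed shape ratio
L/W, and multiplicative lognormal measurement noise of a chosen
coefficient of variation is applied to the volume before the split.

The two-compartment exponential is the simplest mechanism able to produce
all four observed response phenotypes, including the delayed progression of
primary-resistant tumors (growth control for ~15–21 days while the
shrinking sensitive clone still masks the expanding resistant one).
Phenotype parameter priors are invented calibration values, documented in
the methods note; no biological fidelity beyond the phenotypes is claimed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .cohort import CaliperMeasurement, ModelCohort, TumorCourse
from .config import ProtocolConfig, ResponseThresholds
from .protocol import ProtocolResult, ProtocolState, run_protocol, step


@dataclass(frozen=True)
class SimParams:
    """Growth, kill and noise parameters for one simulated tumor.

    Rates are per day. ``rho0`` is the resistant fraction of the enrollment
    volume ``v0_mm3``; ``cv_noise`` the coefficient of variation of the
    multiplicative caliper noise; ``shape_ratio`` the assumed length:width
    ratio used to back-convert volumes to caliper readings.
    """

    g_s: float = 0.08
    g_r: float = 0.12
    k: float = 0.16
    rho0: float = 0.0
    v0_mm3: float = 200.0
    cv_noise: float = 0.0
    shape_ratio: float = 1.25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.g_s < 0 or self.g_r < 0 or self.k < 0:
            raise ValueError("growth/kill rates must be nonnegative")
        if not 0.0 <= self.rho0 < 1.0:
            raise ValueError(f"rho0 must be in [0, 1), got {self.rho0}")
        if self.v0_mm3 <= 0 or self.cv_noise < 0 or self.shape_ratio < 1.0:
            raise ValueError("invalid v0/cv_noise/shape_ratio")


Schedule = Sequence[tuple[float, float]]  # treatment-on intervals [start, end)


def _time_on(schedule: Schedule, t0: float, t1: float) -> float:
    return sum(max(0.0, min(t1, b) - max(t0, a)) for a, b in schedule)


def two_clone_volume(params: SimParams, t: float, schedule: Schedule) -> float:
    """Exact noise-free total volume at time ``t`` (days from enrollment)."""
    on = _time_on(schedule, 0.0, t)
    vs = (1.0 - params.rho0) * params.v0_mm3 * math.exp(params.g_s * t - params.k * on)
    vr = params.rho0 * params.v0_mm3 * math.exp(params.g_r * t)
    return vs + vr


def volume_to_calipers(volume_mm3: float, shape_ratio: float = 1.25
                       ) -> tuple[float, float]:
    """Invert V = L·W²/2 under a fixed L/W ratio; guarantees L ≥ W."""
    if volume_mm3 <= 0:
        raise ValueError("volume must be positive")
    width = (2.0 * volume_mm3 / shape_ratio) ** (1.0 / 3.0)
    return shape_ratio * width, width


def _noise_factors(rng: np.random.Generator, cv: float, n: int) -> np.ndarray:
    if cv == 0:
        return np.ones(n)
    sigma = math.sqrt(math.log1p(cv * cv))
    return np.exp(rng.normal(0.0, sigma, size=n) - 0.5 * sigma * sigma)


def twice_weekly_days(end_day: int, start_day: int = 0) -> list[int]:
    """Measurement grid with the alternating 3/4-day caliper rhythm."""
    days, day, step_ = [], start_day, 3
    while day <= end_day:
        days.append(day)
        day += step_
        step_ = 7 - step_
    return days


def simulate_tumor(params: SimParams, schedule: Schedule,
                   days: Sequence[int], tumor_id: str = "sim",
                   model_id: str = "SIM", arm: str = "combination",
                   max_volume_mm3: float | None = None) -> TumorCourse:
    """Simulate one tumor's caliper course; deterministic given the seed.

    ``schedule`` lists the treatment-on intervals in days (empty = never
    treated). If ``max_volume_mm3`` is given, the tumor is taken off study
    at the first measurement exceeding it (size-limit removal).
    """
    days = sorted(int(d) for d in days)
    rng = np.random.default_rng(params.seed)
    factors = _noise_factors(rng, params.cv_noise, len(days))
    measurements: list[CaliperMeasurement] = []
    removal_day = removal_reason = None
    for day, factor in zip(days, factors):
        observed = two_clone_volume(params, float(day), schedule) * factor
        length, width = volume_to_calipers(observed, params.shape_ratio)
        measurements.append(CaliperMeasurement(tumor_id, day, length, width))
        if max_volume_mm3 is not None and observed > max_volume_mm3:
            removal_day, removal_reason = day, "max_size"
            break
    return TumorCourse(tumor_id=tumor_id, model_id=model_id, arm=arm,
                       measurements=measurements,
                       removal_day=removal_day, removal_reason=removal_reason)


#: Phenotype-specific parameter priors (invented calibration values).
#: ``k_ratio`` is the on-treatment kill rate as a multiple of g_s under the
#: combination; monotherapy arms apply half the combination kill.
PHENOTYPE_PRIORS: dict[str, dict] = {
    "PR": {"k_ratio": 2.0, "rho0": (0.0, 0.0), "g_r": 0.12},
    "SD": {"k_ratio": 1.0, "rho0": (0.0, 0.0), "g_r": 0.12},
    "PD": {"k_ratio": 2.0, "rho0": (0.25, 0.40), "g_r": 0.08},
    "SR": {"k_ratio": 2.0, "rho0": (1e-3, 1e-2), "g_r": 0.12},
}

G_S_MEAN = 0.08          # per-day untreated growth rate around which models vary
G_S_JITTER_SD = 0.05     # lognormal sd of the per-model growth-rate multiplier
ENROLL_MEAN_MM3 = 200.0  # enrollment volume target
ENROLL_SD_MM3 = 15.0     # spread, truncated to ±30 mm³
MONO_KILL_FRACTION = 0.5  # monotherapy kill relative to the combination


@dataclass
class CohortDesign:
    """Design of a simulated trial cohort.

    ``phenotype_counts`` allocates models to response phenotypes (under the
    combination arm); counts must sum to ``n_models``. Each model receives
    ``mice_per_arm`` animals per arm with up to ``sites_per_mouse`` implant
    sites, measured twice weekly until ``study_length_days``.
    """

    n_models: int = 19
    phenotype_counts: dict[str, int] = field(
        default_factory=lambda: {"PR": 9, "SD": 5, "PD": 5})
    arms: tuple[str, ...] = ("control", "combination")
    mice_per_arm: tuple[int, int] = (5, 6)
    sites_per_mouse: int = 2
    study_length_days: int = 59
    cv_noise: float = 0.1
    max_volume_mm3: float | None = 1500.0

    def __post_init__(self) -> None:
        if sum(self.phenotype_counts.values()) != self.n_models:
            raise ValueError("phenotype counts must sum to n_models")
        unknown = set(self.phenotype_counts) - set(PHENOTYPE_PRIORS)
        if unknown:
            raise ValueError(f"unknown phenotypes {sorted(unknown)}")


def _model_params(phenotype: str, rng: np.random.Generator) -> dict:
    prior = PHENOTYPE_PRIORS[phenotype]
    g_s = G_S_MEAN * math.exp(rng.normal(0.0, G_S_JITTER_SD))
    lo, hi = prior["rho0"]
    rho0 = float(rng.uniform(lo, hi)) if hi > lo else lo
    return {"g_s": g_s, "g_r": prior["g_r"], "k": prior["k_ratio"] * g_s,
            "rho0": rho0}


def _draw_v0(rng: np.random.Generator) -> float:
    while True:
        v0 = rng.normal(ENROLL_MEAN_MM3, ENROLL_SD_MM3)
        if abs(v0 - ENROLL_MEAN_MM3) <= 30.0:
            return float(v0)


def _arm_kill(arm: str, k_combo: float) -> float:
    if arm == "control":
        return 0.0
    if arm in ("trametinib", "cetuximab"):
        return MONO_KILL_FRACTION * k_combo
    return k_combo


def simulate_cohort(design: CohortDesign, master_seed: int) -> list[ModelCohort]:
    """Generate a full multi-model cohort; byte-reproducible given the seed.

    Models are assigned phenotypes per ``design.phenotype_counts`` and given
    phenotype-prior parameters with a per-model growth-rate jitter; every
    tumor gets an independent noise stream derived from ``master_seed``.
    """
    model_rng = np.random.default_rng(np.random.SeedSequence([master_seed, 0]))
    phenotypes = [p for p, n in sorted(design.phenotype_counts.items())
                  for _ in range(n)]
    model_rng.shuffle(phenotypes)

    days = twice_weekly_days(design.study_length_days)
    on_schedule = [(0.0, float(design.study_length_days) + 1.0)]
    tumor_counter = 0
    cohorts: list[ModelCohort] = []
    for i, phenotype in enumerate(phenotypes, start=1):
        model_id = f"SIM{i:02d}"
        mp = _model_params(phenotype, model_rng)
        n_mice = int(model_rng.integers(design.mice_per_arm[0],
                                        design.mice_per_arm[1] + 1))
        tumors: list[TumorCourse] = []
        for arm in design.arms:
            k_arm = _arm_kill(arm, mp["k"])
            for mouse in range(1, n_mice + 1):
                n_sites = int(model_rng.integers(1, design.sites_per_mouse + 1))
                for site in range(1, n_sites + 1):
                    tumor_counter += 1
                    seed = int(np.random.SeedSequence(
                        [master_seed, 1, tumor_counter]).generate_state(1)[0])
                    v0_rng = np.random.default_rng(seed ^ 0x5EED)
                    params = SimParams(
                        g_s=mp["g_s"], g_r=mp["g_r"], k=k_arm, rho0=mp["rho0"],
                        v0_mm3=_draw_v0(v0_rng), cv_noise=design.cv_noise,
                        seed=seed,
                    )
                    tumor_id = f"{model_id}-{arm[:4]}-m{mouse}s{site}"
                    schedule = [] if arm == "control" else on_schedule
                    tumors.append(simulate_tumor(
                        params, schedule, days, tumor_id=tumor_id,
                        model_id=model_id, arm=arm,
                        max_volume_mm3=design.max_volume_mm3))
        cohorts.append(ModelCohort(model_id=model_id, kras_variant="G12D",
                                   uicc_stage=None, tumors=tumors))
    return cohorts


def simulate_intermittent(params: SimParams, end_day: int = 250,
                          config: ProtocolConfig | None = None,
                          thresholds: ResponseThresholds | None = None,
                          ) -> tuple[list[tuple[int, float]], ProtocolResult]:
    """Run one tumor closed-loop under the intermittent schedule.

    Treatment is on whenever the protocol state machine says so; dynamics
    advance exactly between the twice-weekly measurement days. Returns the
    observed ``(day, volume)`` series and the protocol audit of it.
    """
    cfg = config or ProtocolConfig()
    th = thresholds or ResponseThresholds()
    days = twice_weekly_days(end_day)
    rng = np.random.default_rng(params.seed)
    factors = _noise_factors(rng, params.cv_noise, len(days))

    vs = (1.0 - params.rho0) * params.v0_mm3
    vr = params.rho0 * params.v0_mm3
    state = ProtocolState()
    on = True  # dosing begins at treatment start
    obs: list[tuple[int, float]] = []
    prev = None
    for day, factor in zip(days, factors):
        if prev is not None:
            dt = float(day - prev)
            vs *= math.exp((params.g_s - (params.k if on else 0.0)) * dt)
            vr *= math.exp(params.g_r * dt)
        observed = (vs + vr) * factor
        obs.append((day, observed))
        state, _ = step(state, day, observed, cfg, th)
        on = state.phase == "on_treatment"
        prev = day
        if state.phase == "finished":
            break
    return obs, run_protocol(obs, cfg, th)


def pr_phenotype_params(seed: int, cv_noise: float = 0.1) -> SimParams:
    """Convenience: a combination-arm tumor drawn from the PR prior."""
    rng = np.random.default_rng(seed)
    g_s = G_S_MEAN * math.exp(rng.normal(0.0, G_S_JITTER_SD))
    return SimParams(g_s=g_s, g_r=0.12, k=2.0 * g_s, rho0=0.0,
                     v0_mm3=_draw_v0(rng), cv_noise=cv_noise, seed=seed)
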