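import math

import numpy as np
import pytest

from pdxtrial.cohort import write_cohort
from pdxtrial.growth import relative_curve, volume_from_caliper
from pdxtrial.response import aggregate_arm, classify, detect_resistance
from pdxtrial.simulate import (
    CohortDesign,
    SimParams,
    pr_phenotype_params,
    simulate_cohort,
    simulate_tumor,
    twice_weekly_days,
    two_clone_volume,
    volume_to_calipers,
)
from pdxtrial.stats import model_calls

ALWAYS_ON = [(0.0, 1000.0)]


class TestDynamics:
    def test_untreated_pure_exponential(self):
        p = SimParams(g_s=0.08, k=0.0, rho0=0.0, v0_mm3=200.0, cv_noise=0.0)
        for t in (0, 10, 30.5):
            assert two_clone_volume(p, t, []) == pytest.approx(
                200.0 * math.exp(0.08 * t), rel=1e-12)

    def test_noise_free_course_matches_closed_form(self):
        p = SimParams(g_s=0.08, g_r=0.12, k=0.16, rho0=0.01, cv_noise=0.0, seed=7)
        course = simulate_tumor(p, ALWAYS_ON, twice_weekly_days(59))
        for m in course.measurements:
            v = volume_from_caliper(m.length_mm, m.width_mm)
            expected = two_clone_volume(p, float(m.day), ALWAYS_ON)
            assert abs(v / expected - 1.0) < 1e-10

    def test_piecewise_schedule_splits_kill_time(self):
        p = SimParams(g_s=0.10, g_r=0.0, k=0.25, rho0=0.0, v0_mm3=100.0)
        # on for days [0, 10), off afterwards
        v = two_clone_volume(p, 20.0, [(0.0, 10.0)])
        assert v == pytest.approx(100.0 * math.exp(0.10 * 20 - 0.25 * 10), rel=1e-12)

    def test_dominant_kill_yields_pr_at_closed_form_crossing(self):
        p = SimParams(g_s=0.08, g_r=0.12, k=0.16, rho0=0.0, cv_noise=0.0)
        course = simulate_tumor(p, ALWAYS_ON, twice_weekly_days(59))
        call = classify(relative_curve(course), 28)
        assert call.category == "PR"
        t_cross = math.log(0.7) / (p.g_s - p.k)  # ≈ 4.5 days
        rel = relative_curve(course)
        below = rel.days[rel.relative_volume <= 0.7]
        assert below.min() == min(d for d in rel.days if d >= t_cross)

    def test_resistant_fraction_drives_sr_at_predicted_day(self):
        p = SimParams(g_s=0.08, g_r=0.12, k=0.16, rho0=5e-3, cv_noise=0.0)
        course = simulate_tumor(p, ALWAYS_ON, twice_weekly_days(59))
        curve = relative_curve(course)
        call = detect_resistance(curve, classify(curve, 28), 59)
        assert call.kind == "secondary"
        # closed-form crossing of total volume above 1.2·v0
        crossing = next(
            t for t in np.linspace(28, 59, 3101)
            if two_clone_volume(p, t, ALWAYS_ON) >= 1.2 * p.v0_mm3)
        grid = twice_weekly_days(59)
        confirm = [d for d in grid if d >= crossing][1]  # second grid day above
        assert call.sr_onset_day == confirm

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            SimParams(rho0=1.0)
        with pytest.raises(ValueError):
            SimParams(g_s=-0.1)


class TestCaliperBackConversion:
    @pytest.mark.parametrize("volume", [10.0, 200.0, 1500.0])
    def test_round_trips_volume(self, volume):
        length, width = volume_to_calipers(volume, shape_ratio=1.25)
        assert length / width == pytest.approx(1.25)
        assert volume_from_caliper(length, width) == pytest.approx(volume, rel=1e-12)


class TestSchedule:
    def test_twice_weekly_rhythm(self):
        days = twice_weekly_days(28)
        assert days == [0, 3, 7, 10, 14, 17, 21, 24, 28]


class TestCohortGeneration:
    def test_same_seed_identical_bytes(self, tmp_path):
        design = CohortDesign(n_models=4, phenotype_counts={"PR": 2, "SD": 1, "PD": 1})
        paths = []
        for run in (1, 2):
            cohorts = simulate_cohort(design, master_seed=11)
            path = tmp_path / f"run{run}.csv"
            write_cohort(cohorts, path)
            paths.append(path.read_bytes())
        assert paths[0] == paths[1]

    def test_distinct_tumors_have_independent_noise(self):
        design = CohortDesign(n_models=1, phenotype_counts={"SD": 1},
                              arms=("combination",), cv_noise=0.2)
        (cohort,) = simulate_cohort(design, master_seed=5)
        curves = [relative_curve(t).relative_volume for t in cohort.tumors[:2]]
        assert not np.allclose(curves[0], curves[1])

    def test_noise_free_design_recovers_phenotype_mix(self):
        design = CohortDesign(cv_noise=0.0)  # default 9 PR / 5 SD / 5 PD
        cohorts = simulate_cohort(design, master_seed=2)
        calls = model_calls(cohorts, "combination", 28)
        assert aggregate_arm(calls, arm="combination").counts == \
            {"PR": 9, "SD": 5, "PD": 5}

    def test_zero_rho0_yields_zero_sr(self):
        # no resistant compartment anywhere: the mechanism cannot regrow
        assert _sr_fraction(0.0) == 0.0
        design = CohortDesign(n_models=6,
                              phenotype_counts={"PR": 3, "SD": 3}, cv_noise=0.0)
        cohorts = simulate_cohort(design, master_seed=3)
        n_sr = 0
        for cohort in cohorts:
            for course in cohort.arm("combination"):
                curve = relative_curve(course)
                call = detect_resistance(curve, classify(curve, 28), 59)
                n_sr += call.kind == "secondary"
        assert n_sr == 0

    def test_bad_phenotype_counts_rejected(self):
        with pytest.raises(ValueError):
            CohortDesign(n_models=3, phenotype_counts={"PR": 1})


def _sr_fraction(rho0: float, n: int = 60) -> float:
    n_sr = 0
    for seed in range(n):
        p = SimParams(g_s=0.08, g_r=0.12, k=0.16, rho0=rho0,
                      cv_noise=0.1, seed=seed)
        course = simulate_tumor(p, ALWAYS_ON, twice_weekly_days(59),
                                tumor_id=f"t{seed}")
        curve = relative_curve(course)
        call = detect_resistance(curve, classify(curve, 28), 59)
        n_sr += call.kind == "secondary"
    return n_sr / n


class TestStochasticRecovery:
    def test_pr_prior_classified_pr_at_10pct_noise(self):
        hits = 0
        for seed in range(200):
            p = pr_phenotype_params(seed=seed, cv_noise=0.1)
            course = simulate_tumor(p, ALWAYS_ON, twice_weekly_days(59),
                                    tumor_id=f"t{seed}")
            hits += classify(relative_curve(course), 28).category == "PR"
        assert hits / 200 >= 0.90

    def test_sr_fraction_monotone_in_rho0(self):
        fractions = [_sr_fraction(r) for r in (0.0, 1e-3, 3e-3, 1e-2)]
        assert fractions == sorted(fractions)
        assert fractions[0] == 0.0
        assert fractions[-1] > 0.5
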