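import itertools

import numpy as np
import pytest
from hypothesis import given, strategies as st

from pdxtrial.config import ResponseThresholds
from pdxtrial.growth import EvaluationError
from pdxtrial.cohort import load_table1_fixture
from pdxtrial.response import (
    aggregate_arm,
    classify,
    detect_resistance,
    time_to_progression,
    waterfall_values,
)

from .oracle import (
    oracle_classify,
    oracle_resistance,
    oracle_ttp,
    oracle_waterfall,
)

GRID = (0.6, 0.8, 1.0, 1.1, 1.25, 1.3)
DAY_GRID = (0, 7, 14, 21, 28, 35)


class TestClassify:
    def test_thirty_percent_reduction_is_pr(self, curve_factory):
        curve = curve_factory([1.0, 0.9, 0.65], days=[0, 14, 28])
        assert classify(curve, 28).category == "PR"

    def test_confirmed_increase_is_pd_with_onset(self, curve_factory):
        curve = curve_factory([1.0, 1.25, 1.30], days=[0, 24, 28])
        call = classify(curve, 28)
        assert call.category == "PD" and call.pd_onset_day == 28

    def test_single_excursion_unconfirmed_is_sd(self, curve_factory):
        curve = curve_factory([1.0, 1.25, 1.10], days=[0, 14, 28])
        assert classify(curve, 28).category == "SD"

    def test_undetectable_volume_is_cr(self, curve_factory):
        # caliper volumes are never exactly zero; the CR cut-off is configurable
        curve = curve_factory([1.0, 0.5, 0.04], days=[0, 14, 28], baseline=200.0)
        th = ResponseThresholds(cr_volume_mm3=10.0)
        assert classify(curve, 28, th).category == "CR"

    def test_exact_plus_20_percent_is_inclusive_pd(self, curve_factory):
        curve = curve_factory([1.0, 1.2, 1.2], days=[0, 24, 28])
        assert classify(curve, 28).category == "PD"

    def test_unevaluable_curve_raises(self, curve_factory):
        curve = curve_factory([1.0, 0.9], days=[0, 7])
        with pytest.raises(EvaluationError):
            classify(curve, 28)

    def test_early_removal_with_confirmed_pd_still_pd(self, curve_factory):
        # size-limit removal before the evaluation day, progression confirmed
        curve = curve_factory([1.0, 1.4, 1.9], days=[0, 10, 17])
        call = classify(curve, 28)
        assert call.category == "PD" and call.pd_onset_day == 17


class TestOracleEquivalence:
    """Exhaustive dual-route check of the printed response definitions."""

    def _curves(self):
        for n_post in range(1, 6):
            days = DAY_GRID[: n_post + 1]
            for values in itertools.product(GRID, repeat=n_post):
                yield days, (1.0,) + values

    def test_classify_matches_brute_force_everywhere(self, curve_factory):
        mismatches = 0
        for days, rel in self._curves():
            curve = curve_factory(list(rel), days=list(days))
            expected = oracle_classify(days, rel, 200.0, 28)
            try:
                call = classify(curve, 28)
                got = (call.category, call.pd_onset_day)
            except EvaluationError:
                got = None
            mismatches += got != expected
        assert mismatches == 0

    def test_resistance_matches_brute_force_everywhere(self, curve_factory):
        for days, rel in self._curves():
            if days[-1] < 28:
                continue
            curve = curve_factory(list(rel), days=list(days))
            expected = oracle_resistance(days, rel, 200.0, 28, 35)
            try:
                call28 = classify(curve, 28)
            except EvaluationError:
                assert expected is None
                continue
            res = detect_resistance(curve, call28, 35)
            assert (res.kind, res.sr_onset_day) == expected

    def test_ttp_matches_brute_force_everywhere(self, curve_factory):
        for days, rel in self._curves():
            curve = curve_factory(list(rel), days=list(days))
            assert time_to_progression(curve, 59) == oracle_ttp(days, rel, 59)


class TestClassifyProperties:
    @given(st.lists(st.sampled_from(GRID), min_size=3, max_size=6))
    def test_partition_exactly_one_category(self, values):
        from .conftest import make_curve

        days = list(range(0, 7 * (len(values) + 1), 7))
        curve = make_curve([1.0] + values, days=days)
        call = classify(curve, days[-1])
        assert call.category in ("CR", "PR", "SD", "PD")

    @given(st.lists(st.floats(0.05, 1.0), min_size=3, max_size=8))
    def test_pointwise_decreasing_never_pd(self, raw):
        from .conftest import make_curve

        rel = [1.0] + sorted(r * 0.99 for r in raw)[::-1]
        days = list(range(0, 7 * len(rel), 7))
        curve = make_curve(rel, days=days)
        assert classify(curve, days[-1]).category != "PD"

    @given(st.lists(st.floats(1.2, 4.0), min_size=2, max_size=8))
    def test_sustained_excess_always_pd(self, values):
        from .conftest import make_curve

        days = list(range(0, 7 * (len(values) + 1), 7))
        curve = make_curve([1.0] + values, days=days)
        assert classify(curve, days[-1]).category == "PD"


class TestDetectResistance:
    def test_sd_then_confirmed_regrowth_is_secondary(self, curve_factory):
        days = [0, 14, 28, 42, 45]
        curve = curve_factory([1.0, 1.05, 1.1, 1.25, 1.28], days=days)
        call = detect_resistance(curve, classify(curve, 28), 59)
        assert call.kind == "secondary" and call.sr_onset_day == 45

    def test_pd_at_day28_is_primary(self, curve_factory):
        curve = curve_factory([1.0, 1.3, 1.5], days=[0, 21, 28])
        call = detect_resistance(curve, classify(curve, 28), 59)
        assert call.kind == "primary"

    def test_maintained_pr_is_none(self, curve_factory):
        curve = curve_factory([1.0, 0.6, 0.5, 0.45], days=[0, 14, 28, 56])
        call = detect_resistance(curve, classify(curve, 28), 59)
        assert call.kind == "none"

    def test_single_point_mode_flag(self, curve_factory):
        days = [0, 14, 28, 42, 49]
        curve = curve_factory([1.0, 1.0, 1.0, 1.25, 1.0], days=days)
        strict = detect_resistance(curve, classify(curve, 28), 59, confirm=False)
        confirmed = detect_resistance(curve, classify(curve, 28), 59)
        assert strict.kind == "secondary" and confirmed.kind == "none"

    def test_short_follow_up_rejected(self, curve_factory):
        curve = curve_factory([1.0, 1.0, 1.0], days=[0, 14, 28])
        with pytest.raises(ValueError):
            detect_resistance(curve, classify(curve, 28), 28)


class TestTimeToProgression:
    def test_shrinking_curve_censored(self, curve_factory):
        curve = curve_factory([1.0, 0.8, 0.6, 0.5], days=[0, 14, 28, 56])
        assert time_to_progression(curve, 59) == (59, True)

    def test_transient_crossing_censored(self, curve_factory):
        curve = curve_factory([1.0, 1.25, 0.9, 0.8], days=[0, 14, 28, 56])
        assert time_to_progression(curve, 59) == (59, True)

    def test_confirmed_pd_day(self, curve_factory):
        curve = curve_factory([1.0, 1.25, 1.4], days=[0, 17, 21])
        assert time_to_progression(curve, 59) == (21, False)


class TestWaterfall:
    def test_values_and_cutoff_rule(self, course_factory):
        a = course_factory([200, 100], days=[0, 56], tumor_id="a")
        b = course_factory([200, 200], days=[0, 56], tumor_id="b")
        c = course_factory([200, 240, 300], days=[0, 56, 63], tumor_id="c")
        values = dict(waterfall_values([a, b, c], cutoff_day=59))
        assert values["a"] == pytest.approx(-50.0)
        assert values["b"] == pytest.approx(0.0)
        assert values["c"] == pytest.approx(20.0)  # day-63 reading ignored

    def test_baseline_only_excluded(self, course_factory):
        only_baseline = course_factory([200], days=[0], tumor_id="solo")
        assert waterfall_values([only_baseline]) == []

    @given(st.lists(st.tuples(st.integers(1, 70), st.floats(0.2, 3.0)),
                    min_size=1, max_size=6, unique_by=lambda t: t[0]))
    def test_agrees_with_oracle(self, points):
        from .conftest import make_course

        points = sorted(points)
        days = [0] + [d for d, _ in points]
        vols = [200.0] + [200.0 * r for _, r in points]
        course = make_course(vols, days=days)
        got = waterfall_values([course], cutoff_day=59)
        expected = oracle_waterfall(days, [v / 200.0 for v in vols], 59)
        if expected is None:
            assert got == []
        else:
            assert got[0][1] == pytest.approx(expected, rel=1e-9)


class TestAggregateArm:
    def test_table1_combination_day28(self):
        df = load_table1_fixture()
        summary = aggregate_arm(df["combo_d28"], arm="combination")
        assert summary.counts == {"PR": 9, "SD": 5, "PD": 5}
        assert summary.disease_control_rate == pytest.approx(14 / 19)
        assert summary.percent_display("PR") == 47
        assert summary.percent_display("SD") == 26
        assert summary.percent_display("CR", "PR", "SD") == 74

    def test_table1_trametinib_day28(self):
        df = load_table1_fixture()
        summary = aggregate_arm(df["tram_d28"], arm="trametinib")
        assert summary.n == 8
        assert float(summary.disease_control_rate) == pytest.approx(0.375)

    def test_table1_day59_sr_counts_as_progression(self):
        df = load_table1_fixture()
        combo = aggregate_arm(df["combo_d59"], arm="combination")
        assert combo.fraction("PR", "SD") * combo.n == 12  # over 15 evaluable
        tram = aggregate_arm(df["tram_d59"], arm="trametinib")
        assert tram.counts == {"SD": 1, "PD": 7}
        assert float(tram.fraction("PD")) == pytest.approx(0.875)

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            aggregate_arm([])

    def test_mixed_evaluation_days_rejected(self, curve_factory):
        a = classify(curve_factory([1.0, 0.6], days=[0, 28]), 28)
        b = classify(curve_factory([1.0, 0.6] + [0.6], days=[0, 28, 59]), 59)
        with pytest.raises(ValueError, match="mixed"):
            aggregate_arm([a, b])
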