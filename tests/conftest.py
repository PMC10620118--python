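import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from pdxtrial.cohort import CaliperMeasurement, ModelCohort, TumorCourse
from pdxtrial.growth import RelativeGrowthCurve

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_course(volumes, days=None, tumor_id="t1", model_id="M1",
                arm="combination", shape_ratio=1.25, **kwargs):
    """Build a TumorCourse whose caliper pairs reproduce given volumes."""
    if days is None:
        days = list(range(0, 7 * len(volumes), 7))
    measurements = []
    for day, vol in zip(days, volumes):
        width = (2.0 * vol / shape_ratio) ** (1.0 / 3.0)
        measurements.append(CaliperMeasurement(tumor_id, day, shape_ratio * width, width))
    return TumorCourse(tumor_id=tumor_id, model_id=model_id, arm=arm,
                       measurements=measurements, **kwargs)


def make_curve(rel, days=None, baseline=200.0, subject="t1"):
    if days is None:
        days = list(range(0, 7 * len(rel), 7))
    return RelativeGrowthCurve(subject=subject, days=np.array(days),
                               relative_volume=np.array(rel, dtype=float),
                               baseline_volume_mm3=baseline)


@pytest.fixture
def course_factory():
    return make_course


@pytest.fixture
def curve_factory():
    return make_curve


@pytest.fixture
def small_cohort():
    """Two models, two arms, one removal — enough structure for I/O tests."""
    t1 = make_course([200, 180, 140], days=[0, 7, 14], tumor_id="A-1",
                     model_id="A", arm="combination")
    t2 = make_course([210, 250, 320], days=[0, 7, 14], tumor_id="A-2",
                     model_id="A", arm="control", removal_day=14,
                     removal_reason="max_size")
    t3 = make_course([190, 195], days=[0, 7], tumor_id="B-1",
                     model_id="B", arm="combination")
    return [
        ModelCohort(model_id="A", kras_variant="G12D", uicc_stage="IIIB",
                    tumors=[t1, t2]),
        ModelCohort(model_id="B", kras_variant="G12V", tumors=[t3]),
    ]
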