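import warnings

import pytest
from hypothesis import settings

import kmdprint as kp

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def targets():
    return kp.build_target_list()


@pytest.fixture(scope="session")
def sebum_profile():
    return kp.default_sebum_profile(seed=0)


@pytest.fixture(scope="session")
def timecourse_samples(sebum_profile):
    """Simulated aging time course (0,1,3,5,7 days; quadruplicate 0/3/7)."""
    return kp.generate_timecourse(seed=3, profile=sebum_profile)


@pytest.fixture(scope="session")
def annotated_timecourse(timecourse_samples, targets):
    samples = []
    for sample in timecourse_samples:
        annotated = kp.annotate_peaks(sample.peaks, targets)
        samples.append(
            kp.TimeCourseSample(
                sample.peaks.age_days, sample.peaks.replicate, annotated
            )
        )
    return kp.TimeCourse(samples)


@pytest.fixture(scope="session")
def day0_sample(timecourse_samples):
    return next(
        s for s in timecourse_samples
        if s.peaks.age_days == 0 and s.peaks.replicate == 1
    )


@pytest.fixture(scope="session")
def day7_sample(timecourse_samples):
    return next(
        s for s in timecourse_samples
        if s.peaks.age_days == 7 and s.peaks.replicate == 1
    )


@pytest.fixture(autouse=True)
def _quiet_marker_warnings():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        yield
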