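import pytest
from hypothesis import settings

import mirbayes as mb
from mirbayes.class_stats import ClassGaussian

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("suite")

# Printed class statistics of the study conditions (mean, SD, n) used as
# fixed inputs throughout the suite: the normalized discriminating measure,
# the normalized helper, the reference, and the optimized combination.
DX205 = {"target": ClassGaussian(1.7, 2.2, 18), "versus": ClassGaussian(-4.6, 2.4, 15)}
DX21 = {"target": ClassGaussian(-6.5, 1.4, 18), "versus": ClassGaussian(-6.6, 2.4, 15)}
XU6 = {"target": ClassGaussian(25.0, 1.4, 19), "versus": ClassGaussian(25.8, 1.9, 16)}
YOPT = {"target": ClassGaussian(6.9, 1.9, 18), "versus": ClassGaussian(0.7, 1.6, 15)}


@pytest.fixture(scope="session")
def study_cohort():
    """Deterministic synthetic stand-in for the study cohort."""
    return mb.study_like_cohort()


@pytest.fixture()
def study_measures(study_cohort):
    """QC'd and normalized measure vectors of the stand-in cohort.

    Function-scoped: downstream tests attach combined measures in place.
    """
    _, policy = mb.fit_qc(study_cohort)
    clean, _ = mb.apply_qc(study_cohort, policy)
    measures, _ = mb.normalize(clean, "U6")
    return measures
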