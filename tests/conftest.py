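import numpy as np
import pytest

from altimet import StudyDesign, generate_cohort


def scaled_design(n_subjects: int, seed: int = 0,
                  full_attendance: bool = True) -> StudyDesign:
    """Study design with the five standard locations at a reduced cohort size."""
    base = StudyDesign()
    if full_attendance:
        locs = tuple((n, a, n_subjects) for n, a, _ in base.locations)
    else:
        locs = tuple((n, a, max(3, int(round(c / 198 * n_subjects))))
                     for n, a, c in base.locations)
    return StudyDesign(locations=locs, n_subjects=n_subjects, seed=seed)


@pytest.fixture(scope="session")
def small_cohort():
    """40 subjects, complete attendance at all five altitudes."""
    return generate_cohort(scaled_design(40, seed=11))


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
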