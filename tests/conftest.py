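import numpy as np
import pytest

from glucluster.preprocessing import NocturnalSegment, SEGMENT_LENGTH
from glucluster.synthetic import ArchetypeSpec, CohortConfig, generate_cohort


def make_segment(values, missing_idx=(), patient="P0001", night=0):
    """Build a NocturnalSegment with missingness at the given indices."""
    values = np.asarray(values, dtype=float).copy()
    mask = np.zeros(len(values), dtype=bool)
    for i in missing_idx:
        mask[i] = True
        values[i] = 0.0
    return NocturnalSegment(patient, night, values, mask)


def complete_values(level=6.0, length=SEGMENT_LENGTH):
    return np.full(length, float(level))


@pytest.fixture
def four_archetypes():
    """The four non-hypoglycemic default patterns."""
    return [
        ArchetypeSpec(1, "stable_target", 6.5, 6.5),
        ArchetypeSpec(2, "stable_elevated", 10.5, 10.5),
        ArchetypeSpec(3, "downward_trend", 10.0, 5.5),
        ArchetypeSpec(4, "upward_trend", 6.0, 11.0),
    ]


@pytest.fixture
def clean_cohort(four_archetypes):
    """Small gap-free low-noise cohort with known archetype labels."""
    cfg = CohortConfig(
        n_patients=80,
        archetypes=four_archetypes,
        gap_rate_single=0.0,
        gap_rate_long=0.0,
        seed=11,
    )
    return generate_cohort(cfg)


@pytest.fixture
def clean_matrix(clean_cohort):
    return np.vstack([s.values for s in clean_cohort.segments])
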