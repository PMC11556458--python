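import numpy as np
import pandas as pd
import pytest

from hairomics import CohortSpec, SpectralCountMatrix, SubjectMetadata, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A modest synthetic cohort shared by read-only tests."""
    spec = CohortSpec(n_proteins=200, n_age_proteins=15, n_sex_proteins=10, seed=11)
    return generate_cohort(spec)


@pytest.fixture()
def toy_matrix():
    """3 proteins x 2 subjects with counts [[4,0],[2,2],[0,7]]."""
    counts = pd.DataFrame(
        [[4, 0], [2, 2], [0, 7]],
        index=["P1", "P2", "P3"],
        columns=["S1", "S2"],
    )
    return SpectralCountMatrix(counts)


def make_metadata(rows):
    """Build SubjectMetadata from (subject, family, role, age, sex, related) tuples."""
    frame = pd.DataFrame(
        rows, columns=["subject_id", "family_id", "role", "age_months", "sex", "related"]
    )
    return SubjectMetadata(frame)


def two_family_metadata():
    return make_metadata(
        [
            ("A_Mo", "A", "mother", 420, "F", True),
            ("A_C1", "A", "child", 24, "F", True),
            ("A_C2", "A", "child", 48, "M", True),
            ("B_Mo", "B", "mother", 400, "F", True),
            ("B_C1", "B", "child", 30, "M", True),
            ("B_C2", "B", "child", 60, "F", True),
        ]
    )
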