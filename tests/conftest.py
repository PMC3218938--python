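import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from fovsample import CohortSpec, FovScoreTable, generate_cohort

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")


@pytest.fixture
def tiny_table() -> FovScoreTable:
    """Two subjects, hand-checkable scores."""
    return FovScoreTable.from_frame(
        pd.DataFrame(
            {
                "subject_id": ["A", "A", "B"],
                "roi_id": ["r1", "r1", "r1"],
                "fov_id": ["f1", "f2", "f1"],
                "score": [2.0, 4.0, 5.0],
            }
        )
    )


@pytest.fixture(scope="session")
def balanced_cohort() -> FovScoreTable:
    """Mid-size balanced cohort reused by fit tests (session-scoped: read-only)."""
    spec = CohortSpec(
        n_subjects=60, rois_per_subject=3, fovs_per_roi=10,
        beta0=50.0, sigma_subject=5.0, sigma_roi=2.0, sigma_resid=3.0, seed=314,
    )
    return generate_cohort(spec)


@pytest.fixture
def zero_variance_cohort() -> FovScoreTable:
    spec = CohortSpec(
        n_subjects=14, rois_per_subject=2, fovs_per_roi=12,
        beta0=10.0, sigma_subject=0.0, sigma_roi=0.0, sigma_resid=0.0, seed=1,
    )
    return generate_cohort(spec)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
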