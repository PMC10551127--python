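import numpy as np
import pytest

from connectoperm import CohortSpec, build_fc_matrix, demo_atlas, sample_cohort
from connectoperm.perm_glm import make_design


@pytest.fixture(scope="session")
def atlas14():
    return demo_atlas(14)


@pytest.fixture(scope="session")
def atlas28():
    return demo_atlas(28)


@pytest.fixture(scope="session")
def small_cohort(atlas14):
    """8+8 subjects, 14 parcels, no injected effect."""
    spec = CohortSpec(
        atlas=atlas14, n_patients=8, n_controls=8, n_timepoints=120, seed=42
    )
    series, pheno, truth = sample_cohort(spec)
    return series, pheno, truth


@pytest.fixture(scope="session")
def small_fcs(small_cohort):
    series, pheno, _ = small_cohort
    fcs = [build_fc_matrix(ts) for ts in series]
    design = make_design(pheno, [ts.subject_id for ts in series])
    return fcs, design


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
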