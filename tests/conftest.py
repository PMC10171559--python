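import numpy as np
import pytest

from fcfingerprint import CohortMatrix, SyntheticSpec, generate_fc_cohort


def cohort_from_columns(columns, p, s):
    """Build a CohortMatrix from a list of column vectors, p subjects x s sessions."""
    values = np.column_stack(columns)
    index = tuple(
        (f"sub{i:02d}", f"ses{j:02d}") for i in range(p) for j in range(s)
    )
    return CohortMatrix(values=values, index=index)


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def fc_cohort():
    """A small identifiable cohort in FC-vector space."""
    return generate_fc_cohort(
        SyntheticSpec(p=5, s=4, n_features=120, rho_within=0.7, rho_between=0.2, seed=7)
    )
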