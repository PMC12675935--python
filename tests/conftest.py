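import numpy as np
import pandas as pd
import pytest

import morphsim as ms


@pytest.fixture(scope="session")
def parc60():
    """Reduced-scale parcellation used across the suite: 30 L + 30 R parcels."""
    return ms.make_parcellation(30, 30, seed=0)


@pytest.fixture(scope="session")
def parc_small():
    return ms.make_parcellation(8, 8, seed=1)


@pytest.fixture(scope="session")
def cohort60(parc60):
    """Cohort with planted effects at the default reduced scale."""
    truth = ms.default_truth(parc60, n_affected=10, seed=7)
    design, features = ms.simulate_cohort(parc60, (10, 10, 10), truth, seed=7)
    return truth, design, features


@pytest.fixture(scope="session")
def strengths60(cohort60):
    _, design, features = cohort60
    sm = ms.strength_matrix([ms.regional_strength(ms.build_msn(f)) for f in features])
    return sm, design


def feature_table(values, subject_id="sub-x", features=None):
    values = np.asarray(values, float)
    cols = features or [f"f{j}" for j in range(values.shape[1])]
    return ms.SubjectFeatures(
        subject_id,
        pd.DataFrame(values, index=pd.RangeIndex(values.shape[0], name="region_id"),
                     columns=cols),
    )
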