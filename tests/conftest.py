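import numpy as np
import pytest

import lge_zmap as lz


@pytest.fixture(scope="session")
def cohort_22():
    """Default-size synthetic cohort (13 DCM / 9 CS), no exclusions."""
    cohort, gt = lz.generate_cohort(lz.SyntheticConfig(n_dcm=13, n_cs=9, seed=11))
    return cohort, gt


@pytest.fixture(scope="session")
def zcohort_22(cohort_22):
    cohort, _ = cohort_22
    z = lz.zscore_standardize(cohort.table)
    return lz.CohortDataset(table=z, labels=cohort.labels)


@pytest.fixture(scope="session")
def calibrated_cohort():
    """Cohort with a designed septal RV-band z difference of 0.5."""
    cohort, gt = lz.generate_calibrated_cohort(13, 9, 0.5, seed=5)
    z = lz.zscore_standardize(cohort.table)
    return lz.CohortDataset(table=z, labels=cohort.labels), gt


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
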