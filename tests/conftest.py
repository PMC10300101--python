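import numpy as np
import pytest

from plasmasieve import (
    CohortSpec,
    high_separation_spec,
    make_cohort,
)


@pytest.fixture(scope="session")
def default_cohort():
    """A small cohort under the default (overlapping) study conditions."""
    return make_cohort(CohortSpec(n_patients=4, seed=11))


@pytest.fixture(scope="session")
def highsep_cohort():
    """Cleanly separable cohort used for end-to-end classifier checks."""
    return make_cohort(high_separation_spec(seed=2))


@pytest.fixture(scope="session")
def highsep_labeled(highsep_cohort):
    return highsep_cohort.labeled_variants()


@pytest.fixture(scope="session")
def cohort_dir(default_cohort, tmp_path_factory):
    """The default cohort written to disk in its standard file formats."""
    d = tmp_path_factory.mktemp("cohort")
    paths = default_cohort.write(d)
    return d, paths


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
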