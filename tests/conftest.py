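import numpy as np
import pytest

from seqstain.io_formats import packaged_table1_path, read_cohort_table
from seqstain.synthetic import SlideSimParams, generate_multiround_slide


@pytest.fixture(scope="session")
def table1():
    """The packaged study cohort, values as printed."""
    return read_cohort_table(packaged_table1_path())


@pytest.fixture(scope="session")
def default_slide():
    """One deterministic two-round synthetic slide with ground truth."""
    return generate_multiround_slide(SlideSimParams(seed=1))


@pytest.fixture(scope="session")
def small_slide_params():
    """Cheap slide configuration for tests that regenerate many slides."""
    return SlideSimParams(shape=(192, 192), n_cells=30, seed=0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
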