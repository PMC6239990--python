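import numpy as np
import pytest

from volsurf.synthetic import PhantomSpec, make_cohort, make_template


@pytest.fixture(scope="session")
def small_spec():
    """A reduced phantom for unit tests: coarse grid, coarse icosphere."""
    return PhantomSpec(
        grid_shape=(36, 36, 36),
        r_in=10.0,
        r_out=14.0,
        n_parcels=8,
        n_subjects=3,
        amplitude=1.0,
        jitter_deg=2.0,
        seed=7,
        subdivisions=2,
    )


@pytest.fixture(scope="session")
def small_template(small_spec):
    return make_template(small_spec)


@pytest.fixture(scope="session")
def small_cohort(small_spec, small_template):
    cohort, truth = make_cohort(small_spec, small_template)
    return cohort, truth


@pytest.fixture(scope="session")
def zero_spec():
    """Zero-amplitude, zero-jitter conditions at reduced scale."""
    return PhantomSpec(
        grid_shape=(36, 36, 36),
        r_in=10.0,
        r_out=14.0,
        n_parcels=8,
        n_subjects=3,
        amplitude=0.0,
        jitter_deg=0.0,
        seed=11,
        subdivisions=2,
    )


@pytest.fixture(scope="session")
def zero_template(zero_spec):
    return make_template(zero_spec)


@pytest.fixture(scope="session")
def zero_cohort(zero_spec, zero_template):
    cohort, truth = make_cohort(zero_spec, zero_template)
    return cohort, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
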