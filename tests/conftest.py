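import pytest

from cinelv.synthetic import (
    CohortSpec,
    InfarctSpec,
    PhantomSpec,
    generate_cohort,
    generate_phantom,
)
from cinelv.volumetry import quantify


@pytest.fixture(scope="session")
def default_phantom():
    """Default no-infarct phantom: 7 x 1 mm slices, 20 phases, EF ~ 60%."""
    return generate_phantom(PhantomSpec())


@pytest.fixture(scope="session")
def default_quantified(default_phantom):
    study, _truth = default_phantom
    return quantify(study)


@pytest.fixture(scope="session")
def infarct_phantom():
    """Phantom with a 90 degree thinned, akinetic wedge on all slices."""
    spec = PhantomSpec(infarct=InfarctSpec(theta_extent_deg=90.0))
    return generate_phantom(spec)


@pytest.fixture(scope="session")
def small_phantom_spec():
    """Reduced phantom for IO / CLI tests (fast to generate and write)."""
    return PhantomSpec(n_slices=4, n_phases=6, vertices_per_contour=32,
                       cavity_length_mm=4.5, slice_thickness_mm=1.0)


@pytest.fixture(scope="session")
def default_cohort():
    cohort, truth = generate_cohort(CohortSpec(seed=7))
    return cohort, truth
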