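import pytest
from hypothesis import settings

from spinemorph.phantom import PhantomSpec, generate_cohort, generate_phantom
from spinemorph.workflow import DEFAULT_GRADE_MIX

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_case():
    """One noise-free phantom with the default mildly lordotic geometry."""
    return generate_phantom(PhantomSpec(seed=0))


@pytest.fixture(scope="session")
def small_cohort():
    """Ten noise-free phantoms across all three lordosis grades."""
    return generate_cohort(10, DEFAULT_GRADE_MIX, seed=5)
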