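import numpy as np
import pytest

from mbdwi.signal_models import BValueScheme
from mbdwi.synthetic import CohortSpec, LesionPhantomSpec, make_lesion_phantom


@pytest.fixture(scope="session")
def scheme() -> BValueScheme:
    return BValueScheme()


@pytest.fixture(scope="session")
def malignant_phantom(scheme):
    """One noiseless malignant phantom shared by read-only tests."""
    spec = LesionPhantomSpec(label="malignant")
    return make_lesion_phantom(spec, scheme, seed=42)


@pytest.fixture(scope="session")
def ellipsoid_mask():
    """An ideal ellipsoid mask with no boundary irregularity."""
    spec = LesionPhantomSpec(label="benign", irregularity=0.0,
                             semi_axes_mm=(6.0, 5.0, 4.0))
    scheme = BValueScheme()
    _, mask, _ = make_lesion_phantom(spec, scheme, seed=7)
    return mask


def pytest_configure(config):
    # keep hypothesis reproducible in CI-free environments
    try:
        from hypothesis import settings

        settings.register_profile("repro", derandomize=True, deadline=None)
        settings.load_profile("repro")
    except ImportError:
        pass
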