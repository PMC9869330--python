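import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from hdpsig import MutationCatalog, enumerate_classes
from hdpsig.catalogs import CatalogScheme

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def sbs96():
    return enumerate_classes("SBS96")


@pytest.fixture(scope="session")
def id83():
    return enumerate_classes("ID83")


@pytest.fixture
def toy_scheme():
    """A generic 4-class scheme for arithmetic-level checks."""
    return CatalogScheme("classes4", ("c0", "c1", "c2", "c3"))


@pytest.fixture
def small_catalog(sbs96):
    """96 x 3 catalog with reproducible random counts."""
    rng = np.random.default_rng(123)
    counts = rng.integers(0, 20, size=(96, 3))
    return MutationCatalog(sbs96, ["S1", "S2", "S3"], counts)
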