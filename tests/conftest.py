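import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from caninedsd.core_io import (
    HET,
    HOM_ALT,
    HOM_REF,
    MISSING,
    GenotypeMatrix,
    VariantSite,
)

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def tiny_matrix() -> GenotypeMatrix:
    """3 samples x 2 sites covering every call class plus a missing cell."""
    sites = [VariantSite("chr1", 100, "A", "C"), VariantSite("chr1", 200, "G", "T")]
    calls = np.array([[HOM_REF, HET], [HET, MISSING], [HOM_ALT, HOM_ALT]], dtype=np.int8)
    return GenotypeMatrix(sites, ["S1", "S2", "S3"], calls)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20251001)


def random_matrix(
    rng: np.random.Generator,
    n_samples: int,
    n_sites: int,
    missing_rate: float = 0.0,
) -> GenotypeMatrix:
    calls = rng.integers(0, 3, size=(n_samples, n_sites)).astype(np.int8)
    if missing_rate:
        calls[rng.random((n_samples, n_sites)) < missing_rate] = MISSING
    sites = [VariantSite("chr1", 10 * (j + 1), "A", "C") for j in range(n_sites)]
    return GenotypeMatrix(sites, [f"S{i}" for i in range(n_samples)], calls)
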