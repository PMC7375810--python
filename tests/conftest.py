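import numpy as np
import pytest

from dynamotype.canonical_model import PathSpec, SphericalPoint


@pytest.fixture(scope="session")
def snsh_path() -> PathSpec:
    """The classic square-wave (SN/SH) exemplar path on the R=0.4 sphere."""
    from dynamotype.experiments import default_path

    return default_path("SN/SH")


@pytest.fixture(scope="session")
def coarse_map():
    """A coarse region map shared by the map tests (fast to build)."""
    from dynamotype.seizure_map import build_region_map

    return build_region_map(0.4, 61, 121)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
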