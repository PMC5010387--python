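import numpy as np
import pytest

from lipodimer.labeling import LabelingYields
from lipodimer.liposomes import RadiusDistribution, default_radius_distribution


@pytest.fixture(scope="session")
def yields() -> LabelingYields:
    """Pooled experimental labeling yields."""
    return LabelingYields(p_cy5=0.72, p_ns=0.14)


@pytest.fixture(scope="session")
def perfect_yields() -> LabelingYields:
    return LabelingYields(p_cy5=1.0, p_ns=0.0)


@pytest.fixture(scope="session")
def radius_dist() -> RadiusDistribution:
    """Packaged synthetic stand-in radius distribution."""
    return default_radius_distribution()


@pytest.fixture(scope="session")
def three_bin_dist() -> RadiusDistribution:
    """Tiny heterogeneous population for exact cross-checks."""
    return RadiusDistribution(
        radii=np.array([20.0, 35.0, 60.0]),
        probs=np.array([0.3, 0.5, 0.2]),
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
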