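import numpy as np
import pytest

from muracam import (
    CameraGeometry,
    MaskPattern,
    SourceScene,
    simulate_detector_image,
)


@pytest.fixture(scope="session")
def geometry():
    """The experimental camera geometry (all defaults)."""
    return CameraGeometry()


@pytest.fixture(scope="session")
def pattern():
    return MaskPattern.from_rank(31)


def _point_source(z, intensity=1e6):
    return SourceScene(sources=[(0.0, 0.0, float(z), intensity)])


@pytest.fixture(scope="session")
def noiseless_30(geometry, pattern):
    """Noiseless centered point source at 30 mm."""
    return simulate_detector_image(_point_source(30.0), geometry,
                                   noisy=False, pattern=pattern)


@pytest.fixture(scope="session")
def noisy_30(geometry, pattern):
    """Poisson-noisy centered point source at 30 mm (fixed seed)."""
    return simulate_detector_image(_point_source(30.0), geometry,
                                   seed=7, noisy=True, pattern=pattern)


@pytest.fixture(scope="session")
def noiseless_50(geometry, pattern):
    return simulate_detector_image(_point_source(50.0), geometry,
                                   noisy=False, pattern=pattern)
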