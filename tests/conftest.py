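import numpy as np
import pytest
from scipy.stats import ncx2

from pbsqa.geometry import (
    DetectorAperture,
    DetectorGeometry,
    DetectorId,
    DetectorRole,
    SpotModel,
)


@pytest.fixture(scope="session")
def geometry() -> DetectorGeometry:
    return DetectorGeometry.default()


@pytest.fixture(scope="session")
def cax_spot() -> SpotModel:
    return SpotModel(4.8)


@pytest.fixture(scope="session")
def cax_aperture() -> DetectorAperture:
    return DetectorAperture(DetectorId.CAX, 13.8, DetectorRole.CENTERING_CHAMBER)


@pytest.fixture(scope="session")
def diode_spot() -> SpotModel:
    return SpotModel(2.2)


@pytest.fixture(scope="session")
def diode_aperture() -> DetectorAperture:
    return DetectorAperture(DetectorId.T2, 0.8, DetectorRole.POSITIONING_DIODE)


def disk_probability_fraction(r, sigma, radius):
    """Independent closed-form oracle for the normalized disk signal.

    A bivariate isotropic normal with mean at distance r and std sigma
    falls inside a centred disk of the given radius with probability
    ncx2.cdf((radius/sigma)^2, df=2, nc=(r/sigma)^2); the normalized
    signal is the ratio of that probability to its value at r=0.
    """
    r = np.asarray(r, dtype=float)
    num = ncx2.cdf((radius / sigma) ** 2, 2, (r / sigma) ** 2)
    den = ncx2.cdf((radius / sigma) ** 2, 2, 0.0)
    return num / den
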