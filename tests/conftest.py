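import numpy as np
import pytest

from sfsmac import FiberGeometry, ReferenceSpectra, SpectralFrame, TissueOptics


def make_frame(intensities, wavelengths=None, rate=10.0, meta=None):
    """Frame from an (n_times, n_wavelengths) array with a uniform clock."""
    intensities = np.atleast_2d(np.asarray(intensities, dtype=float))
    n_t, n_w = intensities.shape
    if wavelengths is None:
        wavelengths = 500.0 + 5.0 * np.arange(n_w)
    times = np.arange(n_t) / rate
    meta = dict(meta or {})
    meta.setdefault("sampling_rate_hz", rate)
    return SpectralFrame(np.asarray(wavelengths, float), times, intensities, meta)


@pytest.fixture
def simple_refs():
    w = np.array([500.0, 545.0, 600.0, 680.0])
    return ReferenceSpectra(w, np.full(4, 10.0), np.full(4, 2.0))


@pytest.fixture(scope="session")
def geom():
    return FiberGeometry()


@pytest.fixture(scope="session")
def tissue():
    return TissueOptics()  # 1% blood volume, 35% sO2, intralipid scattering
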