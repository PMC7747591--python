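import numpy as np
import pytest

from cordmt.phantom import (
    GeometryConfig,
    TissueParams,
    make_tract_atlas,
    simulate_slice_pair,
)

CORD_AREA_MM2 = float(np.pi * 6.5 * 4.25)


@pytest.fixture(scope="session")
def atlas():
    """Default crisp (binary-tract) atlas on the 128x128 grid."""
    return make_tract_atlas()


@pytest.fixture(scope="session")
def soft_atlas():
    """Probabilistic atlas with partial-volume mixing at tissue boundaries."""
    return make_tract_atlas(GeometryConfig(soften_sigma=1.0))


@pytest.fixture(scope="session")
def exact_pair(atlas):
    """Noiseless, unblurred, perfectly aligned pair with uniform WM MTR 40%."""
    tissue = TissueParams(mtr_wm_baseline=40.0, noise_sigma=0.0, psf_sigma_px=0.0)
    return simulate_slice_pair(atlas, tissue, seed=0)


@pytest.fixture(scope="session")
def smooth_pair(atlas):
    """Noiseless pair with the default acquisition blur (for registration)."""
    tissue = TissueParams(mtr_wm_baseline=40.0, noise_sigma=0.0)
    return simulate_slice_pair(atlas, tissue, seed=0)
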