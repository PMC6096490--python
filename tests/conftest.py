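import warnings

import numpy as np
import pytest

import sharpmax as sx

# mask-stability warnings on tiny fixtures are expected and uninformative
warnings.filterwarnings("ignore", message="molecule-volume fraction")


@pytest.fixture(scope="session")
def chain_fixture():
    """Default bonded-chain fixture: blurred (B=80) noisy map + model,
    boxed to within 5 A of the model as real survey maps are."""
    fx = sx.make_map(sx.SyntheticSpec(seed=3, true_b=80.0, noise_sigma=0.008))
    region, model = sx.extract_region_near_model(fx["map"], fx["model"], 5.0)
    fx["region"] = region
    fx["region_model"] = model
    return fx


@pytest.fixture(scope="session")
def blob_fixture():
    """Globular fixture (uniform packing) used where iso-contour
    connectivity should mimic a folded molecule."""
    fx = sx.make_map(sx.SyntheticSpec(seed=1, true_b=80.0, noise_sigma=0.008,
                                      layout="blob"))
    region, model = sx.extract_region_near_model(fx["map"], fx["model"], 5.0)
    fx["region"] = region
    fx["region_model"] = model
    return fx


@pytest.fixture(scope="session")
def blob_trace(blob_fixture):
    """One full sharpening scan of the globular fixture."""
    _, trace = sx.auto_sharpen_sa(blob_fixture["region"], 3.0)
    return trace


def falloff_coeffs(b, n=16, cell=16.0):
    """Coefficients with an exact isotropic Wilson falloff exp(-B s^2/4)."""
    ref = sx.FourierCoefficients(np.zeros((n, n, n), dtype=complex),
                                 np.full(3, cell))
    s2 = ref.s2_grid()
    ref.data = np.exp(-b * s2 / 4.0).astype(complex)
    return ref
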