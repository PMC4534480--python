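import numpy as np
import pytest

import perfvec as pv
from perfvec.phantom import AcquisitionSpec, apply_gaussian_blur, render_volume


@pytest.fixture(scope="session")
def solved_shape():
    """Default ventricle rescaled to the 148 mL cavity volume."""
    return pv.solve_cavity_volume(pv.LVShapeSpec())


@pytest.fixture(scope="session")
def default_grid(solved_shape):
    return pv.build_lv_surface(solved_shape)


@pytest.fixture(scope="session")
def noiseless_acq():
    return AcquisitionSpec(noise=False)


@pytest.fixture(scope="session")
def blurred_normal_volume(solved_shape, noiseless_acq):
    """Noise-free, blurred rendering of the defect-free phantom."""
    vol = render_volume(solved_shape, None, noiseless_acq)
    return apply_gaussian_blur(vol, noiseless_acq.blur_fwhm)


def random_small_grid(rng: np.random.Generator) -> pv.SurfaceGrid:
    """A random 3-50 rectangle grid with positive areas and weights."""
    n = int(rng.integers(3, 51))
    return pv.SurfaceGrid(
        centers=rng.normal(scale=30.0, size=(n, 3)),
        areas=rng.uniform(0.1, 5.0, size=n),
        weights=rng.uniform(0.0, 3.0, size=n) + 1e-6,
    )


def brute_force_centroid(grid: pv.SurfaceGrid, weights=None) -> np.ndarray:
    """Independent scalar-loop evaluation of the weighted-centroid sums."""
    w = grid.weights if weights is None else weights
    num = [0.0, 0.0, 0.0]
    den = 0.0
    for i in range(len(grid)):
        aw = float(grid.areas[i]) * float(w[i])
        den += aw
        for k in range(3):
            num[k] += float(grid.centers[i, k]) * aw
    return np.array([num[k] / den for k in range(3)])
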