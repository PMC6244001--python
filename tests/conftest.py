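import numpy as np
import pytest

import laminarsim as ls


@pytest.fixture(scope="session")
def flat_patch():
    """3 mm flat cortex, 12 mm long, default 0.01 mm raster."""
    return ls.make_flat_patch(3.0, 12.0)


@pytest.fixture(scope="session")
def variable_patch():
    """Seeded anatomically-inspired patch, thickness 1.7-3.7 mm."""
    return ls.make_variable_patch(1.7, 3.7, 20.0, 5.0, 42)


@pytest.fixture(scope="session")
def fine_flat_patch():
    """Flat 3 mm cortex on a 0.25 um raster for quadrature-limited oracles."""
    return ls.make_flat_patch(3.0, 0.75, resolution_mm=0.00025, margin_mm=0.5)


def gaussian_voxel_mean_oracle(center_mm, sigma_mm, peak, lo, hi, gm=(0.0, 3.0)):
    """Closed-form mean of a depth-Gaussian over the y-interval [lo, hi].

    The field is zero outside GM, so the integral runs over the
    intersection with ``gm``; the mean divides by the full voxel height.
    """
    from scipy.special import ndtr

    a, b = max(lo, gm[0]), min(hi, gm[1])
    if b <= a:
        return 0.0
    integral = (
        peak
        * sigma_mm
        * np.sqrt(2.0 * np.pi)
        * (ndtr((b - center_mm) / sigma_mm) - ndtr((a - center_mm) / sigma_mm))
    )
    return integral / (hi - lo)
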