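"""Shared fixtures and independent brute-force oracles.

The oracles here deliberately re-derive quantities with naive loops so they
stay independent of the vectorised implementation paths they check.
"""

from __future__ import annotations

import math

import numpy as np
import pytest

from phenopet.pvc import PSFModel
from phenopet.synthcohort import PhantomSpec, Sphere, default_phantom_spec, make_phantom


def brute_force_blur(image: np.ndarray, sigmas, truncate: float = 6.0) -> np.ndarray:
    """Full-kernel Gaussian convolution with edge renormalisation.

    Builds the complete (non-separable) N-D kernel as an outer product and,
    for every voxel, sums the product over the in-bounds window explicitly —
    an independent path from the separable scipy-based implementation.
    """
    image = np.asarray(image, dtype=float)
    sigmas = np.broadcast_to(np.atleast_1d(np.asarray(sigmas, float)), (image.ndim,))
    kernels = []
    for sigma in sigmas:
        if sigma == 0:
            kernels.append(np.ones(1))
            continue
        radius = int(math.ceil(truncate * sigma))
        x = np.arange(-radius, radius + 1, dtype=float)
        k = np.exp(-0.5 * (x / sigma) ** 2)
        kernels.append(k / k.sum())
    full = kernels[0]
    for k in kernels[1:]:
        full = np.multiply.outer(full, k)
    radii = [len(k) // 2 for k in kernels]
    out = np.zeros_like(image)
    for idx in np.ndindex(image.shape):
        img_sl, ker_sl = [], []
        for axis, r in enumerate(radii):
            lo = max(0, idx[axis] - r)
            hi = min(image.shape[axis], idx[axis] + r + 1)
            img_sl.append(slice(lo, hi))
            ker_sl.append(slice(lo - idx[axis] + r, hi - idx[axis] + r))
        window = full[tuple(ker_sl)]
        out[idx] = float((image[tuple(img_sl)] * window).sum() / window.sum())
    return out


@pytest.fixture(scope="session")
def small_phantom():
    """Compact 24^3 phantom with known activities, for fast PVC tests."""
    spec = default_phantom_spec(grid=24, voxel_size_mm=2.0, n_spheres=4)
    labels, activity = make_phantom(spec)
    truth = {r[0]: r[2] for r in spec.regions}
    truth[0] = spec.background_activity
    return spec, labels, activity, truth


@pytest.fixture(scope="session")
def tiny_psf():
    return PSFModel(fwhm_mm=8.0, voxel_size_mm=2.0)


@pytest.fixture
def two_sphere_spec():
    return PhantomSpec(
        grid_shape=(16, 16, 16),
        voxel_size_mm=2.0,
        regions=(
            (1, Sphere((5, 5, 8), 3.0), 2.0),
            (2, Sphere((11, 11, 8), 3.0), 0.5),
        ),
        background_activity=0.0,
        reference_labels=(2,),
    )
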