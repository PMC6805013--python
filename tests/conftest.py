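"""Shared fixtures: small synthetic inputs with exact ground truth."""

import numpy as np
import pytest

from blebkit.membrane import ModelParams, make_vesicle_mesh


@pytest.fixture(scope="session")
def small_mesh():
    """Relaxed 162-vertex vesicle reused by read-only geometry tests."""
    return make_vesicle_mesh(162, seed=3)


@pytest.fixture(scope="session")
def sphere_mesh_600():
    """Well-relaxed 600-vertex sphere for curvature/bending checks."""
    return make_vesicle_mesh(600, seed=1)


@pytest.fixture()
def default_params():
    return ModelParams()


@pytest.fixture()
def disk_footprint():
    """Odd-sized pixel disk, exactly symmetric about its center pixel."""

    def _make(radius: int = 25, pad: int = 4):
        size = 2 * (radius + pad) + 1
        c = radius + pad
        rows, cols = np.mgrid[0:size, 0:size]
        fp = (rows - c) ** 2 + (cols - c) ** 2 <= radius**2
        return fp, (c, c), radius

    return _make
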