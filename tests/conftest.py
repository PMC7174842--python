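import numpy as np
import pytest

from dotstripe.geometry import DigitGeometry, GridSpec, full_masks


@pytest.fixture
def grid():
    return GridSpec(64, 32, 1.0)


@pytest.fixture
def square_grid():
    return GridSpec(128, 128, 1.0)


@pytest.fixture
def digit():
    # axis-aligned digit centred on a grid row (y = 16 is a bin edge)
    return DigitGeometry(L0=30, L=40, W=10, eps=5, anchor=(10.0, 16.0))


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def make_bands(shape, n_bands, axis="x"):
    """Field with n_bands cosine bands across the chosen axis."""
    ny, nx = shape
    if axis == "x":
        x = np.arange(nx)
        return np.tile(np.cos(2 * np.pi * n_bands * x / nx), (ny, 1))
    y = np.arange(ny)
    return np.tile(np.cos(2 * np.pi * n_bands * y / ny), (nx, 1)).T


def gaussian_bump(shape, cy, cx, width=2.0, amp=1.0):
    ny, nx = shape
    Y, X = np.mgrid[0:ny, 0:nx]
    return amp * np.exp(-((Y - cy) ** 2 + (X - cx) ** 2) / (2 * width**2))
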