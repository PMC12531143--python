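import numpy as np
import pytest

from fcnm.synthetic import default_grid, ellipsoid_gm_mask
from fcnm.volumes import BinaryMask, Volume3D


@pytest.fixture
def grid():
    """3-mm isotropic 12x14x12 template centered on the origin."""
    return default_grid((12, 14, 12), 3.0)


@pytest.fixture
def gm(grid):
    return ellipsoid_gm_mask(grid)


@pytest.fixture
def identity_grid():
    """Unit-spacing grid with an identity affine, for hand geometry checks."""
    return Volume3D(np.zeros((9, 9, 9)), np.eye(4))


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


def brute_force_sphere(coords_mm, radius_mm, grid):
    """Independent sphere oracle: per-voxel loop over center distances,
    always including the voxel containing each in-grid coordinate."""
    shape = grid.shape
    out = np.zeros(shape, dtype=np.uint8)
    inv = np.linalg.inv(grid.affine)
    coords = np.atleast_2d(np.asarray(coords_mm, dtype=float))
    for i in range(shape[0]):
        for j in range(shape[1]):
            for k in range(shape[2]):
                center = (grid.affine @ np.array([i, j, k, 1.0]))[:3]
                for c in coords:
                    if np.sqrt(((center - c) ** 2).sum()) <= radius_mm + 1e-9:
                        out[i, j, k] = 1
    for c in coords:
        nearest = np.rint((inv @ np.append(c, 1.0))[:3]).astype(int)
        if np.all(nearest >= 0) and np.all(nearest < np.array(shape)):
            out[tuple(nearest)] = 1
    return BinaryMask(out, grid.affine)


def bh_stepup(p, q):
    """Hand-rolled Benjamini-Hochberg: reject H_(1..k*) for the largest k
    with p_(k) <= k*q/m. Returns a boolean reject vector (original order)."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    sorted_p = p[order]
    thresh = (np.arange(1, m + 1) * q) / m
    below = np.where(sorted_p <= thresh)[0]
    reject = np.zeros(m, dtype=bool)
    if below.size:
        reject[order[: below[-1] + 1]] = True
    return reject


def bh_adjust(p):
    """Hand-rolled BH adjusted p-values: monotone min of p_(i) * m / i."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    adj = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(adj[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out
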