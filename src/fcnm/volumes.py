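"""Volumetric data model: NIfTI I/O, coordinate geometry, sphere seeds, smoothing.

All maps in the pipeline are carried by :class:`Volume3D` / :class:`Volume4D`
(a scalar grid plus a 4x4 voxel-index -> mm affine, NIfTI RAS+ convention,
0-based indices). Binary masks share the same geometry. Spheres are voxelized
on the analysis grid by a closed-ball test on voxel-center distance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np

__all__ = [
    "Volume3D",
    "Volume4D",
    "BinaryMask",
    "read_volume",
    "write_volume",
    "mm_to_voxel",
    "voxel_to_mm",
    "voxel_centers_mm",
    "make_sphere_seed",
    "smooth_gaussian",
    "filter_coords_in_mask",
]

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


def _check_affine(affine: np.ndarray) -> np.ndarray:
    affine = np.asarray(affine, dtype=float)
    if affine.shape != (4, 4):
        raise ValueError(f"affine must be 4x4, got {affine.shape}")
    if abs(np.linalg.det(affine[:3, :3])) < 1e-12:
        raise ValueError("affine is singular")
    return affine


@dataclass
class Volume3D:
    """A 3-D scalar grid with a voxel-index -> mm affine."""

    data: np.ndarray
    affine: np.ndarray
    space_label: str = "MNI152"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"Volume3D needs 3-D data, got shape {self.data.shape}")
        if min(self.data.shape) < 1:
            raise ValueError("grid dimensions must be >= 1 on each axis")
        self.affine = _check_affine(self.affine)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def spacing(self) -> np.ndarray:
        """Voxel edge lengths in mm per axis."""
        return np.sqrt((self.affine[:3, :3] ** 2).sum(axis=0))

    def same_geometry(self, other: "Volume3D | Volume4D") -> bool:
        return self.shape[:3] == tuple(other.data.shape[:3]) and np.allclose(
            self.affine, other.affine
        )


@dataclass
class Volume4D:
    """A 3-D grid x T time points, with repetition time in seconds."""

    data: np.ndarray
    affine: np.ndarray
    tr_seconds: float = 2.0
    space_label: str = "MNI152"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 4:
            raise ValueError(f"Volume4D needs 4-D data, got shape {self.data.shape}")
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")
        self.affine = _check_affine(self.affine)

    @property
    def shape(self) -> tuple[int, int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def n_volumes(self) -> int:
        return self.data.shape[3]

    @property
    def spacing(self) -> np.ndarray:
        return np.sqrt((self.affine[:3, :3] ** 2).sum(axis=0))

    def template(self) -> Volume3D:
        """A 3-D template volume sharing this grid and affine."""
        return Volume3D(np.zeros(self.data.shape[:3]), self.affine, self.space_label)


@dataclass
class BinaryMask(Volume3D):
    """A Volume3D whose values are restricted to {0, 1}."""

    def __post_init__(self) -> None:
        super().__post_init__()
        vals = np.unique(self.data)
        if not np.all(np.isin(vals, (0, 1))):
            raise ValueError("BinaryMask values must be in {0, 1}")
        self.data = self.data.astype(np.uint8)

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())

    def indices(self) -> np.ndarray:
        """(n, 3) integer voxel indices of mask voxels."""
        return np.argwhere(self.data > 0)


def read_volume(path: str | Path) -> Volume3D | Volume4D:
    """Read a NIfTI-1/2 file into a Volume3D or Volume4D.

    TR for 4-D images is taken from the header zooms. Raises on missing
    files, non-NIfTI payloads, and images that are entirely NaN.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj, dtype=float)
    if np.all(np.isnan(data)):
        raise ValueError(f"{path}: image is entirely NaN")
    if data.ndim == 3:
        return Volume3D(data, img.affine)
    if data.ndim == 4:
        tr = float(img.header.get_zooms()[3]) if len(img.header.get_zooms()) > 3 else 0.0
        if tr <= 0:
            tr = 2.0
        return Volume4D(data, img.affine, tr_seconds=tr)
    raise ValueError(f"{path}: unsupported dimensionality {data.ndim}")


def write_volume(vol: Volume3D | Volume4D, path: str | Path) -> Path:
    """Write a volume to NIfTI; the affine is written exactly as held."""
    path = Path(path)
    img = nib.Nifti1Image(np.asarray(vol.data, dtype=np.float32), vol.affine)
    if isinstance(vol, Volume4D):
        zooms = list(img.header.get_zooms())
        zooms[3] = vol.tr_seconds
        img.header.set_zooms(zooms)
    nib.save(img, str(path))
    return path


def mm_to_voxel(affine: np.ndarray, coord_mm: Sequence[float]) -> np.ndarray:
    """Continuous (fractional) voxel index of an mm coordinate."""
    affine = _check_affine(affine)
    coord = np.asarray(coord_mm, dtype=float)
    return np.linalg.solve(affine, np.append(coord, 1.0))[:3]


def voxel_to_mm(affine: np.ndarray, index: Sequence[float]) -> np.ndarray:
    """mm coordinate of a (possibly fractional) voxel index."""
    affine = _check_affine(affine)
    idx = np.asarray(index, dtype=float)
    return (affine @ np.append(idx, 1.0))[:3]


def voxel_centers_mm(shape: Sequence[int], affine: np.ndarray) -> np.ndarray:
    """mm coordinates of every voxel center, shape (prod(shape), 3)."""
    grid = np.indices(tuple(shape)).reshape(3, -1).T.astype(float)
    homog = np.c_[grid, np.ones(len(grid))]
    return (np.asarray(affine) @ homog.T).T[:, :3]


def make_sphere_seed(
    coords_mm: Sequence[Sequence[float]],
    radius_mm: float,
    grid: Volume3D,
) -> BinaryMask:
    """Union of spheres around mm coordinates, voxelized on ``grid``.

    A voxel belongs to a sphere iff its center lies within <= radius_mm of
    the coordinate (closed ball). The voxel containing each in-grid
    coordinate is always included, so a radius smaller than the voxel
    spacing still yields a nonempty sphere for any coordinate inside the
    grid. Raises if the union is empty (all coordinates outside the grid).
    """
    coords = np.atleast_2d(np.asarray(coords_mm, dtype=float))
    if coords.shape[0] < 1 or coords.shape[1] != 3:
        raise ValueError("need at least one 3-vector coordinate")
    if radius_mm <= 0:
        raise ValueError("radius_mm must be positive")
    centers = voxel_centers_mm(grid.shape, grid.affine)
    mask = np.zeros(len(centers), dtype=bool)
    shape = np.array(grid.shape)
    inv = np.linalg.inv(grid.affine)
    for c in coords:
        d2 = ((centers - c) ** 2).sum(axis=1)
        mask |= d2 <= radius_mm**2 + 1e-9
        nearest = np.rint((inv @ np.append(c, 1.0))[:3]).astype(int)
        if np.all(nearest >= 0) and np.all(nearest < shape):
            mask[np.ravel_multi_index(tuple(nearest), grid.shape)] = True
    if not mask.any():
        raise ValueError("empty seed: all coordinates fall outside the grid")
    return BinaryMask(mask.reshape(grid.shape).astype(np.uint8), grid.affine, grid.space_label)


def smooth_gaussian(vol: Volume3D | Volume4D, fwhm_mm: float):
    """Spatial Gaussian smoothing with FWHM given in mm.

    sigma = fwhm / (2 * sqrt(2 ln 2)) per axis, converted to voxel units via
    the voxel spacing. Reflective boundary handling; fwhm 0 is the identity.
    """
    from scipy import ndimage

    if fwhm_mm < 0:
        raise ValueError("fwhm_mm must be nonnegative")
    if fwhm_mm == 0:
        return vol
    sigma_vox = fwhm_mm * _FWHM_TO_SIGMA / vol.spacing
    if isinstance(vol, Volume4D):
        out = ndimage.gaussian_filter(
            vol.data.astype(float), sigma=(*sigma_vox, 0.0), mode="reflect"
        )
        return Volume4D(out, vol.affine, vol.tr_seconds, vol.space_label)
    out = ndimage.gaussian_filter(vol.data.astype(float), sigma=sigma_vox, mode="reflect")
    return Volume3D(out, vol.affine, vol.space_label)


def filter_coords_in_mask(
    coords_mm: Sequence[Sequence[float]], mask: BinaryMask
) -> tuple[list[np.ndarray], list[np.ndarray]]:
    """Partition coordinates by whether their nearest voxel is inside the mask.

    Nearest-voxel assignment rounds the continuous voxel index; coordinates
    mapping outside the grid are dropped. Order is preserved; an empty
    retained list is a legal outcome.
    """
    retained: list[np.ndarray] = []
    dropped: list[np.ndarray] = []
    inv = np.linalg.inv(mask.affine)
    for c in coords_mm:
        coord = np.asarray(c, dtype=float)
        idx = np.rint((inv @ np.append(coord, 1.0))[:3]).astype(int)
        inside = np.all(idx >= 0) and np.all(idx < np.array(mask.shape))
        if inside and mask.data[tuple(idx)] > 0:
            retained.append(coord)
        else:
            dropped.append(coord)
    return retained, dropped
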