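"""Analysis grid and brain mask.

The analysis lattice is an isotropic grid in Talairach mm covering the brain
bounding box x in [-70, 70], y in [-104, 68], z in [-50, 78] at 2 mm by
default.  Voxel (i, j, k) sits at ``lower_bound + index * voxel_size``; the
affine is the corresponding diagonal NIfTI affine.
"""

from __future__ import annotations

from dataclasses import dataclass

import nibabel as nib
import numpy as np

from .errors import FociInputError, GridMismatchError


@dataclass(frozen=True)
class GridSpec:
    voxel_size: float = 2.0
    x_range: tuple[float, float] = (-70.0, 70.0)
    y_range: tuple[float, float] = (-104.0, 68.0)
    z_range: tuple[float, float] = (-50.0, 78.0)

    def __post_init__(self) -> None:
        if self.voxel_size <= 0:
            raise FociInputError("voxel size must be positive")
        for lo, hi in (self.x_range, self.y_range, self.z_range):
            if hi <= lo:
                raise FociInputError("grid ranges must be increasing")

    @property
    def origin(self) -> np.ndarray:
        return np.array(
            [self.x_range[0], self.y_range[0], self.z_range[0]], dtype=float
        )

    @property
    def shape(self) -> tuple[int, int, int]:
        vs = self.voxel_size
        return tuple(
            int(np.floor((hi - lo) / vs)) + 1
            for lo, hi in (self.x_range, self.y_range, self.z_range)
        )

    @property
    def affine(self) -> np.ndarray:
        aff = np.diag([self.voxel_size] * 3 + [1.0])
        aff[:3, 3] = self.origin
        return aff

    @property
    def voxel_volume(self) -> float:
        return float(self.voxel_size**3)

    def axis_coords(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """mm coordinates of voxel centers along each axis."""
        return tuple(
            self.origin[a] + self.voxel_size * np.arange(self.shape[a])
            for a in range(3)
        )

    def ijk_to_mm(self, ijk) -> np.ndarray:
        return self.origin + np.asarray(ijk, dtype=float) * self.voxel_size

    def mm_to_ijk(self, mm) -> np.ndarray:
        """Nearest-voxel index; may fall outside the grid (caller clips)."""
        return np.rint((np.asarray(mm, dtype=float) - self.origin) / self.voxel_size).astype(int)


def check_same_grid(a: GridSpec, b: GridSpec) -> None:
    if a != b:
        raise GridMismatchError(f"grids differ: {a} vs {b}")


def ellipsoid_mask(grid: GridSpec, shrink: float = 0.95) -> np.ndarray:
    """Procedural brain mask: an ellipsoid inscribed in the grid bounding box.

    A smooth stand-in for a template brain mask — adequate for simulation and
    for null calibration, where only the in-mask volume and its compactness
    matter.  Real analyses should pass a template grey-matter mask resampled
    to the analysis grid.
    """
    xs, ys, zs = grid.axis_coords()
    center = [(lo + hi) / 2 for lo, hi in (grid.x_range, grid.y_range, grid.z_range)]
    radii = [
        shrink * (hi - lo) / 2 for lo, hi in (grid.x_range, grid.y_range, grid.z_range)
    ]
    u = (xs - center[0]) / radii[0]
    v = (ys - center[1]) / radii[1]
    w = (zs - center[2]) / radii[2]
    d2 = (
        u[:, None, None] ** 2 + v[None, :, None] ** 2 + w[None, None, :] ** 2
    )
    return d2 <= 1.0


def load_mask(path, grid: GridSpec) -> np.ndarray:
    """Load a NIfTI brain mask and check it sits on the analysis grid."""
    img = nib.load(str(path))
    if tuple(img.shape[:3]) != grid.shape:
        raise GridMismatchError(
            f"mask shape {img.shape[:3]} does not match grid shape {grid.shape}"
        )
    if not np.allclose(img.affine, grid.affine, atol=1e-4):
        raise GridMismatchError("mask affine does not match the analysis grid")
    return np.asarray(img.dataobj) > 0


def save_mask(mask: np.ndarray, grid: GridSpec, path) -> None:
    img = nib.Nifti1Image(mask.astype(np.uint8), grid.affine)
    nib.save(img, str(path))
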