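"""Likelihood maps: per-study, per-condition mean, and joint.

A study's likelihood map gives, per voxel, the probability that *at least one*
of the study's foci hits the voxel — the union of the per-focus Gaussian hit
events, ``1 - prod_i (1 - p_i)``.  Maps of studies of the same condition are
averaged, and the two condition means are summed into the joint map; averaging
before summation stops the condition reporting more foci from dominating the
joint result.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Sequence

import nibabel as nib
import numpy as np

from .errors import FociInputError
from .foci import StudyFoci
from .grid import GridSpec, check_same_grid
from .kernel import KernelSpec, kernel_prob_at_distance


class MapKind(Enum):
    STUDY = "study"
    CONDITION_MEAN = "condition_mean"
    JOINT = "joint"
    PVALUE = "pvalue"


@dataclass
class LikelihoodMap:
    grid: GridSpec
    values: np.ndarray
    kind: MapKind

    def __post_init__(self) -> None:
        if tuple(self.values.shape) != self.grid.shape:
            raise FociInputError(
                f"map shape {self.values.shape} does not match grid {self.grid.shape}"
            )

    def to_nifti(self, descrip: str | None = None) -> nib.Nifti1Image:
        img = nib.Nifti1Image(self.values.astype(np.float32), self.grid.affine)
        if descrip:
            img.header["descrip"] = descrip.encode()[:79]
        return img


def _multiply_focus_survival(
    out: np.ndarray, focus_mm: np.ndarray, grid: GridSpec, k: KernelSpec
) -> None:
    """In-place multiply ``out`` by (1 - kernel_prob) over the focus patch.

    Only the bounding box of the truncation sphere is touched; everything
    outside it has kernel probability exactly zero.
    """
    r = k.truncation_radius
    vs = grid.voxel_size
    origin = grid.origin
    shape = grid.shape
    lo = np.maximum(np.ceil((focus_mm - r - origin) / vs).astype(int), 0)
    hi = np.minimum(np.floor((focus_mm + r - origin) / vs).astype(int), np.array(shape) - 1)
    if np.any(lo > hi):
        return
    ax = [origin[a] + vs * np.arange(lo[a], hi[a] + 1) - focus_mm[a] for a in range(3)]
    d = np.sqrt(
        ax[0][:, None, None] ** 2 + ax[1][None, :, None] ** 2 + ax[2][None, None, :] ** 2
    )
    p = kernel_prob_at_distance(d, k, grid.voxel_volume)
    out[lo[0] : hi[0] + 1, lo[1] : hi[1] + 1, lo[2] : hi[2] + 1] *= 1.0 - p


def study_map(
    s: StudyFoci,
    grid: GridSpec,
    k: KernelSpec,
    mask: np.ndarray | None = None,
) -> LikelihoodMap:
    """Likelihood map of one study: union of its per-focus hit probabilities."""
    if len(s.foci) == 0:
        raise FociInputError(f"study {s.study_id} has no foci")
    surv = np.ones(grid.shape, dtype=float)
    for f in s.foci:
        _multiply_focus_survival(surv, f.xyz, grid, k)
    vals = 1.0 - surv
    if mask is not None:
        vals[~mask] = 0.0
    return LikelihoodMap(grid=grid, values=vals, kind=MapKind.STUDY)


def condition_mean_map(maps: Sequence[LikelihoodMap]) -> LikelihoodMap:
    """Voxelwise mean of one condition's study maps."""
    if len(maps) == 0:
        raise FociInputError("cannot average zero maps")
    for m in maps[1:]:
        check_same_grid(maps[0].grid, m.grid)
    mean = np.mean([m.values for m in maps], axis=0)
    return LikelihoodMap(grid=maps[0].grid, values=mean, kind=MapKind.CONDITION_MEAN)


def joint_map(a: LikelihoodMap, b: LikelihoodMap) -> LikelihoodMap:
    """Voxelwise sum of the two condition means."""
    check_same_grid(a.grid, b.grid)
    return LikelihoodMap(grid=a.grid, values=a.values + b.values, kind=MapKind.JOINT)
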