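"""The ALE Gaussian focus kernel.

Each focus is modelled as an isotropic trivariate Gaussian centred on the
reported coordinate.  The probability that the focus "hits" a voxel is the
Gaussian density at the voxel centre times the voxel volume, truncated to zero
beyond a few standard deviations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import FociInputError

#: FWHM = 2 sqrt(2 ln 2) sigma
FWHM_PER_SIGMA = 2.0 * math.sqrt(2.0 * math.log(2.0))


@dataclass(frozen=True)
class KernelSpec:
    """Gaussian kernel parameters.

    fwhm
        Full width at half maximum in mm (default 8 mm, the conventional
        smoothing for VBM foci meta-analysis).
    truncation_sigmas
        Radius, in standard deviations, beyond which the kernel is exactly
        zero.  4 sigma discards < 1e-4 of the kernel mass.
    """

    fwhm: float = 8.0
    truncation_sigmas: float = 4.0

    def __post_init__(self) -> None:
        if self.fwhm <= 0:
            raise FociInputError("kernel FWHM must be positive")
        if self.truncation_sigmas < 3.0:
            raise FociInputError("truncation radius must be at least 3 sigma")

    @property
    def sigma(self) -> float:
        return self.fwhm / FWHM_PER_SIGMA

    @property
    def truncation_radius(self) -> float:
        """Truncation radius in mm."""
        return self.truncation_sigmas * self.sigma


def kernel_prob(voxel_center, focus, k: KernelSpec, voxel_volume: float):
    """Per-voxel hit probability of a single focus.

    ``voxel_center`` may be a triple or an (..., 3) array; broadcasting over
    many voxel centres at once is the intended fast path.
    """
    centers = np.asarray(voxel_center, dtype=float)
    f = np.asarray(focus, dtype=float)
    if not (np.all(np.isfinite(centers)) and np.all(np.isfinite(f))):
        raise FociInputError("non-finite input to kernel_prob")
    d2 = np.sum((centers - f) ** 2, axis=-1)
    return kernel_prob_at_distance(np.sqrt(d2), k, voxel_volume)


def kernel_prob_at_distance(dist, k: KernelSpec, voxel_volume: float):
    """Hit probability as a function of Euclidean distance in mm."""
    dist = np.asarray(dist, dtype=float)
    s2 = k.sigma**2
    dens = (2.0 * math.pi * s2) ** -1.5 * np.exp(-(dist**2) / (2.0 * s2))
    p = np.clip(dens * voxel_volume, 0.0, 1.0)
    return np.where(dist >= k.truncation_radius, 0.0, p)
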