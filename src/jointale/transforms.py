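"""Stereotactic coordinate transforms between MNI/ICBM and Talairach space.

Two published mappings are implemented:

* The Brett ``mni2tal`` approximation — a piecewise-linear map with separate
  scaling above and below the AC plane (z >= 0 vs z < 0).  Foci reported as
  "Talairach" but actually produced with this approximation are inverted back
  to MNI before the better-validated Lancaster transform is applied.
* The Lancaster ``icbm2tal`` affine.  Several fitted variants exist depending
  on which analysis software's template orientation the fit targeted; this
  package pins the SPM-oriented variant (``icbm_spm2tal``) and records that
  choice in every run manifest.

All functions accept a length-3 sequence or an (n, 3) array of mm coordinates
and return the same shape.
"""

from __future__ import annotations

import numpy as np

from .errors import FociInputError
from .foci import Focus, Space

# Brett mni2tal: 3x3 linear pieces (no translation; the origin is fixed).
# Rotation about x by ~0.05 rad combined with axis scalings 0.99/0.97/0.92
# above the AC plane and 0.99/0.97/0.84 below it.
BRETT_UP = np.array(
    [
        [0.9900, 0.0000, 0.0000],
        [0.0000, 0.9688, 0.0460],
        [0.0000, -0.0485, 0.9189],
    ]
)
BRETT_DOWN = np.array(
    [
        [0.9900, 0.0000, 0.0000],
        [0.0000, 0.9688, 0.0420],
        [0.0000, -0.0485, 0.8390],
    ]
)
_BRETT_UP_INV = np.linalg.inv(BRETT_UP)
_BRETT_DOWN_INV = np.linalg.inv(BRETT_DOWN)

# Lancaster icbm2tal, SPM-template orientation (icbm_spm2tal), homogeneous.
ICBM2TAL_SPM = np.array(
    [
        [0.9254, 0.0024, -0.0118, -1.0207],
        [-0.0048, 0.9316, -0.0871, -1.7667],
        [0.0152, 0.0883, 0.8924, 4.0926],
        [0.0000, 0.0000, 0.0000, 1.0000],
    ]
)

LANCASTER_VARIANT = "icbm_spm2tal"


def _as_points(p) -> tuple[np.ndarray, bool]:
    pts = np.asarray(p, dtype=float)
    single = pts.ndim == 1
    pts = np.atleast_2d(pts)
    if pts.shape[1] != 3:
        raise FociInputError(f"expected mm triples, got shape {pts.shape}")
    if not np.all(np.isfinite(pts)):
        raise FociInputError("non-finite coordinate passed to a transform")
    return pts, single


def brett_mni2tal(p):
    """Brett piecewise-linear MNI -> Talairach approximation.

    The branch is selected by the sign of the input (MNI) z coordinate; both
    branches agree exactly on the z = 0 plane.
    """
    pts, single = _as_points(p)
    out = pts @ BRETT_UP.T
    below = pts[:, 2] < 0
    if below.any():
        out[below] = pts[below] @ BRETT_DOWN.T
    return out[0] if single else out


def brett_tal2mni(p):
    """Exact functional inverse of :func:`brett_mni2tal`.

    The branch is selected by the sign of the *recovered MNI* z: the candidate
    from the upper-branch inverse has the same z sign as the true MNI point on
    either branch (the y contributions cancel identically in the recovered z),
    so forward/inverse round-trips are exact everywhere, including points whose
    Talairach z changed sign under the forward map.
    """
    pts, single = _as_points(p)
    out = pts @ _BRETT_UP_INV.T
    below = out[:, 2] < 0
    if below.any():
        out[below] = pts[below] @ _BRETT_DOWN_INV.T
    return out[0] if single else out


def lancaster_icbm2tal(p):
    """Lancaster icbm2tal affine (SPM-oriented variant), MNI -> Talairach."""
    pts, single = _as_points(p)
    out = pts @ ICBM2TAL_SPM[:3, :3].T + ICBM2TAL_SPM[:3, 3]
    return out[0] if single else out


def normalize_space(f: Focus) -> Focus:
    """Bring a focus into the working Talairach space.

    * ``TAL_NATIVE`` passes through unchanged.
    * ``MNI`` is mapped with the Lancaster icbm2tal affine.
    * ``TAL_BRETT`` is first undone back to MNI with the Brett inverse, then
      mapped with icbm2tal — the two-step re-conversion that replaces the
      Brett approximation with the Lancaster fit.
    """
    if f.space == Space.TAL_NATIVE:
        return f
    if f.space == Space.MNI:
        x, y, z = lancaster_icbm2tal((f.x, f.y, f.z))
    elif f.space == Space.TAL_BRETT:
        x, y, z = lancaster_icbm2tal(brett_tal2mni((f.x, f.y, f.z)))
    else:  # pragma: no cover - enum is closed
        raise FociInputError(f"unrecognized space tag {f.space!r}")
    return Focus(
        study_id=f.study_id,
        condition=f.condition,
        space=Space.TAL_NATIVE,
        x=float(x),
        y=float(y),
        z=float(z),
        direction=f.direction,
    )
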