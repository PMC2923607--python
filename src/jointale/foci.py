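"""Domain types for stereotactic foci.

A *focus* is one peak coordinate (in mm) of a significant voxel-based group
difference reported by a study, tagged with the study it came from, the
diagnostic condition of that study, the coordinate dialect it was reported in,
and the direction of the effect (grey-matter deficit or excess in patients
relative to controls).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum

import numpy as np

from .errors import FociInputError

#: Sanity bound on |x|, |y|, |z| in mm.  Real stereotactic coordinates never
#: approach this; violations almost always mean voxel indices were pasted in
#: place of mm.
COORD_BOUND_MM = 120.0


class Space(str, Enum):
    """Recognized stereotactic coordinate dialects.

    TAL_NATIVE
        Talairach coordinates as reported by studies that normalized directly
        to the Talairach atlas.  This is the working space of the analysis.
    MNI
        MNI/ICBM coordinates (e.g. SPM or FSL templates).
    TAL_BRETT
        "Talairach" coordinates that were actually produced by applying the
        Brett mni2tal approximation to MNI coordinates.  These are undone back
        to MNI before the Lancaster transform is applied.
    """

    TAL_NATIVE = "tal"
    MNI = "mni"
    TAL_BRETT = "tal_brett"


_SPACE_ALIASES = {
    "tal": Space.TAL_NATIVE,
    "talairach": Space.TAL_NATIVE,
    "tal_native": Space.TAL_NATIVE,
    "mni": Space.MNI,
    "icbm": Space.MNI,
    "mni152": Space.MNI,
    "tal_brett": Space.TAL_BRETT,
    "brett": Space.TAL_BRETT,
    "mni2tal": Space.TAL_BRETT,
}


def parse_space(tag: str) -> Space:
    """Map a free-text space tag onto one of the three recognized dialects."""
    try:
        return _SPACE_ALIASES[tag.strip().lower()]
    except KeyError:
        raise FociInputError(
            f"unknown coordinate space tag {tag!r}; expected one of "
            f"{sorted(set(_SPACE_ALIASES))}"
        ) from None


class Direction(str, Enum):
    """Direction of the reported group difference."""

    DEFICIT = "deficit"
    EXCESS = "excess"


def parse_direction(tag: str) -> Direction:
    try:
        return Direction(tag.strip().lower())
    except ValueError:
        raise FociInputError(
            f"unknown effect direction {tag!r}; expected 'deficit' or 'excess'"
        ) from None


@dataclass(frozen=True)
class Focus:
    """One reported peak coordinate with its provenance."""

    study_id: str
    condition: str
    space: Space
    x: float
    y: float
    z: float
    direction: Direction

    def __post_init__(self) -> None:
        for name, v in (("x", self.x), ("y", self.y), ("z", self.z)):
            if not math.isfinite(v):
                raise FociInputError(
                    f"focus {self.study_id}: coordinate {name}={v!r} is not finite"
                )
            if abs(v) > COORD_BOUND_MM:
                raise FociInputError(
                    f"focus {self.study_id}: |{name}| = {abs(v):g} mm exceeds the "
                    f"{COORD_BOUND_MM:g} mm sanity bound (voxel indices instead "
                    f"of mm?)"
                )

    @property
    def xyz(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z], dtype=float)


@dataclass(frozen=True)
class StudyFoci:
    """All foci of one study for one condition and one effect direction.

    This is the unit over which individual likelihood maps are built; maps of
    studies belonging to the same condition are then averaged.
    """

    study_id: str
    condition: str
    direction: Direction
    foci: tuple[Focus, ...]

    def __post_init__(self) -> None:
        if len(self.foci) == 0:
            raise FociInputError(f"study {self.study_id}: empty focus list")
        for f in self.foci:
            if (f.study_id, f.condition, f.direction) != (
                self.study_id,
                self.condition,
                self.direction,
            ):
                raise FociInputError(
                    f"study {self.study_id}: focus {f} does not match the "
                    "group's study/condition/direction"
                )

    def __len__(self) -> int:
        return len(self.foci)

    @property
    def coordinates(self) -> np.ndarray:
        """(n, 3) array of coordinates in mm."""
        return np.array([[f.x, f.y, f.z] for f in self.foci], dtype=float)
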