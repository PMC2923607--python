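"""Synthetic foci corpora with known ground truth.

Emulates the shape of a two-condition VBM foci corpus: a dozen or so studies
per condition, each reporting a handful of peak coordinates.  True effects
are modelled as *effect centres* — fixed mm locations that each study reports
with some probability per condition, displaced by between-study Gaussian
jitter — plus uniform in-mask noise foci that stand in for idiosyncratic
findings.  A manifest records the provenance of every emitted focus, so
cluster recovery, localization error and contribution percentages can all be
scored against ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import FociInputError
from .foci import Direction, Focus, Space, StudyFoci
from .grid import GridSpec, ellipsoid_mask
from .inference import ClusterResult


@dataclass(frozen=True)
class EffectCenter:
    """A ground-truth anatomical effect.

    ``report_prob`` maps condition label -> probability that one study of
    that condition reports a focus at this centre; the ratio of the two
    probabilities is the centre's expected contribution split.
    """

    location: tuple[float, float, float]
    report_prob: Mapping[str, float]
    jitter_sd: float = 6.0

    def __post_init__(self) -> None:
        if self.jitter_sd < 0:
            raise FociInputError("jitter_sd must be non-negative")
        for c, p in self.report_prob.items():
            if not 0.0 <= p <= 1.0:
                raise FociInputError(f"report probability for {c} outside [0, 1]")

    def expected_pct(self, condition: str) -> float:
        """Expected contribution percentage of ``condition`` at this centre."""
        total = sum(self.report_prob.values())
        if total == 0:
            return float("nan")
        return 100.0 * self.report_prob.get(condition, 0.0) / total


def default_centers(
    conditions: tuple[str, str] = ("ASD", "SCZ"), jitter_sd: float = 6.0
) -> tuple[EffectCenter, ...]:
    """Realistic default ground truth: six shared centres, seven unique to
    the first condition and four unique to the second, at plausible Talairach
    locations in subcortical, limbic and cortical grey matter."""
    a, b = conditions

    def ec(loc, pa, pb):
        return EffectCenter(loc, {a: pa, b: pb}, jitter_sd)

    shared = [
        ec((28.0, -14.0, -15.0), 0.8, 0.8),
        ec((21.0, -56.0, 14.0), 0.8, 0.8),
        ec((28.0, 0.0, 6.0), 0.8, 0.8),
        ec((39.0, -20.0, -4.0), 0.8, 0.8),
        ec((-7.0, -20.0, 10.0), 0.8, 0.8),
        ec((32.0, -17.0, 15.0), 0.8, 0.8),
    ]
    a_only = [
        ec((-23.0, 2.0, 5.0), 0.8, 0.0),
        ec((-30.0, 40.0, 10.0), 0.8, 0.0),
        ec((44.0, -60.0, 20.0), 0.8, 0.0),
        ec((8.0, -80.0, -10.0), 0.8, 0.0),
        ec((-40.0, -55.0, -20.0), 0.8, 0.0),
        ec((50.0, 10.0, 0.0), 0.8, 0.0),
        ec((-10.0, 50.0, -5.0), 0.8, 0.0),
    ]
    b_only = [
        ec((0.0, -45.0, 32.0), 0.0, 0.8),
        ec((10.0, 21.0, 32.0), 0.0, 0.8),
        ec((-38.0, 22.0, 0.0), 0.0, 0.8),
        ec((-2.0, 32.0, 53.0), 0.0, 0.8),
    ]
    return tuple(shared + a_only + b_only)


@dataclass(frozen=True)
class SimConfig:
    """Corpus generator configuration.

    Defaults emulate a two-condition corpus of ~330 foci split roughly 60/40
    between a 14-study and an 11-study condition, with 3–20 foci per study.
    """

    conditions: tuple[str, str] = ("ASD", "SCZ")
    studies_per_condition: tuple[int, int] = (14, 11)
    centers: tuple[EffectCenter, ...] = field(default_factory=default_centers)
    noise_foci_range: tuple[int, int] = (2, 6)
    direction: Direction = Direction.DEFICIT
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.studies_per_condition) < 1:
            raise FociInputError("need at least one study per condition")
        lo, hi = self.noise_foci_range
        if lo < 0 or hi < lo:
            raise FociInputError("invalid noise focus range")


def simulate_corpus(
    sc: SimConfig,
    mask: np.ndarray | None = None,
    grid: GridSpec | None = None,
) -> tuple[list[StudyFoci], pd.DataFrame]:
    """Draw a corpus and its ground-truth manifest.

    Every emitted focus is attributed to exactly one effect centre or to
    noise in the manifest (columns: study_id, condition, direction, x, y, z,
    source) where source is ``center_<i>`` or ``noise``.
    """
    grid = grid or GridSpec()
    if mask is None:
        mask = ellipsoid_mask(grid)
    if not np.any(mask):
        raise FociInputError("empty mask")
    rng = np.random.default_rng(sc.seed)
    inmask_mm = grid.ijk_to_mm(np.argwhere(mask))

    def in_mask(p: np.ndarray) -> bool:
        ijk = grid.mm_to_ijk(p)
        if np.any(ijk < 0) or np.any(ijk >= np.array(grid.shape)):
            return False
        return bool(mask[tuple(ijk)])

    studies: list[StudyFoci] = []
    manifest_rows = []
    for cond, n_studies in zip(sc.conditions, sc.studies_per_condition):
        for j in range(n_studies):
            sid = f"{cond}_s{j + 1:02d}"
            foci: list[Focus] = []

            def emit(p: np.ndarray, source: str) -> None:
                foci.append(
                    Focus(sid, cond, Space.TAL_NATIVE, float(p[0]), float(p[1]),
                          float(p[2]), sc.direction)
                )
                manifest_rows.append(
                    {"study_id": sid, "condition": cond,
                     "direction": sc.direction.value, "x": float(p[0]),
                     "y": float(p[1]), "z": float(p[2]), "source": source}
                )

            for ci, center in enumerate(sc.centers):
                if rng.random() >= center.report_prob.get(cond, 0.0):
                    continue
                loc = np.asarray(center.location, dtype=float)
                p = loc
                for _ in range(100):  # rejection-sample jitter into the mask
                    cand = loc + rng.normal(0.0, center.jitter_sd, size=3)
                    if in_mask(cand):
                        p = cand
                        break
                emit(p, f"center_{ci}")

            n_noise = int(rng.integers(sc.noise_foci_range[0],
                                       sc.noise_foci_range[1] + 1))
            for _ in range(n_noise):
                p = inmask_mm[rng.integers(0, inmask_mm.shape[0])]
                emit(p, "noise")

            if foci:
                studies.append(
                    StudyFoci(study_id=sid, condition=cond,
                              direction=sc.direction, foci=tuple(foci))
                )
    manifest = pd.DataFrame(
        manifest_rows,
        columns=["study_id", "condition", "direction", "x", "y", "z", "source"],
    )
    return studies, manifest


def recovery_report(
    clusters: Sequence[ClusterResult],
    sc: SimConfig,
    match_radius_mm: float = 10.0,
) -> pd.DataFrame:
    """Score pipeline output against the generator's ground truth.

    One row per effect centre: whether a retained cluster's centre of mass
    lies within ``match_radius_mm``, the localization error, and the matched
    cluster's contribution percentage for the first condition next to the
    centre's expected split.
    """
    rows = []
    cond_a = sc.conditions[0]
    for ci, center in enumerate(sc.centers):
        loc = np.asarray(center.location, dtype=float)
        best = None
        best_d = np.inf
        for c in clusters:
            d = float(np.linalg.norm(c.center_of_mass_mm - loc))
            if d < best_d:
                best, best_d = c, d
        matched = best is not None and best_d <= match_radius_mm
        pct_a = np.nan
        if matched and best.contribution is not None:
            pct_a = best.contribution.pct_a
        rows.append(
            {
                "center": f"center_{ci}",
                "x": loc[0], "y": loc[1], "z": loc[2],
                "matched": matched,
                "localization_error_mm": best_d if matched else np.nan,
                "cluster_label": best.label if matched else -1,
                "pct_a": pct_a,
                "expected_pct_a": center.expected_pct(cond_a),
            }
        )
    return pd.DataFrame(rows)
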