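"""Per-cluster condition attribution.

The statistic that makes the joint analysis interpretable: for every retained
cluster, the fraction of the joint likelihood mass contributed by each
condition's mean map, expressed as a percentage.  100/0 means the cluster was
generated entirely by one condition's studies; 50/50 means foci from either
condition were equally likely to have formed it.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np

from .errors import DegenerateClusterError
from .grid import check_same_grid
from .inference import ClusterResult
from .maps import LikelihoodMap


@dataclass(frozen=True)
class ContributionRecord:
    cluster_label: int
    condition_a: str
    condition_b: str
    pct_a: float
    pct_b: float


class AttributionClass(Enum):
    A_ONLY = "a_only"
    B_ONLY = "b_only"
    SHARED = "shared"


def cluster_contribution(
    c: ClusterResult, mean_a: LikelihoodMap, mean_b: LikelihoodMap,
    label_a: str = "A", label_b: str = "B",
) -> ContributionRecord:
    """Intensity-ratio contribution of each condition over the cluster.

    The two condition mean maps are integrated over the cluster's voxels and
    each sum is expressed as a percentage of their total (the joint mass).
    Integrating over the whole cluster rather than reading a single peak voxel
    keeps the ratio stable for small clusters; the two statistics agree in the
    single-condition and perfectly-shared limits.
    """
    check_same_grid(mean_a.grid, mean_b.grid)
    i, j, k = c.voxels[:, 0], c.voxels[:, 1], c.voxels[:, 2]
    sum_a = float(mean_a.values[i, j, k].sum())
    sum_b = float(mean_b.values[i, j, k].sum())
    total = sum_a + sum_b
    if total <= 0.0:
        raise DegenerateClusterError(
            f"cluster {c.label}: zero joint likelihood mass over its voxels"
        )
    return ContributionRecord(
        cluster_label=c.label,
        condition_a=label_a,
        condition_b=label_b,
        pct_a=100.0 * sum_a / total,
        pct_b=100.0 * sum_b / total,
    )


def peak_contribution(
    c: ClusterResult, mean_a: LikelihoodMap, mean_b: LikelihoodMap,
    label_a: str = "A", label_b: str = "B",
) -> ContributionRecord:
    """Variant: the intensity ratio read at the cluster's peak voxel only."""
    check_same_grid(mean_a.grid, mean_b.grid)
    peak = c.voxels[
        int(np.argmax(mean_a.values[tuple(c.voxels.T)] + mean_b.values[tuple(c.voxels.T)]))
    ]
    a = float(mean_a.values[tuple(peak)])
    b = float(mean_b.values[tuple(peak)])
    if a + b <= 0.0:
        raise DegenerateClusterError(
            f"cluster {c.label}: zero joint likelihood at its peak voxel"
        )
    return ContributionRecord(
        cluster_label=c.label,
        condition_a=label_a,
        condition_b=label_b,
        pct_a=100.0 * a / (a + b),
        pct_b=100.0 * b / (a + b),
    )


def attribution_class(
    r: ContributionRecord, band: float = 20.0
) -> AttributionClass:
    """Classify a cluster as condition-specific or shared.

    SHARED when both percentages reach ``band`` (default 20, i.e. anything in
    20–80% counts as contributed to by both conditions); otherwise the
    dominant condition.  Purely presentational — the percentages themselves
    are the statistic.
    """
    if r.pct_a >= band and r.pct_b >= band:
        return AttributionClass.SHARED
    return AttributionClass.A_ONLY if r.pct_a > r.pct_b else AttributionClass.B_ONLY
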