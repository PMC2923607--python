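"""End-to-end orchestration: normalize -> maps -> inference -> contribution.

One :func:`run_analysis` call runs the full protocol separately for each
requested effect direction (grey-matter deficits and excesses are independent
analyses) and returns, per direction, the joint likelihood map, the p-value
map, the cluster label map and a publication-style cluster table with the
per-condition contribution percentages.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np
import pandas as pd

from . import __version__
from .contribution import attribution_class, cluster_contribution, peak_contribution
from .errors import FociInputError, JointAleError
from .foci import Direction, StudyFoci
from .grid import GridSpec, ellipsoid_mask, load_mask
from .inference import (
    ClusterResult,
    PermutationConfig,
    ThresholdConfig,
    extract_clusters,
    fdr_threshold,
    permutation_null,
    voxel_pvalues,
)
from .io import normalize_studies, parse_foci_table, table_conditions
from .kernel import KernelSpec
from .maps import LikelihoodMap, MapKind, condition_mean_map, joint_map, study_map
from .transforms import LANCASTER_VARIANT

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class AnalysisConfig:
    """Full protocol configuration; the defaults are the published protocol
    (8 mm FWHM kernel, 10,000 permutations, FDR q = 0.05, clusters retained
    only above 100 mm^3 and when supported by more than one study)."""

    kernel: KernelSpec = field(default_factory=KernelSpec)
    grid: GridSpec = field(default_factory=GridSpec)
    permutation: PermutationConfig = field(default_factory=PermutationConfig)
    threshold: ThresholdConfig = field(default_factory=ThresholdConfig)
    conditions: tuple[str, str] | None = None  # None: take order from the table
    directions: tuple[Direction, ...] = (Direction.DEFICIT, Direction.EXCESS)
    contribution_mode: str = "integrated"  # or "peak"
    shared_band_pct: float = 20.0

    def to_dict(self) -> dict:
        d = asdict(self)
        d["directions"] = [x.value for x in self.directions]
        d["lancaster_variant"] = LANCASTER_VARIANT
        return d

    @property
    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisConfig":
        d = dict(d)
        d.pop("lancaster_variant", None)
        kw = {}
        if "kernel" in d:
            kw["kernel"] = KernelSpec(**d["kernel"])
        if "grid" in d:
            g = {k: tuple(v) if isinstance(v, list) else v for k, v in d["grid"].items()}
            kw["grid"] = GridSpec(**g)
        if "permutation" in d:
            kw["permutation"] = PermutationConfig(**d["permutation"])
        if "threshold" in d:
            kw["threshold"] = ThresholdConfig(**d["threshold"])
        if d.get("conditions") is not None:
            kw["conditions"] = tuple(d["conditions"])
        if "directions" in d:
            kw["directions"] = tuple(Direction(x) for x in d["directions"])
        for key in ("contribution_mode", "shared_band_pct"):
            if key in d:
                kw[key] = d[key]
        return cls(**kw)


@dataclass
class DirectionResult:
    direction: Direction
    joint: LikelihoodMap | None
    pvalues: LikelihoodMap | None
    cluster_labels: np.ndarray | None
    clusters: list[ClusterResult]
    table: pd.DataFrame
    counts: dict
    note: str = ""
    condition_means: dict[str, LikelihoodMap] | None = None


@dataclass
class RunResult:
    config: AnalysisConfig
    seed: int
    directions: dict[Direction, DirectionResult]
    manifest: dict


def _resolve_conditions(
    studies: Sequence[StudyFoci], cfg: AnalysisConfig
) -> tuple[str, str]:
    if cfg.conditions is not None:
        return cfg.conditions
    conds = table_conditions(studies)
    if len(conds) == 1:
        conds = [conds[0], f"(absent)"]
    if len(conds) != 2:
        raise FociInputError(
            f"expected two condition labels, found {conds}"
        )
    return tuple(conds)


def _cluster_table(
    clusters: Sequence[ClusterResult], cond_a: str, cond_b: str
) -> pd.DataFrame:
    rows = []
    for c in clusters:
        row = {
            "cluster": c.label,
            "peak_x": c.peak_mm[0], "peak_y": c.peak_mm[1], "peak_z": c.peak_mm[2],
            "com_x": c.center_of_mass_mm[0], "com_y": c.center_of_mass_mm[1],
            "com_z": c.center_of_mass_mm[2],
            "volume_mm3": c.volume_mm3,
            f"n_studies_{cond_a}": len(c.supporting_studies.get(cond_a, ())),
            f"n_studies_{cond_b}": len(c.supporting_studies.get(cond_b, ())),
            f"pct_{cond_a}": c.contribution.pct_a if c.contribution else np.nan,
            f"pct_{cond_b}": c.contribution.pct_b if c.contribution else np.nan,
            "attribution": c.attribution.value if hasattr(c, "attribution") else "",
        }
        rows.append(row)
    cols = [
        "cluster", "peak_x", "peak_y", "peak_z", "com_x", "com_y", "com_z",
        "volume_mm3", f"n_studies_{cond_a}", f"n_studies_{cond_b}",
        f"pct_{cond_a}", f"pct_{cond_b}", "attribution",
    ]
    return pd.DataFrame(rows, columns=cols)


def run_direction(
    studies: Sequence[StudyFoci],
    direction: Direction,
    mask: np.ndarray,
    cfg: AnalysisConfig,
    seed: int,
    conditions: tuple[str, str],
) -> DirectionResult:
    """Run the full pipeline for one effect direction."""
    cond_a, cond_b = conditions
    sel = [s for s in studies if s.direction == direction]
    counts = {
        "n_studies": len(sel),
        "n_foci": sum(len(s) for s in sel),
        "per_condition": {
            c: {
                "n_studies": sum(1 for s in sel if s.condition == c),
                "n_foci": sum(len(s) for s in sel if s.condition == c),
            }
            for c in conditions
        },
    }
    if not sel:
        note = f"no foci in direction '{direction.value}'; empty result"
        logger.info(note)
        return DirectionResult(
            direction, None, None, None, [],
            _cluster_table([], cond_a, cond_b), counts, note,
        )

    grid, k = cfg.grid, cfg.kernel
    means = {}
    for c in (cond_a, cond_b):
        c_maps = [study_map(s, grid, k, mask) for s in sel if s.condition == c]
        if c_maps:
            means[c] = condition_mean_map(c_maps)
        else:
            means[c] = LikelihoodMap(grid, np.zeros(grid.shape), MapKind.CONDITION_MEAN)
    joint = joint_map(means[cond_a], means[cond_b])

    pc = PermutationConfig(
        n_permutations=cfg.permutation.n_permutations,
        seed=seed,
        preserve_structure=cfg.permutation.preserve_structure,
    )
    null = permutation_null(sel, grid, k, mask, pc)
    pvals = voxel_pvalues(joint, null, mask)
    supra = fdr_threshold(pvals, cfg.threshold.fdr_q, mask)
    clusters = extract_clusters(supra, cfg.threshold, sel, grid, joint, k)

    contrib_fn = (
        cluster_contribution if cfg.contribution_mode == "integrated"
        else peak_contribution
    )
    labels = np.zeros(grid.shape, dtype=np.int32)
    for c in clusters:
        c.contribution = contrib_fn(
            c, means[cond_a], means[cond_b], cond_a, cond_b
        )
        c.attribution = attribution_class(c.contribution, cfg.shared_band_pct)
        labels[c.voxels[:, 0], c.voxels[:, 1], c.voxels[:, 2]] = c.label
    counts["n_clusters"] = len(clusters)
    logger.info(
        "direction %s: %d studies, %d foci, %d retained clusters",
        direction.value, counts["n_studies"], counts["n_foci"], len(clusters),
    )
    return DirectionResult(
        direction, joint, pvals, labels, clusters,
        _cluster_table(clusters, cond_a, cond_b), counts,
        condition_means=means,
    )


def run_analysis(
    foci,
    mask: np.ndarray | str | Path | None = None,
    cfg: AnalysisConfig | None = None,
    out_dir: str | Path | None = None,
    dry_run: bool = False,
) -> RunResult:
    """Run the complete joint analysis.

    ``foci`` is a foci-table path or a sequence of :class:`StudyFoci`.
    ``mask`` is a boolean array on the analysis grid, a NIfTI path, or None
    for the built-in procedural mask.  With ``dry_run`` the inputs are parsed
    and the run manifest is produced, but no maps are computed.
    """
    cfg = cfg or AnalysisConfig()
    if isinstance(foci, (str, Path)):
        studies = parse_foci_table(foci, allow_single_condition=True)
    else:
        studies = list(foci)
    studies = normalize_studies(studies)
    conditions = _resolve_conditions(studies, cfg)

    if mask is None:
        mask_arr = ellipsoid_mask(cfg.grid)
    elif isinstance(mask, (str, Path)):
        mask_arr = load_mask(mask, cfg.grid)
    else:
        mask_arr = np.asarray(mask, dtype=bool)

    seed = int(cfg.permutation.seed)
    results: dict[Direction, DirectionResult] = {}
    if not dry_run:
        for i, direction in enumerate(cfg.directions):
            results[direction] = run_direction(
                studies, direction, mask_arr, cfg, (seed + i) % 2**31, conditions
            )

    manifest = {
        "package": "jointale",
        "version": __version__,
        "config": cfg.to_dict(),
        "config_hash": cfg.config_hash,
        "seed": seed,
        "protocol": {
            "fwhm_mm": cfg.kernel.fwhm,
            "n_permutations": cfg.permutation.n_permutations,
            "fdr_q": cfg.threshold.fdr_q,
            "min_cluster_volume_mm3": cfg.threshold.min_cluster_volume,
            "min_study_support": cfg.threshold.min_study_support,
            "connectivity": cfg.threshold.connectivity,
        },
        "conditions": list(conditions),
        "inputs": {
            "n_studies": len(studies),
            "n_foci": sum(len(s) for s in studies),
            "per_condition": {
                c: {
                    "n_studies": sum(1 for s in studies if s.condition == c),
                    "n_foci": sum(len(s) for s in studies if s.condition == c),
                }
                for c in conditions
            },
        },
        "directions": {
            d.value: {"counts": r.counts, "note": r.note}
            for d, r in results.items()
        },
        "dry_run": dry_run,
    }
    run = RunResult(config=cfg, seed=seed, directions=results, manifest=manifest)
    if out_dir is not None:
        write_outputs(run, Path(out_dir))
    return run


def _write_table(df: pd.DataFrame, path: Path, cfg_hash: str, seed: int) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(f"# config_hash={cfg_hash}\n# seed={seed}\n")
        fh.write("\t".join(df.columns) + "\n")
        for _, row in df.iterrows():
            cells = []
            for col in df.columns:
                v = row[col]
                if col == "cluster":
                    cells.append(str(int(v)))
                elif col.startswith("n_studies"):
                    cells.append(str(int(v)))
                elif col == "volume_mm3":
                    cells.append(f"{v:.0f}")
                elif col.startswith("pct_"):
                    cells.append(f"{v:.1f}")
                elif col == "attribution":
                    cells.append(str(v))
                else:
                    cells.append(f"{v:.1f}")
            fh.write("\t".join(cells) + "\n")


def write_outputs(run: RunResult, out_dir: Path) -> None:
    """Write NIfTI maps, cluster tables and the JSON run manifest."""
    out_dir.mkdir(parents=True, exist_ok=True)
    tag = run.config.config_hash
    descrip = f"jointale cfg={tag} seed={run.seed}"
    for d, r in run.directions.items():
        prefix = out_dir / d.value
        if r.joint is not None:
            nib.save(r.joint.to_nifti(descrip), f"{prefix}_joint.nii.gz")
            nib.save(r.pvalues.to_nifti(descrip), f"{prefix}_pmap.nii.gz")
            img = nib.Nifti1Image(r.cluster_labels, run.config.grid.affine)
            img.header["descrip"] = descrip.encode()[:79]
            nib.save(img, f"{prefix}_clusters.nii.gz")
        _write_table(r.table, Path(f"{prefix}_clusters.tsv"), tag, run.seed)
    with open(out_dir / "run_manifest.json", "w", encoding="utf-8") as fh:
        json.dump(run.manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
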