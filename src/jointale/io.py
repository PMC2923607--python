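"""Reading and writing foci tables.

The on-disk format is a UTF-8 TSV (CSV via ``dialect="csv"``) with a mandatory
header.  Required columns: ``study_id``, ``condition``, ``x``, ``y``, ``z``,
``direction``.  The ``space`` column is optional; when absent every focus is
assumed to be native Talairach and a warning is logged.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .errors import FociFormatError, FociInputError
from .foci import Direction, Focus, Space, StudyFoci, parse_direction, parse_space
from .transforms import normalize_space

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = ("study_id", "condition", "x", "y", "z", "direction")


def _sep(dialect: str | None, path: Path) -> str:
    if dialect is None:
        dialect = "csv" if path.suffix.lower() == ".csv" else "tsv"
    try:
        return {"tsv": "\t", "csv": ","}[dialect]
    except KeyError:
        raise FociFormatError(f"unknown table dialect {dialect!r}") from None


def parse_foci_table(
    path: str | Path,
    dialect: str | None = None,
    allow_single_condition: bool = False,
) -> list[StudyFoci]:
    """Parse a foci table into study groups.

    Rows are grouped by (study_id, condition, direction), preserving first-
    appearance order.  Exactly two condition labels must be present unless
    ``allow_single_condition`` is set.
    """
    path = Path(path)
    if not path.exists():
        raise FociFormatError(f"foci table not found: {path}")
    df = pd.read_csv(path, sep=_sep(dialect, path), dtype=str, keep_default_na=False)
    df.columns = [c.strip().lower() for c in df.columns]

    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            raise FociFormatError(f"foci table {path} is missing column {col!r}")
    has_space = "space" in df.columns
    if not has_space:
        logger.warning(
            "foci table %s has no 'space' column; assuming native Talairach", path
        )

    groups: dict[tuple[str, str, Direction], list[Focus]] = {}
    for i, row in enumerate(df.itertuples(index=False)):
        line = i + 2  # 1-based, after the header line
        rec = dict(zip(df.columns, row))
        coords = {}
        for axis in ("x", "y", "z"):
            try:
                coords[axis] = float(rec[axis])
            except ValueError:
                raise FociInputError(
                    f"{path} line {line}: non-numeric {axis} coordinate "
                    f"{rec[axis]!r}"
                ) from None
        space = parse_space(rec["space"]) if has_space else Space.TAL_NATIVE
        focus = Focus(
            study_id=rec["study_id"].strip(),
            condition=rec["condition"].strip(),
            space=space,
            x=coords["x"],
            y=coords["y"],
            z=coords["z"],
            direction=parse_direction(rec["direction"]),
        )
        key = (focus.study_id, focus.condition, focus.direction)
        groups.setdefault(key, []).append(focus)

    conditions = _ordered_conditions(groups)
    if len(conditions) > 2:
        raise FociInputError(
            f"foci table {path} contains {len(conditions)} condition labels "
            f"({', '.join(conditions)}); a joint analysis takes exactly two"
        )
    if len(conditions) < 2 and not allow_single_condition:
        raise FociInputError(
            f"foci table {path} contains a single condition label "
            f"({conditions[0] if conditions else 'none'}); pass "
            "allow_single_condition=True to analyse one condition alone"
        )

    return [
        StudyFoci(study_id=k[0], condition=k[1], direction=k[2], foci=tuple(v))
        for k, v in groups.items()
    ]


def _ordered_conditions(groups) -> list[str]:
    seen: list[str] = []
    for _, cond, _ in groups:
        if cond not in seen:
            seen.append(cond)
    return seen


def table_conditions(studies: Iterable[StudyFoci]) -> list[str]:
    """Condition labels in first-appearance order."""
    seen: list[str] = []
    for s in studies:
        if s.condition not in seen:
            seen.append(s.condition)
    return seen


def write_foci_table(
    studies: Sequence[StudyFoci], path: str | Path, dialect: str = "tsv"
) -> None:
    """Write study groups back out with coordinates at 3 decimal places."""
    path = Path(path)
    rows = []
    for s in studies:
        for f in s.foci:
            rows.append(
                {
                    "study_id": f.study_id,
                    "condition": f.condition,
                    "space": f.space.value,
                    "x": f"{f.x:.3f}",
                    "y": f"{f.y:.3f}",
                    "z": f"{f.z:.3f}",
                    "direction": f.direction.value,
                }
            )
    pd.DataFrame(rows).to_csv(path, sep=_sep(dialect, path), index=False)


def normalize_studies(studies: Sequence[StudyFoci]) -> list[StudyFoci]:
    """Map every focus of every study into native Talairach space."""
    out = []
    for s in studies:
        out.append(
            StudyFoci(
                study_id=s.study_id,
                condition=s.condition,
                direction=s.direction,
                foci=tuple(normalize_space(f) for f in s.foci),
            )
        )
    return out
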