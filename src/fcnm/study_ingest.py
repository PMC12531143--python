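"""Included-studies table ingestion, sample summaries, and contrast seeds.

The input is a delimited text table with one row per reported focus; study
columns are repeated on every row of that study. Coordinates may be in MNI
or Talairach space; Talairach foci are converted through a configurable
named affine before seed construction. Foci whose nearest voxel falls
outside the gray-matter mask are dropped and counted, mirroring the usual
exclusion rule for coordinate-based syntheses.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .volumes import BinaryMask, Volume3D, filter_coords_in_mask, make_sphere_seed

logger = logging.getLogger(__name__)

__all__ = [
    "StudyRecord",
    "Focus",
    "ContrastSeed",
    "load_study_table",
    "foci_from_frame",
    "bundled_study_table_path",
    "summarize_sample",
    "tal_to_mni",
    "register_transform",
    "build_contrast_seeds",
]

REQUIRED_COLUMNS = [
    "study_id", "n", "n_female", "n_male", "mean_age",
    "contrast_id", "x", "y", "z", "space",
]


@dataclass(frozen=True)
class StudyRecord:
    study_id: str
    n: int
    n_female: int
    n_male: int
    mean_age: float
    sd_age: float | None = None
    scale: str = ""
    space: str = "MNI"


@dataclass(frozen=True)
class Focus:
    study_id: str
    contrast_id: str
    xyz: tuple[float, float, float]
    space: str = "MNI"
    sign: str = "positive"


@dataclass
class ContrastSeed:
    contrast_id: str
    seed_mask: BinaryMask
    n_foci_used: int
    n_foci_dropped: int


def bundled_study_table_path() -> Path:
    """Path of the packaged included-studies table (synthetic foci)."""
    return Path(resources.files("fcnm").joinpath("data/included_studies_synthetic_foci.csv"))  # type: ignore[arg-type]


def load_study_table(path: str | Path) -> tuple[list[StudyRecord], list[Focus]]:
    """Parse a study/foci table into study records and foci.

    One StudyRecord per distinct study_id; one Focus per row. Lines starting
    with ``#`` are comments. Rows whose F/M counts do not sum to n raise a
    validation error naming the row; duplicate (study, contrast, xyz) rows
    are deduplicated with a warning.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    df = pd.read_csv(path, sep=sep, comment="#", skipinitialspace=True)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing required columns: {missing}")
    if len(df) == 0:
        raise ValueError("no records in study table")

    dup = df.duplicated(subset=["study_id", "contrast_id", "x", "y", "z"])
    if dup.any():
        warnings.warn(
            f"{int(dup.sum())} duplicate study/contrast/xyz rows deduplicated",
            stacklevel=2,
        )
        df = df[~dup]

    records: dict[str, StudyRecord] = {}
    foci: list[Focus] = []
    for i, row in df.iterrows():
        sid = str(row["study_id"])
        n, nf, nm = int(row["n"]), int(row["n_female"]), int(row["n_male"])
        if nf + nm != n:
            raise ValueError(
                f"row {i} (study {sid}): n_female + n_male = {nf + nm} != n = {n}"
            )
        if sid not in records:
            sd = row.get("sd_age")
            records[sid] = StudyRecord(
                study_id=sid,
                n=n,
                n_female=nf,
                n_male=nm,
                mean_age=float(row["mean_age"]),
                sd_age=None if pd.isna(sd) else float(sd),
                scale=str(row.get("scale", "")),
                space=str(row["space"]),
            )
        foci.append(
            Focus(
                study_id=sid,
                contrast_id=str(row["contrast_id"]),
                xyz=(float(row["x"]), float(row["y"]), float(row["z"])),
                space=str(row["space"]),
                sign=str(row.get("sign", "positive")),
            )
        )
    return list(records.values()), foci


def foci_from_frame(df: pd.DataFrame) -> list[Focus]:
    """Convert a DataFrame in the study-table schema to Focus objects."""
    return [
        Focus(
            study_id=str(row["study_id"]),
            contrast_id=str(row["contrast_id"]),
            xyz=(float(row["x"]), float(row["y"]), float(row["z"])),
            space=str(row.get("space", "MNI")),
            sign=str(row.get("sign", "positive")),
        )
        for _, row in df.iterrows()
    ]


def summarize_sample(records: Sequence[StudyRecord]) -> dict:
    """Pooled sample summary: totals and the n-weighted mean of mean ages.

    weighted_mean_age = sum(n_i * age_i) / sum(n_i), reported at 2 decimals.
    """
    if not records:
        raise ValueError("need at least one study record")
    ns = np.array([r.n for r in records], dtype=float)
    ages = np.array([r.mean_age for r in records], dtype=float)
    return {
        "n_studies": len(records),
        "total_n": int(ns.sum()),
        "total_female": int(sum(r.n_female for r in records)),
        "total_male": int(sum(r.n_male for r in records)),
        "weighted_mean_age": round(float((ns * ages).sum() / ns.sum()), 2),
        "min_n": int(ns.min()),
        "max_n": int(ns.max()),
    }


def _load_lancaster() -> np.ndarray:
    spec = json.loads(
        resources.files("fcnm").joinpath("data/tal2mni_lancaster.json").read_text()
    )
    mni2tal = np.asarray(spec["matrix"], dtype=float)
    return np.linalg.inv(mni2tal)  # tal -> mni


_TRANSFORMS: dict[str, np.ndarray] = {"identity": np.eye(4)}


def register_transform(name: str, matrix: np.ndarray) -> None:
    """Register a named 4x4 Talairach->MNI affine."""
    matrix = np.asarray(matrix, dtype=float)
    if matrix.shape != (4, 4):
        raise ValueError("transform must be a 4x4 matrix")
    _TRANSFORMS[name] = matrix


def tal_to_mni(
    coord: Sequence[float], transform: str | np.ndarray = "lancaster"
) -> np.ndarray:
    """Apply a named (or explicit 4x4) Talairach->MNI affine to one coordinate."""
    if isinstance(transform, str):
        if transform == "lancaster" and "lancaster" not in _TRANSFORMS:
            _TRANSFORMS["lancaster"] = _load_lancaster()
        if transform not in _TRANSFORMS:
            raise KeyError(f"unknown transform {transform!r}; known: {sorted(_TRANSFORMS)}")
        mat = _TRANSFORMS[transform]
    else:
        mat = np.asarray(transform, dtype=float)
    coord = np.asarray(coord, dtype=float)
    return (mat @ np.append(coord, 1.0))[:3]


def build_contrast_seeds(
    foci: Iterable[Focus],
    gm_mask: BinaryMask,
    radius_mm: float,
    grid: Volume3D | None = None,
    transform: str | np.ndarray = "lancaster",
) -> list[ContrastSeed]:
    """One sphere-union seed mask per study contrast.

    Talairach foci are converted to MNI first; foci outside the GM mask are
    dropped (counted per contrast); contrasts with no surviving focus are
    excluded with a log line. Raises if nothing survives anywhere.
    """
    if grid is None:
        grid = gm_mask
    if not gm_mask.same_geometry(grid):
        raise ValueError("gm_mask and grid must share geometry")

    by_contrast: dict[str, list[Focus]] = {}
    for f in foci:
        by_contrast.setdefault(f"{f.study_id}:{f.contrast_id}", []).append(f)

    seeds: list[ContrastSeed] = []
    for cid, group in by_contrast.items():
        coords = []
        for f in group:
            xyz = np.asarray(f.xyz, dtype=float)
            if f.space.upper().startswith("TAL"):
                xyz = tal_to_mni(xyz, transform)
            coords.append(xyz)
        retained, dropped = filter_coords_in_mask(coords, gm_mask)
        if not retained:
            logger.info("contrast %s excluded: all %d foci outside GM", cid, len(dropped))
            continue
        seeds.append(
            ContrastSeed(
                contrast_id=cid,
                seed_mask=make_sphere_seed(retained, radius_mm, grid),
                n_foci_used=len(retained),
                n_foci_dropped=len(dropped),
            )
        )
    if not seeds:
        raise ValueError("no contrasts with foci surviving the GM filter")
    return seeds
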