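"""Readers and writers for every external representation the pipeline touches.

Supported formats:

* 4-D NIfTI functional volumes with 3-D NIfTI masks (via :mod:`nibabel`);
* surface time series as plain dense text matrices (vertices x frames) or
  GIFTI functional files (one data array per frame);
* motion parameters as >=6-column whitespace text
  (FSL/HCP ``Movement_Regressors`` layout; only the first six columns,
  three translations then three rotations, are used);
* phenotypes as tab-separated text with a header row.

Readers validate shape and metadata but perform no computation; every
reader has a matching fixture writer so round-trips can be checked.
"""

from __future__ import annotations

from typing import Mapping, Optional

import nibabel as nib
import numpy as np
import pandas as pd

from .core import (
    SURFACE,
    VOLUME_GRAYMATTER,
    BoldRun,
    FormatError,
    HeaderError,
    MaskSet,
    MotionParams,
    SurfaceGeometry,
)

__all__ = [
    "read_volume_run",
    "write_volume_run",
    "read_mask",
    "write_mask",
    "read_surface_run",
    "write_surface_run",
    "read_motion_params",
    "write_motion_params",
    "read_phenotypes",
    "write_phenotypes",
    "read_geometry",
    "write_geometry",
    "PHENOTYPE_COLUMNS",
    "MISSING_SCORE_SENTINEL",
]

#: mandatory phenotype columns (HCP-A style variable labels differ between
#: releases, so a column_map argument lets callers rename on the way in)
PHENOTYPE_COLUMNS = (
    "subject_id",
    "age_at_mri",
    "age_at_menopause",
    "education_years",
    "bmi",
    "psmt_score",
    "ravlt_score",
)

SCORE_COLUMNS = ("psmt_score", "ravlt_score")

#: abnormal-score sentinel treated as missing
MISSING_SCORE_SENTINEL = 999.0


# ---------------------------------------------------------------------------
# volumes

def read_volume_run(path_nifti: str, masks: MaskSet, run_label: str = "") -> BoldRun:
    """Load a 4-D functional volume and keep the voxels covered by the masks.

    The returned :class:`BoldRun` holds the union of gray-matter and CSF-ROI
    voxels (units ordered by flat C-index), with ``unit_masks["gray_matter"]``
    and ``unit_masks["csf"]`` selecting each compartment and ``unit_indices``
    recording the voxel -> unit map.
    """
    img = nib.load(path_nifti)
    data = np.asanyarray(img.dataobj)
    if data.ndim != 4:
        raise FormatError(f"{path_nifti}: expected a 4-D volume, got {data.ndim}-D")
    if data.shape[:3] != masks.shape:
        raise FormatError(
            f"{path_nifti}: volume grid {data.shape[:3]} does not match "
            f"mask grid {masks.shape}")
    zooms = img.header.get_zooms()
    tr = float(zooms[3]) if len(zooms) >= 4 else 0.0
    if not tr > 0:
        raise HeaderError(f"{path_nifti}: non-positive TR in header ({tr})")
    keep = masks.gray_matter | masks.csf_roi
    flat_idx = np.flatnonzero(keep.ravel())
    mat = data.reshape(-1, data.shape[3])[flat_idx].astype(float)
    unit_masks = {
        "gray_matter": masks.gray_matter.ravel()[flat_idx],
        "csf": masks.csf_roi.ravel()[flat_idx],
    }
    return BoldRun(mat, tr_seconds=tr, space=VOLUME_GRAYMATTER,
                   run_label=run_label, unit_masks=unit_masks,
                   unit_indices=flat_idx)


def write_volume_run(path_nifti: str, volume4d: np.ndarray, tr_seconds: float) -> None:
    """Write a 4-D array as NIfTI with the TR stored in the header zooms."""
    volume4d = np.asarray(volume4d, dtype=np.float64)
    if volume4d.ndim != 4:
        raise FormatError("expected a 4-D array")
    img = nib.Nifti1Image(volume4d, affine=np.eye(4))
    img.header.set_zooms((1.0, 1.0, 1.0, float(tr_seconds)))
    img.header.set_xyzt_units(xyz="mm", t="sec")
    nib.save(img, path_nifti)


def read_mask(path_nifti: str) -> np.ndarray:
    img = nib.load(path_nifti)
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise FormatError(f"{path_nifti}: expected a 3-D mask")
    return data > 0


def write_mask(path_nifti: str, mask: np.ndarray) -> None:
    nib.save(nib.Nifti1Image(np.asarray(mask, dtype=np.uint8), np.eye(4)), path_nifti)


# ---------------------------------------------------------------------------
# surfaces

def read_surface_run(path: str, geometry: SurfaceGeometry,
                     tr_seconds: Optional[float] = None,
                     run_label: str = "") -> BoldRun:
    """Load a surface-sampled run (vertices x frames).

    Plain dense text matrices are the native format; ``.gii`` functional
    files (one darray per frame) are also accepted. For text input the TR
    is not stored in the file and must be supplied.
    """
    if path.endswith(".gii"):
        img = nib.load(path)
        mat = np.column_stack([d.data for d in img.darrays]).astype(float)
        if tr_seconds is None:
            raise HeaderError(f"{path}: tr_seconds must be supplied for GIFTI input")
    else:
        mat = np.loadtxt(path, ndmin=2, dtype=float)
        if tr_seconds is None:
            raise HeaderError(f"{path}: tr_seconds must be supplied for text input")
    if mat.shape[0] != geometry.n_vertices:
        raise FormatError(
            f"{path}: {mat.shape[0]} vertices in file, geometry declares "
            f"{geometry.n_vertices}")
    return BoldRun(mat, tr_seconds=float(tr_seconds), space=SURFACE,
                   run_label=run_label)


def write_surface_run(path: str, run: BoldRun) -> None:
    """Write a surface run as a dense text matrix (full float precision)."""
    np.savetxt(path, run.data, fmt="%.17g", delimiter="\t")


# ---------------------------------------------------------------------------
# motion

def read_motion_params(path_table: str, rotation_unit: str = "radians") -> MotionParams:
    """Read realignment parameters; extra columns beyond six are ignored."""
    table = np.loadtxt(path_table, ndmin=2, dtype=float)
    if table.shape[1] < 6:
        raise FormatError(
            f"{path_table}: motion table has {table.shape[1]} columns, need >= 6")
    return MotionParams(table[:, :6], rotation_unit=rotation_unit)


def write_motion_params(path_table: str, mp: MotionParams) -> None:
    np.savetxt(path_table, mp.params, fmt="%.17g", delimiter="\t")


# ---------------------------------------------------------------------------
# phenotypes

def read_phenotypes(path_tsv: str,
                    column_map: Optional[Mapping[str, str]] = None) -> pd.DataFrame:
    """Read and validate the phenotype table.

    Returns a DataFrame with the canonical :data:`PHENOTYPE_COLUMNS` plus an
    ``excluded`` flag. Rows are flagged (not dropped) when the recorded age
    at menopause exceeds the age at MRI — an abnormal response — or when
    either age is missing. Score fields equal to the 999 sentinel or NaN are
    recoded to NaN; missing scores by themselves do not exclude a subject
    here (score-specific exclusion happens per analysis).
    """
    df = pd.read_csv(path_tsv, sep="\t")
    if column_map:
        df = df.rename(columns=dict(column_map))
    missing = [c for c in PHENOTYPE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path_tsv}: missing mandatory columns {missing}")
    df = df.loc[:, list(PHENOTYPE_COLUMNS)].copy()
    if df["subject_id"].duplicated().any():
        dupes = df.loc[df["subject_id"].duplicated(), "subject_id"].tolist()
        raise FormatError(f"{path_tsv}: duplicated subject ids {dupes}")
    for col in PHENOTYPE_COLUMNS[1:]:
        df[col] = pd.to_numeric(df[col], errors="coerce")
    for col in SCORE_COLUMNS:
        df.loc[df[col] == MISSING_SCORE_SENTINEL, col] = np.nan
    bad_age = (
        df["age_at_mri"].isna()
        | df["age_at_menopause"].isna()
        | (df["age_at_menopause"] > df["age_at_mri"])
    )
    df["excluded"] = bad_age
    return df.reset_index(drop=True)


def write_phenotypes(path_tsv: str, df: pd.DataFrame) -> None:
    cols = [c for c in PHENOTYPE_COLUMNS if c in df.columns]
    df.loc[:, cols].to_csv(path_tsv, sep="\t", index=False)


# ---------------------------------------------------------------------------
# geometry

def read_geometry(path_tsv: str) -> SurfaceGeometry:
    """Read a per-vertex scalar table (columns pg_score, parcel_id)."""
    df = pd.read_csv(path_tsv, sep="\t")
    for col in ("pg_score", "parcel_id"):
        if col not in df.columns:
            raise FormatError(f"{path_tsv}: missing column {col!r}")
    return SurfaceGeometry(pg_score=df["pg_score"].to_numpy(float),
                           parcel_id=df["parcel_id"].to_numpy(int))


def write_geometry(path_tsv: str, geometry: SurfaceGeometry) -> None:
    pd.DataFrame({
        "pg_score": geometry.pg_score,
        "parcel_id": geometry.parcel_id,
    }).to_csv(path_tsv, sep="\t", index=False, float_format="%.17g")
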