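"""Data model and file I/O for network-restricted resting-state analysis.

All images are NIfTI-1 (``.nii`` / ``.nii.gz``) on a common, already-normalized
grid; cohort manifests are TSV; motion parameters are whitespace-delimited
6-column text; stage reports are JSON.  Voxel indices are 0-based throughout and
millimetre (MNI) coordinates come only from the affine.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "GridMismatchError",
    "BoldSeries",
    "MotionParams",
    "NetworkMask",
    "SubjectRecord",
    "FeatureMap",
    "read_bold",
    "write_bold",
    "read_motion",
    "write_motion",
    "read_manifest",
    "write_manifest",
    "read_mask",
    "write_mask",
    "build_network_mask",
    "read_feature_map",
    "write_feature_map",
    "check_same_grid",
    "write_json",
    "read_json",
]

AFFINE_ATOL = 1e-6

PATIENT = "patient"
CONTROL = "control"

_GROUP_ALIASES = {
    "patient": PATIENT,
    "ocd": PATIENT,
    "case": PATIENT,
    "control": CONTROL,
    "hc": CONTROL,
    "healthy": CONTROL,
}

_SEX_ALIASES = {"male": "male", "m": "male", "female": "female", "f": "female"}


class GridMismatchError(ValueError):
    """Two images that must share a voxel grid do not."""


def check_same_grid(
    shape_a: Sequence[int],
    affine_a: np.ndarray,
    shape_b: Sequence[int],
    affine_b: np.ndarray,
    what: str = "images",
) -> None:
    """Raise :class:`GridMismatchError` unless spatial shapes and affines agree."""
    if tuple(shape_a[:3]) != tuple(shape_b[:3]):
        raise GridMismatchError(
            f"{what}: spatial shapes differ: {tuple(shape_a[:3])} vs {tuple(shape_b[:3])}"
        )
    if not np.allclose(affine_a, affine_b, atol=AFFINE_ATOL, rtol=0):
        raise GridMismatchError(f"{what}: affines differ beyond {AFFINE_ATOL}")


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class BoldSeries:
    """One subject's 4D BOLD series on a normalized grid.

    ``voxel_data`` is (x, y, z, t) in native scanner units (scl slope/intercept
    applied at load); ``affine`` maps 0-based voxel indices to MNI mm.
    """

    voxel_data: np.ndarray
    affine: np.ndarray
    tr_seconds: float
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.voxel_data = np.asarray(self.voxel_data, dtype=float)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.voxel_data.ndim != 4:
            raise ValueError(
                f"expected 4D BOLD data, got {self.voxel_data.ndim}D"
            )
        if self.voxel_data.shape[3] < 2:
            raise ValueError("BOLD series needs at least 2 volumes")
        if self.tr_seconds <= 0:
            raise ValueError(f"nonpositive TR: {self.tr_seconds}")
        if abs(np.linalg.det(self.affine)) < 1e-12:
            raise ValueError("affine is not invertible")
        if not np.all(np.isfinite(self.voxel_data)):
            n_bad = int(np.sum(~np.isfinite(self.voxel_data)))
            raise ValueError(
                f"BOLD data contains {n_bad} non-finite values; mask or repair "
                "the input before analysis"
            )

    @property
    def n_volumes(self) -> int:
        return self.voxel_data.shape[3]

    @property
    def shape(self) -> tuple[int, int, int, int]:
        return self.voxel_data.shape

    def with_data(self, data: np.ndarray) -> "BoldSeries":
        return replace(self, voxel_data=data)


@dataclass
class MotionParams:
    """Rigid-body motion series: t x 3 translations (mm) and t x 3 rotations (rad)."""

    translations_mm: np.ndarray
    rotations_rad: np.ndarray

    def __post_init__(self) -> None:
        self.translations_mm = np.atleast_2d(np.asarray(self.translations_mm, dtype=float))
        self.rotations_rad = np.atleast_2d(np.asarray(self.rotations_rad, dtype=float))
        if self.translations_mm.shape[1] != 3 or self.rotations_rad.shape[1] != 3:
            raise ValueError("motion parameters must have 3 translation and 3 rotation columns")
        if self.translations_mm.shape[0] != self.rotations_rad.shape[0]:
            raise ValueError("translation and rotation row counts differ")

    @property
    def n_volumes(self) -> int:
        return self.translations_mm.shape[0]

    def __getitem__(self, idx) -> "MotionParams":
        return MotionParams(self.translations_mm[idx], self.rotations_rad[idx])


@dataclass
class NetworkMask:
    """Labeled 3D region image defining the analysis domain.

    ``label_data`` holds nonnegative integer labels, 0 = outside the network.
    """

    label_data: np.ndarray
    affine: np.ndarray
    region_names: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.label_data = np.asarray(self.label_data)
        if self.label_data.ndim != 3:
            raise ValueError("mask must be 3D")
        if not np.issubdtype(self.label_data.dtype, np.integer):
            rounded = np.rint(self.label_data)
            if not np.allclose(self.label_data, rounded, atol=1e-6):
                raise ValueError("mask labels must be integers")
            self.label_data = rounded.astype(np.int32)
        if self.label_data.min() < 0:
            raise ValueError("mask labels must be nonnegative")
        if not np.any(self.label_data):
            raise ValueError("empty mask: no nonzero voxels")
        self.affine = np.asarray(self.affine, dtype=float)

    @property
    def binary(self) -> np.ndarray:
        return self.label_data > 0

    @property
    def indices(self) -> np.ndarray:
        """(V, 3) array of 0-based voxel indices inside the mask (C order)."""
        return np.argwhere(self.label_data > 0)

    @property
    def n_voxels(self) -> int:
        return int(np.count_nonzero(self.label_data))

    @property
    def voxel_size_mm(self) -> np.ndarray:
        return np.sqrt((self.affine[:3, :3] ** 2).sum(axis=0))

    def voxel_to_mm(self, ijk: Sequence[float]) -> np.ndarray:
        ijk = np.asarray(ijk, dtype=float)
        return self.affine[:3, :3] @ ijk + self.affine[:3, 3]


@dataclass
class SubjectRecord:
    """One manifest row: identity, group, demographics and clinical scores.

    Missing clinical values are ``None`` (never imputed); ``mean_fd_mm`` is
    filled by the preprocessing stage, not by manifest parsing.
    """

    subject_id: str
    group: str
    age_years: float
    sex: str
    education_years: float
    illness_duration_months: float | None = None
    ybocs_total: float | None = None
    ybocs_obsessive: float | None = None
    ybocs_compulsive: float | None = None
    hamd: float | None = None
    hama: float | None = None
    mean_fd_mm: float | None = None
    bold_path: str | None = None
    motion_path: str | None = None
    wm_path: str | None = None
    csf_path: str | None = None

    def __post_init__(self) -> None:
        if self.group not in (PATIENT, CONTROL):
            raise ValueError(f"unknown group label: {self.group!r}")
        if self.sex not in ("male", "female"):
            raise ValueError(f"unknown sex label: {self.sex!r}")
        for name in ("ybocs_total", "ybocs_obsessive", "ybocs_compulsive", "hamd", "hama"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"{name} must be nonnegative, got {v}")

    @property
    def is_patient(self) -> bool:
        return self.group == PATIENT


@dataclass
class FeatureMap:
    """Per-subject 3D map of fALFF or NH values, defined on mask voxels only.

    Outside the mask values are NaN (undefined); inside they are finite.
    """

    values: np.ndarray
    kind: str
    subject_id: str = ""
    standardized: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("feature map must be 3D")
        if self.kind not in ("falff", "nh"):
            raise ValueError(f"kind must be 'falff' or 'nh', got {self.kind!r}")

    def masked(self, mask: NetworkMask) -> np.ndarray:
        vals = self.values[mask.binary]
        if not np.all(np.isfinite(vals)):
            raise ValueError("feature map has non-finite values inside the mask")
        return vals


# ---------------------------------------------------------------------------
# NIfTI I/O
# ---------------------------------------------------------------------------


def read_bold(
    path: str | Path,
    tr_override: float | None = None,
    subject_id: str | None = None,
) -> BoldSeries:
    """Load a 4D NIfTI as a :class:`BoldSeries`.

    TR is taken from header pixdim[4] unless ``tr_override`` is given (headers
    are frequently wrong in shared data, so an explicit override wins).
    scl_slope/scl_inter scaling is applied.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    img = nib.load(str(path))
    if img.ndim != 4:
        raise ValueError(f"expected 4D image, got {img.ndim}D: {path}")
    data = np.asarray(img.get_fdata(), dtype=float)  # applies scl_slope/scl_inter
    if tr_override is not None:
        tr = float(tr_override)
    else:
        tr = float(img.header.get_zooms()[3])
        if tr <= 0:
            raise ValueError(
                f"nonpositive TR in NIfTI header field pixdim[4] ({tr}) for {path}; "
                "pass an explicit TR override"
            )
    return BoldSeries(
        voxel_data=data,
        affine=np.asarray(img.affine),
        tr_seconds=tr,
        subject_id=subject_id or path.name.split(".")[0],
    )


def write_bold(bold: BoldSeries, path: str | Path) -> Path:
    path = Path(path)
    img = nib.Nifti1Image(bold.voxel_data, bold.affine)
    zooms = list(img.header.get_zooms())
    zooms[3] = bold.tr_seconds
    img.header.set_zooms(zooms)
    img.header.set_xyzt_units("mm", "sec")
    nib.save(img, str(path))
    return path


def read_mask(path: str | Path, region_names: Mapping[int, str] | None = None) -> NetworkMask:
    img = nib.load(str(Path(path)))
    if img.ndim != 3:
        raise ValueError(f"expected 3D label image, got {img.ndim}D: {path}")
    data = np.asarray(img.get_fdata())
    return NetworkMask(
        label_data=data,
        affine=np.asarray(img.affine),
        region_names=dict(region_names or {}),
    )


def write_mask(mask: NetworkMask, path: str | Path) -> Path:
    path = Path(path)
    img = nib.Nifti1Image(mask.label_data.astype(np.int16), mask.affine)
    nib.save(img, str(path))
    names_path = path.parent / (path.name.split(".")[0] + "_regions.json")
    if mask.region_names:
        write_json({str(k): v for k, v in mask.region_names.items()}, names_path)
    return path


def read_feature_map(path: str | Path, kind: str, subject_id: str = "", standardized: bool = False) -> FeatureMap:
    img = nib.load(str(Path(path)))
    return FeatureMap(
        values=np.asarray(img.get_fdata()),
        kind=kind,
        subject_id=subject_id,
        standardized=standardized,
    )


def write_feature_map(fmap: FeatureMap, affine: np.ndarray, path: str | Path) -> Path:
    path = Path(path)
    nib.save(nib.Nifti1Image(fmap.values, np.asarray(affine, dtype=float)), str(path))
    return path


# ---------------------------------------------------------------------------
# Motion parameters
# ---------------------------------------------------------------------------


def read_motion(path: str | Path, rotations_first: bool = False) -> MotionParams:
    """Read whitespace-delimited 6-column motion text.

    Default column order is translations (mm) then rotations (rad);
    ``rotations_first=True`` flips it for the other common dialect.
    """
    arr = np.loadtxt(str(Path(path)), ndmin=2)
    if arr.shape[1] != 6:
        raise ValueError(f"expected 6 motion columns, got {arr.shape[1]} in {path}")
    if rotations_first:
        return MotionParams(translations_mm=arr[:, 3:6], rotations_rad=arr[:, 0:3])
    return MotionParams(translations_mm=arr[:, 0:3], rotations_rad=arr[:, 3:6])


def write_motion(motion: MotionParams, path: str | Path) -> Path:
    path = Path(path)
    np.savetxt(str(path), np.hstack([motion.translations_mm, motion.rotations_rad]), fmt="%.10g")
    return path


# ---------------------------------------------------------------------------
# Manifest (TSV)
# ---------------------------------------------------------------------------

_REQUIRED_COLUMNS = ("subject_id", "group", "age", "sex", "education")
_OPTIONAL_NUMERIC = {
    "illness_duration": "illness_duration_months",
    "ybocs_total": "ybocs_total",
    "ybocs_obsessive": "ybocs_obsessive",
    "ybocs_compulsive": "ybocs_compulsive",
    "hamd": "hamd",
    "hama": "hama",
    "mean_fd": "mean_fd_mm",
}
_OPTIONAL_PATHS = ("bold_path", "motion_path", "wm_path", "csf_path")


def _parse_optional_float(value) -> float | None:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return None
    if isinstance(value, str) and value.strip() in ("", "NA", "na", "NaN", "nan", "."):
        return None
    return float(value)


def read_manifest(path: str | Path) -> list[SubjectRecord]:
    """Parse a TSV cohort manifest into :class:`SubjectRecord` rows.

    Group and sex strings map case-insensitively (OCD/patient/case; HC/control).
    Missing clinical values stay missing.  Row-level problems report the
    1-based file line number (header is line 1).
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"manifest {path} missing required columns: {missing}")
    records: list[SubjectRecord] = []
    seen: dict[str, int] = {}
    for i, row in df.iterrows():
        line = int(i) + 2
        sid = str(row["subject_id"]).strip()
        if sid in seen:
            raise ValueError(
                f"duplicate subject_id {sid!r} at line {line} (first at line {seen[sid]})"
            )
        seen[sid] = line
        group_raw = str(row["group"]).strip().lower()
        if group_raw not in _GROUP_ALIASES:
            raise ValueError(f"line {line}: unknown group label {row['group']!r}")
        sex_raw = str(row["sex"]).strip().lower()
        if sex_raw not in _SEX_ALIASES:
            raise ValueError(f"line {line}: unknown sex label {row['sex']!r}")
        try:
            age = float(row["age"])
            edu = float(row["education"])
        except (TypeError, ValueError) as exc:
            raise ValueError(f"line {line}: non-numeric age/education: {exc}") from None
        kwargs = {}
        for col, attr in _OPTIONAL_NUMERIC.items():
            if col in df.columns:
                try:
                    kwargs[attr] = _parse_optional_float(row[col])
                except ValueError:
                    raise ValueError(f"line {line}: non-numeric value in column {col!r}") from None
        for col in _OPTIONAL_PATHS:
            if col in df.columns:
                v = row[col]
                kwargs[col] = None if (not isinstance(v, str) or not v.strip()) else v.strip()
        records.append(
            SubjectRecord(
                subject_id=sid,
                group=_GROUP_ALIASES[group_raw],
                age_years=age,
                sex=_SEX_ALIASES[sex_raw],
                education_years=edu,
                **kwargs,
            )
        )
    return records


def write_manifest(records: Iterable[SubjectRecord], path: str | Path) -> Path:
    path = Path(path)
    rows = []
    for r in records:
        row = {
            "subject_id": r.subject_id,
            "group": r.group,
            "age": r.age_years,
            "sex": r.sex,
            "education": r.education_years,
            "illness_duration": r.illness_duration_months,
            "ybocs_total": r.ybocs_total,
            "ybocs_obsessive": r.ybocs_obsessive,
            "ybocs_compulsive": r.ybocs_compulsive,
            "hamd": r.hamd,
            "hama": r.hama,
            "mean_fd": r.mean_fd_mm,
        }
        for col in _OPTIONAL_PATHS:
            v = getattr(r, col)
            if v is not None:
                row[col] = v
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.10g")
    return path


# ---------------------------------------------------------------------------
# Mask building
# ---------------------------------------------------------------------------


def build_network_mask(
    label_image: NetworkMask,
    selected_labels: Iterable[int],
    region_names: Mapping[int, str] | None = None,
) -> NetworkMask:
    """Restrict a label image to a set of region labels.

    Labels absent from the image produce a warning, not a failure; an empty
    result mask is an error because the analysis domain would be empty.
    """
    selected = {int(v) for v in selected_labels}
    if not selected:
        raise ValueError("selected_labels must be nonempty")
    present = set(np.unique(label_image.label_data)) - {0}
    absent = sorted(selected - present)
    if absent:
        warnings.warn(f"labels not present in label image: {absent}", stacklevel=2)
    keep = np.isin(label_image.label_data, sorted(selected))
    out = np.where(keep, label_image.label_data, 0)
    if not np.any(out):
        raise ValueError("empty mask: none of the selected labels has any voxel")
    names = dict(region_names or label_image.region_names)
    names = {k: v for k, v in names.items() if k in selected}
    return NetworkMask(label_data=out, affine=label_image.affine, region_names=names)


# ---------------------------------------------------------------------------
# JSON reports
# ---------------------------------------------------------------------------


def _to_jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, Path):
        return str(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


def write_json(obj, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=_to_jsonable) + "\n")
    return path


def read_json(path: str | Path):
    return json.loads(Path(path).read_text())
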