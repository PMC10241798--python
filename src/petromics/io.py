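"""Volume and table I/O.

PET volumes travel as NIfTI-1 files (``.nii`` / ``.nii.gz``) holding either
activity concentration in Bq/mL or precomputed standardized-uptake values
(SUV).  The SUV conversion implemented here is body-weight SUV:

    SUV = (activity concentration [Bq/mL]) / (injected activity [Bq]) x (body weight [g])

which yields g/mL, conventionally reported as a dimensionless number.
Decay correction of the injected activity to scan time is assumed to have
happened upstream; :class:`InjectionRecord` carries the scan-time activity.

Clinical covariates travel as a CSV with a fixed schema
(``patient_id,age,figo,response,recurrence,cycles,regimen``) and fixed
category vocabularies mirroring a cervical-cancer chemotherapy cohort.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .errors import DataError

__all__ = [
    "ActivityVolume",
    "SUVVolume",
    "InjectionRecord",
    "read_volume",
    "write_volume",
    "activity_to_suv",
    "read_clinical_table",
    "validate_clinical_table",
    "write_feature_table",
    "read_feature_table",
    "CLINICAL_COLUMNS",
    "VOCABULARIES",
]

CLINICAL_COLUMNS = (
    "patient_id",
    "age",
    "figo",
    "response",
    "recurrence",
    "cycles",
    "regimen",
)

VOCABULARIES = {
    "figo": ("IIIC1", "IIIC2", "IVB"),
    "response": ("non-responder", "responder"),
    "recurrence": ("none", "local", "distant"),
    "regimen": (
        "paclitaxel+cisplatin",
        "paclitaxel+carboplatin",
        "paclitaxel+carboplatin+bevacizumab",
        "etoposide+cisplatin",
    ),
}

#: Column order of the per-(patient, timepoint) feature table.
FEATURE_COLUMNS = (
    "patient_id",
    "timepoint",
    "suv_max",
    "suv_mean",
    "suv_sd",
    "cov",
    "mtv_cm3",
    "tlg",
    "asp",
    "skewness",
    "kurtosis",
    "entropy_bits",
    "glcm_contrast",
    "glcm_correlation",
    "glcm_energy",
    "glcm_homogeneity",
    "glcm_levels",
    "glcm_mode",
)


def _check_spacing(spacing: tuple[float, float, float]) -> tuple[float, float, float]:
    spacing = tuple(float(s) for s in spacing)
    if len(spacing) != 3 or any(s <= 0 for s in spacing):
        raise DataError(f"voxel spacing must be 3 positive numbers, got {spacing}")
    return spacing


@dataclass
class _BaseVolume:
    values: np.ndarray
    voxel_spacing: tuple[float, float, float]
    affine: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise DataError(f"non-3D volume: got {self.values.ndim} dimensions")
        if not np.all(np.isfinite(self.values)):
            raise DataError("volume contains non-finite values")
        self.voxel_spacing = _check_spacing(self.voxel_spacing)
        if self.affine is None:
            self.affine = np.diag(list(self.voxel_spacing) + [1.0])

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.voxel_spacing))

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(self.values.shape)


@dataclass
class ActivityVolume(_BaseVolume):
    """3D activity-concentration field in Bq/mL."""


@dataclass
class SUVVolume(_BaseVolume):
    """3D standardized-uptake-value field (dimensionless, g/mL convention).

    ``provenance`` records whether the values were read as SUV directly
    (``"raw-suv"``) or converted from activity concentration (``"converted"``).
    """

    provenance: str = "raw-suv"


@dataclass(frozen=True)
class InjectionRecord:
    """Injected activity (Bq, decay-corrected to scan time) and body weight (g)."""

    injected_activity_bq: float
    body_weight_g: float

    def __post_init__(self) -> None:
        if self.injected_activity_bq <= 0:
            raise DataError("injected activity must be positive")
        if self.body_weight_g <= 0:
            raise DataError("body weight must be positive")


def read_volume(path: str | Path, units: str = "suv") -> SUVVolume | ActivityVolume:
    """Read a 3D NIfTI volume.

    Parameters
    ----------
    path:
        NIfTI-1 file (``.nii`` or ``.nii.gz``).
    units:
        ``"suv"`` to interpret voxel values as SUV, ``"bqml"`` for activity
        concentration in Bq/mL.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"volume file not found: {path}")
    img = nib.load(str(path))
    data = np.asarray(img.get_fdata(), dtype=np.float64)
    if data.ndim != 3:
        raise DataError(f"non-3D volume in {path}: shape {data.shape}")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    if any(s <= 0 for s in spacing):
        raise DataError(f"non-positive voxel spacing in {path}: {spacing}")
    if units == "suv":
        return SUVVolume(data, spacing, np.asarray(img.affine))
    if units == "bqml":
        return ActivityVolume(data, spacing, np.asarray(img.affine))
    raise DataError(f"unknown units {units!r}; expected 'suv' or 'bqml'")


def write_volume(vol: _BaseVolume, path: str | Path) -> Path:
    """Write a volume as 32-bit-float NIfTI-1; round-trips with :func:`read_volume`."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    img = nib.Nifti1Image(np.asarray(vol.values, dtype=np.float32), vol.affine)
    img.header.set_zooms(vol.voxel_spacing)
    nib.save(img, str(path))
    return path


def activity_to_suv(vol: ActivityVolume, inj: InjectionRecord) -> SUVVolume:
    """Convert activity concentration to body-weight SUV.

    Each voxel becomes ``v / injected_activity * body_weight`` so the
    conversion is linear in the input volume.
    """
    values = (
        np.asarray(vol.values, dtype=np.float64)
        / inj.injected_activity_bq
        * inj.body_weight_g
    )
    return SUVVolume(values, vol.voxel_spacing, vol.affine, provenance="converted")


def validate_clinical_table(df: pd.DataFrame) -> pd.DataFrame:
    """Validate schema, uniqueness and vocabularies of a clinical table."""
    missing = [c for c in CLINICAL_COLUMNS if c not in df.columns]
    if missing:
        raise DataError(f"clinical table missing columns: {missing}")
    if df["patient_id"].duplicated().any():
        dups = df.loc[df["patient_id"].duplicated(), "patient_id"].tolist()
        raise DataError(f"duplicate patient_id values: {dups}")
    ages = pd.to_numeric(df["age"], errors="coerce")
    if ages.isna().any() or (ages < 0).any() or (ages > 120).any():
        raise DataError("age must be numeric within [0, 120]")
    for col, vocab in VOCABULARIES.items():
        bad = sorted(set(df[col].astype(str)) - set(vocab))
        if bad:
            raise DataError(
                f"unknown {col} value(s) {bad}; allowed vocabulary: {list(vocab)}"
            )
    cycles = pd.to_numeric(df["cycles"], errors="coerce")
    if cycles.isna().any() or (cycles < 1).any():
        raise DataError("cycles must be a positive integer count")
    return df


def read_clinical_table(path: str | Path) -> pd.DataFrame:
    """Read and validate the clinical covariate CSV."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"clinical table not found: {path}")
    df = pd.read_csv(path)
    return validate_clinical_table(df)


def write_feature_table(df: pd.DataFrame, path: str | Path) -> Path:
    """Write a feature table CSV with stable column order and full precision."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    cols = [c for c in FEATURE_COLUMNS if c in df.columns]
    cols += [c for c in df.columns if c not in cols]
    # pandas default float formatting is shortest round-trip repr
    df.loc[:, cols].to_csv(path, index=False)
    return path


def read_feature_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"feature table not found: {path}")
    return pd.read_csv(path)
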