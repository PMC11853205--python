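"""Reading and writing SUV volumes, exclusion masks, and cohort tables.

Whole-body PET data are handled as 3-D grids of standardized uptake values
(SUV, body-weight convention, dimensionless) with physical voxel spacing in
millimetres.  Volumes are stored as NIfTI-1 files; the spacing comes from the
header and is never guessed.  DICOM series assembly is out of scope: inputs
are assumed to be already converted to SUV grids.
"""

from __future__ import annotations

import dataclasses
import os
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

__all__ = [
    "SUVVolume",
    "ExclusionMask",
    "read_suv_volume",
    "write_suv_volume",
    "read_exclusion_mask",
    "write_exclusion_mask",
    "activity_to_suv",
]


@dataclass(frozen=True)
class SUVVolume:
    """A 3-D scalar field of SUV values with physical voxel spacing.

    Parameters
    ----------
    values : ndarray, shape (nx, ny, nz)
        Non-negative, finite SUV values (dimensionless, g/mL convention).
    spacing : tuple of 3 floats
        Physical voxel size along each axis, in mm; strictly positive.
    axial_axis : int
        Index of the cranio-caudal (axial-slice) axis.  The minimum
        contiguous-slice rule of segmentation is applied along this axis.
    patient_id : str
        Opaque identifier carried through the pipeline.
    """

    values: np.ndarray
    spacing: tuple[float, float, float]
    axial_axis: int = 2
    patient_id: str = ""

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=np.float64)
        object.__setattr__(self, "values", values)
        if values.ndim != 3:
            raise ValueError(f"expected 3-D volume, got {values.ndim}-D data")
        if not np.all(np.isfinite(values)):
            raise ValueError("SUV values must be finite (found NaN or inf)")
        if values.size and values.min() < 0:
            raise ValueError(
                f"SUV values must be non-negative (minimum value {values.min():g})"
            )
        spacing = tuple(float(s) for s in self.spacing)
        if len(spacing) != 3:
            raise ValueError("spacing must have exactly 3 components")
        for axis, s in enumerate(spacing):
            if not np.isfinite(s) or s <= 0:
                raise ValueError(f"voxel spacing must be positive; axis {axis} has {s:g}")
        object.__setattr__(self, "spacing", spacing)
        if self.axial_axis not in (0, 1, 2):
            raise ValueError(f"axial_axis must be 0, 1 or 2, got {self.axial_axis}")

    @property
    def voxel_volume_ml(self) -> float:
        """Volume of one voxel in mL (spacing product in mm^3 / 1000)."""
        return float(np.prod(self.spacing)) / 1000.0

    def with_values(self, values: np.ndarray) -> "SUVVolume":
        return dataclasses.replace(self, values=values)


@dataclass(frozen=True)
class ExclusionMask:
    """Boolean grid flagging physiological-uptake regions to exclude.

    The grid must match the paired :class:`SUVVolume` exactly; no
    registration is performed.  Typical labels: ``"brain"``, ``"bladder"``.
    """

    values: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=bool)
        object.__setattr__(self, "values", values)
        if values.ndim != 3:
            raise ValueError(f"expected 3-D mask, got {values.ndim}-D data")


def _spacing_affine(spacing: tuple[float, float, float]) -> np.ndarray:
    affine = np.eye(4)
    affine[0, 0], affine[1, 1], affine[2, 2] = spacing
    return affine


def _check_raw_spacing(path: str | os.PathLike) -> None:
    """Reject missing/zero voxel spacing before nibabel 'repairs' it to 1."""
    import gzip

    opener = gzip.open if str(path).endswith(".gz") else open
    try:
        with opener(str(path), "rb") as fh:
            header = nib.Nifti1Header.from_fileobj(fh, check=False)
    except Exception:
        return  # non-NIfTI containers: fall through to nibabel's own errors
    ndim = int(header["dim"][0])
    pixdim = np.asarray(header["pixdim"][1:1 + min(ndim, 3)], dtype=float)
    for axis, z in enumerate(pixdim):
        if not np.isfinite(z) or z <= 0:
            raise ValueError(
                f"volume {path} has missing or non-positive voxel spacing on "
                f"axis {axis}: {z:g}")


def read_suv_volume(path: str | os.PathLike, patient_id: str | None = None,
                    axial_axis: int = 2) -> SUVVolume:
    """Read an SUV volume from a NIfTI-1 file.

    Spacing is taken from the header (mm).  Fails rather than guessing:
    non-3-D data, missing/zero spacing, and negative values are rejected.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(f"no such volume file: {path}")
    _check_raw_spacing(path)
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"expected 3-D volume, got {data.ndim}-D data in {path}")
    zooms = img.header.get_zooms()[:3]
    for axis, z in enumerate(zooms):
        if not np.isfinite(z) or z <= 0:
            raise ValueError(
                f"volume {path} has non-positive voxel spacing on axis {axis}: {z:g}"
            )
    if data.size and float(np.min(data)) < 0:
        raise ValueError(
            f"volume {path} contains negative SUV (minimum {float(np.min(data)):g})"
        )
    if patient_id is None:
        stem = os.path.basename(str(path))
        for suffix in (".nii.gz", ".nii"):
            if stem.endswith(suffix):
                stem = stem[: -len(suffix)]
                break
        patient_id = stem
    return SUVVolume(values=np.asarray(data, dtype=np.float64),
                     spacing=tuple(float(z) for z in zooms),
                     axial_axis=axial_axis, patient_id=patient_id)


def write_suv_volume(volume: SUVVolume, path: str | os.PathLike) -> None:
    """Write an SUV volume to NIfTI-1 so that it round-trips bit-exactly."""
    if not isinstance(volume, SUVVolume):
        volume = SUVVolume(**volume) if isinstance(volume, dict) else SUVVolume(
            values=np.asarray(volume), spacing=(1.0, 1.0, 1.0))
    img = nib.Nifti1Image(np.asarray(volume.values, dtype=np.float64),
                          _spacing_affine(volume.spacing))
    img.header.set_zooms(volume.spacing)
    nib.save(img, str(path))


def read_exclusion_mask(path: str | os.PathLike, label: str = "") -> ExclusionMask:
    """Read a boolean exclusion mask from NIfTI (non-zero voxels = excluded)."""
    if not os.path.exists(path):
        raise FileNotFoundError(f"no such mask file: {path}")
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"expected 3-D mask, got {data.ndim}-D data in {path}")
    return ExclusionMask(values=data != 0, label=label or os.path.basename(str(path)))


def write_exclusion_mask(mask: ExclusionMask, spacing: tuple[float, float, float],
                         path: str | os.PathLike) -> None:
    img = nib.Nifti1Image(mask.values.astype(np.uint8), _spacing_affine(spacing))
    img.header.set_zooms(spacing)
    nib.save(img, str(path))


def activity_to_suv(activity: np.ndarray, injected_dose_mbq: float,
                    body_weight_kg: float, *, decay_corrected: bool = True,
                    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
                    axial_axis: int = 2, patient_id: str = "") -> SUVVolume:
    """Convert an activity-concentration grid (kBq/mL) to body-weight SUV.

    SUV = concentration [kBq/mL] x body weight [g] / injected dose [kBq];
    dimensionless under the 1 g/mL tissue-density convention.  The activity
    is expected to be decay-corrected to injection time; pass
    ``decay_corrected=False`` to make the missing correction explicit (the
    conversion itself is unchanged — callers must correct upstream).
    """
    if injected_dose_mbq <= 0:
        raise ValueError(f"injected dose must be positive, got {injected_dose_mbq:g} MBq")
    if body_weight_kg <= 0:
        raise ValueError(f"body weight must be positive, got {body_weight_kg:g} kg")
    activity = np.asarray(activity, dtype=np.float64)
    if not decay_corrected:
        raise ValueError(
            "activity must be decay-corrected to injection time before SUV conversion")
    weight_g = body_weight_kg * 1000.0
    dose_kbq = injected_dose_mbq * 1000.0
    suv = activity * (weight_g / dose_kbq)
    return SUVVolume(values=suv, spacing=spacing, axial_axis=axial_axis,
                     patient_id=patient_id)
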