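"""Core volumetric data model and NIfTI/CSV input-output.

A lesion is represented by three co-registered 3D grids on a common voxel
lattice: an apparent-diffusion-coefficient (ADC) map in units of
10^-3 mm^2/s, a venous-enhancement (VE) map in arbitrary enhancement units,
and a binary lesion mask.  All voxel indices are 0-based and neighborhood
offsets are expressed in voxel-index space; volumes are required to be
pre-aligned on a common grid, so NIfTI orientation metadata is carried
through but never used for resampling.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .errors import AlignmentError, CohortError, ValidationError

#: tolerated voxel-spacing disagreement between paired volumes, in mm
SPACING_TOL_MM = 1e-3


class MapKind(enum.Enum):
    ADC = "adc"
    VE = "ve"


class Grade(enum.IntEnum):
    """Histologic differentiation grade (Edmondson-Steiner), ordered
    well < moderate < poor.  The integer order is the class-index order
    used for classification tie-breaks."""

    well = 0
    moderate = 1
    poor = 2

    @classmethod
    def parse(cls, text: str) -> "Grade":
        try:
            return cls[str(text).strip().lower()]
        except KeyError:
            raise CohortError(f"unknown grade {text!r}; expected one of "
                              f"{[g.name for g in cls]}") from None


@dataclass(frozen=True)
class VolumetricMap:
    """One 3D scalar grid (ADC or VE) with voxel spacing in mm (x, y, z)."""

    grid: np.ndarray
    spacing: tuple[float, float, float]
    kind: MapKind
    affine: np.ndarray | None = field(default=None, compare=False, repr=False)

    def __post_init__(self):
        grid = np.asarray(self.grid)
        if grid.ndim != 3:
            raise ValidationError(f"map grid must be 3D, got shape {grid.shape}")
        if not np.all(np.isfinite(grid)):
            raise ValidationError(f"{self.kind.value} map contains non-finite voxels")
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValidationError(f"spacing must be 3 positive lengths, got {self.spacing}")
        object.__setattr__(self, "grid", grid)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.grid.shape


@dataclass(frozen=True)
class LesionMask:
    """Binary 3D grid defining the region every feature is computed over."""

    grid: np.ndarray
    spacing: tuple[float, float, float]
    affine: np.ndarray | None = field(default=None, compare=False, repr=False)

    def __post_init__(self):
        grid = np.asarray(self.grid)
        if grid.ndim != 3:
            raise ValidationError(f"mask grid must be 3D, got shape {grid.shape}")
        values = np.unique(grid)
        if not np.isin(values, (0, 1)).all():
            raise ValidationError(f"mask values must be 0/1, found {values[:10]}")
        if not grid.any():
            raise ValidationError("mask has no foreground voxels")
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValidationError(f"spacing must be 3 positive lengths, got {self.spacing}")
        object.__setattr__(self, "grid", grid.astype(bool))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.grid.shape

    @property
    def n_foreground(self) -> int:
        return int(self.grid.sum())


@dataclass(frozen=True)
class CohortRecord:
    lesion_id: str
    grade: Grade
    adc_path: Path
    ve_path: Path
    mask_path: Path


def _load_nifti(path: Path) -> tuple[np.ndarray, tuple[float, float, float], np.ndarray]:
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise ValidationError(f"{path}: expected a 3D volume, got shape {data.shape}")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return data, spacing, img.affine


def _check_aligned(name: str, path: Path, shape, spacing, ref_shape, ref_spacing) -> None:
    if shape != ref_shape:
        raise AlignmentError(
            f"{name} volume {path} has shape {shape}, expected {ref_shape}")
    drift = max(abs(a - b) for a, b in zip(spacing, ref_spacing))
    if drift > SPACING_TOL_MM:
        raise AlignmentError(
            f"{name} volume {path} spacing {spacing} deviates from {ref_spacing} "
            f"by {drift:.2g} mm (> {SPACING_TOL_MM} mm)")


def read_lesion(record: CohortRecord) -> tuple[VolumetricMap, VolumetricMap, LesionMask]:
    """Load and validate the ADC map, VE map and mask for one lesion.

    Raises
    ------
    AlignmentError
        if the three grids disagree in shape or spacing (beyond
        ``SPACING_TOL_MM``), naming the offending file.
    ValidationError
        for non-finite voxels, non-binary masks, or an empty mask.
    """
    adc_grid, adc_sp, adc_aff = _load_nifti(record.adc_path)
    ve_grid, ve_sp, ve_aff = _load_nifti(record.ve_path)
    mask_grid, mask_sp, mask_aff = _load_nifti(record.mask_path)

    _check_aligned("VE", record.ve_path, ve_grid.shape, ve_sp, adc_grid.shape, adc_sp)
    _check_aligned("mask", record.mask_path, mask_grid.shape, mask_sp,
                   adc_grid.shape, adc_sp)

    mask_values = np.unique(mask_grid)
    if not np.isin(mask_values, (0, 1)).all():
        raise ValidationError(
            f"mask {record.mask_path} has values outside {{0,1}}: {mask_values[:10]}")

    adc = VolumetricMap(adc_grid, adc_sp, MapKind.ADC, affine=adc_aff)
    ve = VolumetricMap(ve_grid, ve_sp, MapKind.VE, affine=ve_aff)
    mask = LesionMask(mask_grid, mask_sp, affine=mask_aff)
    return adc, ve, mask


COHORT_COLUMNS = ["lesion_id", "grade", "adc_path", "ve_path", "mask_path"]


def read_cohort(csv_path: str | Path) -> list[CohortRecord]:
    """Parse a cohort table into records.

    The CSV must carry the header ``lesion_id,grade,adc_path,ve_path,mask_path``;
    grades are parsed case-insensitively and relative paths are resolved
    against the CSV's directory.
    """
    csv_path = Path(csv_path)
    table = pd.read_csv(csv_path, dtype=str)
    missing = [c for c in COHORT_COLUMNS if c not in table.columns]
    if missing:
        raise CohortError(f"{csv_path}: missing columns {missing}")

    base = csv_path.parent
    records: list[CohortRecord] = []
    seen: set[str] = set()
    for row_num, row in enumerate(table.itertuples(index=False), start=2):
        lesion_id = str(row.lesion_id)
        if lesion_id in seen:
            raise CohortError(f"{csv_path}: duplicate lesion_id {lesion_id!r}")
        seen.add(lesion_id)
        try:
            grade = Grade.parse(row.grade)
        except CohortError as exc:
            raise CohortError(f"{csv_path} row {row_num}: {exc}") from None

        def _resolve(p: str) -> Path:
            path = Path(p)
            return path if path.is_absolute() else base / path

        records.append(CohortRecord(
            lesion_id=lesion_id,
            grade=grade,
            adc_path=_resolve(row.adc_path),
            ve_path=_resolve(row.ve_path),
            mask_path=_resolve(row.mask_path),
        ))
    return records


def write_volume(grid: np.ndarray, spacing: tuple[float, float, float],
                 path: str | Path) -> None:
    """Write a 3D grid as NIfTI-1 with a diagonal affine from the spacing.

    Masks should be passed as uint8 0/1; scalar maps as float32 so that
    a write-read cycle is bit-exact for the stored precision.
    """
    affine = np.diag([spacing[0], spacing[1], spacing[2], 1.0])
    img = nib.Nifti1Image(np.asarray(grid), affine)
    img.header.set_zooms(spacing)
    nib.save(img, str(path))
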