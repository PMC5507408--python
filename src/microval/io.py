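"""Reading and writing 3D grey-level volumes and experimental force records.

Physical conventions used throughout the package:

* lengths are micrometres (um), forces Newton (N), moduli GPa;
* array axis 0 is Z (the axial/compression direction), axis 1 is Y and
  axis 2 is X; physical point coordinates are given as ``(x, y, z)`` in um;
* MetaImage/NRRD headers store spacing in millimetres, converted to um at
  the I/O boundary.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import SimpleITK as sitk
import tifffile

from .errors import MetadataError, ParameterError, ParseError, SchemaError, VolumeFormatError

_MM_TO_UM = 1000.0


@dataclass
class GreyVolume:
    """A 3D scalar image with isotropic voxel size.

    Attributes
    ----------
    data : ndarray, shape (nz, ny, nx)
        Grey values, ordered (z, y, x) with z the axial direction.
    voxel_size : float
        Isotropic voxel edge length in um.
    name : str
        Specimen/stage identifier, used in reports.
    """

    data: np.ndarray
    voxel_size: float
    name: str = ""

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3 or min(self.data.shape) < 1:
            raise ParameterError(f"volume must be 3D with all dims >= 1, got shape {self.data.shape}")
        if not self.voxel_size > 0:
            raise ParameterError(f"voxel size must be positive, got {self.voxel_size}")
        if not np.all(np.isfinite(self.data)):
            raise ParameterError("grey values must be finite")

    @property
    def shape(self) -> tuple:
        return self.data.shape

    def physical_size(self) -> np.ndarray:
        """Extent of the volume per axis (z, y, x) in um."""
        return np.asarray(self.data.shape, dtype=float) * self.voxel_size


@dataclass
class ForceRecord:
    """Per-specimen experimental axial force.

    ``af_exp`` is the force increment between the loaded and preloaded
    states (N); ``free_height`` the unembedded specimen height (mm).
    """

    specimen_id: str
    free_height: float
    af_exp: float

    def __post_init__(self):
        if not np.isfinite(self.af_exp):
            raise ParseError(f"axial force for {self.specimen_id!r} is not finite")
        if not self.free_height > 0:
            raise ParameterError(f"free height must be positive, got {self.free_height}")


def _is_tiff(path: Path) -> bool:
    return path.suffix.lower() in {".tif", ".tiff"}


def read_volume(path: str | os.PathLike, voxel_size_override: float | None = None, name: str | None = None) -> GreyVolume:
    """Read a 3D volume from TIFF (file or slice directory), MetaImage or NRRD.

    Parameters
    ----------
    path : path-like
        A ``.mha/.mhd/.nrrd`` file, a multi-page ``.tif(f)`` file, or a
        directory of 2D TIFF slices (sorted by filename, z ascending).
    voxel_size_override : float, optional
        Voxel size in um; required for TIFF inputs (which carry no
        calibrated spacing) and overrides the header elsewhere.

    Raises
    ------
    VolumeFormatError
        Unreadable file or unsupported extension.
    MetadataError
        Voxel size available neither from the header nor the override.
    """
    path = Path(path)
    if not path.exists():
        raise VolumeFormatError(f"no such file or directory: {path}")
    name = name if name is not None else path.stem

    if path.is_dir():
        slices = sorted(p for p in path.iterdir() if _is_tiff(p))
        if not slices:
            raise VolumeFormatError(f"directory {path} contains no TIFF slices")
        try:
            data = np.stack([tifffile.imread(p) for p in slices], axis=0)
        except Exception as exc:  # pragma: no cover - delegated parsing
            raise VolumeFormatError(f"could not read TIFF stack from {path}: {exc}") from exc
        if voxel_size_override is None:
            raise MetadataError(f"TIFF stack {path} carries no voxel size; pass voxel_size_override")
        return GreyVolume(data, float(voxel_size_override), name)

    suffix = path.suffix.lower()
    if suffix in {".tif", ".tiff"}:
        try:
            data = np.asarray(tifffile.imread(path))
        except Exception as exc:
            raise VolumeFormatError(f"could not read TIFF {path}: {exc}") from exc
        if data.ndim == 2:
            data = data[None]
        if voxel_size_override is None:
            raise MetadataError(f"TIFF {path} carries no voxel size; pass voxel_size_override")
        return GreyVolume(data, float(voxel_size_override), name)

    if suffix in {".mha", ".mhd", ".nrrd"}:
        try:
            img = sitk.ReadImage(str(path))
        except Exception as exc:
            raise VolumeFormatError(f"could not read {path}: {exc}") from exc
        data = sitk.GetArrayFromImage(img)  # (z, y, x)
        if data.ndim != 3:
            raise VolumeFormatError(f"{path} is not a 3D volume (ndim={data.ndim})")
        if voxel_size_override is not None:
            vs = float(voxel_size_override)
        else:
            spacing = img.GetSpacing()  # (x, y, z) in mm
            if not np.allclose(spacing, spacing[0], rtol=1e-6):
                raise MetadataError(f"{path} has anisotropic spacing {spacing}; pass voxel_size_override")
            vs = float(spacing[0]) * _MM_TO_UM
        return GreyVolume(data, vs, name)

    raise VolumeFormatError(f"unsupported volume format: {path.suffix!r}")


def write_volume(vol, path: str | os.PathLike) -> None:
    """Write a volume (grey, binary or label) to TIFF, MetaImage or NRRD.

    The voxel size is stored in the MetaImage/NRRD header (as mm); TIFF
    output keeps data only.  Accepts any object with ``data`` and
    ``voxel_size`` attributes.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    data = np.asarray(vol.data)
    suffix = path.suffix.lower()
    if suffix in {".tif", ".tiff"}:
        tifffile.imwrite(path, data)
        return
    if suffix in {".mha", ".mhd", ".nrrd"}:
        img = sitk.GetImageFromArray(data)
        sp = float(vol.voxel_size) / _MM_TO_UM
        img.SetSpacing((sp, sp, sp))
        sitk.WriteImage(img, str(path))
        return
    raise VolumeFormatError(f"unsupported output format: {path.suffix!r}")


_FORCE_COLUMNS = ("specimen_id", "free_height_mm", "af_exp_N")


def read_force_records(path: str | os.PathLike) -> list[ForceRecord]:
    """Read per-specimen experimental axial forces from CSV.

    The file must have a header with columns ``specimen_id``,
    ``free_height_mm`` and ``af_exp_N``; extra columns are ignored.
    """
    try:
        df = pd.read_csv(path)
    except Exception as exc:
        raise ParseError(f"could not parse CSV {path}: {exc}") from exc
    missing = [c for c in _FORCE_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}")
    records = []
    for _, row in df.iterrows():
        try:
            height = float(row["free_height_mm"])
            force = float(row["af_exp_N"])
        except (TypeError, ValueError) as exc:
            raise ParseError(f"{path}: non-numeric value in row {row.to_dict()}") from exc
        if not (np.isfinite(height) and np.isfinite(force)):
            raise ParseError(f"{path}: non-finite value in row {row.to_dict()}")
        records.append(ForceRecord(str(row["specimen_id"]), height, force))
    return records


def write_force_records(records: list[ForceRecord], path: str | os.PathLike) -> None:
    """Write force records to CSV in the layout :func:`read_force_records` expects."""
    df = pd.DataFrame(
        {
            "specimen_id": [r.specimen_id for r in records],
            "free_height_mm": [r.free_height for r in records],
            "af_exp_N": [r.af_exp for r in records],
        }
    )
    df.to_csv(path, index=False)
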