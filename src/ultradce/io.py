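"""NIfTI and table I/O for dynamic series, ROI masks and parameter maps.

All volumes live on a single spatial grid: masks and maps must match the
shape of the dynamic series exactly (co-registration is an upstream,
external step). Frame times are ``t_k = k * dt`` with ``t_0 = 0`` at the
first acquired frame. Kinetic math elsewhere in the package uses minutes
internally; the empirical-model outputs are expressed in dynamics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

from .errors import (
    ConfigurationError,
    DimensionError,
    EmptyRoiError,
    GridMismatchError,
)

__all__ = [
    "DynamicSeries",
    "RoiMask",
    "ParameterMap",
    "read_series",
    "write_series",
    "read_mask",
    "write_mask",
    "read_parameter_map",
    "write_parameter_map",
]


@dataclass
class DynamicSeries:
    """A 4D dynamic contrast-enhanced signal series on a uniform time grid.

    Attributes
    ----------
    data
        Signal intensities with axes (x, y, z, t), nonnegative.
    dt_seconds
        Spacing between consecutive frames, seconds.
    affine
        4x4 voxel-to-world affine carried through to outputs.
    """

    data: np.ndarray
    dt_seconds: float
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4:
            raise DimensionError(
                f"dynamic series must be 4D, got {self.data.ndim}D"
            )
        if self.n_dynamics < 3:
            raise DimensionError("dynamic series needs at least 3 frames")
        if not self.dt_seconds > 0:
            raise ConfigurationError("dt_seconds must be positive")

    @property
    def spatial_shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    @property
    def n_dynamics(self) -> int:
        return self.data.shape[3]

    @property
    def times_seconds(self) -> np.ndarray:
        """Frame times, seconds, origin at the first acquired frame."""
        return np.arange(self.n_dynamics) * self.dt_seconds

    @property
    def times_minutes(self) -> np.ndarray:
        return self.times_seconds / 60.0


@dataclass
class RoiMask:
    """A binary 3D region of interest on the series grid."""

    data: np.ndarray
    label: str = "lesion"  # artery | lesion | normal
    zone: str = "none"  # PZ | TZ | none

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data) != 0
        if self.data.ndim != 3:
            raise DimensionError(f"mask must be 3D, got {self.data.ndim}D")
        if not self.data.any():
            raise EmptyRoiError(f"mask '{self.label}' has no voxels")

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())


@dataclass
class ParameterMap:
    """One named parameter volume with its validity mask.

    ``valid`` marks voxels whose value is finite, produced by a converged
    fit and inside that parameter's physiologically credible range. On
    disk, invalid voxels are encoded as NaN in the value volume and a
    companion ``*_valid`` volume is always written alongside.
    """

    name: str
    values: np.ndarray
    valid: np.ndarray
    unit: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.valid = np.asarray(self.valid) != 0
        if self.values.shape != self.valid.shape:
            raise GridMismatchError("value and validity shapes differ")
        if self.values.ndim != 3:
            raise DimensionError("parameter map must be 3D")

    @property
    def n_valid(self) -> int:
        return int(self.valid.sum())

    def masked(self) -> np.ndarray:
        """Values with invalid voxels replaced by NaN."""
        out = self.values.copy()
        out[~self.valid] = np.nan
        return out


def _valid_path(path: str | Path) -> Path:
    path = Path(path)
    stem = path.name
    for ext in (".nii.gz", ".nii"):
        if stem.endswith(ext):
            return path.with_name(stem[: -len(ext)] + "_valid" + ext)
    return path.with_name(stem + "_valid")


def read_series(
    path: str | Path, dt_override: float | None = None
) -> DynamicSeries:
    """Load a 4D NIfTI dynamic series.

    The frame spacing is taken from the header's fourth pixdim (zoom);
    ``dt_override`` replaces it when given and is required when the
    header carries no timing.
    """
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 4:
        raise DimensionError(f"{path}: expected 4D volume, got {data.ndim}D")
    dt = dt_override
    if dt is None:
        zooms = img.header.get_zooms()
        if len(zooms) >= 4 and zooms[3] > 0:
            dt = float(zooms[3])
    if dt is None or not dt > 0:
        raise ConfigurationError(
            f"{path}: no frame timing in header and no dt_override given"
        )
    return DynamicSeries(data=data, dt_seconds=float(dt), affine=img.affine)


def write_series(series: DynamicSeries, path: str | Path) -> None:
    img = nib.Nifti1Image(series.data, series.affine)
    img.header.set_zooms((*img.header.get_zooms()[:3], series.dt_seconds))
    img.header.set_xyzt_units("mm", "sec")
    nib.save(img, str(path))


def read_mask(
    path: str | Path,
    series: DynamicSeries,
    label: str = "lesion",
    zone: str = "none",
) -> RoiMask:
    """Load a 3D binary mask and check it against the series grid.

    Any nonzero voxel value counts as inside the ROI.
    """
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise DimensionError(f"{path}: expected 3D mask, got {data.ndim}D")
    if data.shape != series.spatial_shape:
        raise GridMismatchError(
            f"{path}: mask shape {data.shape} does not match series "
            f"grid {series.spatial_shape}"
        )
    return RoiMask(data=data, label=label, zone=zone)


def write_mask(mask: RoiMask, path: str | Path, affine=None) -> None:
    affine = np.eye(4) if affine is None else affine
    nib.save(nib.Nifti1Image(mask.data.astype(np.uint8), affine), str(path))


def write_parameter_map(
    pmap: ParameterMap, path: str | Path, affine=None
) -> None:
    """Write value and companion validity volumes.

    Invalid voxels are NaN in the value volume; the validity volume is
    written next to it with a ``_valid`` suffix.
    """
    affine = np.eye(4) if affine is None else affine
    nib.save(nib.Nifti1Image(pmap.masked(), affine), str(path))
    nib.save(
        nib.Nifti1Image(pmap.valid.astype(np.uint8), affine),
        str(_valid_path(path)),
    )


def read_parameter_map(
    path: str | Path, name: str = "", unit: str = ""
) -> ParameterMap:
    img = nib.load(str(path))
    values = np.asanyarray(img.dataobj).astype(float)
    vpath = _valid_path(path)
    if vpath.exists():
        valid = np.asanyarray(nib.load(str(vpath)).dataobj) != 0
    else:
        valid = np.isfinite(values)
    return ParameterMap(name=name, values=values, valid=valid, unit=unit)
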