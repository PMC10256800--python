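"""Shared domain types, volume IO, resampling and table plumbing.

All volumes in the pipeline live on an :class:`ImageVolume`: a 3D scalar grid
(HU for CT, Gy for dose, dimensionless for ventilation) with physical spacing
and origin in mm.  The in-memory axis convention is ``data[x, y, z]`` with x
fastest, 0-based voxel indices, and physical position
``origin + index * spacing``; all inter-volume operations work in physical
space.  NIfTI (.nii/.nii.gz) and MetaImage (.mha/.mhd) are supported through
SimpleITK.

Tables (curves, grades, concordance rows) are comma-separated UTF-8 text with
a header row throughout the package.
"""

from __future__ import annotations

import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import SimpleITK as sitk
import yaml

__all__ = [
    "ImageVolume",
    "ROIMask",
    "DoseGrid",
    "SubjectRecord",
    "CONTOUR_LABELS",
    "GROUP_B_CONTOURS",
    "GROUP_A_CONTOURS",
    "CT_AIR_HU",
    "read_volume",
    "write_volume",
    "resample_like",
    "load_table",
    "save_table",
    "load_config",
    "get_logger",
]

CT_AIR_HU = -1000.0

#: Controlled contour vocabulary (Table-style analysis points plus the
#: per-dose-bin helper labels used by the perfusion stage).
CONTOUR_LABELS = frozenset(
    {
        "MD", "LDF", "LDNF", "NDF", "NDNF", "CON", "HHV", "HLV", "LLV",
        "parenchyma-bin", "vessel-bin",
    }
)

#: The nine radiation/ventilation analysis contours evaluated per group-B
#: subject, and the subset available for group A.
GROUP_B_CONTOURS = ("MD", "LDF", "LDNF", "NDF", "NDNF", "CON", "HHV", "HLV", "LLV")
GROUP_A_CONTOURS = ("MD", "CON")

_LOG_FORMAT = "%(levelname)s [%(name)s] %(message)s"


def get_logger(stage: str) -> logging.Logger:
    """Structured stage logger writing to stderr."""
    logger = logging.getLogger(f"lungfx.{stage}")
    if not logger.handlers:
        handler = logging.StreamHandler(sys.stderr)
        handler.setFormatter(logging.Formatter(_LOG_FORMAT))
        logger.addHandler(handler)
        logger.setLevel(logging.INFO)
        logger.propagate = False
    return logger


class FormatError(ValueError):
    """Unreadable or unsupported volume file."""


class DimensionalityError(ValueError):
    """Volume payload is not 3D."""


class MetadataError(ValueError):
    """Degenerate or inconsistent geometric metadata."""


class EmptyROIError(ValueError):
    """ROI contains no (valid) voxels."""


@dataclass
class ImageVolume:
    """3D scalar grid with physical metadata.

    Parameters
    ----------
    data : ndarray, shape (nx, ny, nz)
        Scalar values, x fastest.
    spacing : tuple of float
        Per-axis voxel size in mm; all > 0.
    origin : tuple of float
        Physical coordinate of voxel (0, 0, 0) in mm.
    frame_label : str
        Free text (breathing-phase id, contrast frame index, ...).
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    frame_label: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise DimensionalityError(
                f"expected a 3D payload, got {self.data.ndim}D"
            )
        if any(n < 2 for n in self.data.shape):
            raise MetadataError("grid must have >= 2 voxels per axis")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise MetadataError(f"spacings must be three positive values, got {self.spacing}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("volume contains non-finite values")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def congruent_with(self, other: "ImageVolume") -> bool:
        """Same grid: shape, spacing and origin (to 1e-6 mm)."""
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=1e-6)
            and np.allclose(self.origin, other.origin, atol=1e-6)
        )

    def physical_axes(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Per-axis physical coordinates of voxel centres in mm."""
        return tuple(
            self.origin[i] + self.spacing[i] * np.arange(self.shape[i])
            for i in range(3)
        )

    def like(self, data: np.ndarray, frame_label: str | None = None) -> "ImageVolume":
        """New volume with the same geometry and different data."""
        return ImageVolume(
            data=data,
            spacing=self.spacing,
            origin=self.origin,
            frame_label=self.frame_label if frame_label is None else frame_label,
        )

    # --- SimpleITK bridge -------------------------------------------------
    def to_sitk(self) -> sitk.Image:
        # SimpleITK arrays are indexed (z, y, x); our convention is (x, y, z).
        img = sitk.GetImageFromArray(np.ascontiguousarray(self.data.T))
        img.SetSpacing(self.spacing)
        img.SetOrigin(self.origin)
        return img

    @classmethod
    def from_sitk(cls, img: sitk.Image, frame_label: str = "") -> "ImageVolume":
        if img.GetDimension() != 3:
            raise DimensionalityError(
                f"expected a 3D payload, got {img.GetDimension()}D"
            )
        arr = sitk.GetArrayFromImage(img).T.astype(float)
        return cls(
            data=arr,
            spacing=tuple(img.GetSpacing()),
            origin=tuple(img.GetOrigin()),
            frame_label=frame_label,
        )


@dataclass
class ROIMask:
    """Boolean region of interest congruent with a reference volume."""

    mask: np.ndarray
    label: str
    tissue: str = "parenchyma"  # {"vessel", "parenchyma"}

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 3:
            raise DimensionalityError("ROI mask must be 3D")
        if self.label not in CONTOUR_LABELS:
            raise ValueError(
                f"label {self.label!r} not in vocabulary {sorted(CONTOUR_LABELS)}"
            )
        if self.tissue not in ("vessel", "parenchyma"):
            raise ValueError(f"tissue must be vessel|parenchyma, got {self.tissue!r}")
        if not self.mask.any():
            raise EmptyROIError(f"ROI {self.label!r} has no voxels")

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())

    def check_congruent(self, volume: ImageVolume) -> None:
        if self.mask.shape != volume.shape:
            raise MetadataError(
                f"ROI {self.label!r} shape {self.mask.shape} != volume {volume.shape}"
            )


@dataclass
class DoseGrid:
    """Planned dose distribution in Gy on an ImageVolume grid."""

    volume: ImageVolume
    prescription: float = 60.0

    def __post_init__(self) -> None:
        d = self.volume.data
        if np.any(d < 0):
            raise ValueError("dose values must be >= 0 Gy")
        cap = 1.25 * self.prescription
        if np.any(d > cap):
            raise ValueError(f"dose exceeds hot-spot cap {cap} Gy")

    @property
    def data(self) -> np.ndarray:
        return self.volume.data


@dataclass
class SubjectRecord:
    """One animal: id, study group and the contour set available for it."""

    subject_id: str
    group: str  # {"A", "B"}
    contours: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.group not in ("A", "B"):
            raise ValueError(f"group must be A or B, got {self.group!r}")
        if not self.contours:
            self.contours = GROUP_A_CONTOURS if self.group == "A" else GROUP_B_CONTOURS
        unknown = set(self.contours) - CONTOUR_LABELS
        if unknown:
            raise ValueError(f"unknown contour labels {sorted(unknown)}")
        if self.group == "A" and not set(self.contours) <= set(GROUP_B_CONTOURS):
            raise ValueError("group-A contour set must be a subset of the group-B set")
        if self.group == "B" and set(self.contours) != set(GROUP_B_CONTOURS):
            raise ValueError("group-B subjects carry all nine analysis contours")


# --------------------------------------------------------------------------
# Volume IO
# --------------------------------------------------------------------------

_SUPPORTED_SUFFIXES = (".nii", ".nii.gz", ".mha", ".mhd")


def _check_suffix(path: Path) -> None:
    name = path.name.lower()
    if not any(name.endswith(s) for s in _SUPPORTED_SUFFIXES):
        raise FormatError(
            f"unsupported volume format {path.name!r}; expected one of {_SUPPORTED_SUFFIXES}"
        )


def read_volume(path: str | Path) -> ImageVolume:
    """Read a NIfTI or MetaImage volume.

    Spacing and origin come from the file header; the returned array follows
    the package convention ``data[x, y, z]``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    _check_suffix(path)
    try:
        img = sitk.ReadImage(str(path))
    except RuntimeError as exc:  # unreadable header
        raise FormatError(f"could not read {path}: {exc}") from exc
    return ImageVolume.from_sitk(img, frame_label=path.stem)


def write_volume(volume: ImageVolume, path: str | Path) -> Path:
    """Write a volume as NIfTI or MetaImage (chosen by suffix)."""
    path = Path(path)
    _check_suffix(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    sitk.WriteImage(volume.to_sitk(), str(path))
    return path


_INTERPOLATORS = {"nearest": sitk.sitkNearestNeighbor, "linear": sitk.sitkLinear}


def resample_like(
    moving: ImageVolume,
    reference: ImageVolume,
    interpolation: str = "linear",
    fill_value: float | None = None,
) -> ImageVolume:
    """Resample ``moving`` onto the grid of ``reference`` in physical space.

    Out-of-domain voxels are filled with ``fill_value`` (default -1000 HU, the
    neutral air value for CT in a lung context; pass 0 for non-CT maps).
    """
    if interpolation not in _INTERPOLATORS:
        raise ValueError(f"interpolation must be one of {sorted(_INTERPOLATORS)}")
    if fill_value is None:
        fill_value = CT_AIR_HU
    out = sitk.Resample(
        moving.to_sitk(),
        reference.to_sitk(),
        sitk.Transform(),
        _INTERPOLATORS[interpolation],
        float(fill_value),
        sitk.sitkFloat64,
    )
    return ImageVolume.from_sitk(out, frame_label=moving.frame_label)


# --------------------------------------------------------------------------
# Tables and configuration
# --------------------------------------------------------------------------

def load_table(path: str | Path) -> pd.DataFrame:
    """Read a comma-separated UTF-8 table with a header row."""
    return pd.read_csv(path, encoding="utf-8")


def save_table(df: pd.DataFrame, path: str | Path, float_format: str = "%.6g") -> Path:
    """Write a table deterministically (fixed float formatting, no index)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, encoding="utf-8", float_format=float_format)
    return path


def load_config(path: str | Path) -> dict:
    """Load a YAML run configuration (paths, thresholds, seeds)."""
    with open(path, "r", encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh)
    return cfg or {}
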