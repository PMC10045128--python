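"""NIfTI input/output and dataset-level z-score normalization.

Volumes are held as ``MRVolume`` (slices x rows x cols, single channel) with
physical voxel spacing in mm; masks as ``BinaryMask`` aligned to a volume.
Intensity standardization follows the standard-score convention: a pooled mean
and population standard deviation are computed once over every voxel of every
training volume and frozen, then each volume is transformed as
``(I - mu) / sigma``.  Stats are kept per modality because DWI and T2WI
networks are trained separately.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import nibabel as nib
import numpy as np
import pandas as pd

MODALITIES = ("DWI", "T2WI", "synthetic")

#: Largest plausible slice count; used to identify the slice axis of a NIfTI
#: array when the in-plane axes are square.
_MAX_SLICES = 31


class ShapeError(ValueError):
    """Raised when an array violates the geometric contract of a type."""


@dataclass(frozen=True)
class MRVolume:
    """A single-channel MR image volume with physical spacing.

    Parameters
    ----------
    voxels : ndarray, shape (slices, rows, cols)
        Real-valued intensities, arbitrary units.
    spacing_mm : tuple of float
        (slice thickness, row spacing, col spacing) in mm, all positive.
    modality : str
        One of ``"DWI"``, ``"T2WI"``, ``"synthetic"``.
    subject_id : str
    """

    voxels: np.ndarray
    spacing_mm: tuple[float, float, float]
    modality: str = "synthetic"
    subject_id: str = ""

    def __post_init__(self) -> None:
        v = np.asarray(self.voxels)
        if v.ndim != 3:
            raise ShapeError(f"expected a rank-3 volume, got shape {v.shape}")
        if v.shape[1] != v.shape[2]:
            raise ShapeError(f"in-plane dims must be square, got {v.shape[1]}x{v.shape[2]}")
        if v.shape[1] % 32 != 0:
            raise ShapeError(f"in-plane size {v.shape[1]} not divisible by 32")
        if not np.all(np.isfinite(v)):
            raise ValueError("volume contains non-finite voxels")
        if len(self.spacing_mm) != 3 or any(s <= 0 for s in self.spacing_mm):
            raise ValueError(f"spacing must be three positive values, got {self.spacing_mm}")
        if self.modality not in MODALITIES:
            raise ValueError(f"unknown modality {self.modality!r}")
        object.__setattr__(self, "voxels", v)
        object.__setattr__(self, "spacing_mm", tuple(float(s) for s in self.spacing_mm))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def n(self) -> int:
        """In-plane size N (rows == cols)."""
        return self.voxels.shape[1]


@dataclass(frozen=True)
class BinaryMask:
    """A {0,1} mask geometrically aligned to an :class:`MRVolume`."""

    voxels: np.ndarray
    spacing_mm: tuple[float, float, float]
    subject_id: str = ""

    def __post_init__(self) -> None:
        v = np.asarray(self.voxels)
        if v.ndim != 3:
            raise ShapeError(f"expected a rank-3 mask, got shape {v.shape}")
        if not np.isin(v, (0, 1)).all():
            raise ValueError("mask values must be 0 or 1")
        if len(self.spacing_mm) != 3 or any(s <= 0 for s in self.spacing_mm):
            raise ValueError(f"spacing must be three positive values, got {self.spacing_mm}")
        object.__setattr__(self, "voxels", v.astype(np.uint8))
        object.__setattr__(self, "spacing_mm", tuple(float(s) for s in self.spacing_mm))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape


@dataclass(frozen=True)
class DatasetStats:
    """Pooled intensity statistics of a dataset (population convention)."""

    mean: float
    std: float
    n_volumes: int
    n_voxels: int

    def __post_init__(self) -> None:
        if self.std <= 0:
            raise ValueError(f"std must be positive, got {self.std}")


def _slice_axis(shape: tuple[int, ...]) -> int:
    """Identify the slice axis: the axis of length <= 31 whose removal leaves a
    square in-plane pair; falls back to axis 0."""
    for ax in range(3):
        inplane = [shape[i] for i in range(3) if i != ax]
        if shape[ax] <= _MAX_SLICES and inplane[0] == inplane[1]:
            return ax
    return 0


def read_mr_volume(path: str | os.PathLike, modality: str = "synthetic",
                   subject_id: str | None = None) -> MRVolume:
    """Read a 3-D single-channel NIfTI-1 file into an :class:`MRVolume`.

    Spacing is taken from the header zooms; the slice axis is moved to axis 0.
    Raises ``IOError`` for unreadable files and :class:`ShapeError` for 4-D
    images or non-square in-plane dimensions.
    """
    path = Path(path)
    try:
        img = nib.load(path)
    except Exception as exc:  # nibabel raises several types for bad files
        raise IOError(f"cannot read NIfTI file {path}: {exc}") from exc
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise ShapeError(f"{path}: expected a 3-D image, got shape {data.shape}")
    # zooms are float32 in the header; round away representation noise
    zooms = [round(float(z), 6) for z in img.header.get_zooms()[:3]]
    ax = _slice_axis(data.shape)
    order = [ax] + [i for i in range(3) if i != ax]
    data = np.moveaxis(data, ax, 0)
    spacing = tuple(float(zooms[i]) for i in order)
    return MRVolume(
        voxels=np.ascontiguousarray(data, dtype=np.float32),
        spacing_mm=spacing,
        modality=modality,
        subject_id=subject_id if subject_id is not None else path.name.split(".")[0],
    )


def read_mask(path: str | os.PathLike, subject_id: str | None = None) -> BinaryMask:
    """Read a NIfTI mask; values must be {0,1}."""
    vol = read_mr_volume(path, modality="synthetic", subject_id=subject_id)
    return BinaryMask(voxels=vol.voxels.astype(np.uint8), spacing_mm=vol.spacing_mm,
                      subject_id=vol.subject_id)


def _affine_from_spacing(spacing_mm: Sequence[float]) -> np.ndarray:
    # axis order in the file is (slice, row, col); diagonal affine is enough
    # since no anatomical orientation is modeled here.
    return np.diag([spacing_mm[0], spacing_mm[1], spacing_mm[2], 1.0])


def write_mr_volume(volume: MRVolume, path: str | os.PathLike) -> None:
    """Write a volume as float32 NIfTI-1, preserving spacing."""
    img = nib.Nifti1Image(volume.voxels.astype(np.float32),
                          _affine_from_spacing(volume.spacing_mm))
    img.header.set_zooms(volume.spacing_mm)
    try:
        nib.save(img, str(path))
    except Exception as exc:
        raise IOError(f"cannot write NIfTI file {path}: {exc}") from exc


def write_mask(mask: BinaryMask, path: str | os.PathLike) -> None:
    """Write a mask as uint8 NIfTI-1; round-trips voxel values exactly."""
    if not isinstance(mask, BinaryMask):
        mask = BinaryMask(np.asarray(mask.voxels), mask.spacing_mm)  # re-validate
    img = nib.Nifti1Image(mask.voxels.astype(np.uint8), _affine_from_spacing(mask.spacing_mm))
    img.header.set_zooms(mask.spacing_mm)
    try:
        nib.save(img, str(path))
    except Exception as exc:
        raise IOError(f"cannot write NIfTI file {path}: {exc}") from exc


def compute_dataset_stats(volumes: Iterable[MRVolume]) -> DatasetStats:
    """Pooled population mean/std over every voxel of every volume.

    The divide-by-n (population) convention is used; at dataset voxel counts
    the difference from n-1 is negligible but the convention is fixed here.
    """
    total = 0.0
    total_sq = 0.0
    n_vox = 0
    n_vol = 0
    for vol in volumes:
        v = vol.voxels.astype(np.float64)
        total += float(v.sum())
        total_sq += float(np.square(v).sum())
        n_vox += v.size
        n_vol += 1
    if n_vol == 0:
        raise ValueError("cannot compute stats of an empty volume collection")
    mean = total / n_vox
    var = total_sq / n_vox - mean * mean
    std = float(np.sqrt(max(var, 0.0)))
    if std == 0.0:
        raise ValueError("degenerate dataset: pooled standard deviation is zero")
    return DatasetStats(mean=float(mean), std=std, n_volumes=n_vol, n_voxels=n_vox)


def zscore_normalize(volume: MRVolume, stats: DatasetStats) -> MRVolume:
    """Standard-score transform ``(I - mu) / sigma`` with frozen dataset stats."""
    if stats.std <= 0:
        raise ValueError("stats.std must be positive")
    voxels = (volume.voxels.astype(np.float64) - stats.mean) / stats.std
    return replace(volume, voxels=voxels)


# ---------------------------------------------------------------------------
# dataset manifest

MANIFEST_COLUMNS = ["subject_id", "image_path", "mask_path", "modality"]


def write_manifest(rows: Sequence[dict], path: str | os.PathLike) -> None:
    """Write a (subject_id, image_path, mask_path, modality) CSV manifest."""
    df = pd.DataFrame(list(rows), columns=MANIFEST_COLUMNS)
    df.to_csv(path, index=False)


def read_manifest(path: str | os.PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, dtype=str)
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"manifest {path} missing columns: {missing}")
    return df
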