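"""Volume containers, NIfTI I/O and per-volume intensity normalisation.

Conventions used throughout the package:

* voxel indices are 0-based, axis order ``(x, y, z)`` = (sagittal, coronal,
  axial);
* volume data is ``float32``, loss accumulation elsewhere uses ``float64``;
* label maps are integer typed with 0 = background.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = [
    "Volume",
    "LabelMap",
    "PriorAtlas",
    "read_volume",
    "read_label_map",
    "read_prior_atlas",
    "write_volume",
    "write_label_map",
    "write_prior_atlas",
    "normalize_intensity",
]

_ATLAS_SUM_TOL = 1e-3


def _spacing_from_affine(affine: np.ndarray) -> tuple[float, float, float]:
    return tuple(float(np.linalg.norm(affine[:3, i])) for i in range(3))


def _default_affine(spacing) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = spacing
    return aff


@dataclass
class Volume:
    """A 3D scalar field with voxel spacing (mm) and a voxel-to-world affine."""

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    affine: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float32)
        if self.data.ndim != 3:
            raise ValueError(f"volume data must be 3D, got shape {self.data.shape}")
        if min(self.data.shape) < 1:
            raise ValueError("every volume axis must have length >= 1")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 positive lengths, got {self.spacing}")
        if self.affine is None:
            self.affine = _default_affine(self.spacing)
        self.affine = np.asarray(self.affine, dtype=np.float64)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))


@dataclass
class LabelMap:
    """3D integer class map (0 = background) with ``class_count`` classes."""

    data: np.ndarray
    class_count: int
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    affine: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if not np.issubdtype(self.data.dtype, np.integer):
            rounded = np.rint(self.data)
            if not np.allclose(rounded, self.data):
                raise ValueError("label data must be integer valued")
            self.data = rounded
        self.data = self.data.astype(np.int32)
        if self.data.ndim != 3:
            raise ValueError(f"label data must be 3D, got shape {self.data.shape}")
        self.class_count = int(self.class_count)
        if self.class_count < 1:
            raise ValueError("class_count must be positive")
        if self.data.size and (self.data.min() < 0 or self.data.max() >= self.class_count):
            raise ValueError(
                f"labels must lie in [0, {self.class_count - 1}], "
                f"got range [{self.data.min()}, {self.data.max()}]"
            )
        self.spacing = tuple(float(s) for s in self.spacing)
        if self.affine is None:
            self.affine = _default_affine(self.spacing)
        self.affine = np.asarray(self.affine, dtype=np.float64)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


@dataclass
class PriorAtlas:
    """Per-voxel class-probability channels from a registered probabilistic atlas.

    ``data`` has shape ``(nx, ny, nz, K)``; channel 0 is background for the
    structure task and white matter for the tissue (lesion) task.  Channel sums
    may fall short of 1 because atlas registration is not exactly normalised.
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    affine: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float32)
        if self.data.ndim != 4:
            raise ValueError(f"atlas data must be 4D, got shape {self.data.shape}")
        if self.data.size:
            lo, hi = float(self.data.min()), float(self.data.max())
            if lo < -_ATLAS_SUM_TOL or hi > 1 + _ATLAS_SUM_TOL:
                raise ValueError(f"atlas probabilities must lie in [0, 1], got [{lo}, {hi}]")
            sums = self.data.sum(axis=-1)
            if sums.max() > 1 + _ATLAS_SUM_TOL:
                raise ValueError("per-voxel atlas probabilities must sum to at most 1")
        self.spacing = tuple(float(s) for s in self.spacing)
        if self.affine is None:
            self.affine = _default_affine(self.spacing)
        self.affine = np.asarray(self.affine, dtype=np.float64)

    @property
    def n_classes(self) -> int:
        return self.data.shape[-1]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]


def _load_nifti(path) -> nib.Nifti1Image:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such NIfTI file: {path}")
    return nib.load(str(path))


def read_volume(path) -> Volume:
    """Read a 3D NIfTI-1 volume; spacing and affine come from the header."""
    img = _load_nifti(path)
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"expected a 3D image, got {data.ndim}D from {path}")
    return Volume(
        data=data.astype(np.float32),
        spacing=tuple(float(z) for z in img.header.get_zooms()[:3]),
        affine=np.asarray(img.affine),
    )


def read_label_map(path, class_count: int) -> LabelMap:
    img = _load_nifti(path)
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"expected a 3D label image, got {data.ndim}D from {path}")
    return LabelMap(
        data=np.rint(data).astype(np.int32),
        class_count=class_count,
        spacing=tuple(float(z) for z in img.header.get_zooms()[:3]),
        affine=np.asarray(img.affine),
    )


def read_prior_atlas(path) -> PriorAtlas:
    img = _load_nifti(path)
    data = np.asanyarray(img.dataobj)
    if data.ndim != 4:
        raise ValueError(f"expected a 4D atlas image, got {data.ndim}D from {path}")
    return PriorAtlas(
        data=data.astype(np.float32),
        spacing=tuple(float(z) for z in img.header.get_zooms()[:3]),
        affine=np.asarray(img.affine),
    )


def _write_nifti(data: np.ndarray, affine: np.ndarray, spacing, path) -> None:
    path = Path(path)
    if path.is_dir():
        raise IsADirectoryError(f"cannot write NIfTI to a directory: {path}")
    if not path.parent.exists():
        raise FileNotFoundError(f"parent directory does not exist: {path.parent}")
    img = nib.Nifti1Image(data, affine)
    img.header.set_zooms(tuple(spacing) + (1.0,) * (data.ndim - 3))
    nib.save(img, str(path))


def write_volume(volume: Volume, path) -> None:
    """Write a volume as float32 NIfTI-1; inverse of :func:`read_volume`."""
    _write_nifti(volume.data.astype(np.float32), volume.affine, volume.spacing, path)


def write_label_map(labels: LabelMap, path) -> None:
    _write_nifti(labels.data.astype(np.int16), labels.affine, labels.spacing, path)


def write_prior_atlas(atlas: PriorAtlas, path) -> None:
    _write_nifti(atlas.data.astype(np.float32), atlas.affine, atlas.spacing, path)


def normalize_intensity(volume: Volume, mask: np.ndarray | None = None) -> Volume:
    """Shift/scale a volume to zero mean and unit variance.

    Statistics are computed over ``mask`` when given, otherwise over the
    non-zero (brain) voxels, falling back to the full volume when everything
    is non-zero or everything is zero-valued.  The transform itself is applied
    to every voxel (a single affine map per volume).

    Raises
    ------
    ValueError
        If the statistics region has fewer than 2 voxels or zero variance.
    """
    data = volume.data.astype(np.float64)
    if mask is None:
        region = data[data != 0]
        if region.size < 2:
            region = data.ravel()
    else:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != data.shape:
            raise ValueError("mask shape must match volume shape")
        region = data[mask]
    if region.size < 2:
        raise ValueError("need at least 2 voxels to compute normalisation statistics")
    mu = region.mean()
    sigma = region.std()
    if sigma < 1e-12:
        raise ValueError("zero intensity variance: cannot normalise a constant volume")
    out = (data - mu) / sigma
    return Volume(data=out.astype(np.float32), spacing=volume.spacing, affine=volume.affine)
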