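"""Volumes, label masks, slice stacks and their I/O.

A :class:`Volume` is a 3D scalar grid with per-axis voxel spacing in mm and a
mapping of grid axes to the anatomical slicing directions (axial, coronal,
sagittal).  Everything downstream — resampling, intensity normalization,
orthogonal-plane slicing and reassembly — operates on these objects.

Supported on-disk formats are NIfTI-1 (``.nii``/``.nii.gz``, via nibabel) and
NRRD (``.nrrd``, via SimpleITK).  Spacing always comes from the file header;
the anatomical axis mapping is taken from orientation metadata when the format
carries it (NIfTI affines) and from an explicit default otherwise — it is
never guessed from the data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import nibabel as nib
import numpy as np
import SimpleITK as sitk
from scipy import ndimage

from .errors import (
    AssemblyError,
    ConfigurationError,
    DegenerateDataError,
    FormatError,
)

ANATOMICAL_AXES = ("axial", "coronal", "sagittal")

#: grid-axis naming of a RAS-oriented array: axis 0 runs left-right (sliced
#: sagittally), axis 1 posterior-anterior (coronal), axis 2 inferior-superior
#: (axial).
DEFAULT_AXES = ("sagittal", "coronal", "axial")


def _check_axes(axes: Sequence[str]) -> tuple[str, str, str]:
    t = tuple(axes)
    if sorted(t) != sorted(ANATOMICAL_AXES):
        raise ConfigurationError(
            f"axis labels must be a permutation of {ANATOMICAL_AXES}, got {t!r}"
        )
    return t  # type: ignore[return-value]


@dataclass
class Volume:
    """3D scalar grid with voxel spacing (mm) and anatomical axis labels."""

    data: np.ndarray
    spacing: tuple[float, float, float]
    axes: tuple[str, str, str] = DEFAULT_AXES

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise FormatError(f"volume data must be 3D, got ndim={self.data.ndim}")
        if min(self.data.shape) < 1:
            raise FormatError(f"all grid dimensions must be >= 1, got {self.data.shape}")
        self.spacing = tuple(float(s) for s in self.spacing)  # type: ignore[assignment]
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise FormatError(f"spacing must be three positive reals, got {self.spacing}")
        self.axes = _check_axes(self.axes)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    def grid_axis(self, anatomical: str) -> int:
        """Grid axis index sliced along when cutting ``anatomical`` planes."""
        try:
            return self.axes.index(anatomical)
        except ValueError:
            raise ConfigurationError(
                f"unknown anatomical axis {anatomical!r}; volume axes are {self.axes}"
            ) from None


@dataclass
class LabelVolume(Volume):
    """Binary mask geometrically aligned to a :class:`Volume`."""

    def __post_init__(self) -> None:
        super().__post_init__()
        vals = np.unique(self.data)
        if not np.isin(vals, (0, 1)).all():
            raise FormatError(
                f"label volume must contain only {{0,1}}, found values {vals[:5]}"
            )
        self.data = self.data.astype(np.uint8, copy=False)


@dataclass
class SliceStack:
    """Ordered stack of 2D C-channel images cut along one anatomical axis.

    ``slices`` has shape (n_slices, H, W, C), ordered by ascending grid index.
    """

    slices: np.ndarray
    axis: str

    def __post_init__(self) -> None:
        self.slices = np.asarray(self.slices)
        if self.slices.ndim != 4:
            raise FormatError(
                f"slice stack must be (n, H, W, C), got shape {self.slices.shape}"
            )
        if self.axis not in ANATOMICAL_AXES:
            raise ConfigurationError(f"unknown anatomical axis {self.axis!r}")

    def __len__(self) -> int:
        return self.slices.shape[0]

    @property
    def channels(self) -> int:
        return self.slices.shape[3]


@dataclass(frozen=True)
class IntensityNormalizer:
    """Affine standardizer fitted on training intensities only."""

    mean: float
    std: float

    def __post_init__(self) -> None:
        if not self.std > 0:
            raise DegenerateDataError(f"normalizer std must be > 0, got {self.std}")


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

_AXCODE_TO_AXIS = {
    "R": "sagittal", "L": "sagittal",
    "A": "coronal", "P": "coronal",
    "S": "axial", "I": "axial",
}
_AXIS_TO_WORLD_DIM = {"sagittal": 0, "coronal": 1, "axial": 2}


def _axes_from_affine(affine: np.ndarray) -> tuple[str, str, str] | None:
    try:
        codes = nib.aff2axcodes(affine)
    except Exception:
        return None
    axes = tuple(_AXCODE_TO_AXIS.get(c, "") for c in codes)
    if sorted(axes) != sorted(ANATOMICAL_AXES):
        return None
    return axes  # type: ignore[return-value]


def read_volume(path: str | Path, default_axes: Sequence[str] = DEFAULT_AXES) -> Volume:
    """Read a NIfTI or NRRD file into a :class:`Volume`.

    Spacing is taken from the header; grid data are returned unmodified.
    Anatomical axis labels come from NIfTI orientation metadata when present,
    otherwise from ``default_axes``.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"cannot read volume: {path} does not exist")
    suffixes = "".join(path.suffixes)
    if suffixes.endswith((".nii", ".nii.gz")):
        img = nib.load(str(path))
        data = np.asarray(img.dataobj)
        if data.ndim != 3:
            raise FormatError(f"{path}: expected a 3D volume, got ndim={data.ndim}")
        spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
        axes = _axes_from_affine(img.affine) or _check_axes(default_axes)
    elif path.suffix == ".nrrd":
        try:
            img = sitk.ReadImage(str(path))
        except Exception as exc:  # SimpleITK raises RuntimeError on bad files
            raise IOError(f"cannot read volume {path}: {exc}") from exc
        if img.GetDimension() != 3:
            raise FormatError(f"{path}: expected a 3D volume, got {img.GetDimension()}D")
        # GetArrayFromImage returns (z, y, x); transpose back to (x, y, z)
        data = sitk.GetArrayFromImage(img).transpose(2, 1, 0)
        spacing = tuple(float(s) for s in img.GetSpacing())
        axes = _check_axes(default_axes)
    else:
        raise FormatError(f"unsupported volume format: {path.name}")
    if any((not math.isfinite(s)) or s <= 0 for s in spacing):
        raise FormatError(f"{path}: header spacing {spacing} is missing or non-positive")
    return Volume(data=data, spacing=spacing, axes=axes)


def read_label(path: str | Path, default_axes: Sequence[str] = DEFAULT_AXES) -> LabelVolume:
    v = read_volume(path, default_axes)
    return LabelVolume(data=np.rint(v.data).astype(np.uint8), spacing=v.spacing, axes=v.axes)


def _ras_affine(v: Volume) -> np.ndarray:
    """Diagonal-permutation affine encoding spacing and axis labels."""
    affine = np.zeros((4, 4))
    affine[3, 3] = 1.0
    for i, name in enumerate(v.axes):
        affine[_AXIS_TO_WORLD_DIM[name], i] = v.spacing[i]
    return affine


def write_volume(v: Volume, path: str | Path) -> None:
    """Write a Volume to NIfTI or NRRD; spacing goes into the header."""
    path = Path(path)
    suffixes = "".join(path.suffixes)
    if suffixes.endswith((".nii", ".nii.gz")):
        img = nib.Nifti1Image(np.asarray(v.data), _ras_affine(v))
        img.header.set_zooms(v.spacing)
        nib.save(img, str(path))
    elif path.suffix == ".nrrd":
        img = sitk.GetImageFromArray(np.ascontiguousarray(np.asarray(v.data).transpose(2, 1, 0)))
        img.SetSpacing(v.spacing)
        sitk.WriteImage(img, str(path))
    else:
        raise FormatError(f"unsupported volume format: {path.name}")


# ---------------------------------------------------------------------------
# resampling
# ---------------------------------------------------------------------------

def resample_to_cube(v: Volume, size: int = 256, order: int = 3) -> Volume:
    """Resample to a ``size``³ grid with spline interpolation of given order.

    Physical extent is preserved: the output spacing along axis *i* is
    ``spacing_i * shape_i / size``.
    """
    if size < 2:
        raise ConfigurationError(f"resample size must be >= 2, got {size}")
    if order not in range(6):
        raise ConfigurationError(f"interpolation order must be in 0..5, got {order}")
    factors = [size / n for n in v.shape]
    out = ndimage.zoom(
        np.asarray(v.data, dtype=np.float64), factors, order=order,
        mode="nearest", grid_mode=True,
    )
    # grid rounding can leave the shape off by one voxel; enforce exactly size³
    out = out[:size, :size, :size]
    new_spacing = tuple(s * n / size for s, n in zip(v.spacing, v.shape))
    return Volume(data=out, spacing=new_spacing, axes=v.axes)


def resample_label(l: LabelVolume, size: int = 256) -> LabelVolume:
    """Nearest-neighbour label resampling — output stays strictly binary."""
    if size < 2:
        raise ConfigurationError(f"resample size must be >= 2, got {size}")
    factors = [size / n for n in l.shape]
    out = ndimage.zoom(l.data, factors, order=0, mode="nearest", grid_mode=True)
    out = out[:size, :size, :size]
    new_spacing = tuple(s * n / size for s, n in zip(l.spacing, l.shape))
    return LabelVolume(data=out.astype(np.uint8), spacing=new_spacing, axes=l.axes)


# ---------------------------------------------------------------------------
# intensity normalization
# ---------------------------------------------------------------------------

def fit_normalizer(training_volumes: Iterable[Volume]) -> IntensityNormalizer:
    """Pooled mean/std (population) over the voxels of the *training* volumes.

    Test volumes must never be passed here; the cross-validation harness
    refits per fold.
    """
    vols = list(training_volumes)
    if not vols:
        raise DegenerateDataError("need at least one training volume")
    n = sum(v.data.size for v in vols)
    mean = sum(np.asarray(v.data, dtype=np.float64).sum() for v in vols) / n
    ss = sum(((np.asarray(v.data, dtype=np.float64) - mean) ** 2).sum() for v in vols)
    std = math.sqrt(ss / n)
    if std <= 0:
        raise DegenerateDataError("pooled training intensities are constant")
    return IntensityNormalizer(mean=float(mean), std=float(std))


def apply_normalizer(n: IntensityNormalizer, v: Volume) -> Volume:
    """Voxelwise (x - mean) / std; geometry unchanged."""
    return replace(v, data=(np.asarray(v.data, dtype=np.float64) - n.mean) / n.std)


# ---------------------------------------------------------------------------
# orthogonal-plane slicing
# ---------------------------------------------------------------------------

def extract_slices(v: Volume, axis: str) -> SliceStack:
    """Cut the volume into ordered single-channel 2D slices along ``axis``."""
    ax = v.grid_axis(axis)
    planes = np.moveaxis(np.asarray(v.data), ax, 0)[..., np.newaxis]
    return SliceStack(slices=planes.copy(), axis=axis)


def assemble_volume(s: SliceStack, template: Volume) -> Volume:
    """Reassemble a single-channel slice stack into a volume on the
    template's grid.  Exact inverse of :func:`extract_slices`."""
    if s.channels != 1:
        raise AssemblyError(f"can only assemble single-channel stacks, got C={s.channels}")
    ax = template.grid_axis(s.axis)
    expected_n = template.shape[ax]
    expected_hw = tuple(d for i, d in enumerate(template.shape) if i != ax)
    if len(s) != expected_n or s.slices.shape[1:3] != expected_hw:
        raise AssemblyError(
            f"stack geometry {s.slices.shape[:3]} does not match template "
            f"{template.shape} along axis {s.axis!r}"
        )
    data = np.moveaxis(s.slices[..., 0], 0, ax)
    return Volume(data=data.copy(), spacing=template.spacing, axes=template.axes)
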