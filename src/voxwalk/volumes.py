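"""Volumetric image and label I/O with intensity normalization.

Volumes are 3D scalar grids indexed ``(z, y, x)``, 0-based; a "slice" is a
z-plane unless stated otherwise.  Three on-disk formats are supported:
multipage TIFF (one page per z-slice), NRRD, and NIfTI-1 (``.nii`` /
``.nii.gz``).  Label volumes hold non-negative integer voxel codes with 0
meaning background/unlabeled.

Intensity data follow a two-track normalization: 8-bit images pass through
unchanged, while wider integer or floating images are converted to
single-precision float and affinely rescaled so that their global minimum
maps to 0 and their maximum to 255.  The random-walk engine only accepts
normalized volumes.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
import SimpleITK as sitk
import tifffile

__all__ = [
    "IntensityVolume",
    "LabelVolume",
    "VolumeFormatError",
    "VolumeParseError",
    "VolumeDataError",
    "read_volume",
    "normalize_intensities",
    "write_labels",
    "write_scalar",
]

logger = logging.getLogger(__name__)

_TIFF_EXT = (".tif", ".tiff")
_NRRD_EXT = (".nrrd",)
_NIFTI_EXT = (".nii", ".nii.gz")


class VolumeFormatError(ValueError):
    """Unsupported file extension or encoding."""


class VolumeParseError(ValueError):
    """File exists but cannot be interpreted as a 3D volume."""


class VolumeDataError(ValueError):
    """Voxel data violate a contract (e.g. non-finite intensities)."""


@dataclass
class IntensityVolume:
    """A 3D scalar field, ``(z, y, x)`` indexed.

    ``dtype_class`` is ``"uint8"`` or ``"float-rescaled"`` after
    normalization, ``"raw"`` straight from disk.  ``spacing`` is an optional
    per-axis voxel size carried through for information only; all internal
    computations assume unit spacing.
    """

    data: np.ndarray
    dtype_class: str = "raw"
    spacing: tuple[float, float, float] | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3 or min(self.data.shape) < 1:
            raise VolumeDataError(
                f"intensity volume must be 3D with positive extents, got shape {self.data.shape}"
            )

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


@dataclass
class LabelVolume:
    """A 3D integer field of voxel labels; 0 is background.

    Sparse annotations carry nonzero values only on pre-segmented planes;
    dense results label the full volume.  ``metadata`` is an opaque sidecar
    (label names, colors) preserved where the output format supports it.
    """

    data: np.ndarray
    metadata: dict = field(default_factory=dict)
    spacing: tuple[float, float, float] | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3 or min(self.data.shape) < 1:
            raise VolumeDataError(
                f"label volume must be 3D with positive extents, got shape {self.data.shape}"
            )
        if not np.issubdtype(self.data.dtype, np.integer):
            cast = self.data.astype(np.int64)
            if not np.array_equal(cast, self.data):
                raise VolumeDataError("label volume holds non-integer values")
            self.data = cast
        if self.data.size and self.data.min() < 0:
            raise VolumeDataError("label volume holds negative values")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def label_ids(self) -> tuple[int, ...]:
        """Sorted distinct nonzero values actually present."""
        vals = np.unique(self.data)
        return tuple(int(v) for v in vals if v != 0)


def _classify_ext(path: str) -> str:
    low = str(path).lower()
    if low.endswith(_NIFTI_EXT):
        return "nifti"
    if low.endswith(_NRRD_EXT):
        return "nrrd"
    if low.endswith(_TIFF_EXT):
        return "tiff"
    raise VolumeFormatError(
        f"unsupported extension for {path!r}; expected one of "
        ".tif/.tiff, .nrrd, .nii, .nii.gz"
    )


def _read_array(path: str) -> tuple[np.ndarray, tuple | None, dict]:
    kind = _classify_ext(path)
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    try:
        if kind == "tiff":
            arr = tifffile.imread(path)
            spacing = None
            meta: dict = {}
        elif kind == "nrrd":
            img = sitk.ReadImage(str(path))
            arr = sitk.GetArrayFromImage(img)  # already (z, y, x)
            spacing = tuple(reversed(img.GetSpacing()))
            meta = {k: img.GetMetaData(k) for k in img.GetMetaDataKeys()
                    if k.startswith("voxwalk_")}
        else:  # nifti
            img = nib.load(str(path))
            arr = np.asanyarray(img.dataobj)
            # NIfTI arrays are (x, y, z); flip to the (z, y, x) convention.
            arr = np.transpose(arr, (2, 1, 0))
            zooms = img.header.get_zooms()[:3]
            spacing = tuple(reversed([float(z) for z in zooms]))
            meta = {}
    except (VolumeFormatError, FileNotFoundError):
        raise
    except Exception as exc:  # pragma: no cover - backend specific
        raise VolumeParseError(f"cannot parse {path!r}: {exc}") from exc
    if arr.ndim == 2:
        arr = arr[None, ...]
    if arr.ndim != 3:
        raise VolumeParseError(
            f"{path!r} holds a {arr.ndim}-D array; expected a 3D volume"
        )
    return np.ascontiguousarray(arr), spacing, meta


def read_volume(path: str, role: str = "intensity") -> IntensityVolume | LabelVolume:
    """Read a volume from disk in ``(z, y, x)`` order.

    Parameters
    ----------
    path:
        File with extension ``.tif``/``.tiff``, ``.nrrd``, ``.nii`` or
        ``.nii.gz``.
    role:
        ``"intensity"`` returns a raw :class:`IntensityVolume` (call
        :func:`normalize_intensities` before running walks);
        ``"label"`` returns a :class:`LabelVolume` with values cast to an
        integer class without value change.
    """
    if role not in ("intensity", "label"):
        raise ValueError(f"role must be 'intensity' or 'label', got {role!r}")
    arr, spacing, meta = _read_array(path)
    if role == "label":
        if np.issubdtype(arr.dtype, np.floating):
            cast = arr.astype(np.int64)
            if not np.array_equal(cast, arr):
                raise VolumeParseError(f"{path!r}: label values are not integral")
            arr = cast
        return LabelVolume(arr, metadata=meta, spacing=spacing)
    return IntensityVolume(arr, dtype_class="raw", spacing=spacing)


def normalize_intensities(v: IntensityVolume) -> IntensityVolume:
    """Apply the two-track intensity normalization.

    8-bit input is returned unchanged (``dtype_class="uint8"``); any wider
    integer or floating input is converted to float32 and affinely mapped so
    that the global minimum goes to 0 and the maximum to 255
    (``dtype_class="float-rescaled"``).  A constant volume maps to all
    zeros.  Idempotent, and monotone in the input intensities.
    """
    arr = v.data
    if np.issubdtype(arr.dtype, np.floating) and not np.isfinite(arr).all():
        raise VolumeDataError("non-finite intensity values present")
    if arr.dtype == np.uint8:
        return IntensityVolume(arr, dtype_class="uint8", spacing=v.spacing)
    if v.dtype_class == "float-rescaled":
        return IntensityVolume(arr, dtype_class="float-rescaled", spacing=v.spacing)
    arr = arr.astype(np.float64)
    lo = float(arr.min())
    hi = float(arr.max())
    if hi == lo:
        out = np.zeros_like(arr)
    else:
        out = np.clip((arr - lo) * (255.0 / (hi - lo)), 0.0, 255.0)
    return IntensityVolume(out.astype(np.float32), dtype_class="float-rescaled",
                           spacing=v.spacing)


def _write_array(arr: np.ndarray, path: str, metadata: dict | None = None,
                 spacing: tuple | None = None) -> None:
    if os.path.isdir(path):
        raise IsADirectoryError(path)
    kind = _classify_ext(path)
    try:
        if kind == "tiff":
            if metadata:
                logger.warning("TIFF output drops label metadata (%d keys)", len(metadata))
            tifffile.imwrite(path, arr, photometric="minisblack")
        elif kind == "nrrd":
            img = sitk.GetImageFromArray(arr)
            if spacing is not None:
                img.SetSpacing(tuple(reversed([float(s) for s in spacing])))
            for k, val in (metadata or {}).items():
                key = k if str(k).startswith("voxwalk_") else f"voxwalk_{k}"
                img.SetMetaData(key, str(val))
            sitk.WriteImage(img, str(path))
        else:  # nifti
            if metadata:
                logger.warning("NIfTI output drops label metadata (%d keys)", len(metadata))
            nii = nib.Nifti1Image(np.transpose(arr, (2, 1, 0)), affine=np.eye(4))
            if spacing is not None:
                nii.header.set_zooms(tuple(reversed([float(s) for s in spacing])))
            nib.save(nii, str(path))
    except (VolumeFormatError, IsADirectoryError):
        raise
    except OSError:
        raise
    except Exception as exc:  # pragma: no cover - backend specific
        raise OSError(f"cannot write {path!r}: {exc}") from exc


def write_labels(lv: LabelVolume, path: str) -> None:
    """Write a label volume; re-readable by :func:`read_volume` with
    identical values.  Label metadata is written where the format carries
    it (NRRD header fields), otherwise dropped with a warning."""
    arr = lv.data
    # Use the narrowest lossless unsigned type for portability.
    maxv = int(arr.max()) if arr.size else 0
    for dt in (np.uint8, np.uint16, np.uint32, np.int64):
        if maxv <= np.iinfo(dt).max:
            arr = arr.astype(dt)
            break
    _write_array(arr, path, metadata=lv.metadata, spacing=lv.spacing)


def write_scalar(data, path: str) -> None:
    """Write a floating scalar field (uncertainty map, hit-field slice).

    Accepts a bare array or any object with a ``values`` attribute.
    """
    arr = getattr(data, "values", data)
    _write_array(np.asarray(arr, dtype=np.float32), path)
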