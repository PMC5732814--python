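"""Volume/mask I/O, ROI cropping and grey-level quantization.

Images are held as ``ImageVolume`` objects: a 3D scalar array in fixed
``(x, y, z)`` axis order together with per-axis voxel spacing in mm and a
physical origin.  Masks use the convention nonzero = tumor.  NIfTI
(``.nii``/``.nii.gz``) and NRRD (``.nrrd``) are supported through SimpleITK.

Texture analysis operates on a ``QuantizedROI``: in-mask voxels mapped to
integer grey levels ``1..n_levels`` by equal-width binning of the in-mask
intensity range, with 0 reserved as the out-of-mask sentinel so that level
indices are 1-based as in the usual texture-matrix formulas.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import SimpleITK as sitk

__all__ = [
    "ImageVolume",
    "ROIMask",
    "QuantizedROI",
    "read_volume",
    "write_volume",
    "read_mask",
    "crop_to_roi",
    "quantize",
]

_SUPPORTED_EXTENSIONS = (".nii", ".nii.gz", ".nrrd")


@dataclass
class ImageVolume:
    """A 3D scalar grid with physical spacing.

    Parameters
    ----------
    data
        3D array in ``(x, y, z)`` axis order, Hounsfield-unit-like values.
    spacing
        Per-axis voxel size in mm, strictly positive.
    origin
        Physical coordinates of voxel ``(0, 0, 0)``.
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3D volume, got ndim={self.data.ndim}")
        if min(self.data.shape) < 1:
            raise ValueError(f"all dimensions must be >= 1, got shape {self.data.shape}")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 strictly positive values, got {self.spacing}")
        self.origin = tuple(float(o) for o in self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


@dataclass
class ROIMask:
    """Binary tumor mask aligned with an :class:`ImageVolume`."""

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data) != 0
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3D mask, got ndim={self.data.ndim}")
        self.spacing = tuple(float(s) for s in self.spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def n_foreground(self) -> int:
        return int(self.data.sum())


@dataclass
class QuantizedROI:
    """In-mask voxels mapped to integer grey levels ``1..n_levels``.

    ``data`` holds 0 outside the mask; background never enters any texture
    statistic.
    """

    data: np.ndarray
    n_levels: int
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    mask: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.int32)
        if self.mask is None:
            self.mask = self.data > 0
        inside = self.data[self.mask]
        if inside.size and (inside.min() < 1 or inside.max() > self.n_levels):
            raise ValueError("in-mask levels must lie in 1..n_levels")


def _check_path(path: str | os.PathLike) -> str:
    path = os.fspath(path)
    if not any(path.endswith(ext) for ext in _SUPPORTED_EXTENSIONS):
        raise ValueError(f"unsupported image format: {path!r} (expected .nii/.nii.gz/.nrrd)")
    return path


def read_volume(path: str | os.PathLike) -> ImageVolume:
    """Read a NIfTI or NRRD volume into ``(x, y, z)`` axis order.

    SimpleITK returns arrays in ``(z, y, x)``; they are transposed so that
    array axis *i* matches spacing axis *i*.  A missing or degenerate
    spacing in the header is an error — there is no silent 1 mm default for
    files whose header cannot be trusted.
    """
    path = _check_path(path)
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    try:
        img = sitk.ReadImage(path)
    except RuntimeError as exc:  # pragma: no cover - ITK error text varies
        raise ValueError(f"unreadable image file {path!r}: {exc}") from exc
    if img.GetDimension() != 3:
        raise ValueError(f"expected a 3D image, got {img.GetDimension()}D in {path!r}")
    spacing = img.GetSpacing()
    if any(not np.isfinite(s) or s <= 0 for s in spacing):
        raise ValueError(f"invalid voxel spacing {spacing} in {path!r}")
    data = sitk.GetArrayFromImage(img).transpose(2, 1, 0)
    return ImageVolume(data=data, spacing=tuple(spacing), origin=tuple(img.GetOrigin()))


def write_volume(vol: ImageVolume | ROIMask, path: str | os.PathLike) -> None:
    """Write a volume or mask to NIfTI/NRRD (inverse of :func:`read_volume`)."""
    path = _check_path(path)
    data = vol.data
    if data.dtype == bool:
        data = data.astype(np.uint8)
    img = sitk.GetImageFromArray(np.ascontiguousarray(data.transpose(2, 1, 0)))
    img.SetSpacing(tuple(vol.spacing))
    img.SetOrigin(tuple(getattr(vol, "origin", (0.0, 0.0, 0.0))))
    sitk.WriteImage(img, path)


def read_mask(path: str | os.PathLike) -> ROIMask:
    """Read a binary mask (nonzero = tumor)."""
    vol = read_volume(path)
    return ROIMask(data=vol.data != 0, spacing=vol.spacing, origin=vol.origin)


def _require_alignment(vol: ImageVolume, mask: ROIMask) -> None:
    if vol.shape != mask.shape:
        raise ValueError(f"image shape {vol.shape} != mask shape {mask.shape}")


def crop_to_roi(
    vol: ImageVolume, mask: ROIMask, margin: int = 0
) -> tuple[ImageVolume, ROIMask]:
    """Crop image and mask to the tumor bounding box plus ``margin`` voxels.

    The box is the tightest axis-aligned bounding box of the mask
    foreground, expanded by ``margin`` on every side and clipped to the
    array bounds; the foreground voxel count is unchanged.
    """
    _require_alignment(vol, mask)
    if mask.n_foreground == 0:
        raise ValueError("cannot crop to an empty mask")
    if margin < 0:
        raise ValueError("margin must be >= 0")
    slices = []
    for axis in range(3):
        other = tuple(a for a in range(3) if a != axis)
        profile = mask.data.any(axis=other)
        idx = np.flatnonzero(profile)
        lo = max(int(idx[0]) - margin, 0)
        hi = min(int(idx[-1]) + margin + 1, mask.shape[axis])
        slices.append(slice(lo, hi))
    slices = tuple(slices)
    origin = tuple(
        o + s.start * sp for o, s, sp in zip(vol.origin, slices, vol.spacing)
    )
    return (
        ImageVolume(vol.data[slices].copy(), vol.spacing, origin),
        ROIMask(mask.data[slices].copy(), mask.spacing, origin),
    )


def quantize(vol: ImageVolume, mask: ROIMask, n_levels: int = 32) -> QuantizedROI:
    """Uniformly resample in-mask intensities to ``n_levels`` grey levels.

    Equal-width binning of the in-mask intensity range::

        level = min(floor(n_levels * (x - xmin) / (xmax - xmin)) + 1, n_levels)

    where ``xmin``/``xmax`` are the in-mask minimum and maximum.  A
    constant-intensity region maps entirely to level 1 — a degenerate but
    valid input that keeps the texture matrices well-defined.  The map is
    monotone in intensity and invariant to affine rescaling ``a*x + b``
    (``a > 0``) of in-mask values.
    """
    _require_alignment(vol, mask)
    if n_levels < 2:
        raise ValueError(f"n_levels must be >= 2, got {n_levels}")
    if mask.n_foreground == 0:
        raise ValueError("cannot quantize an empty ROI")
    inside = vol.data[mask.data].astype(np.float64)
    xmin, xmax = inside.min(), inside.max()
    out = np.zeros(vol.shape, dtype=np.int32)
    if xmax == xmin:
        out[mask.data] = 1
    else:
        scaled = n_levels * (vol.data[mask.data].astype(np.float64) - xmin) / (xmax - xmin)
        out[mask.data] = np.minimum(np.floor(scaled).astype(np.int32) + 1, n_levels)
    return QuantizedROI(data=out, n_levels=n_levels, spacing=vol.spacing, mask=mask.data.copy())
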