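"""Morphological features of the binary tumor mask.

Five features: volume, surface area, surface-to-volume ratio, sphericity
and a box-counting fractal dimension of the tumor surface.  All are
functions of the mask and voxel spacing only — the image intensities never
enter, so they are invariant to any intensity transform.

Surface area is measured on a marching-cubes isosurface at the 0.5 level of
the binary mask rather than by counting exposed voxel faces: face counting
overestimates the area of smooth bodies by tens of percent, while the mesh
estimate converges to the analytic value for digitized spheres.
"""

from __future__ import annotations

import numpy as np
from skimage import measure
from scipy import ndimage

from .imaging import ROIMask

__all__ = [
    "mask_volume",
    "mask_surface_area",
    "fractal_dimension",
    "shape_vector",
    "SHAPE_FEATURE_NAMES",
]

SHAPE_FEATURE_NAMES: tuple[str, ...] = (
    "shape_volume",
    "shape_surface_area",
    "shape_surface_to_volume",
    "shape_sphericity",
    "shape_fractal_dimension",
)


def _require_nonempty(mask: ROIMask) -> None:
    if mask.n_foreground == 0:
        raise ValueError("empty mask")


def mask_volume(mask: ROIMask) -> float:
    """Tumor volume in mm^3: foreground voxel count x voxel volume."""
    _require_nonempty(mask)
    return float(mask.n_foreground) * float(np.prod(mask.spacing))


_MESH_SIGMA = 0.6  # voxels; sub-voxel surface placement (see docstring)


def mask_surface_area(mask: ROIMask) -> float:
    """Tumor surface area in mm^2 from a 0.5-level isosurface mesh.

    The binary mask is smoothed with a narrow Gaussian (0.6 voxels) before
    meshing: marching cubes on raw binary data quantizes vertex positions
    to mid-voxel planes and overestimates the area of smooth bodies by
    ~7-8%, while the smoothed level set places vertices sub-voxel and is
    within ~2% of the analytic value for digitized spheres (at the price of
    slightly rounding perfectly sharp edges).  The mask is zero-padded so
    the surface is closed even when the tumor touches the array boundary;
    tiny masks whose smoothed peak falls below the iso-level fall back to
    the raw binary mesh.
    """
    _require_nonempty(mask)
    padded = np.pad(mask.data.astype(np.float64), 2)
    smoothed = ndimage.gaussian_filter(padded, sigma=_MESH_SIGMA)
    if smoothed.max() <= 0.5:
        smoothed = padded
    verts, faces, _, _ = measure.marching_cubes(smoothed, level=0.5, spacing=mask.spacing)
    return float(measure.mesh_surface_area(verts, faces))


def _surface_voxels(mask: np.ndarray) -> np.ndarray:
    """Foreground voxels with at least one background 6-neighbor."""
    eroded = ndimage.binary_erosion(mask, structure=ndimage.generate_binary_structure(3, 1))
    return mask & ~eroded


def fractal_dimension(mask: ROIMask) -> float:
    """Box-counting fractal dimension of the tumor surface.

    The surface voxel set is covered by cubic boxes of dyadic edge lengths
    1, 2, 4, ... voxels; the dimension is the least-squares slope of
    ``log N(box)`` against ``log (1/size)``.  A smooth 2D surface yields a
    value near 2; rougher surfaces score higher.
    """
    _require_nonempty(mask)
    surf = _surface_voxels(mask.data)
    coords = np.argwhere(surf)
    if len(coords) == 0:  # single interior voxel ROI: whole mask is surface
        coords = np.argwhere(mask.data)
    extent = coords.max(axis=0) - coords.min(axis=0) + 1
    max_size = int(max(extent))
    sizes = []
    size = 1
    while size <= max(max_size // 2, 1):
        sizes.append(size)
        size *= 2
    if len(sizes) < 2:
        return 2.0  # ROI too small to fit a scaling law; surface-like default
    shifted = coords - coords.min(axis=0)
    counts = []
    for s in sizes:
        boxes = np.unique(shifted // s, axis=0)
        counts.append(len(boxes))
    slope, _ = np.polyfit(np.log(1.0 / np.asarray(sizes, dtype=float)), np.log(counts), 1)
    return float(slope)


def shape_vector(mask: ROIMask) -> dict[str, float]:
    """All five shape features.

    Sphericity is ``pi^(1/3) * (6V)^(2/3) / A`` — 1 for a perfect ball,
    smaller for any other body (up to discretization error).
    """
    volume = mask_volume(mask)
    area = mask_surface_area(mask)
    sphericity = float(np.pi ** (1.0 / 3.0) * (6.0 * volume) ** (2.0 / 3.0) / area)
    return {
        "shape_volume": volume,
        "shape_surface_area": area,
        "shape_surface_to_volume": area / volume,
        "shape_sphericity": sphericity,
        "shape_fractal_dimension": fractal_dimension(mask),
    }
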