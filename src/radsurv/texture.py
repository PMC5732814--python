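"""Texture matrices (GLCM, NGTDM, GLZM) and the 19 derived texture features.

All three matrix builders operate on a :class:`~radsurv.imaging.QuantizedROI`
(in-mask grey levels ``1..Ng``, 0 outside the mask) and never let background
voxels enter any statistic.  Directional statistics are aggregated over the
full 3D neighborhood, so every feature is invariant under spatial axis
permutation of the volume, and — because quantization is rank-preserving —
under affine intensity rescaling of the raw image.

Feature families
----------------
GLCM (8): energy, entropy, contrast, dissimilarity, homogeneity (inverse
difference moment), correlation, variance, autocorrelation.

NGTDM (5): the Amadasun-King set — coarseness, contrast, busyness,
complexity, strength.

GLZM (6): small/large zone emphasis, grey-level non-uniformity, zone size
non-uniformity, zone percentage, large zone / high grey emphasis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .imaging import QuantizedROI

__all__ = [
    "GLCM",
    "NGTDM",
    "GLZM",
    "GLCM_OFFSETS",
    "compute_glcm",
    "glcm_features",
    "compute_ngtdm",
    "ngtdm_features",
    "compute_glzm",
    "glzm_features",
    "extract_texture",
    "TEXTURE_FEATURE_NAMES",
]

_EPS = 1e-12
_COARSENESS_CAP = 1.0 / _EPS  # constant ROI: s_i all zero; keep the value finite

#: The 13 unique direction offsets of the 3D 26-neighborhood (one per
#: antipodal pair), enumerated lexicographically.
GLCM_OFFSETS: tuple[tuple[int, int, int], ...] = tuple(
    (dx, dy, dz)
    for dx in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dz in (-1, 0, 1)
    if (dx, dy, dz) > (0, 0, 0)
)


@dataclass
class GLCM:
    """Normalized grey-level co-occurrence matrix aggregated over offsets."""

    P: np.ndarray  # Ng x Ng, sums to 1
    n_levels: int
    offsets: tuple[tuple[int, int, int], ...]
    symmetric: bool


@dataclass
class NGTDM:
    """Neighborhood grey-tone difference matrix (Amadasun-King).

    ``s[i-1]`` is the summed absolute difference of level-``i`` voxels from
    their 26-neighborhood average; ``n[i-1]`` the voxel count at level ``i``;
    ``p = n / N`` the level probabilities over the ``N`` counted voxels.
    """

    s: np.ndarray
    n: np.ndarray
    p: np.ndarray
    n_levels: int
    n_counted: int

    @property
    def n_occupied(self) -> int:
        return int((self.n > 0).sum())


@dataclass
class GLZM:
    """Grey-level zone matrix: zone counts indexed by (level, zone size)."""

    P: np.ndarray  # Ng x Zmax integer zone counts
    n_levels: int
    n_zones: int
    n_voxels: int


def compute_glcm(q: QuantizedROI, distance: int = 1, symmetric: bool = True) -> GLCM:
    """Accumulate pair counts over the 13 unique 3D directions.

    Both voxels of a pair must be in-mask.  With ``symmetric=True`` each
    pair contributes to both ``(i, j)`` and ``(j, i)``.  Counts are summed
    across all offsets before normalizing to a single probability matrix.
    """
    if distance < 1:
        raise ValueError("distance must be >= 1")
    ng = q.n_levels
    levels = q.data
    counts = np.zeros((ng, ng), dtype=np.int64)
    for off in GLCM_OFFSETS:
        dx, dy, dz = (distance * o for o in off)
        src = _shift_slices(levels.shape, (dx, dy, dz), source=True)
        dst = _shift_slices(levels.shape, (dx, dy, dz), source=False)
        a = levels[src]
        b = levels[dst]
        valid = (a > 0) & (b > 0)
        if not valid.any():
            continue
        np.add.at(counts, (a[valid] - 1, b[valid] - 1), 1)
    if symmetric:
        counts = counts + counts.T
    total = counts.sum()
    if total == 0:
        raise ValueError("no valid in-mask voxel pairs at this distance")
    return GLCM(
        P=counts / total,
        n_levels=ng,
        offsets=tuple((distance * a, distance * b, distance * c) for a, b, c in GLCM_OFFSETS),
        symmetric=symmetric,
    )


def _shift_slices(shape, offset, source: bool):
    """Slice pair implementing pairs (v, v+offset), clipped to bounds."""
    out = []
    for size, d in zip(shape, offset):
        if d >= 0:
            out.append(slice(0, size - d) if source else slice(d, size))
        else:
            out.append(slice(-d, size) if source else slice(0, size + d))
    return tuple(out)


def glcm_features(M: GLCM) -> dict[str, float]:
    """The 8 GLCM features from a normalized co-occurrence matrix.

    Correlation with a zero-variance marginal is defined as 0 so that
    degenerate (constant) ROIs still yield finite feature vectors.
    """
    P = M.P
    ng = M.n_levels
    i = np.arange(1, ng + 1)
    I, J = np.meshgrid(i, i, indexing="ij")
    nz = P > 0
    energy = float((P**2).sum())
    entropy = float(-(P[nz] * np.log2(P[nz])).sum())
    contrast = float(((I - J) ** 2 * P).sum())
    dissimilarity = float((np.abs(I - J) * P).sum())
    homogeneity = float((P / (1.0 + (I - J) ** 2)).sum())
    mu_i = float((I * P).sum())
    mu_j = float((J * P).sum())
    var_i = float(((I - mu_i) ** 2 * P).sum())
    var_j = float(((J - mu_j) ** 2 * P).sum())
    if var_i <= 0 or var_j <= 0:
        correlation = 0.0
    else:
        correlation = float(((I - mu_i) * (J - mu_j) * P).sum() / np.sqrt(var_i * var_j))
    # grand mean over both matrix axes; equals mu_i for symmetric P
    mu = 0.5 * (mu_i + mu_j)
    variance = float((((I - mu) ** 2) * P).sum())
    autocorrelation = float((I * J * P).sum())
    return {
        "glcm_energy": energy,
        "glcm_entropy": entropy,
        "glcm_contrast": contrast,
        "glcm_dissimilarity": dissimilarity,
        "glcm_homogeneity": homogeneity,
        "glcm_correlation": correlation,
        "glcm_variance": variance,
        "glcm_autocorrelation": autocorrelation,
    }


def compute_ngtdm(q: QuantizedROI) -> NGTDM:
    """Per-level deviation of voxels from their 26-neighborhood average.

    For every in-mask voxel with at least one in-mask 26-neighbor, the
    neighborhood average ``A`` is the mean level of its in-mask neighbors
    (center excluded); the voxel contributes ``|i - A|`` to ``s_i`` and 1 to
    ``n_i`` for its own level ``i``.  Voxels with no in-mask neighbor are
    skipped.
    """
    levels = q.data.astype(np.float64)
    mask = q.mask
    kernel = np.ones((3, 3, 3))
    kernel[1, 1, 1] = 0.0
    neighbor_sum = ndimage.convolve(levels * mask, kernel, mode="constant", cval=0.0)
    neighbor_cnt = ndimage.convolve(mask.astype(np.float64), kernel, mode="constant", cval=0.0)
    valid = mask & (neighbor_cnt > 0.5)
    if not valid.any():
        raise ValueError("no in-mask voxel has an in-mask neighbor")
    A = neighbor_sum[valid] / neighbor_cnt[valid]
    lev = q.data[valid]
    diffs = np.abs(lev - A)
    ng = q.n_levels
    s = np.zeros(ng)
    n = np.zeros(ng, dtype=np.int64)
    np.add.at(s, lev - 1, diffs)
    np.add.at(n, lev - 1, 1)
    N = int(valid.sum())
    return NGTDM(s=s, n=n, p=n / N, n_levels=ng, n_counted=N)


def ngtdm_features(T: NGTDM) -> dict[str, float]:
    """The 5 Amadasun-King features.

    Pairwise sums run over occupied levels only (``p_i > 0``).  Coarseness
    is capped at ``1/eps`` for constant ROIs, and contrast/busyness/strength
    fall back to 0 when their denominators vanish, so the vector stays
    finite for any valid ROI.
    """
    occ = T.p > 0
    i_lev = np.arange(1, T.n_levels + 1, dtype=np.float64)[occ]
    p = T.p[occ]
    s = T.s[occ]
    ngp = int(occ.sum())
    N = T.n_counted

    ps = float((p * s).sum())
    coarseness = min(1.0 / (_EPS + ps), _COARSENESS_CAP)

    if ngp <= 1:
        contrast = 0.0
    else:
        pairterm = float(np.sum(p[:, None] * p[None, :] * (i_lev[:, None] - i_lev[None, :]) ** 2))
        contrast = pairterm / (ngp * (ngp - 1)) * (float(T.s.sum()) / N)

    ip = i_lev * p
    denom_busy = float(np.abs(ip[:, None] - ip[None, :]).sum())
    busyness = ps / denom_busy if denom_busy > 0 else 0.0

    absdiff = np.abs(i_lev[:, None] - i_lev[None, :])
    psum = p[:, None] + p[None, :]
    num = p[:, None] * s[:, None] + p[None, :] * s[None, :]
    complexity = float((absdiff * num / psum).sum()) / N

    strength_num = float((psum * (i_lev[:, None] - i_lev[None, :]) ** 2).sum())
    strength = strength_num / (_EPS + float(T.s.sum()))
    if float(T.s.sum()) == 0.0:
        strength = 0.0

    return {
        "ngtdm_coarseness": coarseness,
        "ngtdm_contrast": contrast,
        "ngtdm_busyness": busyness,
        "ngtdm_complexity": complexity,
        "ngtdm_strength": strength,
    }


_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)


def compute_glzm(q: QuantizedROI) -> GLZM:
    """Zone matrix: maximal 26-connected same-level regions of the ROI.

    ``P[i-1, z-1]`` counts zones of grey level ``i`` and size ``z`` voxels.
    Mass conservation holds exactly in integer arithmetic:
    ``sum_z z * P[i, z]`` over all ``i`` equals the in-mask voxel count.
    """
    nv = int(q.mask.sum())
    if nv == 0:
        raise ValueError("empty ROI")
    sizes_per_level: list[np.ndarray] = []
    zmax = 1
    for level in range(1, q.n_levels + 1):
        binary = q.data == level
        if not binary.any():
            sizes_per_level.append(np.zeros(0, dtype=np.int64))
            continue
        labels, n_comp = ndimage.label(binary, structure=_STRUCT_26)
        sizes = np.bincount(labels.ravel())[1:]
        sizes_per_level.append(sizes.astype(np.int64))
        zmax = max(zmax, int(sizes.max()))
    P = np.zeros((q.n_levels, zmax), dtype=np.int64)
    n_zones = 0
    for idx, sizes in enumerate(sizes_per_level):
        for size in sizes:
            P[idx, size - 1] += 1
            n_zones += 1
    return GLZM(P=P, n_levels=q.n_levels, n_zones=n_zones, n_voxels=nv)


def glzm_features(Z: GLZM) -> dict[str, float]:
    """The 6 zone-matrix features."""
    if Z.n_zones < 1:
        raise ValueError("zone matrix has no zones")
    P = Z.P.astype(np.float64)
    nz = Z.n_zones
    i = np.arange(1, Z.n_levels + 1, dtype=np.float64)
    z = np.arange(1, P.shape[1] + 1, dtype=np.float64)
    row = P.sum(axis=1)  # per grey level
    col = P.sum(axis=0)  # per zone size
    return {
        "glzm_small_zone_emphasis": float((P / z[None, :] ** 2).sum() / nz),
        "glzm_large_zone_emphasis": float((P * z[None, :] ** 2).sum() / nz),
        "glzm_grey_level_nonuniformity": float((row**2).sum() / nz),
        "glzm_zone_size_nonuniformity": float((col**2).sum() / nz),
        "glzm_zone_percentage": nz / Z.n_voxels,
        "glzm_large_zone_high_grey_emphasis": float(
            (P * (i[:, None] ** 2) * (z[None, :] ** 2)).sum() / nz
        ),
    }


def extract_texture(q: QuantizedROI, distance: int = 1) -> dict[str, float]:
    """All 19 texture features (8 GLCM + 5 NGTDM + 6 GLZM), stable order."""
    feats: dict[str, float] = {}
    feats.update(glcm_features(compute_glcm(q, distance=distance)))
    feats.update(ngtdm_features(compute_ngtdm(q)))
    feats.update(glzm_features(compute_glzm(q)))
    return feats


TEXTURE_FEATURE_NAMES: tuple[str, ...] = (
    "glcm_energy",
    "glcm_entropy",
    "glcm_contrast",
    "glcm_dissimilarity",
    "glcm_homogeneity",
    "glcm_correlation",
    "glcm_variance",
    "glcm_autocorrelation",
    "ngtdm_coarseness",
    "ngtdm_contrast",
    "ngtdm_busyness",
    "ngtdm_complexity",
    "ngtdm_strength",
    "glzm_small_zone_emphasis",
    "glzm_large_zone_emphasis",
    "glzm_grey_level_nonuniformity",
    "glzm_zone_size_nonuniformity",
    "glzm_zone_percentage",
    "glzm_large_zone_high_grey_emphasis",
)
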