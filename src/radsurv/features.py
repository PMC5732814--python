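"""End-to-end per-patient feature extraction: 24 named radiomic features."""

from __future__ import annotations

from .imaging import ImageVolume, ROIMask, crop_to_roi, quantize
from .shape import SHAPE_FEATURE_NAMES, shape_vector
from .texture import TEXTURE_FEATURE_NAMES, extract_texture

__all__ = ["FEATURE_NAMES", "extract_features"]

#: Fixed order of the 24 radiomic features (19 texture + 5 shape).
FEATURE_NAMES: tuple[str, ...] = TEXTURE_FEATURE_NAMES + SHAPE_FEATURE_NAMES


def extract_features(
    vol: ImageVolume, mask: ROIMask, n_levels: int = 32, distance: int = 1
) -> dict[str, float]:
    """Compute the full 24-feature vector for one tumor.

    The image is cropped to the tumor bounding box, in-mask intensities are
    uniformly resampled to ``n_levels`` grey levels, and texture features
    are computed on the quantized ROI; shape features use the mask and
    voxel spacing only.
    """
    cvol, cmask = crop_to_roi(vol, mask, margin=1)
    q = quantize(cvol, cmask, n_levels=n_levels)
    feats = extract_texture(q, distance=distance)
    feats.update(shape_vector(cmask))
    assert len(feats) == len(FEATURE_NAMES)
    return {name: feats[name] for name in FEATURE_NAMES}
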