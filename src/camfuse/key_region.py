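"""Key-region extraction: threshold an importance map, mask the image.

Pixels whose importance weight reaches the threshold τ are kept; everything
else is masked to black.  The masked image — the "key region" — is what the
downstream SVM sees, resized to a fixed side and flattened into a feature
vector.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .gradcam import ImportanceMap, resize_bilinear

__all__ = ["KeyRegionImage", "threshold_mask", "apply_mask", "feature_vector"]

DEFAULT_TAU = 0.5
DEFAULT_FEATURE_SIDE = 64


@dataclass
class KeyRegionImage:
    """An RGB image with sub-threshold pixels masked to black."""

    image: np.ndarray  # (H, W, 3) in [0, 1], zero where mask == 0
    mask: np.ndarray  # (H, W) bool
    tau: float = DEFAULT_TAU

    def __post_init__(self):
        self.image = np.asarray(self.image, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.image.ndim != 3 or self.image.shape[2] != 3:
            raise ValueError("image must be (H, W, 3)")
        if self.mask.shape != self.image.shape[:2]:
            raise ValueError("mask shape must match image (H, W)")

    @property
    def kept_fraction(self) -> float:
        return float(self.mask.mean())


def threshold_mask(m: ImportanceMap | np.ndarray, tau: float = DEFAULT_TAU) -> np.ndarray:
    """Binary mask of pixels whose importance weight is >= tau."""
    if not 0.0 <= tau <= 1.0:
        raise ValueError(f"tau must lie in [0, 1], got {tau}")
    values = m.values if isinstance(m, ImportanceMap) else np.asarray(m, dtype=float)
    return values >= tau


def apply_mask(image: np.ndarray, mask: np.ndarray, tau: float = DEFAULT_TAU) -> KeyRegionImage:
    """Zero all three channels wherever the mask is 0; keep the rest."""
    image = np.asarray(image, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError("image must be (H, W, 3)")
    if mask.shape != image.shape[:2]:
        raise ValueError(
            f"mask shape {mask.shape} does not match image {image.shape[:2]}"
        )
    if not mask.any():
        warnings.warn("empty mask: key region is entirely black", stacklevel=2)
    return KeyRegionImage(image=image * mask[..., None], mask=mask, tau=tau)


def feature_vector(kr: KeyRegionImage, side: int = DEFAULT_FEATURE_SIDE) -> np.ndarray:
    """Resize the masked image to side×side and flatten (channel-last,
    row-major) into a length 3·side² vector."""
    if side < 8:
        raise ValueError("feature side must be >= 8")
    h, w, _ = kr.image.shape
    if (h, w) == (side, side):
        resized = kr.image
    else:
        resized = np.stack(
            [resize_bilinear(kr.image[..., c], (side, side)) for c in range(3)],
            axis=-1,
        )
    return resized.reshape(-1)
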