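"""Gradient-weighted class-activation maps (Grad-CAM) and map utilities.

The CAM for a target class is built from the target-layer activations
``A_k`` and the gradient of the class logit with respect to them: each
channel is weighted by its spatially averaged gradient (the neuron
importance weight), the weighted sum is rectified, upsampled bilinearly to
the image resolution and min–max normalised to [0, 1].  Maps are the
currency of the whole pipeline: per-pixel importance weights aligned to an
image, persisted as 16-bit PNG plus a JSON sidecar.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image
from skimage.transform import resize as _sk_resize

from .backbones import BackboneOutput

__all__ = [
    "ImportanceMap",
    "channel_weights",
    "compute_cam",
    "iou",
    "save_map",
    "load_map",
]

_SOURCES = ("cnn", "vit", "swin", "fused")


@dataclass
class ImportanceMap:
    """Per-pixel importance weights in [0, 1] aligned to an image."""

    values: np.ndarray  # (H, W) float in [0, 1]
    source: str  # cnn | vit | swin | fused
    image_id: str = ""
    target_class: int = -1

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("importance map must be 2-D")
        if self.source not in _SOURCES:
            raise ValueError(f"source must be one of {_SOURCES}")
        lo, hi = float(self.values.min()), float(self.values.max())
        if lo < -1e-9 or hi > 1 + 1e-9:
            raise ValueError(f"map values outside [0, 1]: [{lo}, {hi}]")
        np.clip(self.values, 0.0, 1.0, out=self.values)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


def channel_weights(out: BackboneOutput) -> np.ndarray:
    """Neuron importance weight per channel: spatial mean of the gradients."""
    return out.gradients.mean(axis=(1, 2))


def minmax_normalize(x: np.ndarray) -> np.ndarray:
    """Scale to [0, 1]; an all-constant (incl. all-zero) array maps to zeros."""
    lo, hi = float(x.min()), float(x.max())
    if hi - lo <= 0:
        return np.zeros_like(x, dtype=float)
    return (x - lo) / (hi - lo)


def resize_bilinear(x: np.ndarray, out_size: tuple[int, int]) -> np.ndarray:
    """Bilinear resampling with output pixel centers at (i + 0.5)/H."""
    if x.shape == tuple(out_size):
        return x.astype(float)
    return _sk_resize(
        x.astype(float), out_size, order=1, mode="edge",
        anti_aliasing=False, preserve_range=True,
    )


def compute_cam(
    out: BackboneOutput,
    out_size: tuple[int, int],
    *,
    source: str = "fused",
    image_id: str = "",
) -> ImportanceMap:
    """Grad-CAM: ReLU of the gradient-weighted channel sum, upsampled and
    min–max normalised.  An all-zero rectified map stays all zeros."""
    if out_size[0] <= 0 or out_size[1] <= 0:
        raise ValueError("out_size must be positive")
    alphas = channel_weights(out)
    raw = np.maximum(np.einsum("k,kuv->uv", alphas, out.activations), 0.0)
    up = resize_bilinear(raw, tuple(out_size))
    up = np.maximum(up, 0.0)  # guard tiny negative interpolation overshoot
    return ImportanceMap(
        values=minmax_normalize(up),
        source=source,
        image_id=image_id,
        target_class=out.target_class,
    )


def iou(a: np.ndarray, b: np.ndarray) -> float:
    """Intersection-over-union of two binary masks; 1.0 if both are empty."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"mask shapes differ: {a.shape} vs {b.shape}")
    union = np.logical_or(a, b).sum()
    if union == 0:
        return 1.0
    return float(np.logical_and(a, b).sum() / union)


# ---------------------------------------------------------------------------
# persistence: 16-bit single-channel PNG + JSON sidecar
# ---------------------------------------------------------------------------

def save_map(m: ImportanceMap, path: str | Path) -> Path:
    """Write a map as 16-bit PNG (value = round(65535·w)) plus a sidecar
    ``<path>.json`` carrying identity metadata."""
    path = Path(path)
    arr = np.round(m.values * 65535.0).astype(np.uint16)
    Image.fromarray(arr).save(path, format="PNG")
    sidecar = {
        "image_id": m.image_id,
        "source": m.source,
        "target_class": m.target_class,
        "dtype_range": [0, 65535],
    }
    Path(str(path) + ".json").write_text(json.dumps(sidecar, indent=2))
    return path


def load_map(path: str | Path) -> ImportanceMap:
    path = Path(path)
    arr = np.asarray(Image.open(path), dtype=np.uint16).astype(float) / 65535.0
    sidecar_path = Path(str(path) + ".json")
    meta = json.loads(sidecar_path.read_text()) if sidecar_path.exists() else {}
    return ImportanceMap(
        values=arr,
        source=meta.get("source", "fused"),
        image_id=meta.get("image_id", path.stem),
        target_class=int(meta.get("target_class", -1)),
    )
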