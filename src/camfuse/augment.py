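"""Stochastic image augmentation with the fixed seven-method protocol.

Seven methods, applied independently with per-method probabilities and
parameter ranges (HF: horizontal flip; BC: brightness/contrast; Shift;
Scale; Rotate; GB: Gaussian blur; Sharpen).  A sampled *plan* — the ordered
list of included methods with their drawn parameters — is recorded with
every augmented image so the transformation is exactly reproducible.

Conventions (ranges alone do not pin these down):

* Shift limits are fractions of each image dimension; vacated pixels are
  filled by reflection.
* BC: ``out = (in − 0.5)·(1 + contrast) + 0.5 + brightness``.
* GB kernel size is an odd integer in [3, 7]; the blur sigma follows the
  usual kernel-size convention ``0.3·((k−1)/2 − 1) + 0.8``.
* Sharpen is an unsharp blend: ``out = (1−α)·in + α·(in + lightness·(in −
  blur(in)))``.

Outputs are clipped to [0, 1] and keep the source resolution.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage as ndi
from skimage.transform import AffineTransform, rotate as _sk_rotate, warp as _sk_warp

__all__ = [
    "AugmentationSpec",
    "default_specs",
    "sample_plan",
    "apply_plan",
    "balance_dataset",
    "read_manifest",
    "write_manifest",
]

METHOD_ORDER = ("HF", "BC", "Shift", "Scale", "Rotate", "GB", "Sharpen")


@dataclass(frozen=True)
class AugmentationSpec:
    """One augmentation method with its parameter limits and probability."""

    method: str
    limits: dict = field(default_factory=dict)
    probability: float = 0.5

    def __post_init__(self):
        if self.method not in METHOD_ORDER:
            raise ValueError(f"unknown augmentation method {self.method!r}")
        if not 0.0 <= self.probability <= 1.0:
            raise ValueError("probability must lie in [0, 1]")


def default_specs() -> list[AugmentationSpec]:
    """The default protocol, in its fixed application order."""
    return [
        AugmentationSpec("HF", {}, 0.5),
        AugmentationSpec(
            "BC", {"brightness": (-0.3, 0.3), "contrast": (-0.3, 0.3)}, 0.4
        ),
        AugmentationSpec("Shift", {"shift": (-0.65, 0.65)}, 0.4),
        AugmentationSpec("Scale", {"scale": (-0.1, 0.1)}, 0.3),
        AugmentationSpec("Rotate", {"angle": (-45.0, 45.0)}, 0.4),
        AugmentationSpec("GB", {"kernel": (3, 7)}, 0.5),
        AugmentationSpec(
            "Sharpen", {"alpha": (0.2, 0.5), "lightness": (0.5, 1.0)}, 0.3
        ),
    ]


def _draw_params(spec: AugmentationSpec, rng: np.random.Generator) -> dict:
    m = spec.method
    if m == "HF":
        return {}
    if m == "BC":
        return {
            "brightness": rng.uniform(*spec.limits["brightness"]),
            "contrast": rng.uniform(*spec.limits["contrast"]),
        }
    if m == "Shift":
        lo, hi = spec.limits["shift"]
        return {"dx": rng.uniform(lo, hi), "dy": rng.uniform(lo, hi)}
    if m == "Scale":
        return {"scale": rng.uniform(*spec.limits["scale"])}
    if m == "Rotate":
        return {"angle": rng.uniform(*spec.limits["angle"])}
    if m == "GB":
        lo, hi = spec.limits["kernel"]
        odd = np.arange(int(lo), int(hi) + 1)
        odd = odd[odd % 2 == 1]
        return {"kernel": int(rng.choice(odd))}
    if m == "Sharpen":
        return {
            "alpha": rng.uniform(*spec.limits["alpha"]),
            "lightness": rng.uniform(*spec.limits["lightness"]),
        }
    raise AssertionError(m)


def sample_plan(
    specs: list[AugmentationSpec] | None = None, rng_seed: int = 0
) -> list[tuple[str, dict]]:
    """Draw an augmentation plan: each method included independently with
    its probability, parameters uniform within their limits.  Deterministic
    given the seed."""
    specs = default_specs() if specs is None else specs
    rng = np.random.default_rng(rng_seed)
    plan = []
    for spec in specs:
        if rng.uniform() < spec.probability:
            plan.append((spec.method, _draw_params(spec, rng)))
    return plan


# ---------------------------------------------------------------------------
# transforms
# ---------------------------------------------------------------------------

def _apply_bc(img: np.ndarray, brightness: float, contrast: float) -> np.ndarray:
    return (img - 0.5) * (1.0 + contrast) + 0.5 + brightness


def _apply_shift(img: np.ndarray, dx: float, dy: float) -> np.ndarray:
    h, w, _ = img.shape
    return ndi.shift(img, (dy * h, dx * w, 0.0), order=1, mode="reflect")


def _apply_scale(img: np.ndarray, scale: float) -> np.ndarray:
    h, w, _ = img.shape
    s = 1.0 + scale
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    tf = (
        AffineTransform(translation=(-cx, -cy))
        + AffineTransform(scale=(s, s))
        + AffineTransform(translation=(cx, cy))
    )
    return _sk_warp(img, tf.inverse, order=1, mode="reflect", preserve_range=True)


def _apply_gb(img: np.ndarray, kernel: int) -> np.ndarray:
    radius = (kernel - 1) / 2.0
    sigma = 0.3 * (radius - 1.0) + 0.8
    return ndi.gaussian_filter(
        img, (sigma, sigma, 0.0), truncate=max(radius / sigma, 1e-6)
    )


def _apply_sharpen(img: np.ndarray, alpha: float, lightness: float) -> np.ndarray:
    blur = ndi.gaussian_filter(img, (1.0, 1.0, 0.0))
    sharpened = img + lightness * (img - blur)
    return (1.0 - alpha) * img + alpha * sharpened


def apply_plan(image: np.ndarray, plan: list[tuple[str, dict]]) -> np.ndarray:
    """Apply a sampled plan to an (H, W, 3) image in [0, 1].

    Methods execute in the fixed protocol order regardless of plan order;
    the result is clipped to [0, 1] and keeps the input resolution.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError("image must be (H, W, 3)")
    by_method = dict(plan)
    for method in METHOD_ORDER:
        if method not in by_method:
            continue
        p = by_method[method]
        if method == "HF":
            img = img[:, ::-1]
        elif method == "BC":
            img = _apply_bc(img, p["brightness"], p["contrast"])
        elif method == "Shift":
            img = _apply_shift(img, p["dx"], p["dy"])
        elif method == "Scale":
            img = _apply_scale(img, p["scale"])
        elif method == "Rotate":
            img = _sk_rotate(img, p["angle"], mode="reflect", preserve_range=True)
        elif method == "GB":
            img = _apply_gb(img, p["kernel"])
        elif method == "Sharpen":
            img = _apply_sharpen(img, p["alpha"], p["lightness"])
    return np.clip(img, 0.0, 1.0)


# ---------------------------------------------------------------------------
# dataset balancing + manifests
# ---------------------------------------------------------------------------

MANIFEST_FIELDS = ("path", "label", "origin", "plan")


def write_manifest(rows: list[dict], path: str | Path) -> Path:
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=MANIFEST_FIELDS)
        writer.writeheader()
        for row in rows:
            writer.writerow({k: row.get(k, "") for k in MANIFEST_FIELDS})
    return path


def read_manifest(path: str | Path) -> list[dict]:
    with Path(path).open(newline="") as fh:
        return list(csv.DictReader(fh))


def balance_dataset(
    manifest: list[dict],
    target_per_class: int,
    rng_seed: int = 0,
    specs: list[AugmentationSpec] | None = None,
) -> list[dict]:
    """Top every class up to ``target_per_class`` entries by adding
    augmented copies of uniformly sampled source images.

    Originals are always retained; each augmented entry records the source
    path and the JSON-encoded plan so it can be regenerated exactly.
    """
    if not manifest:
        raise ValueError("cannot balance an empty manifest")
    rng = np.random.default_rng(rng_seed)
    by_label: dict[str, list[dict]] = {}
    for row in manifest:
        by_label.setdefault(str(row["label"]), []).append(row)
    out = list(manifest)
    for label in sorted(by_label):
        rows = by_label[label]
        if not rows:
            raise ValueError(f"class {label!r} has no images")
        n_extra = target_per_class - len(rows)
        for j in range(max(n_extra, 0)):
            src = rows[int(rng.integers(len(rows)))]
            plan_seed = int(rng.integers(2**31))
            plan = sample_plan(specs, rng_seed=plan_seed)
            out.append(
                {
                    "path": src["path"],
                    "label": label,
                    "origin": "augmented",
                    "plan": json.dumps({"seed": plan_seed, "plan": plan}),
                }
            )
    return out
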