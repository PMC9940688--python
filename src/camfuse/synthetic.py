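"""Synthetic fine-grained image fixtures with complementary-view maps.

Each image is a textured elliptical "insect" on a textured background.  The
class signal is carried by the foreground texture (stripe frequency and
orientation) and by the ellipse eccentricity, so classes differ in fine
detail rather than gross layout — the regime where key-region extraction
matters.  A ground-truth foreground mask is stored with every image.

When ``complementary_views`` is on, every image also gets three importance
maps (labelled cnn / vit / swin) that deliberately emulate the behaviour of
different backbone views: each map highlights a different, partially
overlapping band of the ellipse (≈ half of its area, so no single view
covers more than 60 %), plus low-level background noise.  Their union
covers the whole insect; their pairwise overlaps are non-empty.  This makes
"fusing views recovers the whole object" a designed, testable property of
the fixtures rather than an empirical hope.

A paired generator produces original/rotated image pairs whose per-view
maps are perturbed in complementary directions (each view highlights a
*different* band after augmentation), for robustness analysis of the
fusion rule.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from PIL import Image
from scipy import ndimage as ndi

from .gradcam import ImportanceMap, minmax_normalize, save_map, load_map

__all__ = [
    "SyntheticSpec",
    "SyntheticDataset",
    "RobustnessPair",
    "generate_dataset",
    "make_synthetic_dataset",
    "load_dataset",
    "make_robustness_pairs",
]

VIEWS = ("cnn", "vit", "swin")

# Bands along the ellipse major axis, as fractions of the extent [0, 1].
# Each covers ≈ half the ellipse area (< 0.6), adjacent bands overlap, the
# three together cover the full extent, and no pixel lies in all three.
VIEW_BANDS = ((0.0, 0.42), (0.29, 0.71), (0.58, 1.0))


@dataclass(frozen=True)
class SyntheticSpec:
    """Study conditions for the synthetic fixture set."""

    n_classes: int = 3
    per_class: int = 100
    image_side: int = 64
    eccentricity: tuple[float, float] = (0.35, 0.65)
    fg_freq: tuple[float, float] = (4.0, 9.0)
    bg_freq: tuple[float, float] = (1.0, 2.0)
    noise_sd: float = 0.08
    complementary_views: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.per_class < 2:
            raise ValueError("per_class must be >= 2")
        if self.image_side < 32:
            raise ValueError("image_side must be >= 32")
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")


@dataclass
class SyntheticDataset:
    spec: SyntheticSpec
    images: list  # (H, W, 3) float in [0, 1]
    labels: np.ndarray
    masks: list  # (H, W) bool ground-truth foreground
    image_ids: list
    view_maps: dict = field(default_factory=dict)  # view -> [ImportanceMap]


def _smooth_noise(rng: np.random.Generator, side: int, sigma: float) -> np.ndarray:
    """Band-limited noise field, min-max normalised to [0, 1]."""
    return minmax_normalize(ndi.gaussian_filter(rng.normal(size=(side, side)), sigma))


def _ellipse_geometry(
    rng: np.random.Generator, spec: SyntheticSpec, label: int
) -> dict:
    s = spec.image_side
    # shape and pose are class-free nuisance variation; the class signal
    # lives in the marking positions (see _render_image)
    ecc = rng.uniform(*spec.eccentricity)
    theta = rng.uniform(0.0, np.pi)
    cy = s / 2 + rng.uniform(-0.05, 0.05) * s
    cx = s / 2 + rng.uniform(-0.05, 0.05) * s
    a = 0.30 * s * (1 + rng.uniform(-0.08, 0.08))
    b = a * (1 - ecc)
    return {"cy": cy, "cx": cx, "a": a, "b": b, "phi": theta}


def _ellipse_coords(geom: dict, side: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Return (mask, t, r2): axis coordinate t in [0, 1] and squared radial
    coordinate of every pixel in the ellipse frame."""
    yy, xx = np.mgrid[0:side, 0:side]
    dy, dx = yy - geom["cy"], xx - geom["cx"]
    c, s = np.cos(geom["phi"]), np.sin(geom["phi"])
    u = (dx * c + dy * s) / geom["a"]  # along major axis, in [-1, 1] inside
    v = (-dx * s + dy * c) / geom["b"]
    r2 = u**2 + v**2
    mask = r2 <= 1.0
    t = np.clip((u + 1.0) / 2.0, 0.0, 1.0)
    return mask, t, r2


def _render_image(
    rng: np.random.Generator, spec: SyntheticSpec, label: int, geom: dict
) -> tuple[np.ndarray, np.ndarray]:
    """Textured ellipse on a textured background.

    The stripe texture, tint, eccentricity and orientation are class-free
    nuisance variation; the class is identified solely by a dark marking at
    the centre of axis band ``label % 3`` (a second marking, offset off-axis,
    encodes ``label // 3`` for more than three classes).  Because each view
    map highlights one band, no single view sees more than one class's
    marking position — the class signal is deliberately distributed, so
    recognition genuinely benefits from fusing complementary views.
    """
    s = spec.image_side
    mask, t, _ = _ellipse_coords(geom, s)
    # background: low-frequency texture around mid grey
    bg_sigma = s / (4.0 * rng.uniform(*spec.bg_freq))
    bg = 0.30 + 0.30 * _smooth_noise(rng, s, bg_sigma)
    # foreground: stripes along the major axis, per-image frequency/phase
    freq = rng.uniform(*spec.fg_freq)
    phase = rng.uniform(0, 2 * np.pi)
    yy, xx = np.mgrid[0:s, 0:s]
    c, sn = np.cos(geom["phi"]), np.sin(geom["phi"])
    u_px = ((xx - geom["cx"]) * c + (yy - geom["cy"]) * sn) / s
    fg = 0.60 + 0.30 * np.sin(2 * np.pi * freq * u_px + phase)
    # class marking(s): dark elliptical spots at band-dependent positions
    band_centers = (-0.58, 0.0, 0.58)  # ellipse-frame u of the band centres
    v_norm = (-(xx - geom["cx"]) * sn + (yy - geom["cy"]) * c) / geom["b"]
    u_norm = ((xx - geom["cx"]) * c + (yy - geom["cy"]) * sn) / geom["a"]
    marks = [(band_centers[label % 3], 0.0)]
    if label >= 3:
        marks.append((band_centers[(label // 3) % 3], 0.45))
    spot = np.zeros((s, s), dtype=bool)
    for mu, mv in marks:
        spot |= ((u_norm - mu) ** 2 + 0.35 * (v_norm - mv) ** 2) < 0.06
    fg = np.where(spot & mask, 0.12, fg)
    tint = 0.75 + 0.20 * rng.uniform(size=3)
    img = np.empty((s, s, 3))
    for ch in range(3):
        img[..., ch] = np.where(mask, fg * tint[ch], bg)
    img += rng.normal(0.0, spec.noise_sd, size=img.shape)
    return np.clip(img, 0.0, 1.0), mask


def _view_map(
    rng: np.random.Generator,
    geom: dict,
    side: int,
    band: tuple[float, float],
    view: str,
    image_id: str,
    label: int,
) -> ImportanceMap:
    mask, t, _ = _ellipse_coords(geom, side)
    in_band = mask & (t >= band[0]) & (t <= band[1])
    noise = _smooth_noise(rng, side, side / 10.0)
    values = 0.25 * noise
    values[in_band] = 0.85 + 0.10 * noise[in_band]
    return ImportanceMap(
        values=minmax_normalize(values),
        source=view,
        image_id=image_id,
        target_class=label,
    )


def generate_dataset(spec: SyntheticSpec) -> SyntheticDataset:
    """Generate the fixture set in memory, fully determined by the seed."""
    rng = np.random.default_rng(spec.seed)
    images, labels, masks, ids = [], [], [], []
    view_maps: dict[str, list[ImportanceMap]] = {v: [] for v in VIEWS}
    for label in range(spec.n_classes):
        for i in range(spec.per_class):
            image_id = f"c{label}_i{i:04d}"
            geom = _ellipse_geometry(rng, spec, label)
            img, mask = _render_image(rng, spec, label, geom)
            images.append(img)
            labels.append(label)
            masks.append(mask)
            ids.append(image_id)
            if spec.complementary_views:
                for view, band in zip(VIEWS, VIEW_BANDS):
                    view_maps[view].append(
                        _view_map(rng, geom, spec.image_side, band, view, image_id, label)
                    )
    return SyntheticDataset(
        spec=spec,
        images=images,
        labels=np.asarray(labels),
        masks=masks,
        image_ids=ids,
        view_maps=view_maps if spec.complementary_views else {},
    )


# ---------------------------------------------------------------------------
# disk layout
# ---------------------------------------------------------------------------

def _save_png(arr01: np.ndarray, path: Path) -> None:
    Image.fromarray(np.round(arr01 * 255).astype(np.uint8)).save(path, format="PNG")


def make_synthetic_dataset(spec: SyntheticSpec, out_dir: str | Path) -> Path:
    """Write the fixture set to disk: class-labelled image PNGs, ground-truth
    mask PNGs, per-view 16-bit importance-map PNGs and a CSV manifest."""
    out_dir = Path(out_dir)
    ds = generate_dataset(spec)
    (out_dir / "images").mkdir(parents=True, exist_ok=True)
    (out_dir / "masks").mkdir(exist_ok=True)
    rows = []
    for img, label, mask, image_id in zip(ds.images, ds.labels, ds.masks, ds.image_ids):
        cls_dir = out_dir / "images" / f"class_{label}"
        cls_dir.mkdir(exist_ok=True)
        img_path = cls_dir / f"{image_id}.png"
        _save_png(img, img_path)
        _save_png(mask.astype(float), out_dir / "masks" / f"{image_id}.png")
        rows.append(
            {"path": str(img_path.relative_to(out_dir)), "label": int(label),
             "origin": "original", "plan": ""}
        )
    for view, maps in ds.view_maps.items():
        vdir = out_dir / "maps" / view
        vdir.mkdir(parents=True, exist_ok=True)
        for m in maps:
            save_map(m, vdir / f"{m.image_id}.png")
    manifest = out_dir / "manifest.csv"
    with manifest.open("w") as fh:
        fh.write("path,label,origin,plan\n")
        for r in rows:
            fh.write(f"{r['path']},{r['label']},{r['origin']},\n")
    (out_dir / "spec.json").write_text(json.dumps(asdict(spec), indent=2))
    return out_dir


def load_dataset(root: str | Path) -> SyntheticDataset:
    """Read a dataset written by :func:`make_synthetic_dataset`."""
    root = Path(root)
    spec = SyntheticSpec(**json.loads((root / "spec.json").read_text()))
    # tuples arrive as lists from JSON
    spec = SyntheticSpec(
        **{
            k: tuple(v) if isinstance(v, list) else v
            for k, v in json.loads((root / "spec.json").read_text()).items()
        }
    )
    images, labels, masks, ids = [], [], [], []
    with (root / "manifest.csv").open() as fh:
        next(fh)
        for line in fh:
            path, label, _, _ = line.rstrip("\n").split(",")
            img = np.asarray(Image.open(root / path), dtype=float) / 255.0
            image_id = Path(path).stem
            mask = np.asarray(Image.open(root / "masks" / f"{image_id}.png")) > 127
            images.append(img)
            labels.append(int(label))
            masks.append(mask)
            ids.append(image_id)
    view_maps: dict[str, list[ImportanceMap]] = {}
    maps_dir = root / "maps"
    if maps_dir.exists():
        for vdir in sorted(maps_dir.iterdir()):
            view_maps[vdir.name] = [
                load_map(vdir / f"{image_id}.png") for image_id in ids
            ]
    return SyntheticDataset(
        spec=spec, images=images, labels=np.asarray(labels), masks=masks,
        image_ids=ids, view_maps=view_maps,
    )


# ---------------------------------------------------------------------------
# robustness pairs
# ---------------------------------------------------------------------------

@dataclass
class RobustnessPair:
    """An original/rotated image pair with per-view importance maps.

    The maps of the rotated member live in the rotated frame and each view
    highlights a *different* band than it did on the original — modelling
    augmentation-induced deviation of single-view attention."""

    angle: float  # degrees, counter-clockwise
    image_a: np.ndarray
    image_b: np.ndarray
    mask_a: np.ndarray
    mask_b: np.ndarray
    maps_a: dict
    maps_b: dict


def _rotate_geom(geom: dict, angle_deg: float, side: int) -> dict:
    """Ellipse parameters after rotating the image by ``angle_deg`` CCW
    about the image centre (matching skimage.transform.rotate)."""
    alpha = np.deg2rad(angle_deg)
    c0 = (side - 1) / 2.0
    dy, dx = geom["cy"] - c0, geom["cx"] - c0
    # image CCW rotation in (row, col) coordinates
    cos_a, sin_a = np.cos(alpha), np.sin(alpha)
    dx2 = dx * cos_a + dy * sin_a
    dy2 = -dx * sin_a + dy * cos_a
    return {
        "cy": c0 + dy2, "cx": c0 + dx2,
        "a": geom["a"], "b": geom["b"],
        "phi": geom["phi"] - alpha,
    }


def make_robustness_pairs(
    n_pairs: int = 50,
    image_side: int = 64,
    seed: int = 0,
    angle_range: tuple[float, float] = (-45.0, 45.0),
    spec: SyntheticSpec | None = None,
) -> list[RobustnessPair]:
    """Generate original/rotated pairs with complementary view perturbations."""
    if n_pairs < 1:
        raise ValueError("need at least one pair")
    spec = spec or SyntheticSpec(image_side=image_side, seed=seed)
    rng = np.random.default_rng(seed)
    from skimage.transform import rotate as _sk_rotate

    pairs = []
    for p in range(n_pairs):
        label = int(rng.integers(spec.n_classes))
        geom = _ellipse_geometry(rng, spec, label)
        img_a, mask_a = _render_image(rng, spec, label, geom)
        angle = float(rng.uniform(*angle_range))
        img_b = np.clip(
            _sk_rotate(img_a, angle, mode="reflect", preserve_range=True), 0, 1
        )
        geom_b = _rotate_geom(geom, angle, spec.image_side)
        mask_b, _, _ = _ellipse_coords(geom_b, spec.image_side)
        maps_a, maps_b = {}, {}
        for vi, view in enumerate(VIEWS):
            image_id = f"pair{p:03d}"
            maps_a[view] = _view_map(
                rng, geom, spec.image_side, VIEW_BANDS[vi], view, image_id, label
            )
            # perturbed: after augmentation each view locks onto the next band
            maps_b[view] = _view_map(
                rng, geom_b, spec.image_side, VIEW_BANDS[(vi + 1) % 3], view,
                image_id + "_rot", label,
            )
        pairs.append(
            RobustnessPair(
                angle=angle, image_a=img_a, image_b=img_b,
                mask_a=mask_a, mask_b=mask_b, maps_a=maps_a, maps_b=maps_b,
            )
        )
    return pairs
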