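"""Attention-selection fusion of per-backbone importance maps.

Three importance maps — one per backbone view — are fused into a single
reconstructed map.  The fusion network follows the extract → select →
reconstruct layout of general-purpose CNN image fusion (IFCNN-style):

* CONV1 (7×7) and CONV2 (3×3) extract attention features from each input
  map with weights shared across the inputs;
* the selection rule combines, per feature channel ``k`` and pixel, the
  consensus and the complement of the per-view features ``α_i^k``::

      fused_k = w0 · min_i α_i^k  +  w1 · (max_i α_i^k − min_i α_i^k)

  i.e. a fuzzy-set intersection weighted by ``w0`` plus the union-minus-
  intersection remainder weighted by ``w1`` (``w0 ≥ w1 ≥ 0``), optionally
  followed by *eigen smoothing* — a rank-1 reconstruction of the channel
  stack that suppresses channel-incoherent noise;
* CONV3 (3×3) tunes the selected features and CONV4 (1×1) reconstructs a
  3-channel output, whose luminance becomes the fused importance map.

A convolution-free *map-level* mode applies the selection rule directly to
the raw maps (K = 1); it is the analysis reference and generalises to
subsets of views for ablation studies.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from . import _nn
from .gradcam import ImportanceMap, minmax_normalize

__all__ = [
    "FusionConfig",
    "FeatureStack",
    "FusedStack",
    "FusionNet",
    "extract_features",
    "attention_rec",
    "eigen_smooth",
    "reconstruct",
    "fuse_cams",
    "fuse_maps",
]

N_INPUTS = 3  # one map per backbone view (cnn, vit, swin)


@dataclass(frozen=True)
class FusionConfig:
    """Selection weights and fusion-network sizing.

    ``w0`` boosts the consensus (most important) regions, ``w1`` the
    remaining union; the invariant ``w0 ≥ w1 ≥ 0`` keeps the selection a
    weighted soft union.  ``conv_channels`` are the output widths of
    CONV1–CONV3; the reconstruction output is fixed at 3 channels and the
    number of fused inputs at 3.
    """

    w0: float = 1.0
    w1: float = 0.5
    eigen: bool = True
    conv_channels: tuple[int, int, int] = (64, 64, 64)
    out_channels: int = 3
    n_inputs: int = N_INPUTS
    seed: int = 0

    def __post_init__(self):
        if not (self.w0 >= self.w1 >= 0):
            raise ValueError(f"require w0 >= w1 >= 0, got w0={self.w0}, w1={self.w1}")
        if self.n_inputs != N_INPUTS:
            raise ValueError("the full fusion network takes exactly 3 input maps")
        if self.out_channels != 3:
            raise ValueError("reconstruction output is fixed at 3 channels")


@dataclass
class FeatureStack:
    """Per-input feature maps α_i^k, shape (n_inputs, K, u, v)."""

    maps: np.ndarray
    normalized: bool = False

    def __post_init__(self):
        self.maps = np.asarray(self.maps, dtype=float)
        if self.maps.ndim != 4:
            raise ValueError("feature stack must be (n_inputs, K, u, v)")
        if self.normalized and (
            self.maps.min() < -1e-9 or self.maps.max() > 1 + 1e-9
        ):
            raise ValueError("stack flagged normalized but values leave [0, 1]")


@dataclass
class FusedStack:
    """Selected feature maps f̂^k, shape (K, u, v)."""

    maps: np.ndarray

    def __post_init__(self):
        self.maps = np.asarray(self.maps, dtype=float)
        if self.maps.ndim != 3:
            raise ValueError("fused stack must be (K, u, v)")
        if not np.all(np.isfinite(self.maps)):
            raise ValueError("fused stack contains non-finite values")


class FusionNet:
    """Seeded convolution weights for CONV1–CONV4 (zero biases by default)."""

    def __init__(self, cfg: FusionConfig):
        rng = np.random.default_rng(cfg.seed)
        c1, c2, c3 = cfg.conv_channels
        self.cfg = cfg
        self.params = {
            "conv1.w": _nn.he_normal(rng, (c1, 3, 7, 7), 3 * 49),
            "conv1.b": np.zeros(c1),
            "conv2.w": _nn.he_normal(rng, (c2, c1, 3, 3), c1 * 9),
            "conv2.b": np.zeros(c2),
            "conv3.w": _nn.he_normal(rng, (c3, c2, 3, 3), c2 * 9),
            "conv3.b": np.zeros(c3),
            "conv4.w": _nn.he_normal(rng, (3, c3, 1, 1), c3),
            "conv4.b": np.zeros(3),
        }

    def save_weights(self, path) -> None:
        np.savez(path, **self.params)

    def load_weights(self, path) -> None:
        with np.load(path) as npz:
            for k in self.params:
                if k not in npz.files:
                    raise ValueError(f"weight archive missing {k!r}")
                if npz[k].shape != self.params[k].shape:
                    raise ValueError(f"shape mismatch for {k!r}")
                self.params[k] = npz[k]


def _check_maps(cams: list[ImportanceMap], n_expected: int | None = N_INPUTS) -> None:
    if n_expected is not None and len(cams) != n_expected:
        raise ValueError(f"expected {n_expected} maps, got {len(cams)}")
    if not cams:
        raise ValueError("need at least one importance map")
    shape = cams[0].shape
    for m in cams[1:]:
        if m.shape != shape:
            raise ValueError(f"map shapes differ: {m.shape} vs {shape}")
    sources = [m.source for m in cams]
    if len(set(sources)) != len(sources):
        warnings.warn(
            f"fusing maps with duplicate sources {sources}", stacklevel=3
        )


def extract_features(
    cams: list[ImportanceMap], cfg: FusionConfig, net: FusionNet | None = None
) -> FeatureStack:
    """CONV1 → CONV2 attention-feature extraction, shared across inputs.

    Each single-channel map is replicated to 3 channels before CONV1; the
    CONV2 outputs are per-channel min–max normalised to [0, 1] so they can
    serve as the selection weights α_i^k.
    """
    _check_maps(cams)
    net = net or FusionNet(cfg)
    p = net.params
    feats = []
    for m in cams:
        x = np.repeat(m.values[None], 3, axis=0)
        x = _nn.relu(_nn.conv2d(x, p["conv1.w"], p["conv1.b"]))
        x = _nn.relu(_nn.conv2d(x, p["conv2.w"], p["conv2.b"]))
        feats.append(x)
    stack = np.stack(feats)  # (n, K, u, v)
    normed = np.stack(
        [[minmax_normalize(ch) for ch in inp] for inp in stack]
    )
    return FeatureStack(maps=normed, normalized=True)


def attention_rec(stack: FeatureStack, cfg: FusionConfig) -> FusedStack:
    """Selection rule: w0·intersection + w1·(union − intersection), with
    optional eigen smoothing; output clipped to [0, w0].

    Intersection/union over the continuous α are the elementwise min/max
    (fuzzy-set semantics).  Works for any number of input views ≥ 1, which
    is what the two-view ablation uses.
    """
    if not stack.normalized:
        raise ValueError("attention_rec requires a normalized feature stack")
    inter = stack.maps.min(axis=0)
    union = stack.maps.max(axis=0)
    fused = cfg.w0 * inter + cfg.w1 * (union - inter)
    if cfg.eigen:
        fused = eigen_smooth(fused)
    return FusedStack(maps=np.clip(fused, 0.0, cfg.w0))


def eigen_smooth(stack: np.ndarray) -> np.ndarray:
    """Rank-1 reconstruction of a (K, u, v) channel stack.

    The stack is flattened to K×(u·v), approximated by its leading singular
    triplet (sign fixed so the spatial component correlates nonnegatively
    with the channel-mean map), reshaped back and rectified.  Stacks that
    are already rank 1 are fixed points.
    """
    k, u, v = stack.shape
    x = stack.reshape(k, u * v)
    uu, ss, vt = np.linalg.svd(x, full_matrices=False)
    u1, s1, v1 = uu[:, 0], ss[0], vt[0]
    if np.dot(v1, x.mean(axis=0)) < 0:
        u1, v1 = -u1, -v1
    rec = s1 * np.outer(u1, v1)
    return np.maximum(rec.reshape(k, u, v), 0.0)


def reconstruct(fused: FusedStack, cfg: FusionConfig, net: FusionNet | None = None) -> np.ndarray:
    """CONV3 tuning + CONV4 3-channel reconstruction, min–max normalised."""
    net = net or FusionNet(cfg)
    p = net.params
    k = fused.maps.shape[0]
    w3 = p["conv3.w"]
    if w3.shape[1] != k:
        raise ValueError(
            f"fused stack has {k} channels but CONV3 expects {w3.shape[1]}"
        )
    x = _nn.relu(_nn.conv2d(fused.maps, w3, p["conv3.b"]))
    x = _nn.conv2d(x, p["conv4.w"], p["conv4.b"])
    return minmax_normalize(x)


def fuse_maps(
    cams: list[ImportanceMap],
    cfg: FusionConfig,
    *,
    mode: str = "map",
    net: FusionNet | None = None,
    image_id: str = "",
) -> ImportanceMap:
    """Fuse 1–3 importance maps into one ``source='fused'`` map.

    ``mode='map'`` applies the selection rule directly to the raw maps
    (K = 1, no convolutions) — the convolution-free reference that also
    serves ablation subsets.  ``mode='network'`` runs the full extract →
    select → reconstruct network (requires exactly 3 inputs) and takes the
    luminance (channel mean) of the reconstruction.
    """
    if mode == "map":
        _check_maps(cams, n_expected=None)
        stack = FeatureStack(
            maps=np.stack([m.values[None] for m in cams]), normalized=True
        )
        fused = attention_rec(stack, cfg)
        values = minmax_normalize(fused.maps[0])
    elif mode == "network":
        net = net or FusionNet(cfg)
        stack = extract_features(cams, cfg, net)
        fused = attention_rec(stack, cfg)
        rgb = reconstruct(fused, cfg, net)
        values = minmax_normalize(rgb.mean(axis=0))
    else:
        raise ValueError(f"unknown fusion mode {mode!r}")
    tc = cams[0].target_class if len({m.target_class for m in cams}) == 1 else -1
    return ImportanceMap(
        values=values,
        source="fused",
        image_id=image_id or cams[0].image_id,
        target_class=tc,
    )


def fuse_cams(
    cams: list[ImportanceMap],
    cfg: FusionConfig,
    *,
    mode: str = "network",
    net: FusionNet | None = None,
    image_id: str = "",
) -> ImportanceMap:
    """Fuse exactly three backbone maps (the standard three-view pipeline)."""
    _check_maps(cams, n_expected=N_INPUTS)
    return fuse_maps(cams, cfg, mode=mode, net=net, image_id=image_id)
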