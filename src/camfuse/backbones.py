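"""Tiny CNN-, ViT- and Swin-style backbones with a uniform Grad-CAM contract.

Each backbone exposes the same three-part interface:

* ``features(image)`` — forward pass up to the CAM target layer, returning a
  spatial activation tensor ``A`` of shape ``(C*, u, v)``.  For the CNN this
  is the last residual-stage output; for the transformer variants it is the
  output of the *patch transformation* step, which drops the class token
  (ViT) and arranges the remaining tokens row-major into a square/rectangular
  spatial grid so class-activation mapping applies to token tensors.
* ``head(A)`` — global average pool over ``(u, v)`` followed by a linear
  classifier, producing pre-softmax logits.
* ``head_grad(A, c)`` — the exact gradient ``∂ logit_c / ∂ A``.  Because the
  head is GAP + linear this is ``W[c] / (u·v)`` broadcast over the spatial
  grid; an independent finite-difference check lives in the test suite.

Models are deliberately small (a few stages/blocks, configurable) — the
recognition method under study depends on the *structure* of the activation
maps, not on ImageNet-scale weights.  All initialisation is seeded and
bit-reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import yaml

from . import _nn

__all__ = [
    "ConfigurationError",
    "BackboneSpec",
    "BackboneOutput",
    "Backbone",
    "TinyCNN",
    "TinyViT",
    "TinySwin",
    "build_backbone",
    "patch_transform_vit",
    "inverse_patch_transform_vit",
    "patch_transform_swin",
    "inverse_patch_transform_swin",
    "forward_with_grads",
]


class ConfigurationError(ValueError):
    """Raised when a backbone spec violates a geometric constraint."""


@dataclass(frozen=True)
class BackboneSpec:
    """Geometry and sizing of one backbone.

    Parameters
    ----------
    family : {"cnn", "vit", "swin"}
    input_size : (H, W) expected image resolution.
    channels : input image channels (3 for RGB).
    patch_size : ViT patch side P; the token count is N = H·W / P².
    window_down : Swin total downsampling factor (default 32, so the final
        grid is H/32 × W/32 with 8·embed_dim channels).
    embed_dim : stem width (CNN first-stage channels / transformer embedding).
    depth : CNN residual stages (each halves the resolution) or transformer
        blocks at the final resolution.
    num_classes : classifier output size.
    seed : weight-initialisation seed; same seed ⇒ bit-identical weights.
    """

    family: str
    input_size: tuple[int, int] = (64, 64)
    channels: int = 3
    patch_size: int = 8
    window_down: int = 32
    embed_dim: int = 16
    depth: int = 2
    num_classes: int = 3
    seed: int = 0

    def __post_init__(self):
        h, w = self.input_size
        if self.family not in ("cnn", "vit", "swin"):
            raise ConfigurationError(f"unknown backbone family {self.family!r}")
        if h <= 0 or w <= 0 or self.channels <= 0 or self.embed_dim <= 0:
            raise ConfigurationError("sizes must be positive")
        if self.depth < 1 or self.num_classes < 1:
            raise ConfigurationError("depth and num_classes must be >= 1")
        if self.family == "vit":
            p = self.patch_size
            if p <= 0 or (h * w) % (p * p) != 0 or h % p != 0 or w % p != 0:
                raise ConfigurationError(
                    f"vit: input {h}x{w} is not divisible into {p}x{p} patches"
                )
            n = (h * w) // (p * p)
            s = int(round(np.sqrt(n)))
            if s * s != n:
                raise ConfigurationError(
                    f"vit: patch count N={n} is not a perfect square"
                )
        if self.family == "swin":
            d = self.window_down
            if d < 4 or (d & (d - 1)) != 0:
                raise ConfigurationError(
                    f"swin: window_down={d} must be a power of two >= 4"
                )
            if h % d != 0 or w % d != 0:
                raise ConfigurationError(
                    f"swin: input {h}x{w} not divisible by window_down={d}"
                )

    # -- serialisation -----------------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        d["input_size"] = list(self.input_size)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "BackboneSpec":
        d = dict(d)
        d["input_size"] = tuple(d["input_size"])
        return cls(**d)

    def save(self, path: str | Path) -> None:
        path = Path(path)
        text = (
            yaml.safe_dump(self.to_dict())
            if path.suffix in (".yml", ".yaml")
            else json.dumps(self.to_dict(), indent=2)
        )
        path.write_text(text)

    @classmethod
    def load(cls, path: str | Path) -> "BackboneSpec":
        path = Path(path)
        raw = path.read_text()
        d = yaml.safe_load(raw) if path.suffix in (".yml", ".yaml") else json.loads(raw)
        return cls.from_dict(d)


@dataclass
class BackboneOutput:
    """Activations and class-score gradients at the CAM target layer."""

    activations: np.ndarray  # (C*, u, v)
    gradients: np.ndarray  # same shape, d class_scores[target_class] / dA
    class_scores: np.ndarray  # pre-softmax logits
    target_class: int

    def __post_init__(self):
        if self.activations.shape != self.gradients.shape:
            raise ValueError("activations and gradients must share a shape")


# ---------------------------------------------------------------------------
# patch transformation (token tensor -> spatial map)
# ---------------------------------------------------------------------------

def patch_transform_vit(tokens: np.ndarray) -> np.ndarray:
    """Reshape ViT output tokens to a spatial map, dropping the class token.

    ``tokens`` has shape (N+1, C'): the class token first, then N patch
    tokens in row-major order.  N must be a perfect square; the result has
    shape (C', √N, √N).
    """
    if tokens.ndim != 2 or tokens.shape[0] < 2:
        raise ValueError("expected at least a class token plus one patch token")
    n = tokens.shape[0] - 1
    side = int(round(np.sqrt(n)))
    if side * side != n:
        raise ValueError(f"patch count {n} is not a perfect square")
    return np.ascontiguousarray(
        tokens[1:].reshape(side, side, tokens.shape[1]).transpose(2, 0, 1)
    )


def inverse_patch_transform_vit(spatial: np.ndarray) -> np.ndarray:
    """Invert :func:`patch_transform_vit` back to the N patch tokens."""
    c, h, w = spatial.shape
    return np.ascontiguousarray(spatial.transpose(1, 2, 0).reshape(h * w, c))


def patch_transform_swin(tokens: np.ndarray, grid: tuple[int, int]) -> np.ndarray:
    """Reshape Swin output tokens (h·w, C') row-major into (C', h, w)."""
    h, w = grid
    if tokens.ndim != 2 or tokens.shape[0] != h * w:
        raise ValueError(
            f"token count {tokens.shape[0]} does not match declared grid {h}x{w}"
        )
    return np.ascontiguousarray(tokens.reshape(h, w, tokens.shape[1]).transpose(2, 0, 1))


def inverse_patch_transform_swin(spatial: np.ndarray) -> np.ndarray:
    c, h, w = spatial.shape
    return np.ascontiguousarray(spatial.transpose(1, 2, 0).reshape(h * w, c))


# ---------------------------------------------------------------------------
# models
# ---------------------------------------------------------------------------

class Backbone:
    """Base class: parameter store, GAP+linear head, weight persistence."""

    target_layer: str = "features"

    def __init__(self, spec: BackboneSpec):
        self.spec = spec
        self.params: dict[str, np.ndarray] = {}
        self._rng = np.random.default_rng(spec.seed)

    # subclasses set self.feature_channels then call this
    def _init_head(self, feature_channels: int) -> None:
        self.feature_channels = feature_channels
        self.params["head.w"] = _nn.glorot_uniform(
            self._rng,
            (self.spec.num_classes, feature_channels),
            feature_channels,
            self.spec.num_classes,
        )
        self.params["head.b"] = np.zeros(self.spec.num_classes)

    def features(self, image: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def head(self, acts: np.ndarray) -> np.ndarray:
        pooled = acts.mean(axis=(1, 2))
        return self.params["head.w"] @ pooled + self.params["head.b"]

    def head_grad(self, acts: np.ndarray, target_class: int) -> np.ndarray:
        _, u, v = acts.shape
        w = self.params["head.w"][target_class]
        return np.broadcast_to(w[:, None, None] / (u * v), acts.shape).copy()

    def _check_image(self, image: np.ndarray) -> np.ndarray:
        h, w = self.spec.input_size
        if image.shape != (self.spec.channels, h, w):
            raise ValueError(
                f"image shape {image.shape} does not match spec "
                f"({self.spec.channels}, {h}, {w})"
            )
        return np.asarray(image, dtype=float)

    # -- persistence -------------------------------------------------------
    def save_weights(self, path: str | Path) -> None:
        np.savez(path, **self.params)

    def load_weights(self, path: str | Path) -> None:
        with np.load(path) as npz:
            loaded = {k: npz[k] for k in npz.files}
        missing = set(self.params) - set(loaded)
        if missing:
            raise ValueError(f"weight archive missing layers: {sorted(missing)}")
        for k, v in loaded.items():
            if k in self.params and self.params[k].shape != v.shape:
                raise ValueError(f"shape mismatch for layer {k!r}")
        self.params.update(loaded)


class TinyCNN(Backbone):
    """Residual CNN: stem conv, then ``depth`` stride-2 stages of one
    residual block each.  Stage i has embed_dim·2^i channels."""

    target_layer = "stage_last"

    def __init__(self, spec: BackboneSpec):
        super().__init__(spec)
        rng, p = self._rng, self.params
        c_in, width = spec.channels, spec.embed_dim
        p["stem.w"] = _nn.he_normal(rng, (width, c_in, 3, 3), c_in * 9)
        p["stem.b"] = np.zeros(width)
        c = width
        for i in range(spec.depth):
            co = width * (2**i)
            p[f"down{i}.w"] = _nn.he_normal(rng, (co, c, 3, 3), c * 9)
            p[f"down{i}.b"] = np.zeros(co)
            for j in (1, 2):
                p[f"res{i}.conv{j}.w"] = _nn.he_normal(rng, (co, co, 3, 3), co * 9)
                p[f"res{i}.conv{j}.b"] = np.zeros(co)
            c = co
        self._init_head(c)

    def features(self, image: np.ndarray) -> np.ndarray:
        x = self._check_image(image)
        p = self.params
        x = _nn.relu(_nn.conv2d(x, p["stem.w"], p["stem.b"]))
        for i in range(self.spec.depth):
            x = _nn.relu(_nn.conv2d(x, p[f"down{i}.w"], p[f"down{i}.b"], stride=2))
            y = _nn.relu(_nn.conv2d(x, p[f"res{i}.conv1.w"], p[f"res{i}.conv1.b"]))
            y = _nn.conv2d(y, p[f"res{i}.conv2.w"], p[f"res{i}.conv2.b"])
            x = _nn.relu(x + y)
        return x


class TinyViT(Backbone):
    """Patch-embedding transformer with a class token.

    The CAM target is the patch-transformed output of the last block: the
    class token is dropped and the N patch tokens become a √N×√N map with
    embed_dim channels.
    """

    target_layer = "patch_transform"
    n_heads = 2

    def __init__(self, spec: BackboneSpec):
        super().__init__(spec)
        rng, p = self._rng, self.params
        d = spec.embed_dim
        patch_dim = spec.channels * spec.patch_size**2
        h, w = spec.input_size
        n = (h * w) // spec.patch_size**2
        self.n_patches = n
        self.grid_side = int(round(np.sqrt(n)))
        p["embed.w"] = _nn.glorot_uniform(rng, (patch_dim, d), patch_dim, d)
        p["embed.b"] = np.zeros(d)
        p["cls_token"] = rng.normal(0.0, 0.02, size=(1, d))
        p["pos_embed"] = rng.normal(0.0, 0.02, size=(n + 1, d))
        for i in range(spec.depth):
            p[f"blk{i}.ln1.g"] = np.ones(d)
            p[f"blk{i}.ln1.b"] = np.zeros(d)
            p[f"blk{i}.qkv.w"] = _nn.glorot_uniform(rng, (d, 3 * d), d, 3 * d)
            p[f"blk{i}.qkv.b"] = np.zeros(3 * d)
            p[f"blk{i}.proj.w"] = _nn.glorot_uniform(rng, (d, d), d, d)
            p[f"blk{i}.proj.b"] = np.zeros(d)
            p[f"blk{i}.ln2.g"] = np.ones(d)
            p[f"blk{i}.ln2.b"] = np.zeros(d)
            p[f"blk{i}.mlp1.w"] = _nn.glorot_uniform(rng, (d, 2 * d), d, 2 * d)
            p[f"blk{i}.mlp1.b"] = np.zeros(2 * d)
            p[f"blk{i}.mlp2.w"] = _nn.glorot_uniform(rng, (2 * d, d), 2 * d, d)
            p[f"blk{i}.mlp2.b"] = np.zeros(d)
        p["ln_f.g"] = np.ones(d)
        p["ln_f.b"] = np.zeros(d)
        self._init_head(d)

    def _patchify(self, image: np.ndarray) -> np.ndarray:
        ps = self.spec.patch_size
        c, h, w = image.shape
        # (gy, gx, c*ps*ps) row-major patches
        patches = (
            image.reshape(c, h // ps, ps, w // ps, ps)
            .transpose(1, 3, 0, 2, 4)
            .reshape(self.n_patches, c * ps * ps)
        )
        return patches

    def tokens(self, image: np.ndarray) -> np.ndarray:
        x = self._check_image(image)
        p = self.params
        tok = _nn.linear(self._patchify(x), p["embed.w"], p["embed.b"])
        tok = np.concatenate([p["cls_token"], tok], axis=0) + p["pos_embed"]
        for i in range(self.spec.depth):
            y = _nn.layer_norm(tok, p[f"blk{i}.ln1.g"], p[f"blk{i}.ln1.b"])
            tok = tok + _nn.multi_head_attention(
                y,
                p[f"blk{i}.qkv.w"],
                p[f"blk{i}.qkv.b"],
                p[f"blk{i}.proj.w"],
                p[f"blk{i}.proj.b"],
                self.n_heads,
            )
            y = _nn.layer_norm(tok, p[f"blk{i}.ln2.g"], p[f"blk{i}.ln2.b"])
            y = _nn.gelu(_nn.linear(y, p[f"blk{i}.mlp1.w"], p[f"blk{i}.mlp1.b"]))
            tok = tok + _nn.linear(y, p[f"blk{i}.mlp2.w"], p[f"blk{i}.mlp2.b"])
        return _nn.layer_norm(tok, p["ln_f.g"], p["ln_f.b"])

    def features(self, image: np.ndarray) -> np.ndarray:
        return patch_transform_vit(self.tokens(image))


class TinySwin(Backbone):
    """Hierarchical windowed transformer.

    A 4×4 patch embedding is followed by log2(window_down/4) stages, each
    one shifted-window attention block plus a 2×2 patch merge that doubles
    the channel width, then ``depth`` blocks at the final resolution. With
    window_down = 32 the output grid is H/32 × W/32 with 8·embed_dim
    channels; the patch transformation reshapes those tokens into the CAM
    target map.
    """

    target_layer = "patch_transform"
    n_heads = 2
    window = 4

    def __init__(self, spec: BackboneSpec):
        super().__init__(spec)
        rng, p = self._rng, self.params
        self.n_merges = int(np.log2(spec.window_down // 4))
        h, w = spec.input_size
        self.grid = (h // spec.window_down, w // spec.window_down)
        d = spec.embed_dim
        patch_dim = spec.channels * 16
        p["embed.w"] = _nn.glorot_uniform(rng, (patch_dim, d), patch_dim, d)
        p["embed.b"] = np.zeros(d)
        n_blocks = self.n_merges + spec.depth
        dims = [d * 2**min(i, self.n_merges) for i in range(n_blocks + 1)]
        self._block_dims = dims
        for i in range(n_blocks):
            di = dims[i] if i < self.n_merges else dims[self.n_merges]
            self._add_block(i, di)
        for i in range(self.n_merges):
            di = dims[i]
            p[f"merge{i}.w"] = _nn.glorot_uniform(rng, (4 * di, 2 * di), 4 * di, 2 * di)
            p[f"merge{i}.b"] = np.zeros(2 * di)
        self._init_head(d * 2**self.n_merges)

    def _add_block(self, i: int, d: int) -> None:
        rng, p = self._rng, self.params
        p[f"blk{i}.ln1.g"] = np.ones(d)
        p[f"blk{i}.ln1.b"] = np.zeros(d)
        p[f"blk{i}.qkv.w"] = _nn.glorot_uniform(rng, (d, 3 * d), d, 3 * d)
        p[f"blk{i}.qkv.b"] = np.zeros(3 * d)
        p[f"blk{i}.proj.w"] = _nn.glorot_uniform(rng, (d, d), d, d)
        p[f"blk{i}.proj.b"] = np.zeros(d)
        p[f"blk{i}.ln2.g"] = np.ones(d)
        p[f"blk{i}.ln2.b"] = np.zeros(d)
        p[f"blk{i}.mlp1.w"] = _nn.glorot_uniform(rng, (d, 2 * d), d, 2 * d)
        p[f"blk{i}.mlp1.b"] = np.zeros(2 * d)
        p[f"blk{i}.mlp2.w"] = _nn.glorot_uniform(rng, (2 * d, d), 2 * d, d)
        p[f"blk{i}.mlp2.b"] = np.zeros(d)

    def _window_attention(self, x: np.ndarray, i: int, shift: int) -> np.ndarray:
        """x: (h, w, d) grid; windowed MHA with optional cyclic shift."""
        p = self.params
        h, w, d = x.shape
        ws = max(
            s for s in range(1, min(h, w, self.window) + 1) if h % s == 0 and w % s == 0
        )
        shift = min(shift, ws // 2)
        if shift:
            x = np.roll(x, (-shift, -shift), axis=(0, 1))
        xw = x.reshape(h // ws, ws, w // ws, ws, d).transpose(0, 2, 1, 3, 4)
        out = np.empty_like(xw)
        for a in range(xw.shape[0]):
            for b in range(xw.shape[1]):
                tok = xw[a, b].reshape(ws * ws, d)
                y = _nn.layer_norm(tok, p[f"blk{i}.ln1.g"], p[f"blk{i}.ln1.b"])
                tok = tok + _nn.multi_head_attention(
                    y,
                    p[f"blk{i}.qkv.w"],
                    p[f"blk{i}.qkv.b"],
                    p[f"blk{i}.proj.w"],
                    p[f"blk{i}.proj.b"],
                    self.n_heads,
                )
                y = _nn.layer_norm(tok, p[f"blk{i}.ln2.g"], p[f"blk{i}.ln2.b"])
                y = _nn.gelu(_nn.linear(y, p[f"blk{i}.mlp1.w"], p[f"blk{i}.mlp1.b"]))
                tok = tok + _nn.linear(y, p[f"blk{i}.mlp2.w"], p[f"blk{i}.mlp2.b"])
                out[a, b] = tok.reshape(ws, ws, d)
        x = out.transpose(0, 2, 1, 3, 4).reshape(h, w, d)
        if shift:
            x = np.roll(x, (shift, shift), axis=(0, 1))
        return x

    def tokens(self, image: np.ndarray) -> np.ndarray:
        x = self._check_image(image)
        p = self.params
        c, h, w = x.shape
        patches = (
            x.reshape(c, h // 4, 4, w // 4, 4)
            .transpose(1, 3, 0, 2, 4)
            .reshape(h // 4, w // 4, c * 16)
        )
        g = _nn.linear(patches, p["embed.w"], p["embed.b"])  # (h/4, w/4, d)
        blk = 0
        for m in range(self.n_merges):
            shift = (self.window // 2) if blk % 2 == 1 else 0
            g = self._window_attention(g, blk, shift)
            blk += 1
            gh, gw, d = g.shape
            merged = (
                g.reshape(gh // 2, 2, gw // 2, 2, d)
                .transpose(0, 2, 1, 3, 4)
                .reshape(gh // 2, gw // 2, 4 * d)
            )
            g = _nn.linear(merged, p[f"merge{m}.w"], p[f"merge{m}.b"])
        for _ in range(self.spec.depth):
            shift = (self.window // 2) if blk % 2 == 1 else 0
            g = self._window_attention(g, blk, shift)
            blk += 1
        gh, gw, d = g.shape
        return g.reshape(gh * gw, d)

    def features(self, image: np.ndarray) -> np.ndarray:
        return patch_transform_swin(self.tokens(image), self.grid)


_FAMILIES = {"cnn": TinyCNN, "vit": TinyViT, "swin": TinySwin}


def build_backbone(spec: BackboneSpec) -> Backbone:
    """Construct a seeded backbone for ``spec.family``."""
    return _FAMILIES[spec.family](spec)


def forward_with_grads(
    model: Backbone, image: np.ndarray, target_class: int | str = "argmax"
) -> BackboneOutput:
    """Forward an image and return target-layer activations with the gradient
    of the chosen class logit with respect to them."""
    acts = model.features(image)
    scores = model.head(acts)
    if target_class == "argmax":
        idx = int(np.argmax(scores))
    else:
        idx = int(target_class)
        if not 0 <= idx < scores.shape[0]:
            raise ValueError(f"class index {idx} out of range [0, {scores.shape[0]})")
    grads = model.head_grad(acts, idx)
    return BackboneOutput(
        activations=acts, gradients=grads, class_scores=scores, target_class=idx
    )
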