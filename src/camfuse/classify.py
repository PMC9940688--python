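"""SVM classification of key-region features, with the view-ablation protocol.

The classifier stage is deliberately light: per-feature standardisation
(fit on the training split only) followed by a support-vector machine with
an RBF kernel by default — well suited to the few-shot regime where some
classes or growth stages have scarce images.  The ablation protocol fuses
every requested subset of backbone views (min/max selection generalises to
any subset size), extracts key regions, and reports scores per subset.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from sklearn.model_selection import train_test_split
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .fusion import FusionConfig, fuse_maps
from .gradcam import ImportanceMap
from .key_region import DEFAULT_FEATURE_SIDE, DEFAULT_TAU, apply_mask, feature_vector, threshold_mask
from .metrics import ClassificationReport, classification_report

__all__ = [
    "SplitSpec",
    "SvmConfig",
    "split_indices",
    "fit",
    "evaluate",
    "keyregion_features",
    "ablation",
    "ablation_to_csv",
]


@dataclass(frozen=True)
class SplitSpec:
    train_fraction: float = 0.8
    stratified: bool = True
    seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must lie strictly between 0 and 1")


@dataclass(frozen=True)
class SvmConfig:
    kernel: str = "rbf"
    C: float = 1.0
    gamma: float | str = "scale"
    standardize: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.kernel not in ("rbf", "linear"):
            raise ValueError("kernel must be 'rbf' or 'linear'")
        if self.C <= 0:
            raise ValueError("C must be positive")


def split_indices(labels, spec: SplitSpec) -> tuple[np.ndarray, np.ndarray]:
    """Train/test index split, stratified by class when requested."""
    labels = np.asarray(labels)
    idx = np.arange(labels.size)
    return train_test_split(
        idx,
        train_size=spec.train_fraction,
        stratify=labels if spec.stratified else None,
        random_state=spec.seed,
        shuffle=True,
    )


def fit(features: np.ndarray, labels, cfg: SvmConfig = SvmConfig()) -> Pipeline:
    """Fit the (scaler +) SVM pipeline.  Standardisation statistics come
    from the supplied training data only."""
    features = np.asarray(features, dtype=float)
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    if classes.size < 2:
        raise ValueError("need at least two classes to fit a classifier")
    if counts.min() < 2:
        raise ValueError("need at least two samples per class")
    steps = []
    if cfg.standardize:
        steps.append(("scale", StandardScaler()))
    steps.append(
        (
            "svm",
            SVC(
                kernel=cfg.kernel,
                C=cfg.C,
                gamma=cfg.gamma,
                decision_function_shape="ovr",
                random_state=cfg.seed,
            ),
        )
    )
    model = Pipeline(steps)
    model.fit(features, labels)
    return model


def evaluate(model: Pipeline, features: np.ndarray, labels) -> ClassificationReport:
    features = np.asarray(features, dtype=float)
    labels = np.asarray(labels)
    if features.shape[0] == 0:
        raise ValueError("cannot evaluate on an empty set")
    n_expected = model[-1].n_features_in_ if len(model) == 1 else model[0].n_features_in_
    if features.shape[1] != n_expected:
        raise ValueError(
            f"feature dimension {features.shape[1]} != fitted dimension {n_expected}"
        )
    y_pred = model.predict(features)
    return classification_report(labels, y_pred)


def keyregion_features(
    images: list[np.ndarray],
    maps: list[ImportanceMap],
    tau: float = DEFAULT_TAU,
    side: int = DEFAULT_FEATURE_SIDE,
) -> np.ndarray:
    """Threshold each map, mask its image, and stack the flattened
    key-region feature vectors."""
    if len(images) != len(maps):
        raise ValueError("images and maps must pair up")
    feats = []
    import warnings as _warnings

    for img, m in zip(images, maps):
        mask = threshold_mask(m, tau)
        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore")  # empty masks degrade, not crash
            kr = apply_mask(img, mask, tau)
        feats.append(feature_vector(kr, side))
    return np.stack(feats)


def _fuse_subset(
    view_maps: dict[str, list[ImportanceMap]],
    subset: tuple[str, ...],
    cfg: FusionConfig,
    i: int,
) -> ImportanceMap:
    maps = [view_maps[v][i] for v in subset]
    return fuse_maps(maps, cfg, mode="map")


def ablation(
    subsets: list[tuple[str, ...]],
    images: list[np.ndarray],
    labels,
    view_maps: dict[str, list[ImportanceMap]],
    fusion_cfg: FusionConfig = FusionConfig(),
    tau: float = DEFAULT_TAU,
    side: int = DEFAULT_FEATURE_SIDE,
    split: SplitSpec = SplitSpec(),
    svm: SvmConfig = SvmConfig(),
) -> dict[str, ClassificationReport]:
    """Classification reports for every requested subset of views.

    A singleton subset reduces exactly to the single-backbone pipeline
    (min = max = identity in the selection rule); larger subsets are fused
    map-level.  The same split is used for every subset so the comparison
    isolates the fused representation.
    """
    labels = np.asarray(labels)
    if not subsets:
        raise ValueError("need at least one view subset")
    for s in subsets:
        if not s:
            raise ValueError("empty view subset")
        for v in s:
            if v not in view_maps:
                raise ValueError(f"unknown view {v!r}")
    tr, te = split_indices(labels, split)
    out: dict[str, ClassificationReport] = {}
    for subset in subsets:
        key = "+".join(sorted(subset))
        fused = [
            _fuse_subset(view_maps, tuple(sorted(subset)), fusion_cfg, i)
            for i in range(len(images))
        ]
        feats = keyregion_features(images, fused, tau, side)
        model = fit(feats[tr], labels[tr], svm)
        out[key] = evaluate(model, feats[te], labels[te])
    return out


def ablation_to_csv(reports: dict[str, ClassificationReport], path: str | Path) -> Path:
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["Backbones", "F1", "Rec", "Pre", "Acc"])
        for key, rep in reports.items():
            writer.writerow([key, rep.f1, rep.recall, rep.precision, rep.accuracy])
    return path
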