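"""Backbone / prediction-layer models for disease detection audits.

A *backbone* maps raw inputs (latent feature vectors or small grayscale
images) to a d-dimensional penultimate representation; *prediction heads* are
linear layers reading that shared representation.  The disease head emits one
sigmoid score per condition (multi-label); optional sex and race heads turn a
single-task model into a multitask one.  Backbones can be frozen, after which
training passes leave their parameters bitwise unchanged — the property the
linear-probe test depends on.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Any

import numpy as np

from . import nn
from ._densenet import DenseNet121Features
from .synthetic import Cohort, GROUPS, SEXES

__all__ = [
    "Backbone",
    "ModelBundle",
    "build_backbone",
    "build_generic_pretrained",
    "train_single_task",
    "train_multitask",
    "freeze",
    "extract_features",
    "predict_logits",
    "predict_proba",
    "cohort_inputs",
]

BACKBONE_KINDS = ("mlp", "small_cnn", "random_init", "densenet121", "external")


@dataclass
class Backbone:
    kind: str
    input_spec: dict
    feature_dim: int
    seed: int
    net: Any
    input_type: str               # 'features' or 'images'
    frozen: bool = False
    tag: str = ""                 # free-form identifier used in panel tables

    def _prep(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=np.float64)
        if self.input_type == "images" and x.ndim == 3:
            x = x[:, None]
        return x

    def features(self, x: np.ndarray, batch_size: int = 256) -> np.ndarray:
        """Penultimate activations, shape (n, feature_dim)."""
        x = self._prep(x)
        if isinstance(self.net, DenseNet121Features):
            chunks = [self.net.forward(x[i : i + 32]) for i in range(0, len(x), 32)]
            return np.concatenate(chunks)
        if callable(self.net) and not isinstance(self.net, nn.Sequential):
            return np.asarray(self.net(x), dtype=np.float64)
        out = [
            self.net.forward(x[i : i + batch_size]) for i in range(0, len(x), batch_size)
        ]
        return np.concatenate(out)

    @property
    def trainable(self) -> bool:
        return (
            not self.frozen
            and isinstance(self.net, nn.Sequential)
            and self.kind not in ("random_init",)
        )

    def params(self) -> list[np.ndarray]:
        if isinstance(self.net, nn.Sequential):
            return self.net.params()
        if isinstance(self.net, DenseNet121Features):
            return self.net.all_params()
        return []

    def checksum(self) -> str:
        return nn.params_checksum(self.params())


def build_backbone(
    kind: str,
    input_spec: dict,
    feature_dim: int = 32,
    seed: int = 0,
    hidden: int = 64,
) -> Backbone:
    """Construct an initialized, unfrozen backbone.

    ``random_init`` backbones share the MLP/CNN architecture but are never
    trained and act as a fixed random projection.  ``densenet121`` builds the
    standard DenseNet-121 feature extractor (penultimate dimension 1024).
    ``external`` wraps a user feature function given as
    ``input_spec={'feature_fn': fn, 'feature_dim': d}``.
    """
    rng = np.random.default_rng(seed)
    if kind == "densenet121":
        size = int(input_spec.get("image_size", 32))
        if size < 32:
            raise ValueError("densenet121 requires image_size >= 32")
        net = DenseNet121Features(seed=seed)
        return Backbone(kind, dict(input_spec), net.feature_dim, seed, net, "images")
    if kind == "external":
        fn = input_spec.get("feature_fn")
        d = input_spec.get("feature_dim")
        if fn is None or d is None:
            raise ValueError("external backbone needs 'feature_fn' and 'feature_dim'")
        itype = input_spec.get("input_type", "features")
        return Backbone(kind, dict(input_spec), int(d), seed, fn, itype)
    if kind in ("mlp", "random_init") and "input_dim" in input_spec:
        k = int(input_spec["input_dim"])
        net = nn.Sequential(
            [nn.Dense(k, hidden, rng), nn.ReLU(), nn.Dense(hidden, feature_dim, rng), nn.ReLU()]
        )
        return Backbone(kind, dict(input_spec), feature_dim, seed, net, "features")
    if kind in ("small_cnn", "random_init") and "image_size" in input_spec:
        size = int(input_spec["image_size"])
        if size < 16 or size % 4 != 0:
            raise ValueError("small_cnn requires image_size >= 16, divisible by 4")
        net = nn.Sequential(
            [
                nn.Conv2d(1, 8, 3, rng, pad=1), nn.ReLU(), nn.AvgPool2d(2),
                nn.Conv2d(8, 16, 3, rng, pad=1), nn.ReLU(), nn.AvgPool2d(2),
                nn.Conv2d(16, 32, 3, rng, pad=1), nn.ReLU(), nn.GlobalAvgPool(),
                nn.Dense(32, feature_dim, rng), nn.ReLU(),
            ]
        )
        return Backbone(kind, dict(input_spec), feature_dim, seed, net, "images")
    raise ValueError(
        f"backbone kind {kind!r} incompatible with input_spec keys {sorted(input_spec)}"
    )


@dataclass
class ModelBundle:
    """A backbone plus named linear prediction heads sharing its features."""

    backbone: Backbone
    heads: dict[str, nn.Dense]
    head_kinds: dict[str, str]                    # 'bce' or 'softmax'
    head_classes: dict[str, list[str]] = field(default_factory=dict)
    label_names: list[str] = field(default_factory=list)
    training_log: list[dict] = field(default_factory=list)
    best_epoch: int = -1


def cohort_inputs(backbone: Backbone, cohort: Cohort) -> np.ndarray:
    if backbone.input_type == "images":
        if cohort.images is None:
            raise ValueError("backbone consumes images but cohort has none rendered")
        return cohort.images
    if cohort.features is None:
        raise ValueError("backbone consumes features but cohort has none")
    return cohort.features


def _head_targets(cohort: Cohort, name: str):
    if name == "disease":
        return cohort.labels.astype(float)
    if name == "sex":
        return np.searchsorted(np.array(SEXES), cohort.attr("sex"))
    if name == "race":
        return np.searchsorted(np.array(GROUPS), cohort.attr("group"))
    raise ValueError(f"unknown head {name!r}")


def _train_bundle(
    backbone: Backbone,
    cohort: Cohort,
    head_names: list[str],
    epochs: int,
    seed: int,
    lr: float,
    batch_size: int,
    weight_decay: float,
) -> ModelBundle:
    if backbone.kind == "random_init":
        raise ValueError("random_init backbones are never trained; freeze and probe them")
    train = cohort.split("train")
    val = cohort.split("val")
    if train.n == 0:
        raise ValueError("cohort has an empty train split")
    if val.n == 0:
        raise ValueError("cohort has an empty val split")
    if "disease" in head_names and cohort.labels.shape[1] != len(cohort.label_names):
        raise ValueError("label matrix inconsistent with label names")

    rng = np.random.default_rng(seed)
    heads: dict[str, nn.Dense] = {}
    head_kinds: dict[str, str] = {}
    head_classes: dict[str, list[str]] = {}
    d = backbone.feature_dim
    for name in head_names:
        if name == "disease":
            heads[name] = nn.Dense(d, len(cohort.label_names), rng)
            head_kinds[name] = "bce"
        elif name == "sex":
            heads[name] = nn.Dense(d, 2, rng)
            head_kinds[name] = "softmax"
            head_classes[name] = list(SEXES)
        elif name == "race":
            heads[name] = nn.Dense(d, 3, rng)
            head_kinds[name] = "softmax"
            head_classes[name] = list(GROUPS)

    X_train = backbone._prep(cohort_inputs(backbone, train))
    X_val = backbone._prep(cohort_inputs(backbone, val))
    y_train = {name: _head_targets(train, name) for name in head_names}
    y_val = {name: _head_targets(val, name) for name in head_names}

    train_backbone = backbone.trainable
    if not train_backbone:
        # frozen / fixed backbone: extract features once, train heads only
        F_train = backbone.features(X_train)
        F_val = backbone.features(X_val)

    params = [p for h in heads.values() for p in h.params()]
    if train_backbone:
        params = backbone.net.params() + params
    opt = nn.Adam(params, lr=lr, weight_decay=weight_decay)

    def head_loss(name, feats, y):
        logits = heads[name].forward(feats)
        if head_kinds[name] == "bce":
            return nn.bce_with_logits(logits, y)
        return nn.softmax_cross_entropy(logits, y)

    def eval_losses(feats_or_x, ys, use_net):
        feats = backbone.features(feats_or_x) if use_net else feats_or_x
        return {name: head_loss(name, feats, ys[name])[0] for name in head_names}

    # model selection tracks the primary task: with a disease head present the
    # best epoch is the one minimizing the disease validation loss (auxiliary
    # demographic heads overfit much faster and would otherwise truncate
    # primary-task training); single-head models use their own head's loss
    select_head = "disease" if "disease" in head_names else head_names[0]

    n = train.n
    log: list[dict] = []
    best = (np.inf, -1, None)
    for epoch in range(epochs):
        order = rng.permutation(n)
        ep_loss = 0.0
        n_batches = 0
        for start in range(0, n, batch_size):
            idx = order[start : start + batch_size]
            if train_backbone:
                feats = backbone.net.forward(X_train[idx])
            else:
                feats = F_train[idx]
            dfeats = np.zeros_like(feats)
            batch_loss = 0.0
            for name in head_names:
                loss, dlog = head_loss(name, feats, _take(y_train[name], idx))
                batch_loss += loss
                dfeats += heads[name].backward(dlog)
            if train_backbone:
                backbone.net.backward(dfeats)
            grads = [g for h in heads.values() for g in h.grads()]
            if train_backbone:
                grads = backbone.net.grads() + grads
            opt.step(grads)
            ep_loss += batch_loss
            n_batches += 1
        if train_backbone:
            vl = eval_losses(X_val, y_val, use_net=True)
        else:
            vl = eval_losses(F_val, y_val, use_net=False)
        entry = {
            "epoch": epoch,
            "train_loss": float(ep_loss / max(n_batches, 1)),
            "val_loss": float(sum(vl.values())),
        }
        entry.update({f"val_loss_{k}": float(v) for k, v in vl.items()})
        log.append(entry)
        if vl[select_head] < best[0]:
            best = (vl[select_head], epoch, [p.copy() for p in params])
    # restore the best-validation-loss snapshot (model selection)
    for p, bp in zip(params, best[2]):
        p[...] = bp
    return ModelBundle(
        backbone=backbone,
        heads=heads,
        head_kinds=head_kinds,
        head_classes=head_classes,
        label_names=list(cohort.label_names),
        training_log=log,
        best_epoch=best[1],
    )


def _take(y, idx):
    return y[idx]


def train_single_task(
    backbone: Backbone,
    cohort: Cohort,
    epochs: int = 30,
    seed: int = 0,
    lr: float = 5e-3,
    batch_size: int = 128,
    weight_decay: float = 5e-3,
) -> ModelBundle:
    """Multi-label disease training (per-label BCE, shared backbone)."""
    return _train_bundle(
        backbone, cohort, ["disease"], epochs, seed, lr, batch_size, weight_decay
    )


def train_multitask(
    backbone: Backbone,
    cohort: Cohort,
    epochs: int = 30,
    seed: int = 0,
    lr: float = 5e-3,
    batch_size: int = 128,
    weight_decay: float = 5e-3,
) -> ModelBundle:
    """Joint disease + sex + race training; equal-weight sum of head losses."""
    return _train_bundle(
        backbone,
        cohort,
        ["disease", "sex", "race"],
        epochs,
        seed,
        lr,
        batch_size,
        weight_decay,
    )


def train_attribute_model(
    backbone: Backbone,
    cohort: Cohort,
    attribute: str,
    epochs: int = 30,
    seed: int = 0,
    lr: float = 5e-3,
    batch_size: int = 128,
    weight_decay: float = 5e-3,
) -> ModelBundle:
    """Single-task direct classifier for 'sex' or 'race' (panel reference)."""
    if attribute not in ("sex", "race"):
        raise ValueError("attribute must be 'sex' or 'race'")
    return _train_bundle(
        backbone, cohort, [attribute], epochs, seed, lr, batch_size, weight_decay
    )


def build_generic_pretrained(
    input_spec: dict,
    feature_dim: int = 32,
    seed: int = 0,
    epochs: int = 15,
    n_train: int = 2000,
) -> Backbone:
    """Backbone pretrained on a synthetic non-medical task.

    For vector inputs the task is sign classification of a random linear
    teacher on Gaussian inputs; for images it is orientation classification of
    a noisy bar.  Either way the backbone has never seen cohort data, standing
    in for generic natural-image pretraining.
    """
    rng = np.random.default_rng(seed)
    if "input_dim" in input_spec:
        k = int(input_spec["input_dim"])
        backbone = build_backbone("mlp", input_spec, feature_dim, seed=seed)
        X = rng.standard_normal((n_train, k))
        w = rng.standard_normal(k)
        y = (X @ w > 0).astype(float)[:, None]
    else:
        size = int(input_spec["image_size"])
        backbone = build_backbone("small_cnn", input_spec, feature_dim, seed=seed)
        y_int = rng.integers(0, 2, n_train)
        X = 0.1 * rng.standard_normal((n_train, size, size)) + 0.3
        mid = size // 2
        for i in range(n_train):
            if y_int[i]:
                X[i, mid - 1 : mid + 1, :] += 0.5
            else:
                X[i, :, mid - 1 : mid + 1] += 0.5
        X = np.clip(X, 0, 1)[:, None]
        y = y_int.astype(float)[:, None]
    head = nn.Dense(feature_dim, 1, rng)
    params = backbone.net.params() + head.params()
    opt = nn.Adam(params, lr=1e-2, weight_decay=1e-4)
    n = len(X)
    for _ in range(epochs):
        order = rng.permutation(n)
        for start in range(0, n, 128):
            idx = order[start : start + 128]
            feats = backbone.net.forward(backbone._prep(X[idx]))
            loss, dlog = nn.bce_with_logits(head.forward(feats), y[idx])
            backbone.net.backward(head.backward(dlog))
            opt.step(backbone.net.grads() + head.grads())
    backbone.tag = "generic_pretrained"
    return backbone


def freeze(backbone: Backbone) -> Backbone:
    """Mark the backbone frozen (idempotent); training then skips its weights."""
    backbone.frozen = True
    return backbone


def extract_features(model: ModelBundle | Backbone, inputs) -> np.ndarray:
    backbone = model.backbone if isinstance(model, ModelBundle) else model
    if isinstance(inputs, Cohort):
        inputs = cohort_inputs(backbone, inputs)
    return backbone.features(inputs)


def predict_logits(bundle: ModelBundle, inputs, head: str = "disease") -> np.ndarray:
    """Pre-sigmoid / pre-softmax scores of the named prediction head."""
    if head not in bundle.heads:
        raise ValueError(f"unknown head {head!r}; available: {sorted(bundle.heads)}")
    feats = extract_features(bundle, inputs)
    return feats @ bundle.heads[head].W + bundle.heads[head].b


def predict_proba(bundle: ModelBundle, inputs, head: str = "disease") -> np.ndarray:
    z = predict_logits(bundle, inputs, head)
    if bundle.head_kinds[head] == "bce":
        return 1.0 / (1.0 + np.exp(-z))
    e = np.exp(z - z.max(axis=1, keepdims=True))
    return e / e.sum(axis=1, keepdims=True)


def clone_backbone(backbone: Backbone) -> Backbone:
    """Deep copy (used to keep panel backbones independent)."""
    return copy.deepcopy(backbone)
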