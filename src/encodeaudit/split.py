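"""Supervised prediction-layer information test (SPLIT).

Freeze a backbone, train a fresh linear prediction layer for a protected
attribute on the penultimate features, and measure its classification
performance on held-out data.  A *negative* result (chance-level AUC) shows
the attribute is not encoded in the representation; a *positive* result shows
encoding but is necessary, not sufficient, evidence that the primary task
uses the attribute — shared features with orthogonal decision boundaries
produce perfect probes without any output-level coupling.

``split_panel`` assembles the standard comparison: probes on a random-init
backbone, a generically pretrained backbone that has never seen cohort data,
the all-data disease backbone, and a disease backbone trained on the largest
subgroup only, next to two direct references (a single-task attribute
classifier and the multitask model's attribute head).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.preprocessing import StandardScaler

from .metrics import EvalConfig, bootstrap_ci, tpr_fpr_at, youden_threshold
from .models import (
    Backbone,
    ModelBundle,
    build_backbone,
    build_generic_pretrained,
    cohort_inputs,
    freeze,
    predict_proba,
    train_attribute_model,
    train_multitask,
    train_single_task,
)
from .synthetic import Cohort, GROUPS, ScenarioToy
from sklearn.metrics import roc_auc_score

__all__ = [
    "SplitResult",
    "run_split",
    "split_panel",
    "toy_primary_backbone",
]

_MIN_SUBGROUP_TRAIN = 50


@dataclass
class SplitResult:
    attribute: str
    backbone_id: str
    table: pd.DataFrame        # per class: auc, auc_lo, auc_hi, tpr, fpr, threshold
    head_dim: int
    n_classes: int

    @property
    def mean_auc(self) -> float:
        return float(self.table["auc"].mean())


def _attribute_labels(obj, attribute: str) -> tuple[np.ndarray, list[str]]:
    if isinstance(obj, ScenarioToy):
        if attribute == "shape":
            return obj.shape_label, ["cross", "circle"]
        if attribute == "color":
            return obj.color_label, ["blue", "orange"]
        raise ValueError(f"toy attribute must be 'color' or 'shape', got {attribute!r}")
    if attribute == "race":
        return np.searchsorted(np.array(GROUPS), obj.attr("group")), list(GROUPS)
    if attribute == "sex":
        classes = ["female", "male"]
        return (obj.attr("sex") == "male").astype(int), classes
    raise ValueError(f"attribute must be 'race' or 'sex', got {attribute!r}")


def _inputs(backbone: Backbone, obj) -> np.ndarray:
    if isinstance(obj, ScenarioToy):
        return obj.x
    return cohort_inputs(backbone, obj)


def _ovr_rows(prob: np.ndarray, y: np.ndarray, classes: list[str], cfg: EvalConfig) -> list[dict]:
    rows = []
    for j, c in enumerate(classes):
        member = (y == j).astype(int)
        if member.sum() in (0, len(member)):
            rows.append({"class": c, "auc": None, "flag": "class_absent"})
            continue
        s = prob[:, j]
        auc = float(roc_auc_score(member, s))
        lo, hi = bootstrap_ci(
            lambda yy, ss: roc_auc_score(yy, ss), (member, s), cfg, strata=member
        )
        thr = youden_threshold(s, member)
        tpr, fpr = tpr_fpr_at(s, member, thr)
        rows.append(
            {
                "class": c,
                "auc": auc,
                "auc_lo": lo,
                "auc_hi": hi,
                "tpr": tpr,
                "fpr": fpr,
                "youden_threshold": thr,
                "flag": "",
            }
        )
    return rows


def run_split(
    backbone: Backbone,
    train_cohort,
    test_cohort,
    attribute: str,
    seed: int = 0,
    eval_cfg: EvalConfig | None = None,
    C: float = 1.0,
) -> SplitResult:
    """Train a fresh linear head for ``attribute`` on frozen features.

    The head is an L2-regularized multinomial logistic regression — a convex,
    deterministic stand-in for a linear prediction layer.  The backbone must
    be frozen and is verified bitwise unchanged.
    """
    if not backbone.frozen:
        raise RuntimeError("SPLIT contract: backbone must be frozen before probing")
    cfg = eval_cfg or EvalConfig()
    y_train, classes = _attribute_labels(train_cohort, attribute)
    y_test, _ = _attribute_labels(test_cohort, attribute)
    if len(np.unique(y_train)) < 2:
        raise ValueError(f"attribute {attribute!r} is constant in the train split")
    before = backbone.checksum()
    F_train = backbone.features(_inputs(backbone, train_cohort))
    F_test = backbone.features(_inputs(backbone, test_cohort))
    scaler = StandardScaler().fit(F_train)
    clf = LogisticRegression(C=C, max_iter=2000)
    clf.fit(scaler.transform(F_train), y_train)
    prob = clf.predict_proba(scaler.transform(F_test))
    if prob.shape[1] < len(classes):
        # some class absent from training: expand columns with zeros
        full = np.zeros((len(prob), len(classes)))
        for col, cls in enumerate(clf.classes_):
            full[:, int(cls)] = prob[:, col]
        prob = full
    after = backbone.checksum()
    if before != after:
        raise RuntimeError("SPLIT contract violated: backbone parameters changed")
    rows = _ovr_rows(prob, y_test, classes, cfg)
    return SplitResult(
        attribute=attribute,
        backbone_id=backbone.tag or backbone.kind,
        table=pd.DataFrame(rows),
        head_dim=F_train.shape[1],
        n_classes=len(classes),
    )


def toy_primary_backbone(
    toy: ScenarioToy, task: str = "color", seed: int = 0, rel_tol: float = 0.1
) -> Backbone:
    """Feature map of a linear primary-task model on a scenario toy.

    Fits an L1-regularized logistic model for the primary task and keeps the
    input coordinates whose coefficient magnitude exceeds ``rel_tol`` times
    the largest one; the backbone projects onto those coordinates.  On the
    axis-separable geometry this recovers a single-coordinate representation;
    on the shared-feature geometry it keeps both coordinates.
    """
    y, _ = _attribute_labels(toy, task)
    clf = LogisticRegression(solver="liblinear", C=1.0, l1_ratio=1, random_state=seed)
    clf.fit(toy.x, y)
    coef = np.abs(clf.coef_[0])
    keep = np.flatnonzero(coef >= rel_tol * coef.max())
    if keep.size == 0:
        keep = np.array([int(np.argmax(coef))])
    keep_idx = keep.copy()

    def project(x, _k=keep_idx):
        return np.asarray(x)[:, _k]

    return Backbone(
        kind="external",
        input_spec={"feature_fn": project, "feature_dim": int(keep.size)},
        feature_dim=int(keep.size),
        seed=seed,
        net=project,
        input_type="features",
        tag=f"toy_{task}_model",
    )


def split_panel(
    cohort: Cohort,
    attribute: str,
    seed: int = 0,
    epochs: int = 20,
    eval_cfg: EvalConfig | None = None,
    multitask_bundle: ModelBundle | None = None,
    single_task_bundle: ModelBundle | None = None,
) -> pd.DataFrame:
    """SPLIT over the standard backbone panel plus two direct references.

    Panel backbones: ``random_init``, ``generic_pretrained``,
    ``all_data_disease``, and ``subgroup_only_disease`` (trained on the
    majority group for race, on male patients for sex — the largest
    subgroups, minimizing the sample-size confound).  Reference rows:
    ``single_task_direct`` (a model trained for the attribute itself) and
    ``multitask`` (the attribute head of the joint model).
    """
    cfg = eval_cfg or EvalConfig()
    if cohort.features is None:
        raise ValueError("split_panel requires a feature cohort")
    ss = np.random.SeedSequence(seed)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(8)]
    input_spec = {"input_dim": cohort.features.shape[1]}
    train, test = cohort.split("train"), cohort.split("test")

    head_name = "race" if attribute == "race" else "sex"
    backbones: dict[str, Backbone] = {}
    backbones["random_init"] = build_backbone("random_init", input_spec, seed=seeds[0])
    backbones["generic_pretrained"] = build_generic_pretrained(
        input_spec, seed=seeds[1]
    )
    bb_all = build_backbone("mlp", input_spec, seed=seeds[2])
    if single_task_bundle is None:
        single_task_bundle = train_single_task(bb_all, cohort, epochs=epochs, seed=seeds[2])
    backbones["all_data_disease"] = single_task_bundle.backbone

    if attribute == "race":
        sub_mask = cohort.attr("group") == GROUPS[0]
        sub_id = "subgroup_only_disease(majority_group)"
    else:
        sub_mask = cohort.attr("sex") == "male"
        sub_id = "subgroup_only_disease(male)"
    sub = cohort.subset(sub_mask)
    if sub.split("train").n < _MIN_SUBGROUP_TRAIN:
        raise ValueError(
            f"subgroup train split too small ({sub.split('train').n}); "
            f"need at least {_MIN_SUBGROUP_TRAIN} samples"
        )
    bb_sub = build_backbone("mlp", input_spec, seed=seeds[3])
    sub_bundle = train_single_task(bb_sub, sub, epochs=epochs, seed=seeds[3])
    backbones[sub_id] = sub_bundle.backbone

    rows = []
    for name, bb in backbones.items():
        bb.tag = bb.tag or name
        if name != bb.tag:
            bb.tag = name
        freeze(bb)
        res = run_split(bb, train, test, attribute, seed=seeds[4], eval_cfg=cfg)
        t = res.table.copy()
        t.insert(0, "backbone_id", name)
        t.insert(0, "attribute", attribute)
        t["source"] = "split"
        rows.append(t)

    # reference 1: direct single-task attribute classifier
    bb_direct = build_backbone("mlp", input_spec, seed=seeds[5])
    direct = train_attribute_model(bb_direct, cohort, head_name, epochs=epochs, seed=seeds[5])
    prob = predict_proba(direct, test, head=head_name)
    y_test, classes = _attribute_labels(test, attribute)
    t = pd.DataFrame(_ovr_rows(prob, y_test, classes, cfg))
    t.insert(0, "backbone_id", "single_task_direct")
    t.insert(0, "attribute", attribute)
    t["source"] = "direct"
    rows.append(t)

    # reference 2: multitask model's attribute head
    if multitask_bundle is None:
        bb_mt = build_backbone("mlp", input_spec, seed=seeds[6])
        multitask_bundle = train_multitask(bb_mt, cohort, epochs=epochs, seed=seeds[6])
    prob = predict_proba(multitask_bundle, test, head=head_name)
    t = pd.DataFrame(_ovr_rows(prob, y_test, classes, cfg))
    t.insert(0, "backbone_id", "multitask")
    t.insert(0, "attribute", attribute)
    t["source"] = "direct"
    rows.append(t)

    return pd.concat(rows, ignore_index=True)
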