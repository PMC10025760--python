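"""Performance statistics for subgroup audits.

AUC/ROC, decision-threshold calibration to a target population false positive
rate, per-subgroup TPR/FPR/Youden's J at a shared threshold, Youden-optimal
thresholds, one-vs-rest multiclass AUC, and stratified percentile bootstrap
confidence intervals.

Conventions: a sample is called positive when its score is greater than or
equal to the decision threshold.  AUC uses the midrank (Mann-Whitney) tie
convention.  Metrics that are undefined on a subgroup (no positives, no
negatives, a single class) are flagged rather than silently returned as NaN.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.metrics import roc_auc_score, roc_curve

__all__ = [
    "UndefinedMetricError",
    "ROCResult",
    "EvalConfig",
    "SubgroupReport",
    "roc_and_auc",
    "calibrate_threshold",
    "tpr_fpr_at",
    "youden_threshold",
    "subgroup_performance",
    "one_vs_rest_auc",
    "bootstrap_ci",
]


class UndefinedMetricError(ValueError):
    """Raised when a metric has no defined value on the given sample."""


@dataclass
class ROCResult:
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float


@dataclass
class EvalConfig:
    """Evaluation constants: FPR target 0.20, 2000 bootstrap resamples, 95% CI."""

    target_fpr: float = 0.20
    n_boot: int = 2000
    ci_level: float = 0.95
    boot_seed: int = 0

    def __post_init__(self):
        if not 0 < self.target_fpr < 1:
            raise ValueError("target_fpr must lie in (0, 1)")
        if not 0 < self.ci_level < 1:
            raise ValueError("ci_level must lie in (0, 1)")


def _check_binary(labels: np.ndarray) -> np.ndarray:
    labels = np.asarray(labels).astype(int)
    if labels.min() < 0 or labels.max() > 1:
        raise ValueError("labels must be binary 0/1")
    return labels


def roc_and_auc(scores, labels) -> ROCResult:
    """ROC curve (thresholds at unique scores) and midrank AUC."""
    scores = np.asarray(scores, dtype=float)
    labels = _check_binary(labels)
    if labels.sum() == 0 or labels.sum() == len(labels):
        raise UndefinedMetricError("ROC requires at least one positive and one negative")
    fpr, tpr, thr = roc_curve(labels, scores, drop_intermediate=False)
    return ROCResult(fpr=fpr, tpr=tpr, thresholds=thr, auc=float(roc_auc_score(labels, scores)))


def calibrate_threshold(scores, labels, target_fpr: float = 0.20) -> float:
    """Smallest threshold whose achieved FPR does not exceed ``target_fpr``.

    With the >=-threshold convention this is the empirical upper quantile of
    the negative-class scores: at most ``floor(target_fpr * n_neg)`` negatives
    may sit at or above the returned value, so the achieved FPR is the largest
    attainable value that stays at or below the target.
    """
    scores = np.asarray(scores, dtype=float)
    labels = _check_binary(labels)
    neg = scores[labels == 0]
    if neg.size == 0:
        raise UndefinedMetricError("threshold calibration requires negative samples")
    k = int(np.floor(target_fpr * neg.size))
    uniq = np.unique(neg)[::-1]                      # descending unique negatives
    # number of negatives >= each candidate
    counts = neg.size - np.searchsorted(np.sort(neg), uniq, side="left")
    admissible = uniq[counts <= k]
    if admissible.size:
        return float(admissible.min())
    # even the largest score admits too many ties: step just above the maximum
    return float(np.nextafter(uniq[0], np.inf))


def tpr_fpr_at(scores, labels, threshold: float) -> tuple[float | None, float | None]:
    """TPR and FPR at a fixed threshold; None when the class is absent."""
    scores = np.asarray(scores, dtype=float)
    labels = _check_binary(labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    tpr = float(np.mean(pos >= threshold)) if pos.size else None
    fpr = float(np.mean(neg >= threshold)) if neg.size else None
    return tpr, fpr


def youden_threshold(scores, labels) -> float:
    """Threshold maximizing J = TPR - FPR; ties broken by the larger threshold."""
    scores = np.asarray(scores, dtype=float)
    labels = _check_binary(labels)
    if labels.sum() in (0, len(labels)):
        raise UndefinedMetricError("Youden threshold requires both classes")
    uniq = np.unique(scores)
    candidates = np.append(uniq, np.nextafter(uniq[-1], np.inf))
    pos = np.sort(scores[labels == 1])
    neg = np.sort(scores[labels == 0])
    tpr = 1.0 - np.searchsorted(pos, candidates, side="left") / pos.size
    fpr = 1.0 - np.searchsorted(neg, candidates, side="left") / neg.size
    j = tpr - fpr
    best = np.flatnonzero(j >= j.max() - 1e-15)
    return float(candidates[best.max()])


@dataclass
class SubgroupReport:
    """Per-group operating statistics with bootstrap CIs at a shared threshold."""

    table: pd.DataFrame
    threshold: float
    eval_cfg: EvalConfig = field(default_factory=EvalConfig)

    def row(self, group: str) -> pd.Series:
        return self.table.set_index("group").loc[group]


def _boot_metrics(scores, labels, threshold, cfg: EvalConfig, rng) -> dict:
    """Percentile CIs for (auc, tpr, fpr, j) via label-stratified resampling."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    out = {}
    n_boot = cfg.n_boot
    alpha = (1.0 - cfg.ci_level) / 2.0
    aucs = np.empty(n_boot)
    tprs = np.empty(n_boot)
    fprs = np.empty(n_boot)
    has_pos, has_neg = pos.size > 0, neg.size > 0
    for b in range(n_boot):
        p = pos[rng.integers(0, pos.size, pos.size)] if has_pos else pos
        q = neg[rng.integers(0, neg.size, neg.size)] if has_neg else neg
        tprs[b] = np.mean(p >= threshold) if has_pos else np.nan
        fprs[b] = np.mean(q >= threshold) if has_neg else np.nan
        if has_pos and has_neg:
            # midrank AUC via the rank statistic (cheaper than a full ROC)
            ranks = rankdata(np.concatenate([p, q]))
            aucs[b] = (ranks[: p.size].sum() - p.size * (p.size + 1) / 2) / (
                p.size * q.size
            )
        else:
            aucs[b] = np.nan
    qs = [100 * alpha, 100 * (1 - alpha)]
    if has_pos and has_neg:
        out["auc_ci"] = tuple(np.percentile(aucs, qs))
        out["j_ci"] = tuple(np.percentile(tprs - fprs, qs))
    if has_pos:
        out["tpr_ci"] = tuple(np.percentile(tprs, qs))
    if has_neg:
        out["fpr_ci"] = tuple(np.percentile(fprs, qs))
    return out


def subgroup_performance(
    scores,
    labels,
    groups,
    threshold: float,
    eval_cfg: EvalConfig | None = None,
    group_order: list[str] | None = None,
) -> SubgroupReport:
    """AUC / TPR / FPR / Youden's J per subgroup at a shared fixed threshold."""
    cfg = eval_cfg or EvalConfig()
    scores = np.asarray(scores, dtype=float)
    labels = _check_binary(labels)
    groups = np.asarray(groups)
    if not (len(scores) == len(labels) == len(groups)):
        raise ValueError("scores, labels and groups must be aligned")
    rng = np.random.default_rng(cfg.boot_seed)
    order = group_order or sorted(pd.unique(groups).tolist())
    rows = []
    for g in order:
        m = groups == g
        s, y = scores[m], labels[m]
        flags = []
        n_pos, n_neg = int(y.sum()), int((1 - y).sum())
        if n_pos == 0:
            flags.append("tpr_undefined")
        if n_neg == 0:
            flags.append("fpr_undefined")
        if n_pos == 0 or n_neg == 0:
            flags.append("auc_undefined")
        tpr, fpr = tpr_fpr_at(s, y, threshold) if m.any() else (None, None)
        auc = float(roc_auc_score(y, s)) if (n_pos and n_neg) else None
        j = tpr - fpr if (tpr is not None and fpr is not None) else None
        cis = _boot_metrics(s, y, threshold, cfg, rng) if m.any() else {}
        rows.append(
            {
                "group": g,
                "n": int(m.sum()),
                "n_pos": n_pos,
                "n_neg": n_neg,
                "auc": auc,
                "auc_lo": cis.get("auc_ci", (None, None))[0],
                "auc_hi": cis.get("auc_ci", (None, None))[1],
                "tpr": tpr,
                "tpr_lo": cis.get("tpr_ci", (None, None))[0],
                "tpr_hi": cis.get("tpr_ci", (None, None))[1],
                "fpr": fpr,
                "fpr_lo": cis.get("fpr_ci", (None, None))[0],
                "fpr_hi": cis.get("fpr_ci", (None, None))[1],
                "youden_j": j,
                "j_lo": cis.get("j_ci", (None, None))[0],
                "j_hi": cis.get("j_ci", (None, None))[1],
                "flags": ";".join(flags),
            }
        )
    return SubgroupReport(table=pd.DataFrame(rows), threshold=float(threshold), eval_cfg=cfg)


def one_vs_rest_auc(score_matrix, class_labels, classes: list[str] | None = None) -> pd.DataFrame:
    """Per-class AUC of each score column against class membership."""
    scores = np.asarray(score_matrix, dtype=float)
    class_labels = np.asarray(class_labels)
    if classes is None:
        classes = sorted(pd.unique(class_labels).tolist())
    if scores.ndim != 2 or scores.shape[1] != len(classes):
        raise ValueError("score_matrix columns must correspond to classes")
    rows = []
    for j, c in enumerate(classes):
        y = (class_labels == c).astype(int)
        if y.sum() in (0, len(y)):
            rows.append({"class": c, "auc": None, "flag": "class_absent"})
        else:
            rows.append({"class": c, "auc": float(roc_auc_score(y, scores[:, j])), "flag": ""})
    return pd.DataFrame(rows)


def bootstrap_ci(
    statistic_fn,
    data,
    eval_cfg: EvalConfig | None = None,
    strata=None,
) -> tuple[float, float]:
    """Percentile bootstrap interval; optional stratified resampling.

    ``data`` is one array or a tuple of aligned arrays passed positionally to
    ``statistic_fn`` after resampling.  When ``strata`` is given, each stratum
    is resampled with replacement to its own size (stratification by targets).
    """
    cfg = eval_cfg or EvalConfig()
    arrays = data if isinstance(data, (tuple, list)) else (data,)
    arrays = tuple(np.asarray(a) for a in arrays)
    n = len(arrays[0])
    if n == 0:
        raise ValueError("bootstrap requires non-empty data")
    if any(len(a) != n for a in arrays):
        raise ValueError("all data arrays must share the same length")
    rng = np.random.default_rng(cfg.boot_seed)
    if strata is None:
        groups = [np.arange(n)]
    else:
        strata = np.asarray(strata)
        groups = [np.flatnonzero(strata == v) for v in pd.unique(strata)]
        if any(g.size == 0 for g in groups):
            raise ValueError("bootstrap stratum of size 0")
    stats = np.empty(cfg.n_boot)
    for b in range(cfg.n_boot):
        idx = np.concatenate([g[rng.integers(0, g.size, g.size)] for g in groups])
        stats[b] = statistic_fn(*(a[idx] for a in arrays))
    alpha = (1.0 - cfg.ci_level) / 2.0
    lo, hi = np.percentile(stats, [100 * alpha, 100 * (1 - alpha)])
    return float(lo), float(hi)
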