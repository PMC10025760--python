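"""Unsupervised exploration of penultimate features and logit outputs.

PCA captures the main modes of variation of the penultimate representation
(first four modes, centered, unwhitened, fitted on the full test set); t-SNE
gives a nonlinear 2-D embedding; the paired logits of the two mutually
exclusive focal labels visualize the prediction layer's output space.
Marginal distributions along each axis are compared between subgroup pairs
with two-sample Kolmogorov-Smirnov tests, adjusted jointly per table with the
Benjamini-Yekutieli procedure (valid under arbitrary dependence).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import ks_2samp
from sklearn.decomposition import PCA
from sklearn.manifold import TSNE
from statsmodels.stats.multitest import multipletests

from .models import ModelBundle, cohort_inputs, extract_features, predict_logits
from .synthetic import Cohort, FOCAL_LABELS, GROUPS

__all__ = [
    "InspectionResult",
    "inspect",
    "marginal_ks_table",
    "ks_table",
    "alignment_summary",
    "DEFAULT_PAIRS",
]

N_MODES = 4
_EXACT_KS_MAX = 25  # per-side size below which the exact KS null is used

# (pair name, attribute column, class a, class b) — focal-label pair first,
# then all group pairs and the sex pair
DEFAULT_PAIRS = (
    ("no_finding/condition_x", "disease_class", "no_finding", "condition_x"),
    ("g0/g1", "group", "g0", "g1"),
    ("g1/g2", "group", "g1", "g2"),
    ("g2/g0", "group", "g2", "g0"),
    ("male/female", "sex", "male", "female"),
)


@dataclass
class InspectionResult:
    pca_projections: np.ndarray        # (n, 4)
    explained_variance: np.ndarray     # (4,) fractions
    pca_modes: np.ndarray              # (4, d) orthonormal rows
    tsne_xy: np.ndarray                # (n, 2)
    logit_xy: np.ndarray               # (n, 2): focal-label logits
    overlay: pd.DataFrame              # disease_class, sex, group, age
    plot_indices: np.ndarray           # subsample used for scatter plots
    manifest: dict = field(default_factory=dict)

    @property
    def axes(self) -> dict[str, np.ndarray]:
        out = {f"pca_mode_{k + 1}": self.pca_projections[:, k] for k in range(N_MODES)}
        out["logit_no_finding"] = self.logit_xy[:, 0]
        out["logit_condition_x"] = self.logit_xy[:, 1]
        return out


def inspect(
    bundle: ModelBundle,
    cohort_test: Cohort,
    plot_sample: int = 1000,
    seed: int = 0,
    tsne_perplexity: float = 30.0,
    tsne_iter: int = 1000,
) -> InspectionResult:
    """Extract features and logits and compute the PCA/t-SNE/logit views."""
    feats = extract_features(bundle, cohort_inputs(bundle.backbone, cohort_test))
    n = len(feats)
    pca = PCA(n_components=N_MODES, svd_solver="full")
    proj = pca.fit_transform(feats)
    logits = predict_logits(bundle, cohort_test, head="disease")
    nf_col = bundle.label_names.index(FOCAL_LABELS[0])
    cx_col = bundle.label_names.index(FOCAL_LABELS[1])
    logit_xy = logits[:, [nf_col, cx_col]]
    perpl = min(tsne_perplexity, max(5.0, (n - 1) / 3.0))
    tsne = TSNE(
        n_components=2,
        perplexity=perpl,
        max_iter=tsne_iter,
        random_state=seed,
        init="pca",
    )
    tsne_xy = tsne.fit_transform(feats)

    overlay = pd.DataFrame(
        {
            "disease_class": cohort_test.disease_class(),
            "sex": cohort_test.attr("sex"),
            "group": cohort_test.attr("group"),
            "age": cohort_test.attr("age"),
        }
    )
    rng = np.random.default_rng(seed)
    picks = []
    short_groups = []
    for g in GROUPS:
        members = np.flatnonzero(overlay["group"].to_numpy() == g)
        if members.size == 0:
            continue
        if members.size >= plot_sample:
            picks.append(rng.choice(members, plot_sample, replace=False))
        else:
            short_groups.append(g)
            picks.append(rng.choice(members, plot_sample, replace=True))
    plot_idx = np.concatenate(picks) if picks else np.arange(n)
    manifest = {
        "n_test": n,
        "plot_sample_per_group": plot_sample,
        "groups_sampled_with_replacement": short_groups,
        "tsne": {"perplexity": perpl, "max_iter": tsne_iter, "seed": seed, "init": "pca"},
        "pca": {"n_modes": N_MODES, "centered": True, "whitened": False},
    }
    return InspectionResult(
        pca_projections=proj,
        explained_variance=pca.explained_variance_ratio_,
        pca_modes=pca.components_,
        tsne_xy=np.asarray(tsne_xy, dtype=float),
        logit_xy=logit_xy,
        overlay=overlay,
        plot_indices=plot_idx,
        manifest=manifest,
    )


def _ks(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    method = "exact" if (len(a) <= _EXACT_KS_MAX and len(b) <= _EXACT_KS_MAX) else "asymp"
    with warnings.catch_warnings():
        # ties make the exact null unavailable; scipy then falls back to the
        # asymptotic p-value, which is the documented behavior here
        warnings.filterwarnings("ignore", message="ks_2samp")
        res = ks_2samp(a, b, method=method)
    return float(res.statistic), float(res.pvalue)


def ks_table(
    axes: dict[str, np.ndarray],
    overlay: pd.DataFrame,
    pairs=DEFAULT_PAIRS,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Two-sample KS tests for each axis x subgroup pair, BY-adjusted jointly.

    The focal-label pair compares 'no_finding' against 'condition_x' samples
    (the 'other' class is excluded from that row by construction).
    """
    rows = []
    for axis, values in axes.items():
        values = np.asarray(values, dtype=float)
        for pair_name, col, ca, cb in pairs:
            attr = overlay[col].to_numpy()
            a = values[attr == ca]
            b = values[attr == cb]
            if len(a) == 0 or len(b) == 0:
                rows.append(
                    {"axis": axis, "pair": pair_name, "D": None, "p_raw": None,
                     "flag": "pair_member_absent"}
                )
                continue
            d, p = _ks(a, b)
            rows.append({"axis": axis, "pair": pair_name, "D": d, "p_raw": p, "flag": ""})
    table = pd.DataFrame(rows)
    defined = table["p_raw"].notna()
    table["p_adj"] = np.nan
    if defined.any():
        _, p_adj, _, _ = multipletests(
            table.loc[defined, "p_raw"].to_numpy(), alpha=alpha, method="fdr_by"
        )
        table.loc[defined, "p_adj"] = np.minimum(p_adj, 1.0)
    table["significant"] = table["p_adj"] < alpha
    table["stars"] = np.select(
        [table["p_adj"] < 0.001, table["p_adj"] < alpha], ["**", "*"], default=""
    )
    return table


def marginal_ks_table(result: InspectionResult, pairs=DEFAULT_PAIRS) -> pd.DataFrame:
    """KS table over the PCA-mode and focal-logit axes of one model."""
    return ks_table(result.axes, result.overlay, pairs=pairs)


_SEP_ATTRS = ("disease_class", "sex", "group")


def _separation(values: np.ndarray, attr: np.ndarray) -> float | None:
    """Max pairwise KS D between attribute classes along one axis."""
    classes = [c for c in pd.unique(attr)]
    if len(classes) < 2:
        return None
    best = 0.0
    for i in range(len(classes)):
        for j in range(i + 1, len(classes)):
            a = values[attr == classes[i]]
            b = values[attr == classes[j]]
            if len(a) and len(b):
                best = max(best, _ks(a, b)[0])
    return best


def alignment_summary(
    result_single: InspectionResult, result_multi: InspectionResult
) -> pd.DataFrame:
    """Which PCA mode encodes which attribute, for both models.

    For every model x PCA mode x overlay attribute, reports the separation
    score (maximum pairwise KS D between the attribute's classes along that
    mode), quantifying which factor dominates each mode.  For the disease
    attribute only the two focal classes are compared.
    """
    if len(result_single.overlay) != len(result_multi.overlay):
        raise ValueError("inspection results come from different cohorts")
    if not result_single.overlay["group"].equals(result_multi.overlay["group"]):
        raise ValueError("inspection results come from different cohorts")
    rows = []
    for model, res in (("single_task", result_single), ("multitask", result_multi)):
        for k in range(N_MODES):
            values = res.pca_projections[:, k]
            for attr_name in _SEP_ATTRS:
                attr = res.overlay[attr_name].to_numpy()
                if attr_name == "disease_class":
                    mask = attr != "other"
                    score = _separation(values[mask], attr[mask])
                else:
                    score = _separation(values, attr)
                rows.append(
                    {
                        "model": model,
                        "mode": k + 1,
                        "attribute": attr_name,
                        "separation": score,
                        "flag": "" if score is not None else "single_class",
                    }
                )
    return pd.DataFrame(rows)
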