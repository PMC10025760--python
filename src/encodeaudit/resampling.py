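"""Strategic test-set resampling for unbiased subgroup performance estimates.

Subgroup operating-point disparities can arise purely from population and
prevalence shifts: groups differing in size, age distribution, or disease
frequency will show shifted TPR/FPR at a shared threshold even for an
unbiased scorer.  Resampling the test set with replacement to equalize group
proportions, age histograms, and per-group focal-label prevalence removes
those statistical sources, so disparities that *remain* point at the model
rather than the test-set composition.

The joint cell targets are the product of the group target, the age-bin
reference histogram, and the per-group focal-label stratum probabilities
(conditional independence across the controlled factors); integer cell counts
come from largest-remainder apportionment, and each cell is then filled by
with-replacement draws from the matching source records.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .metrics import SubgroupReport
from .synthetic import Cohort, GROUPS

__all__ = [
    "ResamplingSpec",
    "InfeasibleResamplingError",
    "resample_test_set",
    "shift_diagnosis",
]

DEFAULT_AGE_EDGES = (18, 45, 65, 96)
DISEASE_STRATA = ("no_finding", "condition_x", "other")


class InfeasibleResamplingError(ValueError):
    """A required cell has positive target mass but no source records."""


@dataclass
class ResamplingSpec:
    group_targets: dict[str, float] | None = None       # None -> uniform
    age_edges: tuple[float, ...] = DEFAULT_AGE_EDGES
    age_reference: dict | str = "pooled"                # 'pooled' or {bin: mass}
    prevalence_targets: dict[str, dict[str, float]] | str = "pooled"
    n_out: int | None = None                            # None -> source size
    seed: int = 0

    def resolved_group_targets(self) -> dict[str, float]:
        if self.group_targets is None:
            return {g: 1.0 / len(GROUPS) for g in GROUPS}
        total = sum(self.group_targets.values())
        if abs(total - 1.0) > 1e-6:
            raise ValueError("group_targets must sum to 1")
        return dict(self.group_targets)


def _largest_remainder(weights: np.ndarray, total: int) -> np.ndarray:
    """Apportion ``total`` integer counts proportionally to ``weights``."""
    weights = np.asarray(weights, dtype=float)
    if weights.sum() <= 0:
        raise ValueError("weights must have positive mass")
    quota = weights / weights.sum() * total
    counts = np.floor(quota).astype(int)
    rem = total - counts.sum()
    if rem > 0:
        order = np.argsort(-(quota - counts), kind="stable")
        counts[order[:rem]] += 1
    return counts


def _disease_stratum(cohort: Cohort) -> np.ndarray:
    return cohort.disease_class()


def resample_test_set(cohort_test: Cohort, spec: ResamplingSpec) -> Cohort:
    """Draw a balanced test set matching the spec's marginal targets.

    Every output record is a copy of a source record; a ``source_index``
    provenance column records its origin.  Deterministic under ``spec.seed``.
    """
    n_out = spec.n_out or cohort_test.n
    rng = np.random.default_rng(spec.seed)
    gt = spec.resolved_group_targets()
    edges = np.asarray(spec.age_edges, dtype=float)
    age = cohort_test.attr("age").astype(float)
    if age.min() < edges[0] or age.max() > edges[-1]:
        raise ValueError("age bins do not cover the cohort age range")
    age_bin = np.clip(np.searchsorted(edges, age, side="right") - 1, 0, len(edges) - 2)
    n_bins = len(edges) - 1

    if spec.age_reference == "pooled":
        age_ref = np.bincount(age_bin, minlength=n_bins).astype(float)
        age_ref /= age_ref.sum()
    else:
        age_ref = np.array([spec.age_reference.get(b, 0.0) for b in range(n_bins)], float)
        age_ref /= age_ref.sum()

    stratum = _disease_stratum(cohort_test)
    if spec.prevalence_targets == "pooled":
        p_nf = float(np.mean(stratum == "no_finding"))
        p_cx = float(np.mean(stratum == "condition_x"))
        prev = {g: {"no_finding": p_nf, "condition_x": p_cx} for g in GROUPS}
    else:
        prev = spec.prevalence_targets
    for g, pg in prev.items():
        if pg["no_finding"] + pg["condition_x"] > 1 + 1e-9:
            raise ValueError(f"prevalence targets for group {g} sum above 1")

    group = cohort_test.attr("group")
    cells = []
    weights = []
    for g in GROUPS:
        pg = prev.get(g, {"no_finding": 0.0, "condition_x": 0.0})
        strat_p = {
            "no_finding": pg["no_finding"],
            "condition_x": pg["condition_x"],
            "other": 1.0 - pg["no_finding"] - pg["condition_x"],
        }
        for b in range(n_bins):
            for s in DISEASE_STRATA:
                cells.append((g, b, s))
                weights.append(gt.get(g, 0.0) * age_ref[b] * strat_p[s])
    counts = _largest_remainder(np.asarray(weights), n_out)

    chosen = []
    for (g, b, s), c in zip(cells, counts):
        if c == 0:
            continue
        members = np.flatnonzero((group == g) & (age_bin == b) & (stratum == s))
        if members.size == 0:
            raise InfeasibleResamplingError(
                f"required cell empty in source: group={g}, age_bin="
                f"[{edges[b]:.0f},{edges[b + 1]:.0f}), stratum={s}, "
                f"target count={c}"
            )
        chosen.append(members[rng.integers(0, members.size, c)])
    idx = np.concatenate(chosen)
    out = cohort_test.subset(idx)
    out.data = out.data.copy()
    out.data["source_index"] = idx
    counts_per = pd.Series(idx).value_counts()
    out.data["duplication_count"] = counts_per.reindex(idx).to_numpy()
    return out


_METRICS = ("auc", "tpr", "fpr", "youden_j")
_CI = {"auc": ("auc_lo", "auc_hi"), "tpr": ("tpr_lo", "tpr_hi"),
       "fpr": ("fpr_lo", "fpr_hi"), "youden_j": ("j_lo", "j_hi")}


def shift_diagnosis(
    report_original: SubgroupReport, report_resampled: SubgroupReport
) -> pd.DataFrame:
    """Original vs resampled per-group metrics with deltas and CI overlap."""
    a = report_original.table.set_index("group")
    b = report_resampled.table.set_index("group")
    if set(a.index) != set(b.index):
        raise ValueError("reports cover different group sets")
    rows = []
    for g in a.index:
        for m in _METRICS:
            lo, hi = _CI[m]
            va, vb = a.loc[g, m], b.loc[g, m]
            undefined = pd.isna(va) or pd.isna(vb) or va is None or vb is None
            overlap = None
            if not undefined and not any(
                pd.isna(v) for v in (a.loc[g, lo], a.loc[g, hi], b.loc[g, lo], b.loc[g, hi])
            ):
                overlap = bool(
                    a.loc[g, lo] <= b.loc[g, hi] and b.loc[g, lo] <= a.loc[g, hi]
                )
            rows.append(
                {
                    "group": g,
                    "metric": m,
                    "original": va,
                    "resampled": vb,
                    "delta": (vb - va) if not undefined else None,
                    "ci_overlap": overlap,
                    "flag": "undefined" if undefined else "",
                }
            )
    return pd.DataFrame(rows)
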