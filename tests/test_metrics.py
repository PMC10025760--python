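import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from encodeaudit.metrics import (
    EvalConfig,
    UndefinedMetricError,
    bootstrap_ci,
    calibrate_threshold,
    one_vs_rest_auc,
    roc_and_auc,
    subgroup_performance,
    tpr_fpr_at,
    youden_threshold,
)

HSET = settings(max_examples=60, deadline=None, derandomize=True)


# ---------- independent brute-force oracles ----------

def auc_pair_counting(scores, labels):
    """Fraction of (positive, negative) pairs correctly ordered; ties count 1/2."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


def youden_exhaustive(scores, labels):
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    uniq = np.unique(scores)
    candidates = list(uniq) + [np.nextafter(uniq[-1], np.inf)]
    best_j, best_t = -np.inf, None
    for t in candidates:
        tpr = np.mean(scores[labels == 1] >= t)
        fpr = np.mean(scores[labels == 0] >= t)
        j = tpr - fpr
        if j > best_j + 1e-15 or (abs(j - best_j) <= 1e-15 and t > best_t):
            best_j, best_t = j, t
    return best_t, best_j


@st.composite
def binary_scored_sample(draw, max_n=30):
    n = draw(st.integers(4, max_n))
    # scores on a coarse grid so ties actually occur
    scores = draw(st.lists(st.integers(0, 12), min_size=n, max_size=n))
    labels = draw(st.lists(st.integers(0, 1), min_size=n, max_size=n))
    if sum(labels) == 0:
        labels[0] = 1
    if sum(labels) == len(labels):
        labels[-1] = 0
    return np.asarray(scores, float) / 12.0, np.asarray(labels)


# ---------- ROC / AUC ----------

class TestRocAuc:
    def test_perfect_separation(self):
        res = roc_and_auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        assert res.auc == 1.0
        assert res.fpr[0] == 0.0 and res.tpr[0] == 0.0
        assert res.fpr[-1] == 1.0 and res.tpr[-1] == 1.0

    def test_label_flip_symmetry(self):
        scores = np.array([0.1, 0.4, 0.35, 0.8, 0.65, 0.7])
        labels = np.array([0, 0, 1, 1, 0, 1])
        a = roc_and_auc(scores, labels).auc
        b = roc_and_auc(scores, 1 - labels).auc
        assert a + b == pytest.approx(1.0)

    def test_worked_example_matches_pair_counting(self):
        scores = [0.1, 0.4, 0.35, 0.8, 0.65, 0.7]
        labels = [0, 0, 1, 1, 0, 1]
        assert roc_and_auc(scores, labels).auc == pytest.approx(
            auc_pair_counting(scores, labels)
        )

    def test_single_class_raises(self):
        with pytest.raises(UndefinedMetricError):
            roc_and_auc([0.1, 0.2], [1, 1])

    @HSET
    @given(binary_scored_sample())
    def test_auc_equals_mann_whitney_pair_statistic(self, sample):
        scores, labels = sample
        assert roc_and_auc(scores, labels).auc == pytest.approx(
            auc_pair_counting(scores, labels), abs=1e-12
        )


# ---------- threshold calibration ----------

class TestCalibrateThreshold:
    def test_ten_negatives_target_020_admits_two(self):
        neg = np.arange(0.05, 1.0, 0.10)  # 0.05, 0.15, ..., 0.95
        scores = np.concatenate([neg, [0.99, 0.98]])
        labels = np.array([0] * 10 + [1, 1])
        t = calibrate_threshold(scores, labels, 0.20)
        fp = int(np.sum(neg >= t))
        assert fp == 2 and fp / 10 == pytest.approx(0.20)

    def test_target_near_zero_threshold_above_max_negative(self):
        scores = np.array([0.1, 0.5, 0.9, 0.95])
        labels = np.array([0, 0, 0, 1])
        t = calibrate_threshold(scores, labels, 0.01)
        assert t > 0.9
        assert np.mean(scores[labels == 0] >= t) == 0.0

    def test_target_one_threshold_at_or_below_min(self):
        scores = np.array([0.1, 0.5, 0.9, 0.95])
        labels = np.array([0, 0, 0, 1])
        t = calibrate_threshold(scores, labels, 1.0)
        assert np.mean(scores[labels == 0] >= t) == 1.0

    def test_no_negatives_raises(self):
        with pytest.raises(UndefinedMetricError):
            calibrate_threshold([0.5, 0.6], [1, 1], 0.2)

    @HSET
    @given(binary_scored_sample(), st.floats(0.05, 0.95))
    def test_achieved_fpr_at_most_target_and_threshold_minimal(self, sample, target):
        scores, labels = sample
        neg = scores[labels == 0]
        t = calibrate_threshold(scores, labels, target)
        fpr_t = np.mean(neg >= t)
        assert fpr_t <= target + 1e-12
        # no other admissible threshold achieves an FPR closer to the target
        for cand in np.unique(scores):
            fpr_c = np.mean(neg >= cand)
            if fpr_c <= target:
                assert fpr_c <= fpr_t + 1e-12


# ---------- Youden threshold ----------

class TestYoudenThreshold:
    def test_perfect_separation_j_is_one(self):
        scores = np.array([0.9, 0.8, 0.2, 0.1])
        labels = np.array([1, 1, 0, 0])
        t = youden_threshold(scores, labels)
        tpr, fpr = tpr_fpr_at(scores, labels, t)
        assert tpr - fpr == 1.0

    def test_identical_scores_j_zero_boundary_threshold(self):
        scores = np.full(6, 0.5)
        labels = np.array([1, 0, 1, 0, 1, 0])
        t = youden_threshold(scores, labels)
        tpr, fpr = tpr_fpr_at(scores, labels, t)
        assert tpr - fpr == 0.0
        assert t > 0.5  # tie broken toward the larger (boundary) threshold

    def test_single_class_raises(self):
        with pytest.raises(UndefinedMetricError):
            youden_threshold([0.1, 0.2], [0, 0])

    @HSET
    @given(binary_scored_sample())
    def test_matches_exhaustive_search(self, sample):
        scores, labels = sample
        t = youden_threshold(scores, labels)
        t_ref, j_ref = youden_exhaustive(scores, labels)
        tpr, fpr = tpr_fpr_at(scores, labels, t)
        assert tpr - fpr == pytest.approx(j_ref, abs=1e-12)
        assert t == pytest.approx(t_ref)


# ---------- subgroup report ----------

class TestSubgroupPerformance:
    @pytest.mark.parametrize(
        "tpr,fpr,expected_j", [(0.79, 0.20, 0.59), (0.71, 0.16, 0.55), (0.78, 0.21, 0.57)]
    )
    def test_j_identity_at_printed_operating_points(self, tpr, fpr, expected_j):
        # construct a group realizing the printed operating point exactly
        n = 100
        pos = np.concatenate([np.full(int(tpr * n), 0.8), np.full(n - int(tpr * n), 0.2)])
        neg = np.concatenate([np.full(int(fpr * n), 0.8), np.full(n - int(fpr * n), 0.2)])
        scores = np.concatenate([pos, neg])
        labels = np.array([1] * n + [0] * n)
        groups = np.array(["g"] * 2 * n)
        rep = subgroup_performance(scores, labels, groups, threshold=0.5,
                                   eval_cfg=EvalConfig(n_boot=50))
        row = rep.row("g")
        assert row["youden_j"] == pytest.approx(expected_j, abs=1e-12)
        assert row["youden_j"] == pytest.approx(row["tpr"] - row["fpr"])

    def test_all_negative_group_flags_tpr(self, rng):
        scores = rng.random(80)
        labels = np.array([0] * 40 + [1] * 40)
        groups = np.array(["neg_only"] * 40 + ["mixed"] * 40)
        labels[groups == "neg_only"] = 0
        rep = subgroup_performance(scores, labels, groups, 0.5, EvalConfig(n_boot=50))
        row = rep.row("neg_only")
        assert "tpr_undefined" in row["flags"]
        assert row["fpr"] is not None and not np.isnan(row["fpr"])

    def test_j_identity_on_every_row(self, rng):
        scores = rng.random(300)
        labels = rng.integers(0, 2, 300)
        groups = rng.choice(["a", "b", "c"], 300)
        rep = subgroup_performance(scores, labels, groups, 0.4, EvalConfig(n_boot=50))
        for _, row in rep.table.iterrows():
            if row["youden_j"] is not None:
                assert row["youden_j"] == pytest.approx(row["tpr"] - row["fpr"])
                assert -1.0 <= row["youden_j"] <= 1.0


# ---------- one-vs-rest ----------

class TestOneVsRest:
    def test_one_hot_scores_perfect(self):
        labels = np.array(["a", "b", "c"] * 10)
        scores = np.zeros((30, 3))
        for j, c in enumerate(["a", "b", "c"]):
            scores[labels == c, j] = 1.0
        table = one_vs_rest_auc(scores, labels, classes=["a", "b", "c"])
        assert (table["auc"] == 1.0).all()

    def test_uniform_scores_near_chance(self, rng):
        labels = rng.choice(["a", "b", "c"], 2000)
        scores = rng.random((2000, 3))
        table = one_vs_rest_auc(scores, labels, classes=["a", "b", "c"])
        assert table["auc"].between(0.45, 0.55).all()

    def test_absent_class_flagged(self, rng):
        labels = np.array(["a", "b"] * 10)
        scores = rng.random((20, 3))
        table = one_vs_rest_auc(scores, labels, classes=["a", "b", "c"])
        row = table.set_index("class").loc["c"]
        assert row["flag"] == "class_absent"
        assert pd.isna(row["auc"])


# ---------- bootstrap ----------

class TestBootstrapCI:
    def test_constant_statistic_zero_width(self, rng):
        data = rng.random(50)
        lo, hi = bootstrap_ci(lambda x: 0.7, data, EvalConfig(n_boot=100))
        assert lo == hi == 0.7

    def test_point_estimate_inside_interval(self, rng):
        data = rng.normal(size=200)
        lo, hi = bootstrap_ci(np.mean, data, EvalConfig(n_boot=400, boot_seed=1))
        assert lo <= data.mean() <= hi

    def test_deterministic_under_seed(self, rng):
        data = rng.random(100)
        cfg = EvalConfig(n_boot=200, boot_seed=7)
        assert bootstrap_ci(np.mean, data, cfg) == bootstrap_ci(np.mean, data, cfg)

    def test_stratified_resampling_preserves_stratum_sizes(self, rng):
        labels = np.array([0] * 30 + [1] * 70)
        # statistic = positive fraction; stratified resampling keeps it fixed
        lo, hi = bootstrap_ci(
            lambda y: y.mean(), labels, EvalConfig(n_boot=100), strata=labels
        )
        assert lo == hi == pytest.approx(0.7)

    def test_empty_data_raises(self):
        with pytest.raises(ValueError):
            bootstrap_ci(np.mean, np.array([]), EvalConfig(n_boot=10))
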