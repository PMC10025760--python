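import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from encodeaudit import nn
from encodeaudit.inspection import (
    _ks,
    alignment_summary,
    inspect,
    ks_table,
    marginal_ks_table,
)
from encodeaudit.models import Backbone, ModelBundle, build_backbone, train_multitask, train_single_task
from encodeaudit.synthetic import CohortConfig, make_cohort

HSET = settings(max_examples=50, deadline=None, derandomize=True)


def ks_bruteforce(a, b):
    """Max |ECDF_a - ECDF_b| over all sample points."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    best = 0.0
    for t in np.concatenate([a, b]):
        d = abs(np.mean(a <= t) - np.mean(b <= t))
        best = max(best, d)
    return best


def identity_bundle(cohort):
    """Bundle whose backbone is the identity map and whose disease head reads
    the generating focal-label direction; used to craft known feature spaces."""
    d = cohort.features.shape[1]
    bb = Backbone(
        kind="external",
        input_spec={"feature_fn": lambda x: np.asarray(x), "feature_dim": d},
        feature_dim=d,
        seed=0,
        net=lambda x: np.asarray(x),
        input_type="features",
    )
    rng = np.random.default_rng(0)
    head = nn.Dense(d, len(cohort.label_names), rng)
    return ModelBundle(
        backbone=bb,
        heads={"disease": head},
        head_kinds={"disease": "bce"},
        label_names=list(cohort.label_names),
    )


@pytest.fixture(scope="module")
def small_inspection():
    cohort = make_cohort(CohortConfig(n=900), seed=60)
    bb = build_backbone("mlp", {"input_dim": cohort.features.shape[1]}, seed=60)
    bundle = train_single_task(bb, cohort, epochs=8, seed=60)
    test = cohort.split("test")
    result = inspect(bundle, test, plot_sample=50, seed=60, tsne_iter=260)
    return cohort, bundle, test, result


class TestInspect:
    def test_pca_modes_orthonormal(self, small_inspection):
        *_, result = small_inspection
        gram = result.pca_modes @ result.pca_modes.T
        np.testing.assert_allclose(gram, np.eye(4), atol=1e-8)

    def test_explained_variance_nonincreasing_in_unit_interval(self, small_inspection):
        *_, result = small_inspection
        ev = result.explained_variance
        assert (np.diff(ev) <= 1e-12).all()
        assert ((ev >= 0) & (ev <= 1)).all()

    def test_every_sample_has_one_disease_overlay_class(self, small_inspection):
        *_, result = small_inspection
        assert set(result.overlay["disease_class"]).issubset(
            {"no_finding", "condition_x", "other"}
        )
        assert len(result.overlay) == len(result.pca_projections)

    def test_logit_pair_is_pre_sigmoid(self, small_inspection):
        _, bundle, test, result = small_inspection
        from encodeaudit.models import predict_logits

        z = predict_logits(bundle, test, head="disease")
        nf = bundle.label_names.index("no_finding")
        cx = bundle.label_names.index("condition_x")
        np.testing.assert_allclose(result.logit_xy, z[:, [nf, cx]])

    def test_plot_subsample_per_group_with_replacement_flag(self, small_inspection):
        *_, result = small_inspection
        # minority group smaller than requested 50 is impossible here; check bookkeeping
        assert result.manifest["plot_sample_per_group"] == 50
        assert len(result.plot_indices) >= 50

    def test_tsne_deterministic_under_seed(self):
        cohort = make_cohort(CohortConfig(n=300), seed=61)
        bundle = identity_bundle(cohort)
        test = cohort.subset(np.arange(250))
        a = inspect(bundle, test, plot_sample=20, seed=3, tsne_iter=260)
        b = inspect(bundle, test, plot_sample=20, seed=3, tsne_iter=260)
        np.testing.assert_array_equal(a.tsne_xy, b.tsne_xy)

    def test_designed_covariance_disease_separates_group_does_not(self):
        # features carry only the disease factor plus isotropic noise
        cfg = CohortConfig(n=2500)
        cfg.signal_strengths = {"disease": 2.5, "group": 0.0, "sex": 0.0,
                                "age": 0.0, "filler": 0.0}
        cohort = make_cohort(cfg, seed=62)
        bundle = identity_bundle(cohort)
        result = inspect(bundle, cohort, plot_sample=100, seed=62, tsne_iter=260)
        table = marginal_ks_table(result)
        mode1 = table[table["axis"] == "pca_mode_1"].set_index("pair")
        assert mode1.loc["no_finding/condition_x", "p_adj"] < 0.05
        group_rows = table[table["pair"].isin(["g0/g1", "g1/g2", "g2/g0"])
                           & table["axis"].str.startswith("pca")]
        assert (group_rows["p_adj"] > 0.05).all()


class TestFigures:
    def test_inspection_figure_written(self, small_inspection, tmp_path):
        from encodeaudit.figures import plot_inspection

        *_, result = small_inspection
        out = tmp_path / "inspection.png"
        plot_inspection(result, out)
        assert out.exists() and out.stat().st_size > 0


class TestKSTable:
    def test_identical_samples(self):
        d, p = _ks(np.arange(10.0), np.arange(10.0))
        assert d == 0.0 and p == 1.0

    def test_disjoint_supports(self):
        d, _ = _ks(np.arange(10.0), np.arange(10.0) + 100.0)
        assert d == 1.0

    def test_worked_example_matches_cdf_oracle(self):
        a = np.array([0.1, 0.2, 0.3])
        b = np.array([0.25, 0.35, 0.45])
        d, _ = _ks(a, b)
        assert d == pytest.approx(ks_bruteforce(a, b))

    @HSET
    @given(
        st.lists(st.integers(0, 20), min_size=2, max_size=50),
        st.lists(st.integers(0, 20), min_size=2, max_size=50),
    )
    def test_ks_statistic_equals_bruteforce(self, xs, ys):
        a = np.asarray(xs, float) / 4.0
        b = np.asarray(ys, float) / 4.0
        d, _ = _ks(a, b)
        assert d == pytest.approx(ks_bruteforce(a, b), abs=1e-12)

    def test_by_adjustment_monotone_and_bounded(self, rng):
        axes = {f"ax{i}": rng.standard_normal(120) for i in range(4)}
        overlay = pd.DataFrame(
            {
                "disease_class": rng.choice(["no_finding", "condition_x", "other"], 120),
                "group": rng.choice(["g0", "g1", "g2"], 120),
                "sex": rng.choice(["male", "female"], 120),
            }
        )
        table = ks_table(axes, overlay)
        ok = table.dropna(subset=["p_raw"]).sort_values("p_raw")
        assert (ok["p_adj"] >= ok["p_raw"] - 1e-12).all()
        assert (ok["p_adj"].diff().dropna() >= -1e-12).all()
        assert (ok["p_adj"] <= 1.0).all()
        assert ((table["p_adj"] < 0.05) == table["significant"]).all()

    def test_absent_pair_member_flagged(self, rng):
        axes = {"ax": rng.standard_normal(40)}
        overlay = pd.DataFrame(
            {
                "disease_class": ["other"] * 40,
                "group": ["g0"] * 40,
                "sex": rng.choice(["male", "female"], 40),
            }
        )
        table = ks_table(axes, overlay)
        flagged = table[table["pair"] == "g0/g1"]
        assert (flagged["flag"] == "pair_member_absent").all()


class TestAlignmentSummary:
    def test_multitask_sex_mode_differs_from_disease_mode(self):
        cfg = CohortConfig(n=4000)
        cfg.signal_strengths = dict(cfg.signal_strengths, sex=2.5, group=2.0)
        cohort = make_cohort(cfg, seed=63)
        spec = {"input_dim": cohort.features.shape[1]}
        single = train_single_task(build_backbone("mlp", spec, seed=63), cohort,
                                   epochs=10, seed=63)
        multi = train_multitask(build_backbone("mlp", spec, seed=63), cohort,
                                epochs=10, seed=63)
        test = cohort.split("test")
        res_s = inspect(single, test, plot_sample=100, seed=63, tsne_iter=260)
        res_m = inspect(multi, test, plot_sample=100, seed=63, tsne_iter=260)
        table = alignment_summary(res_s, res_m)
        mt = table[table["model"] == "multitask"].pivot(
            index="mode", columns="attribute", values="separation"
        )
        assert mt["sex"].idxmax() != mt["disease_class"].idxmax()

    def test_no_group_encoding_gives_low_group_separation(self):
        cfg = CohortConfig(n=2500, encoding="none")
        cohort = make_cohort(cfg, seed=64)
        bundle = identity_bundle(cohort)
        res = inspect(bundle, cohort, plot_sample=100, seed=64, tsne_iter=260)
        table = alignment_summary(res, res)
        grp = table[(table["model"] == "single_task") & (table["attribute"] == "group")]
        assert (grp["separation"] < 0.2).all()

    def test_mismatched_cohorts_rejected(self):
        a = make_cohort(CohortConfig(n=300), seed=65)
        b = make_cohort(CohortConfig(n=320), seed=66)
        res_a = inspect(identity_bundle(a), a, plot_sample=20, seed=0, tsne_iter=260)
        res_b = inspect(identity_bundle(b), b, plot_sample=20, seed=0, tsne_iter=260)
        with pytest.raises(ValueError):
            alignment_summary(res_a, res_b)

    def test_single_class_attribute_flagged(self):
        cohort = make_cohort(CohortConfig(n=300), seed=67)
        cohort.data["sex"] = "female"
        res = inspect(identity_bundle(cohort), cohort, plot_sample=20, seed=0,
                      tsne_iter=260)
        table = alignment_summary(res, res)
        sex_rows = table[table["attribute"] == "sex"]
        assert (sex_rows["flag"] == "single_class").all()
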