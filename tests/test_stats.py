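import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from conftest import make_table
from lipidims.stats import (PLSDiscriminantAnalysis, call_regulated,
                            cross_compartment_correlation, factorial_anova,
                            normality_gated_test, pca_scores, plsda_vip,
                            saturation_totals, sum_lipid_classes)


class TestClassSums:
    def _table(self):
        values = pd.DataFrame([[2.0, 3.0, 5.0]], index=["s1"],
                              columns=["pc1", "pc2", "tg1"])
        feature_meta = {
            "class_code": ["PC", "PC", "TG"],
            "annotated": [True, True, True],
            "top_annotation": ["PC 34:1", "PC 36:2", "TG 52:2"],
        }
        return make_table(values, feature_meta=feature_meta)

    def test_worked_example_with_tg_pl_ratio(self):
        sums = sum_lipid_classes(self._table())
        assert sums.loc["s1", "PC"] == 5.0
        assert sums.loc["s1", "TG"] == 5.0
        assert sums.loc["s1", "TG_PL_ratio"] == 1.0

    def test_isobar_counted_once_under_top_rank(self):
        values = pd.DataFrame([[4.0]], index=["s1"], columns=["amb"])
        table = make_table(values, feature_meta={
            "class_code": ["PE"], "annotated": [True],
            "top_annotation": ["PC 34:1"]})  # PE ion, PC-ranked isobar group
        sums = sum_lipid_classes(table)
        assert sums.loc["s1", "PC"] == 4.0
        assert "PE" not in sums.columns

    def test_unannotated_reported_separately(self):
        values = pd.DataFrame([[1.0, 9.0]], index=["s1"], columns=["x", "pc"])
        table = make_table(values, feature_meta={
            "class_code": [None, "PC"], "annotated": [False, True],
            "top_annotation": [None, "PC 34:1"]})
        sums = sum_lipid_classes(table)
        assert sums.loc["s1", "unassigned"] == 1.0

    def test_glycerides_pooled_and_naive_oracle_agrees(self):
        rng = np.random.default_rng(0)
        codes = ["PC", "PE", "TG", "DG", "MG", "SM"] * 3
        values = pd.DataFrame(rng.uniform(0, 5, (4, len(codes))),
                              index=[f"s{i}" for i in range(4)],
                              columns=[f"f{i}" for i in range(len(codes))])
        table = make_table(values, feature_meta={
            "class_code": codes, "annotated": [True] * len(codes),
            "top_annotation": [f"{c} 34:1" for c in codes]})
        sums = sum_lipid_classes(table)
        for sample in values.index:
            oracle = {}
            for fid, code in zip(values.columns, codes):
                bucket = "TG" if code in {"MG", "DG", "TG"} else code
                oracle[bucket] = oracle.get(bucket, 0.0) + values.loc[sample, fid]
            for bucket, total in oracle.items():
                assert sums.loc[sample, bucket] == pytest.approx(total, rel=1e-12)


class TestSaturationTotals:
    def test_double_bond_buckets_partition_totals(self):
        values = pd.DataFrame([[1.0, 2.0, 4.0, 8.0]], index=["s1"],
                              columns=["fa160", "fa181", "fa226", "noise"])
        table = make_table(values, feature_meta={
            "class_code": ["FA", "FA", "FA", None],
            "annotated": [True, True, True, False],
            "double_bonds": [0, 1, 6, np.nan],
            "top_annotation": ["FA 16:0", "FA 18:1", "FA 22:6", None]})
        out = saturation_totals(table)
        assert out.loc["s1"].tolist() == [1.0, 2.0, 4.0]
        assert out.loc["s1"].sum() == 7.0  # unannotated excluded
        assert out.attrs["n_unannotated"] == 1

    def test_all_saturated(self):
        values = pd.DataFrame([[1.0, 1.0]], index=["s"], columns=["a", "b"])
        table = make_table(values, feature_meta={
            "class_code": ["FA", "FA"], "annotated": [True, True],
            "double_bonds": [0, 0]})
        out = saturation_totals(table)
        assert out.loc["s", "MUFA"] == 0.0 and out.loc["s", "PUFA"] == 0.0


class TestNormalityGatedTest:
    def test_normal_groups_take_t_route(self):
        test, p = normality_gated_test([1, 2, 3, 4, 5], [2, 3, 4, 5, 6])
        assert test == "t"
        assert p == pytest.approx(0.3466, abs=2e-4)

    def test_identical_constant_groups(self):
        test, p = normality_gated_test([2.0] * 5, [2.0] * 5)
        assert test == "mann_whitney" and p == 1.0

    def test_skewed_group_routes_to_mann_whitney(self):
        rng = np.random.default_rng(0)
        x = np.exp(rng.normal(0, 2, 25))  # heavily skewed
        y = rng.normal(0, 1, 25)
        assert sps.shapiro(x).pvalue < 0.05  # the gate's premise
        test, _ = normality_gated_test(x, y)
        assert test == "mann_whitney"

    def test_small_groups_rejected(self):
        with pytest.raises(ValueError):
            normality_gated_test([1, 2], [1, 2, 3])

    def test_calibration_of_each_route(self):
        """Both branch tests hold their nominal level on unconditioned
        normal data (the gate's conditional selection is documented as
        anti-conservative for the rank branch)."""
        rng = np.random.default_rng(11)
        n = 4000
        t_hits = t_n = 0
        mw_hits = 0
        for _ in range(n):
            x, y = rng.normal(size=8), rng.normal(size=8)
            test, p = normality_gated_test(x, y)
            if test == "t":
                t_n += 1
                t_hits += p < 0.05
            mw_hits += sps.mannwhitneyu(x, y, method="exact").pvalue < 0.05
        for rate, count in ((t_hits / t_n, t_n), (mw_hits / n, n)):
            se = np.sqrt(0.05 * 0.95 / count)
            assert abs(rate - 0.05) < 3 * se


class TestPLSDA:
    def test_vip_normalization_identity(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(14, 25))
        y = np.array(["A"] * 7 + ["B"] * 7)
        vip = plsda_vip(X, y)
        assert (vip ** 2).sum() == pytest.approx(25.0, abs=1e-6)

    def test_informative_feature_attains_top_vip(self):
        rng = np.random.default_rng(2)
        y = np.array(["A"] * 8 + ["B"] * 8)
        X = rng.normal(size=(16, 10))
        X[:, 3] = np.where(y == "A", -1.0, 1.0)
        vip = plsda_vip(X, y)
        assert vip.argmax() == 3 and vip[3] > 1.0

    def test_component_cap_leaves_result_unchanged(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(6, 12))
        y = np.array(["A", "A", "A", "B", "B", "B"])
        big = PLSDiscriminantAnalysis(n_components=40).fit(X, y)
        assert big.n_components_ <= 5  # capped at the effective rank
        at_rank = PLSDiscriminantAnalysis(n_components=big.n_components_).fit(X, y)
        np.testing.assert_allclose(big.vip_, at_rank.vip_, rtol=1e-10)

    def test_zero_variance_feature_warned_and_zeroed(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(10, 5))
        X[:, 2] = 7.0
        y = np.array(["A"] * 5 + ["B"] * 5)
        with pytest.warns(UserWarning, match="zero-variance"):
            vip = plsda_vip(X, y)
        assert vip[2] == 0.0

    def test_matches_sklearn_pls_weights(self):
        """Independent cross-check: VIP recomputed from sklearn's NIPALS
        PLS regression agrees with ours."""
        from sklearn.cross_decomposition import PLSRegression

        rng = np.random.default_rng(5)
        X = rng.normal(size=(20, 8))
        y = np.array(["A"] * 10 + ["B"] * 10)
        ours = PLSDiscriminantAnalysis(n_components=2).fit(X, y)

        yv = np.where(y == "B", 1.0, -1.0)
        skl = PLSRegression(n_components=2, scale=True).fit(X, yv)
        W = skl.x_weights_
        T = skl.x_scores_
        Q = skl.y_loadings_.ravel()
        ssy = Q ** 2 * (T ** 2).sum(axis=0)
        w2 = (W / np.linalg.norm(W, axis=0)) ** 2
        vip_skl = np.sqrt(X.shape[1] * (w2 @ ssy) / ssy.sum())
        np.testing.assert_allclose(ours.vip_, vip_skl, rtol=1e-6)

    def test_predicts_training_classes_on_separable_data(self):
        rng = np.random.default_rng(6)
        y = np.array(["A"] * 6 + ["B"] * 6)
        X = rng.normal(size=(12, 4)) + np.where(y == "B", 3.0, 0.0)[:, None]
        model = PLSDiscriminantAnalysis().fit(X, y)
        assert (model.predict(X) == y).all()


class TestCallRegulated:
    @pytest.mark.parametrize(
        "p, vip, expected",
        [(0.03, 1.2, True), (0.03, 0.9, False), (0.06, 2.0, False)],
    )
    def test_conjunction_rule(self, p, vip, expected):
        records = pd.DataFrame({"p_value": [p], "vip": [vip]})
        out = call_regulated(records)
        assert bool(out["regulated"].iloc[0]) is expected

    def test_regulated_set_subset_of_significant(self):
        rng = np.random.default_rng(7)
        records = pd.DataFrame({"p_value": rng.uniform(0, 0.2, 100),
                                "vip": rng.uniform(0, 3, 100)})
        out = call_regulated(records)
        assert set(out.index[out["regulated"]]) <= set(out.index[out["p_value"] < 0.05])
        assert out["p_bh_fdr"].between(0, 1).all()


class TestFactorialAnova:
    def test_balanced_textbook_values(self):
        values = [1, 2, 1, 2, 3, 4, 3, 4]
        diet = ["CTL"] * 4 + ["OB"] * 4
        sex = ["M", "M", "F", "F"] * 2
        rec = factorial_anova(values, diet, sex)
        assert rec.f_diet == pytest.approx(16.0, abs=1e-9)
        assert rec.p_diet == pytest.approx(0.0161, abs=1e-4)
        assert rec.f_sex == pytest.approx(0.0, abs=1e-9)
        assert rec.f_interaction == pytest.approx(0.0, abs=1e-9)

    def test_sex_label_swap_preserves_diet_p(self):
        values = [1, 2, 1, 2, 3, 4, 3, 4]
        diet = ["CTL"] * 4 + ["OB"] * 4
        sex = ["M", "M", "F", "F"] * 2
        swapped = ["F", "F", "M", "M"] * 2
        assert (factorial_anova(values, diet, sex).p_diet
                == pytest.approx(factorial_anova(values, diet, swapped).p_diet))

    def test_degenerate_data_rejected(self):
        with pytest.raises(ValueError):
            factorial_anova([5.0] * 8, ["CTL"] * 4 + ["OB"] * 4,
                            ["M", "M", "F", "F"] * 2)

    def test_sparse_cells_rejected(self):
        with pytest.raises(ValueError):
            factorial_anova([1, 2, 3, 4], ["CTL", "CTL", "OB", "OB"],
                            ["M", "M", "M", "M"])


class TestCrossCompartmentCorrelation:
    def _frames(self, y_map):
        maternal = pd.DataFrame({"sp": [1.0, 2.0, 3.0]}, index=["d1", "d2", "d3"])
        fetal = pd.DataFrame({
            "dam_id": ["d1", "d1", "d2", "d2", "d3", "d3"],
            "sp": [y_map(1.0)] * 2 + [y_map(2.0)] * 2 + [y_map(3.0)] * 2})
        return maternal, fetal

    def test_identity_relationship(self):
        out = cross_compartment_correlation(*self._frames(lambda v: v))
        row = out.loc["sp"]
        assert row["pearson_r"] == pytest.approx(1.0)
        assert row["slope"] == pytest.approx(1.0)
        assert row["intercept"] == pytest.approx(0.0, abs=1e-12)

    def test_anticorrelated(self):
        out = cross_compartment_correlation(*self._frames(lambda v: 4.0 - v))
        assert out.loc["sp", "pearson_r"] == pytest.approx(-1.0)

    def test_doubling_slope(self):
        out = cross_compartment_correlation(*self._frames(lambda v: 2.0 * v))
        assert out.loc["sp", "slope"] == pytest.approx(2.0)
        assert out.loc["sp", "pearson_r"] == pytest.approx(1.0)

    def test_fetal_values_averaged_per_dam(self):
        maternal = pd.DataFrame({"sp": [1.0, 2.0, 3.0]}, index=["d1", "d2", "d3"])
        fetal = pd.DataFrame({"dam_id": ["d1", "d1", "d2", "d3"],
                              "sp": [0.0, 2.0, 2.0, 3.0]})  # d1 mean = 1
        out = cross_compartment_correlation(maternal, fetal)
        assert out.loc["sp", "pearson_r"] == pytest.approx(1.0)

    def test_zero_variance_reported_na(self):
        out = cross_compartment_correlation(*self._frames(lambda v: 5.0))
        assert np.isnan(out.loc["sp", "pearson_r"])

    def test_too_few_pairs_rejected(self):
        maternal = pd.DataFrame({"sp": [1.0, 2.0]}, index=["d1", "d2"])
        fetal = pd.DataFrame({"dam_id": ["d1", "d2"], "sp": [1.0, 2.0]})
        with pytest.raises(ValueError):
            cross_compartment_correlation(maternal, fetal)


class TestPCA:
    def test_duplicated_samples_identical_scores(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(5, 4))
        X2 = np.vstack([X, X[0]])
        scores, _ = pca_scores(X2)
        np.testing.assert_allclose(scores.iloc[0], scores.iloc[-1], atol=1e-12)

    def test_one_dimensional_data_pc1_explains_all(self):
        t = np.linspace(0, 1, 8)
        X = np.column_stack([t, 2 * t])
        _, explained = pca_scores(X)
        assert explained[0] == pytest.approx(1.0)

    def test_explained_fractions_sum_to_one(self):
        rng = np.random.default_rng(9)
        _, explained = pca_scores(rng.normal(size=(10, 6)))
        assert explained.sum() == pytest.approx(1.0, abs=1e-9)

    def test_fewer_than_two_samples_rejected(self):
        with pytest.raises(ValueError):
            pca_scores(np.ones((1, 3)))
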