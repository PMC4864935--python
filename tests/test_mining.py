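"""Joint mining: screens, CCA, Cox models, KM / log-rank."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import histobof as hb
from histobof import PlantedJointSpec, gen_joint_dataset
from histobof.exceptions import DegenerateInputError, ParameterError


def _with_feature(ds, name, values):
    ds.features[name] = values
    return ds


class TestCorrelationScreen:
    def test_identical_columns_kept_with_rho_one(self):
        ds = gen_joint_dataset(PlantedJointSpec(n=40, seed=1))
        ds.features["freq_C.01"] = ds.expression["gene_01"]
        tab = hb.correlate_features_genes(ds)
        row = tab[(tab.feature == "freq_C.01") & (tab.gene == "gene_01")].iloc[0]
        assert row.rho == pytest.approx(1.0) and row.kept

    def test_exact_negative_kept_by_absolute_rule(self):
        ds = gen_joint_dataset(PlantedJointSpec(n=40, seed=2))
        ds.features["freq_C.01"] = -ds.expression["gene_01"]
        tab = hb.correlate_features_genes(ds)
        row = tab[(tab.feature == "freq_C.01") & (tab.gene == "gene_01")].iloc[0]
        assert row.rho == pytest.approx(-1.0) and row.kept

    def test_matches_textbook_pearson_on_four_points(self):
        ds = gen_joint_dataset(PlantedJointSpec(n=4, n_features=1, n_genes=1,
                                                seed=3))
        ds.features.iloc[:, 0] = [1.0, 2.0, 4.0, 8.0]
        ds.expression.iloc[:, 0] = [0.5, 1.0, 3.0, 5.0]
        tab = hb.correlate_features_genes(ds)
        r, p = stats.pearsonr(ds.features.iloc[:, 0], ds.expression.iloc[:, 0])
        assert tab.rho.iloc[0] == pytest.approx(r, abs=1e-12)
        assert tab.p_value.iloc[0] == pytest.approx(p, abs=1e-12)

    def test_zero_variance_pair_not_testable(self):
        ds = gen_joint_dataset(PlantedJointSpec(n=30, seed=4))
        ds.features["freq_C.01"] = 1.0
        tab = hb.correlate_features_genes(ds)
        rows = tab[tab.feature == "freq_C.01"]
        assert (~rows.testable).all() and (~rows.kept).all()

    def test_planted_correlation_recovered(self):
        # planted bivariate-normal rho = 0.6 at n = 65: the mean estimate is
        # close to the target and the screen keeps the pair most of the time
        rhos, kept = [], 0
        reps = 300
        for i in range(reps):
            ds = gen_joint_dataset(PlantedJointSpec(
                n=65, n_features=2, n_genes=2, seed=1000 + i,
                feature_gene_corr=[(0, 0, 0.6)]))
            tab = hb.correlate_features_genes(ds)
            row = tab[(tab.feature == "freq_C.01") &
                      (tab.gene == "gene_01")].iloc[0]
            rhos.append(row.rho)
            kept += int(row.kept)
        assert np.mean(rhos) == pytest.approx(0.6, abs=0.03)
        assert kept / reps > 0.5


class TestSumCorrelatedFeatures:
    def test_group_of_one_is_identity(self, joint_ds):
        s = hb.sum_correlated_features(joint_ds, ["C.02"])
        np.testing.assert_allclose(s, joint_ds.features["freq_C.02"])

    def test_pooling_raises_correlation(self):
        # three features each sharing a latent driver with one gene: their
        # sum correlates more strongly than any single feature
        rng = np.random.default_rng(5)
        n = 400
        latent = rng.normal(size=n)
        feats = pd.DataFrame(
            {f"freq_C.{i + 1:02d}": 0.5 * latent + rng.normal(size=n)
             for i in range(3)},
            index=[f"s{i}" for i in range(n)])
        expr = pd.DataFrame({"gene_01": 0.5 * latent + rng.normal(size=n)},
                            index=feats.index)
        clin = pd.DataFrame({"T": "T2", "G": "G2"}, index=feats.index)
        surv = pd.DataFrame({"time": 1.0, "event": 1}, index=feats.index)
        ds = hb.JointDataset(feats, expr, clin, surv)
        s = hb.sum_correlated_features(ds, ["C.01", "C.02", "C.03"])
        r_sum = abs(np.corrcoef(s, expr.gene_01)[0, 1])
        r_each = [abs(np.corrcoef(feats.iloc[:, i], expr.gene_01)[0, 1])
                  for i in range(3)]
        assert r_sum > max(r_each)

    def test_unknown_feature_rejected(self, joint_ds):
        with pytest.raises(ParameterError):
            hb.sum_correlated_features(joint_ds, ["C.99"])


class TestDichotomizedClinical:
    def test_identical_groups_give_p_one(self):
        ds = gen_joint_dataset(PlantedJointSpec(n=40, seed=6))
        vals = np.tile([0.1, 0.5, 0.9, 0.3, 0.7], 8)
        ds.features["freq_C.01"] = vals
        ds.clinical["T"] = np.where(np.arange(40) % 2 == 0, "T2", "T3")
        ds.features.loc[ds.clinical["T"] == "T3", "freq_C.01"] = vals[::2]
        ds.features.loc[ds.clinical["T"] == "T2", "freq_C.01"] = vals[::2]
        row = hb.dichotomize_clinical_test(ds, "freq_C.01", "T")
        assert row["p_value"] == pytest.approx(1.0, abs=1e-9)

    def test_large_shift_detected(self):
        ds = gen_joint_dataset(PlantedJointSpec(n=40, seed=7))
        ds.clinical["G"] = np.where(np.arange(40) < 20, "G2", "G3")
        x = np.random.default_rng(8).normal(size=40)
        x[20:] += 10.0  # 10 SD shift
        ds.features["freq_C.01"] = x
        row = hb.dichotomize_clinical_test(ds, "freq_C.01", "G")
        assert row["p_value"] < 1e-6

    def test_grouping_map(self):
        # T2 belongs to the low group, T3 high; G2 low, G3 high
        ds = gen_joint_dataset(PlantedJointSpec(n=30, seed=9))
        ds.clinical["T"] = ["T2"] * 15 + ["T3"] * 15
        ds.features["freq_C.01"] = [0.0] * 15 + [5.0] * 15
        row = hb.dichotomize_clinical_test(ds, "freq_C.01", "T")
        assert row["statistic"] < 0  # low-group mean minus high-group mean

    def test_undersized_group_not_testable(self):
        ds = gen_joint_dataset(PlantedJointSpec(n=30, seed=10))
        ds.clinical["T"] = ["T3"] + ["T2"] * 29
        row = hb.dichotomize_clinical_test(ds, "freq_C.01", "T")
        assert row["testable"] is False


class TestCCA:
    def test_one_by_one_equals_absolute_pearson(self, joint_ds):
        f = joint_ds.features[["freq_C.01"]]
        g = joint_ds.expression[["gene_01"]]
        cc, lam, p = hb.cca_screen(f, g)
        r = np.corrcoef(f.iloc[:, 0], g.iloc[:, 0])[0, 1]
        assert cc[0] == pytest.approx(abs(r), abs=1e-9)

    def test_exact_linear_transform_gives_unit_correlation(self):
        rng = np.random.default_rng(11)
        F = pd.DataFrame(rng.normal(size=(60, 3)))
        E = F @ np.array([[1.0, 0.2], [0.3, -1.0], [0.5, 0.7]])
        cc, lam, p = hb.cca_screen(F, pd.DataFrame(E))
        assert cc[0] == pytest.approx(1.0, abs=1e-8)

    def test_insufficient_samples_rejected(self):
        rng = np.random.default_rng(12)
        F = pd.DataFrame(rng.normal(size=(5, 3)))
        E = pd.DataFrame(rng.normal(size=(5, 3)))
        with pytest.raises(ParameterError):
            hb.cca_screen(F, E)

    def test_rank_deficiency_rejected(self):
        rng = np.random.default_rng(13)
        F = pd.DataFrame(rng.normal(size=(30, 2)))
        F[2] = F[0] + F[1]
        E = pd.DataFrame(rng.normal(size=(30, 2)))
        with pytest.raises(DegenerateInputError):
            hb.cca_screen(F, E)


class TestCoxUnivariate:
    def test_scaling_invariance_of_iqr_standardized_hr(self, joint_ds):
        r1 = hb.cox_univariate(joint_ds, "freq_C.01")
        scaled = joint_ds.features["freq_C.01"] * 37.5
        scaled.name = "scaled"
        r2 = hb.cox_univariate(joint_ds, scaled)
        assert r1.hazard_ratios.iloc[0] == pytest.approx(
            r2.hazard_ratios.iloc[0], rel=1e-9)

    def test_ci_contains_hr(self, joint_ds):
        r = hb.cox_univariate(joint_ds, "freq_C.01")
        hr = r.hazard_ratios.iloc[0]
        assert r.conf_int.iloc[0, 0] < hr < r.conf_int.iloc[0, 1]
        assert hr > 0

    def test_zero_iqr_rejected(self, joint_ds):
        const = pd.Series(1.0, index=joint_ds.features.index, name="c")
        with pytest.raises(ParameterError):
            hb.cox_univariate(joint_ds, const)


class TestImageScore:
    def test_equal_components_return_value(self, joint_ds):
        for c in ("C.01", "C.02", "C.03"):
            joint_ds.features[f"freq_{c}"] = 0.42
        s = hb.image_score(joint_ds, ["C.01", "C.02", "C.03"])
        assert np.allclose(s, 0.42)

    def test_arithmetic_mean(self):
        ds = gen_joint_dataset(PlantedJointSpec(n=10, n_features=5, seed=14))
        ds.features.iloc[0, :5] = [1, 2, 3, 4, 5]
        s = hb.image_score(ds, ["C.01", "C.02", "C.03", "C.04", "C.05"])
        assert s.iloc[0] == pytest.approx(3.0)

    def test_matches_row_mean_oracle(self, joint_ds):
        comps = ["C.01", "C.02", "C.03", "C.04", "C.05"]
        s = hb.image_score(joint_ds, comps)
        oracle = joint_ds.features[[f"freq_{c}" for c in comps]].to_numpy().mean(axis=1)
        np.testing.assert_allclose(s.to_numpy(), oracle, atol=1e-12)

    def test_missing_component_rejected(self, joint_ds):
        with pytest.raises(ParameterError):
            hb.image_score(joint_ds, ["C.01", "C.77"])


class TestCombinedModel:
    def test_duplicated_score_adds_nothing(self, joint_ds):
        score = hb.image_score(joint_ds, ["C.01", "C.02"])
        jitter = pd.Series(
            np.random.default_rng(17).normal(0, 1e-6, len(score)),
            index=score.index)
        with pytest.warns(UserWarning):
            res = hb.combined_model_test(joint_ds, score, score + jitter)
        assert res.lrt_p_vs_univariate["vs_image_only"] > 0.9

    def test_nested_log_likelihood_ordering(self, joint_ds):
        score = hb.image_score(joint_ds, ["C.02", "C.03"])
        res = hb.combined_model_test(joint_ds, score, joint_ds.genomic_score)
        uni = hb.cox_univariate(joint_ds, score.rename("image_score"))
        assert res.bivariate.log_likelihood >= uni.log_likelihood - 1e-8


class TestKMByMedian:
    def test_identical_survival_gives_p_near_one(self):
        ds = gen_joint_dataset(PlantedJointSpec(n=30, seed=15, censoring=0.2))
        dup = hb.JointDataset(
            pd.concat([ds.features] * 2).set_index(
                pd.Index([f"d{i}" for i in range(60)])),
            pd.concat([ds.expression] * 2).set_index(
                pd.Index([f"d{i}" for i in range(60)])),
            pd.concat([ds.clinical] * 2).set_index(
                pd.Index([f"d{i}" for i in range(60)])),
            pd.concat([ds.survival] * 2).set_index(
                pd.Index([f"d{i}" for i in range(60)])),
        )
        score = pd.Series([0.0] * 30 + [1.0] * 30, index=dup.features.index)
        _, p, _ = hb.km_by_median(dup, score)
        assert p > 0.95

    def test_group_sizes_differ_by_at_most_one(self, joint_ds):
        score = joint_ds.features["freq_C.02"]  # continuous, all distinct
        groups, _, _ = hb.km_by_median(joint_ds, score)
        assert abs((groups == "low").sum() - (groups == "high").sum()) <= 1

    def test_constant_score_rejected(self, joint_ds):
        const = pd.Series(2.0, index=joint_ds.features.index)
        with pytest.raises(DegenerateInputError):
            hb.km_by_median(joint_ds, const)


class TestSurvivalAtHorizon:
    def test_monotone_decreasing_in_score_when_hr_above_one(self, joint_ds):
        res = hb.cox_univariate(joint_ds, "freq_C.01")
        s = hb.survival_at_horizon(res, np.linspace(-2, 2, 9), t=4.0)
        assert np.all(np.diff(s.to_numpy()) < 0)

    def test_mean_covariate_matches_baseline_survival(self, joint_ds):
        res = hb.cox_univariate(joint_ds, "freq_C.01")
        cph = res.model
        mean_raw = float(joint_ds.features["freq_C.01"].mean())
        s = hb.survival_at_horizon(res, [mean_raw], t=4.0)
        t_idx = cph.baseline_survival_.index
        base = float(np.interp(4.0, t_idx, cph.baseline_survival_.iloc[:, 0]))
        assert s.iloc[0] == pytest.approx(base, abs=1e-6)

    def test_extrapolation_warns(self, joint_ds):
        res = hb.cox_univariate(joint_ds, "freq_C.01")
        far = float(joint_ds.survival["time"].max()) + 10
        with pytest.warns(UserWarning):
            hb.survival_at_horizon(res, [0.0], t=far)


def test_screens_invariant_to_sample_reordering(joint_ds):
    rng = np.random.default_rng(16)
    perm = rng.permutation(joint_ds.features.index)
    shuffled = hb.JointDataset(
        joint_ds.features.loc[perm], joint_ds.expression.loc[perm],
        joint_ds.clinical.loc[perm], joint_ds.survival.loc[perm],
        joint_ds.genomic_score.loc[perm],
    )
    t1 = hb.correlate_features_genes(joint_ds)
    t2 = hb.correlate_features_genes(shuffled)
    np.testing.assert_allclose(t1.rho.to_numpy(), t2.rho.to_numpy(), atol=1e-12)
    r1 = hb.cox_univariate(joint_ds, "freq_C.01")
    r2 = hb.cox_univariate(shuffled, "freq_C.01")
    assert r1.hazard_ratios.iloc[0] == pytest.approx(
        r2.hazard_ratios.iloc[0], rel=1e-8)
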