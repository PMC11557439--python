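import numpy as np
import pytest
from scipy import stats

from hemocascade import (
    CohortSpec,
    box_cox,
    box_tidwell,
    build_features,
    feature_columns,
    feature_importance,
    fit_predict_cv,
    generate_cohort,
    recover_coefficients,
)
from hemocascade.synthetic import DEFAULT_COEF_A


@pytest.fixture(scope="module")
def cohort():
    return generate_cohort(CohortSpec(n_patients=1000, seed=42))


class TestBuildFeatures:
    def test_basic_has_five_columns(self, cohort):
        X, y, _ = build_features(cohort.head(10), "CRASH_BASIC", scheme="A")
        assert X.shape == (10, 5)
        assert list(X.columns) == feature_columns("CRASH_BASIC")

    def test_full_model_has_sixteen_columns(self, cohort):
        X, _, _ = build_features(cohort, "CRASH_CT_VOL_SUB")
        assert X.shape[1] == 16

    def test_nesting_is_strict(self):
        prev: list = []
        for name in ("CRASH_BASIC", "CRASH_CT", "CRASH_CT_VOL", "CRASH_CT_VOL_SUB"):
            cols = feature_columns(name)
            assert cols[: len(prev)] == prev and len(cols) > len(prev)
            prev = cols

    def test_both_reactive_reference_coding(self, cohort):
        X, _, _ = build_features(cohort, "CRASH_BASIC")
        ref = cohort["pupils"] == "both_reactive"
        assert (X.loc[ref.to_numpy(), ["pupils_one_reactive", "pupils_both_nonreactive"]] == 0).all().all()

    def test_nonevacuated_is_negation(self, cohort):
        X, _, _ = build_features(cohort, "CRASH_CT")
        np.testing.assert_array_equal(
            X["nonevacuated_hematoma"].to_numpy(), 1 - cohort["evacuated_hematoma"].to_numpy()
        )

    def test_missing_columns_reported(self, cohort):
        with pytest.raises(ValueError, match="volume_ml"):
            build_features(cohort.drop(columns=["volume_ml"]), "CRASH_CT_VOL")


class TestBoxCox:
    def test_forced_lambda_one_is_shift(self):
        x = np.array([1.0, 2.0, 5.0])
        y, lam = box_cox(x, lam=1.0)
        np.testing.assert_allclose(y, x - 1)

    def test_forced_lambda_zero_is_log(self):
        x = np.array([1.0, np.e, np.e**2])
        y, _ = box_cox(x, lam=0.0)
        np.testing.assert_allclose(y, [0, 1, 2], atol=1e-12)

    def test_lognormal_data_lambda_near_zero(self):
        x = np.random.default_rng(7).lognormal(0.0, 1.0, 5000)
        _, lam = box_cox(x)
        assert -0.1 <= lam <= 0.1

    def test_matches_scipy_profile_likelihood(self):
        """Independent oracle: scipy's unconstrained Box-Cox MLE."""
        x = np.random.default_rng(11).gamma(4.0, 2.0, 2000)
        _, lam = box_cox(x)
        lam_scipy = stats.boxcox(x)[1]
        assert lam == pytest.approx(lam_scipy, abs=0.01)  # grid resolution

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            box_cox(np.array([1.0, 0.0]))


class TestBoxTidwell:
    def test_constant_predictor_rejected(self):
        y = np.array([0, 1] * 20)
        with pytest.raises(ValueError):
            box_tidwell(np.ones(40), None, y)

    def test_detects_log_nonlinearity(self):
        rng = np.random.default_rng(3)
        n = 2000
        x = rng.lognormal(3.0, 0.5, n)
        p = 1 / (1 + np.exp(-(-6 + 2.0 * np.log(x))))
        y = (rng.random(n) < p).astype(float)
        assert box_tidwell(x, None, y) < 0.01

    def test_accepts_linear_truth(self):
        rng = np.random.default_rng(4)
        n = 2000
        x = rng.lognormal(3.0, 0.5, n)
        p = 1 / (1 + np.exp(-(-2 + 0.08 * x)))
        y = (rng.random(n) < p).astype(float)
        assert box_tidwell(x, None, y) > 0.05


class TestCrossValidation:
    def test_deterministic_under_seed(self, cohort):
        a = fit_predict_cv(cohort, "CRASH_BASIC", "logistic", "A", seed=5)
        b = fit_predict_cv(cohort, "CRASH_BASIC", "logistic", "A", seed=5)
        assert a.fold_metrics == b.fold_metrics
        for ia, ib in zip(a.fold_test_indices, b.fold_test_indices):
            np.testing.assert_array_equal(ia, ib)

    def test_record_order_permutation_invariant_means(self, cohort):
        shuffled = cohort.sample(frac=1.0, random_state=9).reset_index(drop=True)
        a = fit_predict_cv(cohort, "CRASH_CT", "logistic", "A", seed=5)
        b = fit_predict_cv(shuffled, "CRASH_CT", "logistic", "A", seed=5)
        # same records, same stratified design: means agree closely
        assert a.mean("auc") == pytest.approx(b.mean("auc"), abs=0.03)

    def test_five_folds_partition_cohort(self, cohort):
        cv = fit_predict_cv(cohort, "CRASH_BASIC", "logistic", "A", seed=1)
        all_idx = np.sort(np.concatenate(cv.fold_test_indices))
        np.testing.assert_array_equal(all_idx, np.arange(len(cohort)))

    def test_null_cohort_auc_near_chance(self):
        dfn = generate_cohort(CohortSpec.null(n_patients=2000, seed=6))
        cv = fit_predict_cv(dfn, "CRASH_CT_VOL_SUB", "logistic", "A", seed=2)
        assert 0.45 <= cv.mean("auc") <= 0.55

    def test_volume_feature_improves_auc(self):
        df = generate_cohort(CohortSpec(n_patients=2000, seed=3))
        base = fit_predict_cv(df, "CRASH_CT", "logistic", "A", seed=7)
        vol = fit_predict_cv(df, "CRASH_CT_VOL", "logistic", "A", seed=7)
        assert vol.mean("auc") > base.mean("auc")

    def test_scheme_b_uses_death_or_coma(self, cohort):
        cv = fit_predict_cv(cohort, "CRASH_BASIC", "logistic", "B", seed=1)
        assert cv.scheme == "B"

    def test_too_few_records_rejected(self, cohort):
        with pytest.raises(ValueError):
            fit_predict_cv(cohort.head(10), "CRASH_BASIC", "logistic", "A")


class TestCoefficientRecovery:
    def test_wald_intervals_cover_generating_truth(self):
        df = generate_cohort(CohortSpec(n_patients=5000, seed=11))
        est = recover_coefficients(df, "CRASH_CT_VOL_SUB", "A", boxcox_lambda=0.0)
        inside = 0
        for name in est.index:
            true = DEFAULT_COEF_A["intercept" if name == "intercept" else name]
            inside += est.loc[name, "ci_low"] <= true <= est.loc[name, "ci_high"]
        assert inside >= 14  # ~95% coverage over 17 coefficients

    def test_null_cohort_slopes_near_zero(self):
        df = generate_cohort(CohortSpec.null(n_patients=4000, seed=12))
        est = recover_coefficients(df, "CRASH_BASIC", "A", boxcox_lambda=0.0)
        slopes = est.drop(index="intercept")
        assert ((slopes["ci_low"] <= 0) & (0 <= slopes["ci_high"])).sum() >= 4


class TestFeatureImportance:
    def test_requires_random_forest(self, cohort):
        cv = fit_predict_cv(cohort, "CRASH_BASIC", "logistic", "A", seed=1)
        with pytest.raises(ValueError):
            feature_importance(cv)

    def test_shares_sum_to_one_and_sorted(self, cohort):
        cv = fit_predict_cv(
            cohort, "CRASH_CT_VOL", "random_forest", "A", seed=1, rf_trees=50
        )
        ranked = feature_importance(cv)
        shares = [s for _, s in ranked]
        assert sum(shares) == pytest.approx(1.0, abs=1e-9)
        assert shares == sorted(shares, reverse=True)

    def test_dominant_volume_effect_ranks_first(self):
        spec = CohortSpec(n_patients=3000, seed=13)
        spec.coefficients = {**{k: 0.0 for k in spec.coefficients}, "volume_ml": 0.15,
                             "intercept": -2.5}
        df = generate_cohort(spec)
        cv = fit_predict_cv(df, "CRASH_CT_VOL", "random_forest", "A", seed=3, rf_trees=100)
        assert feature_importance(cv)[0][0] == "volume_ml"
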