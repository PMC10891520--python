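"""OLS fitting and the validation-statistics battery."""

import numpy as np
import pandas as pd
import pytest

from ip6kqsar.oracle import brute_force_loo
from ip6kqsar.validation import (
    collinearity,
    external_metrics,
    fit_ols,
    loo_predictions,
    q2_lmo,
    q2_loo,
    rm2_metrics,
    standardized_coefficients,
    validate_model,
    williams_ad,
    y_randomization,
)


class TestFitOLS:
    def test_exact_linear_data_interpolated(self, rng):
        X = pd.DataFrame({"a": rng.normal(size=15), "b": rng.normal(size=15)})
        y = 2.0 * X["a"] - 1.0 * X["b"] + 3.0
        model = fit_ols(X, y)
        assert model.coefficients == pytest.approx([2.0, -1.0], abs=1e-10)
        assert model.intercept == pytest.approx(3.0, abs=1e-10)
        assert np.allclose(model.predict(X), y)

    def test_standard_errors_match_statsmodels_textbook_case(self, random_regression):
        # unbiased residual variance: check one SE by the closed form
        X, y = random_regression(n=25, p=2, seed=3)
        model = fit_ols(X, y)
        A = np.column_stack([np.ones(len(X)), X.to_numpy()])
        resid = y.to_numpy() - A @ np.concatenate([[model.intercept], model.coefficients])
        s2 = resid @ resid / (len(y) - 3)
        cov = s2 * np.linalg.inv(A.T @ A)
        assert model.coefficient_se == pytest.approx(np.sqrt(np.diag(cov))[1:])

    def test_rank_deficiency_names_columns(self, rng):
        X = pd.DataFrame({"a": rng.normal(size=10)})
        X["b"] = 2.0 * X["a"]
        with pytest.raises(np.linalg.LinAlgError, match="a.*b|b.*a"):
            fit_ols(X, pd.Series(rng.normal(size=10)))

    def test_two_points_one_descriptor_warns(self):
        X = pd.DataFrame({"a": [0.0, 1.0]})
        y = pd.Series([1.0, 3.0])
        with pytest.warns(UserWarning, match="degrees of freedom"):
            model = fit_ols(X, y)
        assert model.predict(X) == pytest.approx([1.0, 3.0])


class TestCrossValidation:
    def test_perfect_linear_data(self, rng):
        X = pd.DataFrame({"a": rng.normal(size=12)})
        y = 1.5 * X["a"] + 4.0
        assert q2_loo(X, y) == pytest.approx(1.0)

    def test_closed_form_equals_refit_loop(self, random_regression):
        for seed in range(20):
            X, y = random_regression(
                n=int(10 + 3 * (seed % 7)), p=1 + seed % 4, sigma=0.5, seed=seed
            )
            assert loo_predictions(X, y) == pytest.approx(
                brute_force_loo(X, y), abs=1e-9
            )

    def test_lmo_close_to_loo_and_seeded(self, random_regression):
        X, y = random_regression(n=30, p=3, sigma=0.3, seed=8)
        a = q2_lmo(X, y, groups=5, runs=20, seed=1)
        b = q2_lmo(X, y, groups=5, runs=20, seed=1)
        assert a == b
        assert a == pytest.approx(q2_loo(X, y), abs=0.15)


class TestExternalMetrics:
    def test_f1_equals_f2_when_means_agree(self, random_regression):
        X, y = random_regression(n=20, p=2, seed=5)
        model = fit_ols(X, y)
        Xt, yt = X.iloc[:6], y.iloc[:6]
        out = external_metrics(model, Xt, yt, ytrain_mean=float(yt.mean()))
        assert out["Q2_F1"] == pytest.approx(out["Q2_F2"])

    def test_three_point_hand_computation(self):
        from ip6kqsar.validation import MLRModel

        model = MLRModel(names=["x"], coefficients=[1.0], intercept=0.0)
        Xt = pd.DataFrame({"x": [1.0, 2.0, 3.0]})
        yt = np.array([1.5, 1.5, 3.0])
        # predictions are (1, 2, 3); errors (0.5, -0.5, 0); SSE = 0.5
        # train mean 1.0: denom_F1 = 0.25 + 0.25 + 4 = 4.5
        # test mean 2.0:  denom_F2 = 0.25 + 0.25 + 1 = 1.5
        out = external_metrics(model, Xt, yt, ytrain_mean=1.0)
        assert out["Q2_F1"] == pytest.approx(1 - 0.5 / 4.5)
        assert out["Q2_F2"] == pytest.approx(1 - 0.5 / 1.5)
        assert out["RMSEP"] == pytest.approx(np.sqrt(0.5 / 3))
        assert out["MAE_test"] == pytest.approx(1.0 / 3)


class TestRm2:
    def test_perfect_agreement(self):
        y = np.array([4.0, 5.0, 6.0, 7.0])
        out = rm2_metrics(y, y)
        assert out["rm2"] == pytest.approx(1.0)
        assert out["delta_rm2"] == pytest.approx(0.0)

    def test_five_point_spreadsheet_value(self):
        # through-origin fit computed by hand:
        # yobs = (4, 5, 6, 7, 8), ypred = (4.2, 4.8, 6.3, 6.9, 7.8)
        yo = np.array([4.0, 5.0, 6.0, 7.0, 8.0])
        yp = np.array([4.2, 4.8, 6.3, 6.9, 7.8])
        r2 = np.corrcoef(yo, yp)[0, 1] ** 2
        k = (yo @ yp) / (yo @ yo)
        r02 = 1 - np.sum((yp - k * yo) ** 2) / np.sum((yp - yp.mean()) ** 2)
        expected_fwd = r2 * (1 - np.sqrt(max(r2 - r02, 0.0)))
        out = rm2_metrics(yo, yp)
        assert out["rm2"] == pytest.approx(expected_fwd)
        assert out["delta_rm2"] == pytest.approx(abs(out["rm2"] - out["rm2_reverse"]))

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError):
            rm2_metrics([5.0, 5.0, 5.0], [4.0, 5.0, 6.0])


class TestCollinearity:
    def test_orthogonal_columns_unit_vif(self):
        X = pd.DataFrame({"a": [1, 1, -1, -1], "b": [1, -1, 1, -1]}, dtype=float)
        out = collinearity(X)
        assert out["vif"]["a"] == pytest.approx(1.0)
        assert out["vif"]["b"] == pytest.approx(1.0)
        assert out["max_abs_r"] == pytest.approx(0.0)

    def test_duplicated_column_infinite_vif(self, rng):
        X = pd.DataFrame({"a": rng.normal(size=10)})
        X["b"] = X["a"]
        out = collinearity(X)
        assert np.isinf(out["vif"]["a"])
        assert out["max_abs_r"] == pytest.approx(1.0)


class TestYRandomization:
    def test_strong_signal_high_crp2(self, random_regression):
        X, y = random_regression(n=30, p=3, sigma=0.1, seed=2)
        out = y_randomization(X, y, iterations=100, seed=0)
        assert out["cRp2"] > 0.7

    def test_pure_noise_low_crp2(self, rng):
        X = pd.DataFrame(rng.normal(size=(30, 3)), columns=list("abc"))
        vals = [
            y_randomization(X, pd.Series(rng.normal(size=30)), iterations=100, seed=s)["cRp2"]
            for s in range(10)
        ]
        assert np.mean(vals) < 0.25

    def test_seeded_and_iteration_contract(self, random_regression):
        X, y = random_regression(seed=4)
        assert y_randomization(X, y, seed=7) == y_randomization(X, y, seed=7)
        with pytest.raises(ValueError):
            y_randomization(X, y, iterations=5)


class TestWilliamsAD:
    def test_leverage_sum_is_p_plus_one(self, random_regression):
        X, y = random_regression(n=25, p=4, seed=6)
        model = fit_ols(X, y)
        rep = williams_ad(model, X, y)
        train_h = rep.table.loc[rep.table["set"] == "train", "leverage"]
        assert train_h.sum() == pytest.approx(5.0)
        assert ((train_h > 0) & (train_h <= 1)).all()

    def test_warning_leverage_for_five_descriptors_29_compounds(self, random_regression):
        X, y = random_regression(n=29, p=5, seed=9)
        model = fit_ols(X, y)
        rep = williams_ad(model, X, y)
        assert rep.h_star == pytest.approx(3 * 6 / 29)

    def test_far_test_point_flagged_structural(self, random_regression):
        X, y = random_regression(n=25, p=3, seed=10)
        model = fit_ols(X, y)
        Xt = pd.DataFrame([[50.0, 50.0, 50.0]], columns=X.columns, index=["far"])
        rep = williams_ad(model, X, y, Xt, np.array([5.0]))
        row = rep.table.set_index("id").loc["far"]
        assert row["structural_outlier"]

    def test_clean_fit_no_outliers(self, rng):
        X = pd.DataFrame(rng.normal(size=(30, 3)), columns=list("abc"))
        y = X @ np.array([1.0, 0.5, -1.0]) + 5 + 0.1 * rng.normal(size=30)
        model = fit_ols(X, y)
        rep = williams_ad(model, X, y)
        assert rep.n_response_outliers == 0


class TestStandardizedCoefficients:
    def test_single_descriptor_equals_pearson_r(self, rng):
        X = pd.DataFrame({"a": rng.normal(size=40)})
        y = 2.0 * X["a"] + rng.normal(size=40)
        model = fit_ols(X, y)
        std = standardized_coefficients(model, X, y)
        assert std["a"] == pytest.approx(np.corrcoef(X["a"], y)[0, 1])

    def test_scale_invariance(self, random_regression):
        X, y = random_regression(n=30, p=3, seed=12)
        std1 = standardized_coefficients(fit_ols(X, y), X, y)
        X2 = X.copy()
        X2["x0"] = 10.0 * X2["x0"]
        std2 = standardized_coefficients(fit_ols(X2, y), X2, y)
        assert std1["x0"] == pytest.approx(std2["x0"])


class TestValidateModel:
    def test_full_report_consistency(self, random_regression):
        X, y = random_regression(n=30, p=4, sigma=0.4, seed=1)
        Xt, yt = random_regression(n=8, p=4, sigma=0.4, seed=2)
        model, rep = validate_model(X, y, Xt, yt, seed=3)
        assert 0.0 <= rep.R2 <= 1.0
        assert rep.Q2_LOO <= rep.R2 + 1e-12
        assert rep.R2_adj <= rep.R2
        assert all(v >= 1.0 for v in rep.vif.values())
        assert rep.delta_rm2_LOO >= 0
        assert set(rep.standardized_coefficients) == set(X.columns)
        # report serializes and the markdown table renders all statistics
        assert "Q2_LOO" in rep.to_json()
        assert "RMSEP" in rep.to_markdown()

    def test_row_order_invariance(self, random_regression):
        X, y = random_regression(n=24, p=3, sigma=0.3, seed=14)
        _, rep1 = validate_model(X, y, seed=5)
        perm = np.random.default_rng(0).permutation(len(X))
        _, rep2 = validate_model(X.iloc[perm], y.iloc[perm], seed=5)
        assert rep1.R2 == pytest.approx(rep2.R2)
        assert rep1.Q2_LOO == pytest.approx(rep2.Q2_LOO)
        assert rep1.MAE == pytest.approx(rep2.MAE)
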