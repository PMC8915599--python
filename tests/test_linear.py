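"""Weighted MLR core, GSE and ABSOLV models."""

import numpy as np
import pandas as pd
import pytest

from intrinsol.linear import (
    AbsolvModel,
    CollinearityError,
    FittedLinearModel,
    GSEModel,
    absolv_fit,
    absolv_predict,
    fit_by_class,
    gse_fit,
    gse_fixed_model,
    gse_predict,
    weighted_mlr_fit,
)


@pytest.fixture
def design():
    rng = np.random.default_rng(0)
    X = np.column_stack([np.ones(60), rng.normal(size=(60, 2))])
    beta = np.array([1.0, -2.0, 0.5])
    return X, beta


class TestWeightedMLR:
    def test_equal_sd_equals_ols(self, design):
        X, beta = design
        rng = np.random.default_rng(1)
        y = X @ beta + rng.normal(0, 0.3, len(X))
        m = weighted_mlr_fit(X, y, sd=np.full(len(X), 0.2))
        ols = np.linalg.lstsq(X, y, rcond=None)[0]
        np.testing.assert_allclose(m.params, ols, atol=1e-10)

    def test_duplicate_row_equals_sqrt2_weighting(self, design):
        X, beta = design
        rng = np.random.default_rng(2)
        y = X @ beta + rng.normal(0, 0.3, len(X))
        sd = np.full(len(X), 0.2)
        # duplicating row 0 == halving its sd by sqrt(2)
        m1 = weighted_mlr_fit(np.vstack([X, X[:1]]), np.append(y, y[0]),
                              np.append(sd, sd[0]))
        sd2 = sd.copy()
        sd2[0] /= np.sqrt(2)
        m2 = weighted_mlr_fit(X, y, sd2)
        np.testing.assert_allclose(m1.params, m2.params, atol=1e-8)

    def test_noise_free_recovery(self, design):
        X, beta = design
        m = weighted_mlr_fit(X, X @ beta, sd=np.full(len(X), 0.1))
        np.testing.assert_allclose(m.params, beta, atol=1e-8)

    def test_matches_statsmodels_wls(self, design):
        import statsmodels.api as sm

        X, beta = design
        rng = np.random.default_rng(3)
        sd = rng.uniform(0.1, 0.4, len(X))
        y = X @ beta + rng.normal(0, sd)
        m = weighted_mlr_fit(X, y, sd)
        ref = sm.WLS(y, X, weights=1.0 / np.maximum(sd, 0.05) ** 2).fit()
        np.testing.assert_allclose(m.params, ref.params, atol=1e-10)
        np.testing.assert_allclose(m.bse, ref.bse, rtol=1e-8)

    def test_weighted_residuals_orthogonal_to_design(self, design):
        X, beta = design
        rng = np.random.default_rng(4)
        sd = rng.uniform(0.1, 0.5, len(X))
        y = X @ beta + rng.normal(0, sd)
        m = weighted_mlr_fit(X, y, sd)
        w = 1.0 / np.maximum(sd, 0.05) ** 2
        r = y - X @ m.params
        assert np.abs(X.T @ (w * r)).max() < 1e-6

    def test_collinear_columns_named(self, design):
        X, beta = design
        X = np.column_stack([X, X[:, 1] * 2.0])
        with pytest.raises(CollinearityError):
            weighted_mlr_fit(X, X @ np.append(beta, 0.0),
                             names=["const", "a", "b", "a_copy"])

    def test_json_roundtrip(self, design):
        X, beta = design
        m = weighted_mlr_fit(X, X @ beta, names=["const", "a", "b"])
        back = FittedLinearModel.from_json(m.to_json())
        np.testing.assert_allclose(back.params, m.params)
        assert back.names == m.names


class TestGSE:
    def test_fixed_coefficients_are_canonical(self):
        m = gse_fixed_model()
        assert m.coefficients == {"const": 0.5, "logP": -1.0, "tm25": -0.01}

    @pytest.mark.parametrize("logp,tm,expected", [
        (2.0, 125.0, -2.5),
        (-1.0, 25.0, 1.5),
        (4.0, 14.0, -3.5),   # liquid: melting term clamped to zero
    ])
    def test_predict(self, logp, tm, expected):
        assert gse_predict(logp, tm) == pytest.approx(expected, abs=1e-12)

    def test_strictly_decreasing_in_logp(self):
        lp = np.linspace(-2, 6, 50)
        pred = gse_predict(lp, 150.0)
        np.testing.assert_allclose(np.diff(pred) / np.diff(lp), -1.0, atol=1e-12)

    def test_noise_free_refit_recovers_fixed_coefs(self):
        rng = np.random.default_rng(10)
        logp = rng.normal(2, 1.5, 200)
        tm = rng.uniform(40, 250, 200)
        y = gse_predict(logp, tm)
        m = gse_fit(logp, tm, y)
        np.testing.assert_allclose(
            [m.coefficients[k] for k in ("const", "logP", "tm25")],
            [0.5, -1.0, -0.01], atol=1e-6)

    def test_refit_reports_intercept_tm_correlation(self):
        rng = np.random.default_rng(11)
        logp = rng.normal(2, 1.5, 500)
        tm = rng.uniform(40, 250, 500)
        y = gse_predict(logp, tm) + rng.normal(0, 0.3, 500)
        m = gse_fit(logp, tm, y)
        assert m.extra["const_tm_correlation"] < -0.5  # strong anticorrelation

    def test_too_few_rows(self):
        with pytest.raises(ValueError):
            gse_fit([1.0, 2.0], [100.0, 120.0], [0.0, -1.0])

    def test_facade(self):
        rng = np.random.default_rng(12)
        df = pd.DataFrame({"logP": rng.uniform(0, 4, 30),
                           "tm_C": rng.uniform(50, 250, 30)})
        df["log_s0"] = gse_predict(df["logP"], df["tm_C"])
        res = GSEModel.from_dataframe(df).fit()
        assert "gse_trained" in res.summary()


class TestAbsolv:
    @pytest.fixture
    def fitted(self):
        rng = np.random.default_rng(20)
        X = pd.DataFrame(rng.uniform(0, 2, (100, 5)),
                         columns=["A", "B", "Spi", "E", "V"])
        beta = {"const": 0.3, "A": 1.2, "B": 2.0, "Spi": 0.5,
                "E": -1.0, "V": -3.5, "AB": -2.0}
        y = (beta["const"] + X["A"] * beta["A"] + X["B"] * beta["B"]
             + X["Spi"] * beta["Spi"] + X["E"] * beta["E"] + X["V"] * beta["V"]
             + X["A"] * X["B"] * beta["AB"])
        return X, y, beta, absolv_fit(X, y)

    def test_noise_free_coefficients(self, fitted):
        _, _, beta, m = fitted
        for k, v in beta.items():
            assert m.coefficients[k] == pytest.approx(v, abs=1e-8)

    def test_zero_descriptors_predict_intercept(self, fitted):
        _, _, beta, m = fitted
        zero = {"A": 0, "B": 0, "Spi": 0, "E": 0, "V": 0}
        assert absolv_predict(zero, m) == pytest.approx(beta["const"], abs=1e-8)

    def test_cross_term_activates(self, fitted):
        _, _, beta, m = fitted
        one = {"A": 1.0, "B": 1.0, "Spi": 0, "E": 0, "V": 0}
        expect = beta["const"] + beta["A"] + beta["B"] + beta["AB"]
        assert absolv_predict(one, m) == pytest.approx(expect, abs=1e-8)

    def test_training_residuals_vanish(self, fitted):
        X, y, _, m = fitted
        pred = absolv_predict(X, m)
        assert np.abs(pred - y).max() < 1e-8

    def test_missing_descriptor_named(self, fitted):
        _, _, _, m = fitted
        with pytest.raises(ValueError, match="V"):
            absolv_predict({"A": 1, "B": 1, "Spi": 1, "E": 1}, m)

    def test_facade(self, fitted):
        X, y, beta, _ = fitted
        df = X.assign(log_s0=y)
        res = AbsolvModel.from_dataframe(df).fit()
        assert res.coefficients["B"] == pytest.approx(beta["B"], abs=1e-8)


class TestFitByClass:
    def _frame(self, classes, n_per=60, seed=0):
        rng = np.random.default_rng(seed)
        frames = []
        for i, c in enumerate(classes):
            X = pd.DataFrame(rng.uniform(0, 2, (n_per, 5)),
                             columns=["A", "B", "Spi", "E", "V"])
            X["abclass"] = c
            X["log_s0"] = -1.0 - i + 1.5 * X["A"] - 2.0 * X["V"] \
                + rng.normal(0, 0.05, n_per)
            X["sd_log"] = 0.05
            frames.append(X)
        return pd.concat(frames, ignore_index=True)

    def test_only_acids(self):
        res = fit_by_class(self._frame(["acid"]), "absolv")
        assert set(res["models"]) == {"all", "acid"}

    def test_per_class_and_pooled_recovery(self):
        df = self._frame(["acid", "base"], n_per=150, seed=3)
        res = fit_by_class(df, "absolv")
        c_acid = res["models"]["acid"].coefficients["const"]
        c_base = res["models"]["base"].coefficients["const"]
        c_all = res["models"]["all"].coefficients["const"]
        assert c_acid == pytest.approx(-1.0, abs=0.1)
        assert c_base == pytest.approx(-2.0, abs=0.1)
        assert min(c_acid, c_base) - 0.1 < c_all < max(c_acid, c_base) + 0.1

    def test_small_class_skipped(self):
        df = self._frame(["acid"])
        small = self._frame(["zwitterion"], n_per=5, seed=1)
        res = fit_by_class(pd.concat([df, small], ignore_index=True), "absolv")
        assert "zwitterion" in res["skipped"]

    def test_quaternary_only_input_advises_qa_form(self):
        df = self._frame(["quaternary"])
        res = fit_by_class(df, "absolv")
        assert not res["models"]
        assert "absolv_qa" in res["skipped"]["all"]

    def test_quaternary_routed_to_qa_form(self):
        df = self._frame(["quaternary"])
        res = fit_by_class(df, "absolv_qa")
        assert "all" in res["models"]
        assert res["models"]["all"].form == "absolv_qa"
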