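"""Metrics, splitting protocol, interlab statistics, PCA and the benchmark."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from intrinsol.evaluation import (
    interlab_reproducibility,
    metrics,
    nearest_neighbors,
    pca_fit,
    run_benchmark,
    split_train_test,
)

from conftest import merge_dataset


class TestMetrics:
    def test_perfect_predictions(self):
        y = np.array([-3.0, -5.5, 0.2, -7.1])
        r = metrics(y, y)
        assert (r.r2, r.rmse, r.bias, r.mpp) == (1.0, 0.0, 0.0, 100.0)

    def test_worked_two_point_case(self):
        r = metrics([0.0, 2.0], [1.0, 1.0], p=1)
        assert r.rmse == 1.0 and r.bias == 0.0 and r.r2 == 0.0

    def test_mpp_boundary_inclusive(self):
        obs = np.zeros(4)
        calc = np.array([0.0, 0.5, 0.51, 1.0])
        assert metrics(obs, calc).mpp == 50.0

    def test_f_statistic_formula(self):
        rng = np.random.default_rng(0)
        obs = rng.normal(size=40)
        calc = obs + rng.normal(0, 0.3, 40)
        r = metrics(obs, calc, p=3)
        dev = np.sum((obs - obs.mean()) ** 2)
        rss = np.sum((obs - calc) ** 2)
        assert r.f_stat == pytest.approx((40 - 3 - 1) / 3 * dev / rss)

    def test_f_null_when_underdetermined(self):
        with pytest.warns(UserWarning, match="F statistic"):
            r = metrics([0.0, 1.0, 2.0], [0.1, 1.1, 1.9], p=2)
        assert r.f_stat is None

    def test_r2_can_go_negative(self):
        r = metrics([0.0, 1.0, 2.0], [5.0, -5.0, 9.0])
        assert r.r2 < 0

    def test_rmse_dominates_bias(self):
        rng = np.random.default_rng(1)
        obs = rng.normal(size=30)
        calc = obs + rng.normal(0.5, 0.4, 30)
        r = metrics(obs, calc)
        assert r.rmse**2 >= r.bias**2

    @given(shift=st.floats(min_value=-5, max_value=5))
    @settings(max_examples=30, deadline=None)
    def test_mpp_shift_invariant(self, shift):
        obs = np.array([-3.0, -4.0, -5.0, -2.0])
        calc = np.array([-3.2, -4.7, -5.1, -2.6])
        assert metrics(obs + shift, calc + shift).mpp == metrics(obs, calc).mpp


class TestSplit:
    def test_seventy_thirty(self):
        train, test = split_train_test(range(10), seed=1)
        assert len(train) == 7 and len(test) == 3
        assert sorted(train + test) == list(range(10))

    def test_deterministic(self):
        assert split_train_test(range(50), seed=9) == split_train_test(range(50), seed=9)

    def test_stratified_within_one(self):
        ids = list(range(200))
        labels = ["acid"] * 60 + ["base"] * 80 + ["neutral"] * 40 + ["zwitterion"] * 20
        train, _ = split_train_test(ids, seed=2, stratify_by=labels)
        for lab, total in [("acid", 60), ("base", 80), ("neutral", 40), ("zwitterion", 20)]:
            got = sum(1 for i in train if labels[i] == lab)
            assert abs(got - 0.7 * total) <= 1

    def test_singleton_class_goes_to_train(self):
        with pytest.warns(UserWarning, match="<2 members"):
            train, test = split_train_test(["a", "b", "c"], seed=0,
                                           stratify_by=["x", "x", "lone"])
        assert "c" in train

    def test_bad_fraction(self):
        with pytest.raises(ValueError):
            split_train_test(range(5), fraction=1.5)


class TestInterlab:
    def test_population_sd_two_values(self):
        df = pd.DataFrame({"molecule_id": ["m", "m"], "log_s0": [-3.0, -3.4]})
        rep = interlab_reproducibility(df)
        # population (1/n) form: 0.200, not the sample-SD 0.283
        assert rep.per_molecule["sd"].iloc[0] == pytest.approx(0.200, abs=1e-12)
        assert rep.sd_avg == pytest.approx(0.200, abs=1e-12)

    def test_all_singletons_undefined(self):
        df = pd.DataFrame({"molecule_id": ["a", "b"], "log_s0": [-3.0, -4.0]})
        rep = interlab_reproducibility(df)
        assert rep.sd_avg is None and rep.n_replicated == 0

    def test_noise_free_replicates_give_zero(self):
        df = pd.DataFrame({"molecule_id": ["a"] * 3 + ["b"] * 2,
                           "log_s0": [-2.0] * 3 + [-5.5] * 2})
        rep = interlab_reproducibility(df)
        assert rep.sd_avg == 0.0 and rep.sd_avg_corrected == 0.0

    def test_trend_table_covers_replicated_molecules(self):
        rng = np.random.default_rng(3)
        df = pd.DataFrame({
            "molecule_id": np.repeat([f"m{i}" for i in range(30)], 3),
            "log_s0": np.repeat(rng.uniform(-8, 0, 30), 3) + rng.normal(0, 0.2, 90),
        })
        rep = interlab_reproducibility(df)
        assert rep.trend["n_molecules"].sum() == 30


class TestPCA:
    def test_collinear_features_one_component(self):
        rng = np.random.default_rng(4)
        a = rng.normal(size=100)
        res = pca_fit(np.column_stack([a, 3 * a + 1]))
        assert res.explained_variance_ratio[0] == pytest.approx(1.0, abs=1e-8)

    def test_loadings_orthonormal(self):
        rng = np.random.default_rng(5)
        res = pca_fit(rng.normal(size=(80, 6)))
        np.testing.assert_allclose(res.loadings.T @ res.loadings, np.eye(6), atol=1e-10)

    def test_eigenvalues_match_covariance_oracle(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(100, 10)) @ rng.normal(size=(10, 10))
        res = pca_fit(X)
        Z = (X - X.mean(0)) / X.std(0)
        evals = np.sort(np.linalg.eigvalsh(Z.T @ Z / len(Z)))[::-1]
        got = res.explained_variance_ratio * evals.sum()
        np.testing.assert_allclose(got, evals, atol=1e-8)

    def test_variance_fractions_sum_to_one(self):
        rng = np.random.default_rng(7)
        res = pca_fit(rng.normal(size=(50, 5)))
        assert res.explained_variance_ratio.sum() == pytest.approx(1.0, abs=1e-10)

    def test_zero_variance_column_dropped(self):
        rng = np.random.default_rng(8)
        X = pd.DataFrame({"a": rng.normal(size=30), "b": np.ones(30),
                          "c": rng.normal(size=30)})
        with pytest.warns(UserWarning, match="zero-variance"):
            res = pca_fit(X)
        assert res.dropped == ["b"] and res.columns == ["a", "c"]

    def test_sign_convention(self):
        rng = np.random.default_rng(9)
        res = pca_fit(rng.normal(size=(60, 4)))
        for j in range(res.loadings.shape[1]):
            col = res.loadings[:, j]
            assert col[np.argmax(np.abs(col))] > 0


class TestNearestNeighbors:
    def test_duplicate_query_found_first(self):
        pts = np.array([[0.0, 0], [0, 0], [5, 5], [9, 9]])
        out = nearest_neighbors(pts, ["a", "b", "c", "d"], "a", k=2, ncomp=2)
        assert out["molecule_id"].iloc[0] == "b" and out["distance"].iloc[0] == 0.0

    def test_three_point_line(self):
        pts = np.array([[0.0, 0], [4.0, 0], [10.0, 0]])
        out = nearest_neighbors(pts, ["L", "M", "R"], "M", k=1, ncomp=2)
        assert out["molecule_id"].iloc[0] == "L"

    def test_matches_brute_force(self):
        rng = np.random.default_rng(10)
        pts = rng.normal(size=(200, 5))
        ids = [f"p{i}" for i in range(200)]
        out = nearest_neighbors(pts, ids, "p17", k=5, ncomp=3)
        d = np.sqrt(((pts[:, :3] - pts[17, :3]) ** 2).sum(1))
        d[17] = np.inf
        want = [ids[i] for i in np.argsort(d, kind="stable")[:5]]
        assert out["molecule_id"].tolist() == want

    def test_response_spread_reported(self):
        pts = np.array([[0.0, 0], [1, 0], [0, 1], [8, 8]])
        resp = np.array([-10.4, -8.0, -3.7, -5.0])
        out = nearest_neighbors(pts, list("abcd"), "a", k=2, ncomp=2, responses=resp)
        assert out.attrs["response_variance"] == pytest.approx(np.var([-8.0, -3.7]))

    def test_k_too_large(self):
        with pytest.raises(ValueError):
            nearest_neighbors(np.zeros((3, 2)), list("abc"), "a", k=3, ncomp=2)


class TestBenchmark:
    def test_single_model_block(self, linear_dataset):
        res = run_benchmark(merge_dataset(linear_dataset), models=("gse_fixed",),
                            seed=0, by_class=False)
        assert set(res["table"]["model"]) == {"gse_fixed"}

    def test_absent_class_row_present_with_null_metrics(self, linear_dataset):
        df = merge_dataset(linear_dataset)
        df = df[df["abclass"].isin(["acid", "base", "quaternary"])]
        res = run_benchmark(df, models=("gse_fixed",), seed=0)
        t = res["table"]
        row = t[(t["scope"] == "zwitterion") & (t["split"] == "test")].iloc[0]
        assert row["n"] == 0 and pd.isna(row["rmse"])

    def test_reproducible_under_fixed_seed(self, linear_dataset):
        df = merge_dataset(linear_dataset)
        r1 = run_benchmark(df, models=("gse_trained", "absolv"), seed=5)
        r2 = run_benchmark(df, models=("gse_trained", "absolv"), seed=5)
        pd.testing.assert_frame_equal(r1["table"], r2["table"])

    def test_quaternary_routed_to_qa_model_only(self, linear_dataset):
        df = merge_dataset(linear_dataset)
        res = run_benchmark(df, models=("absolv",), seed=1)
        t = res["table"]
        # the four-class absolv rows never include quaternary molecules
        n_main = t[(t["model"] == "absolv") & (t["scope"] == "all")]["n"].sum()
        n_qa = int((df["abclass"] == "quaternary").sum())
        assert n_main <= len(df) - n_qa
        assert (t[t["model"] == "absolv_qa"]["scope"] == "quaternary").all()
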