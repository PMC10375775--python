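"""Grading model: boundary, SVM duals, DJ weighting, Platt sigmoid, QCEI map."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.metrics import roc_auc_score
from sklearn.metrics.pairwise import rbf_kernel

import licograde as lg
from licograde.qcei_model import default_c_grid, default_gamma_grid

from conftest import SMALL_C_GRID, SMALL_GAMMA_GRID, compliant_feature_table, small_study_config


class TestBoundary:
    def test_training_mean_is_inside_with_zero_distance(self):
        rng = np.random.default_rng(0)
        X = rng.normal(0, 1, (60, 4))
        b = lg.fit_boundary(X)
        assert b.distance2(X.mean(axis=0))[0] == pytest.approx(0.0, abs=1e-18)
        assert b.contains(X.mean(axis=0))[0]

    def test_far_outlier_is_outside(self):
        rng = np.random.default_rng(1)
        X = rng.normal(0, 1, (60, 4))
        point = X.mean(axis=0) + np.array([100.0, 0, 0, 0]) * X.std(axis=0)[0]
        assert not lg.fit_boundary(X).contains(point)[0]

    def test_chi_square_coverage(self):
        """On multivariate normal data the inside fraction matches the
        quantile within 0.02 at n = 5000."""
        rng = np.random.default_rng(2)
        A = rng.normal(0, 1, (5, 5))
        X = rng.normal(0, 1, (5000, 5)) @ A.T + rng.normal(0, 1, 5)
        for q in (0.95, 0.99):
            b = lg.fit_boundary(X, quantile=q)
            assert np.mean(b.contains(X)) == pytest.approx(q, abs=0.02)

    def test_too_few_rows_rejected(self):
        with pytest.raises(ValueError, match="rows"):
            lg.fit_boundary(np.eye(4), quantile=0.99)


class TestTrainSvm:
    def test_two_point_separable_toy(self):
        """Hand-solvable 2-variable dual: both points become support vectors
        and sit on or outside the +-1 margins at large C."""
        X = np.array([[0.0], [1.0]])
        y = np.array([-1, 1])
        model = lg.train_svm(X, y, C=1e6, gamma=1.0, scale=False)
        assert set(model.support) == {0, 1}
        f = model.decision_function(X, scaled=True)
        assert f[0] <= -1.0 + 1e-4
        assert f[1] >= 1.0 - 1e-4
        # dual closed form: alpha_0 = alpha_1 = 1/(1 - K01) for this geometry
        alpha_expected = 1.0 / (1.0 - np.exp(-1.0))
        np.testing.assert_allclose(model.alphas, alpha_expected, rtol=1e-3)

    def test_duplicated_training_set_same_decision_function(self):
        rng = np.random.default_rng(4)
        X = rng.normal(0, 1, (30, 3))
        y = np.where(X[:, 0] + rng.normal(0, 0.5, 30) > 0, 1, -1)
        if len(np.unique(y)) < 2:
            pytest.skip("degenerate draw")
        m1 = lg.train_svm(X, y, C=10.0, gamma=0.5)
        m2 = lg.train_svm(np.vstack([X, X]), np.concatenate([y, y]), C=5.0, gamma=0.5)
        grid = rng.normal(0, 1, (20, 3))
        np.testing.assert_allclose(
            m1.decision_function(grid), m2.decision_function(grid), atol=1e-4
        )

    def test_kkt_conditions_on_random_data(self):
        rng = np.random.default_rng(5)
        X = rng.normal(0, 1, (50, 4))
        y = np.where(rng.uniform(size=50) > 0.5, 1, -1)
        y[:2] = [1, -1]
        model = lg.train_svm(X, y, C=3.0, gamma=0.2)
        assert np.all(model.alphas >= -1e-8)
        assert np.all(model.alphas <= model.C + 1e-8)
        assert abs(model.alphas @ model.y) <= 1e-6 * model.C

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="2 classes"):
            lg.train_svm(np.eye(3), np.ones(3), C=1.0, gamma=1.0)


class TestDualObjective:
    def test_zero_duals_give_zero(self):
        assert lg.dual_objective(np.zeros(3), np.array([1, -1, 1]), np.eye(3)) == 0.0

    def test_single_sample_closed_form(self):
        a = 0.7
        assert lg.dual_objective([a], [1.0], [[1.0]]) == pytest.approx(a - a * a / 2.0)

    def test_matches_brute_force_double_loop(self):
        rng = np.random.default_rng(6)
        n = 12
        alphas = rng.uniform(0, 2, n)
        y = np.where(rng.uniform(size=n) > 0.5, 1.0, -1.0)
        K = rbf_kernel(rng.normal(0, 1, (n, 2)), gamma=0.7)
        brute = sum(alphas) - 0.5 * sum(
            alphas[i] * alphas[j] * y[i] * y[j] * K[i, j]
            for i in range(n)
            for j in range(n)
        )
        assert lg.dual_objective(alphas, y, K) == pytest.approx(brute, rel=1e-12)

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError, match="dimension"):
            lg.dual_objective(np.ones(3), np.ones(3), np.eye(4))


def _toy_model(X, y, C=5.0, gamma=0.3, names=None):
    return lg.train_svm(X, y, C=C, gamma=gamma, feature_subset=names)


class TestDjContributions:
    @pytest.fixture(scope="class")
    def toy(self):
        rng = np.random.default_rng(7)
        n = 40
        y = np.repeat([1, -1], n // 2)
        informative = y + rng.normal(0, 0.6, n)
        X = np.c_[informative, rng.normal(0, 1, n), np.full(n, 3.7), informative * 0 + rng.normal(0, 1, n)]
        return X, y

    def test_constant_feature_has_exactly_zero_dj(self, toy):
        X, y = toy
        model = _toy_model(X, y, names=("inf", "noise", "const", "noise2"))
        table = lg.dj_contributions(model).set_index("index")
        assert table.loc["const", "dj"] == 0.0
        assert table.loc["const", "contribution"] == 0.0

    def test_duplicated_feature_gets_equal_dj(self):
        rng = np.random.default_rng(8)
        n = 40
        y = np.repeat([1, -1], n // 2)
        base = y + rng.normal(0, 0.6, n)
        X = np.c_[base, base, rng.normal(0, 1, n)]
        model = _toy_model(X, y, names=("a", "a_copy", "noise"))
        table = lg.dj_contributions(model).set_index("index")
        assert table.loc["a", "dj"] == pytest.approx(table.loc["a_copy", "dj"], rel=1e-9)

    def test_contributions_sum_to_100(self, toy):
        X, y = toy
        table = lg.dj_contributions(_toy_model(X, y))
        assert table["contribution"].sum() == pytest.approx(100.0, rel=1e-9)
        assert (table["contribution"] >= 0).all()

    def test_all_constant_features_rejected(self):
        n = 20
        y = np.repeat([1, -1], n // 2)
        X = np.ones((n, 2))
        model = lg.train_svm(X, y, C=1.0, gamma=0.5)
        with pytest.raises(ValueError, match="all DJ"):
            lg.dj_contributions(model)

    def test_informative_outranks_noise_in_most_seeds(self):
        wins = 0
        for seed in range(30):
            rng = np.random.default_rng(seed)
            n = 40
            y = np.repeat([1, -1], n // 2)
            X = np.c_[y + rng.normal(0, 0.6, n), rng.normal(0, 1, n)]
            table = lg.dj_contributions(_toy_model(X, y)).set_index("index")
            wins += table.loc["x0", "contribution"] > table.loc["x1", "contribution"]
        assert wins >= 29  # >= 95 %


class TestGridSearch:
    def test_separable_clusters_reach_perfect_cv(self):
        rng = np.random.default_rng(9)
        X = np.vstack([rng.normal(-4, 0.3, (30, 2)), rng.normal(4, 0.3, (30, 2))])
        y = np.repeat([-1, 1], 30)
        C, g, acc = lg.grid_search(X, y, SMALL_C_GRID, SMALL_GAMMA_GRID, folds=5, seed=0)
        assert acc == 1.0

    def test_same_seed_identical_output(self, compliant_features):
        train = compliant_features[compliant_features["true_grade"].isin(["premium", "first"])]
        X = train[["diameter", "liquiritin"]].to_numpy()
        y = np.where(train["true_grade"] == "premium", 1, -1)
        out1 = lg.grid_search(X, y, SMALL_C_GRID, SMALL_GAMMA_GRID, seed=11)
        out2 = lg.grid_search(X, y, SMALL_C_GRID, SMALL_GAMMA_GRID, seed=11)
        assert out1 == out2

    def test_tie_break_prefers_smaller_c_then_gamma(self):
        # all grid points tie on this trivially separable data
        X = np.repeat([[0.0], [10.0]], 10, axis=0)
        X = X + np.linspace(0, 0.1, 20)[:, None]
        y = np.repeat([-1, 1], 10)
        C, g, _ = lg.grid_search(X, y, [1.0, 10.0], [0.1, 1.0], folds=2, seed=0)
        assert (C, g) == (1.0, 0.1)

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError, match="grid"):
            lg.grid_search(np.eye(4), np.array([1, 1, -1, -1]), [], [1.0], folds=2)


class TestSelectTopFeatures:
    def test_identity_and_topk(self):
        table = pd.DataFrame({"index": ["a", "b", "c"], "dj": [5, 3, 2], "contribution": [50.0, 30.0, 20.0]})
        assert lg.select_top_features(table, 3) == ("a", "b", "c")
        assert lg.select_top_features(table, 2) == ("a", "b")

    def test_ties_keep_reporting_order(self):
        table = pd.DataFrame({"index": ["a", "b", "c"], "contribution": [40.0, 30.0, 30.0]})
        assert lg.select_top_features(table, 2) == ("a", "b")

    def test_invalid_k_rejected(self):
        table = pd.DataFrame({"index": ["a"], "contribution": [100.0]})
        with pytest.raises(ValueError):
            lg.select_top_features(table, 0)
        with pytest.raises(ValueError):
            lg.select_top_features(table, 2)


class TestPlatt:
    def test_symmetric_decisions_give_half_at_zero(self):
        f = np.array([-1.0] * 50 + [1.0] * 50)
        y = np.array([-1] * 50 + [1] * 50)
        cal = lg.platt_fit(f, y)
        assert cal.posterior(0.0) == pytest.approx(0.5, abs=1e-3)

    def test_closed_form_sigmoid(self):
        cal = lg.PlattCalibration(A=-1.0, B=0.0)
        assert cal.posterior(0.0) == pytest.approx(0.5)
        assert cal.posterior(2.0) == pytest.approx(1.0 / (1.0 + np.exp(-2.0)))

    def test_parameter_recovery(self):
        """Labels sampled from a known sigmoid (A=-2, B=0.5) are recovered
        within +-0.15 at n = 2000."""
        rng = np.random.default_rng(12)
        f = rng.normal(0, 2, 2000)
        p = 1.0 / (1.0 + np.exp(-2.0 * f + 0.5))
        y = np.where(rng.uniform(size=2000) < p, 1, -1)
        cal = lg.platt_fit(f, y)
        assert cal.A == pytest.approx(-2.0, abs=0.15)
        assert cal.B == pytest.approx(0.5, abs=0.15)

    def test_posterior_preserves_ranking_auc(self):
        rng = np.random.default_rng(13)
        f = rng.normal(0, 1, 300)
        y = np.where(f + rng.normal(0, 1, 300) > 0, 1, -1)
        cal = lg.platt_fit(f, y)
        assert roc_auc_score(y, cal.posterior(f)) == pytest.approx(roc_auc_score(y, f), abs=1e-12)

    def test_non_finite_decisions_rejected(self):
        with pytest.raises(ValueError, match="non-finite"):
            lg.platt_fit([0.0, np.inf], [1, -1])


class TestQceiScore:
    @pytest.mark.parametrize(
        "p,grade,score",
        [(1.0, "premium", 100.0), (0.0, "first", 70.0), (0.5, "premium", 86.0)],
    )
    def test_band_endpoints(self, p, grade, score):
        r = lg.qcei_score(p, inside_boundary=True)
        assert r.predicted_grade == grade
        assert r.qcei == pytest.approx(score)

    @given(st.floats(0.0, 1.0), st.floats(0.0, 1.0))
    @settings(max_examples=60, derandomize=True)
    def test_monotone_in_posterior_with_consistent_bands(self, p1, p2):
        r1 = lg.qcei_score(p1, True)
        r2 = lg.qcei_score(p2, True)
        if p1 <= p2:
            assert r1.qcei <= r2.qcei + 1e-12
        for r in (r1, r2):
            if r.predicted_grade == "premium":
                assert 86.0 <= r.qcei <= 100.0
            else:
                assert 70.0 <= r.qcei < 85.0 + 1e-9

    def test_outside_boundary_scores_below_70_decaying_with_distance(self):
        near = lg.qcei_score(0.9, False, boundary_distance=30.0, boundary_cutoff=25.0)
        far = lg.qcei_score(0.9, False, boundary_distance=300.0, boundary_cutoff=25.0)
        assert near.predicted_grade == far.predicted_grade == "second"
        assert far.qcei < near.qcei < 70.0

    def test_invalid_posterior_rejected(self):
        with pytest.raises(ValueError):
            lg.qcei_score(1.2, True)


class TestFullPipeline:
    def test_scores_and_structure_on_default_study(self, pipeline_result, compliant_features):
        res = pipeline_result
        assert len(res.scores) == 189
        assert res.contributions["contribution"].sum() == pytest.approx(100.0, rel=1e-9)
        assert len(res.model.feature_subset) == 9
        # scored grades respect the band definitions
        s = res.scores
        assert (s.loc[s.predicted_grade == "premium", "qcei"] >= 86.0).all()
        assert (s.loc[s.predicted_grade == "first", "qcei"] <= 85.0).all()
        assert (s.loc[s.predicted_grade == "second", "qcei"] < 70.0).all()

    def test_rerun_same_seed_identical_contributions(self):
        cfg = small_study_config(seed=21)
        features = compliant_feature_table(cfg)
        kwargs = dict(
            C_grid=SMALL_C_GRID, gamma_grid=SMALL_GAMMA_GRID, seed=3, min_class_size=10, folds=5
        )
        r1 = lg.run_full_pipeline(features, **kwargs)
        r2 = lg.run_full_pipeline(features, **kwargs)
        pd.testing.assert_frame_equal(r1.contributions, r2.contributions)
        pd.testing.assert_frame_equal(r1.scores, r2.scores)

    def test_undersized_classes_rejected(self, compliant_features):
        tiny = compliant_features.head(30)
        with pytest.raises(ValueError, match="per class"):
            lg.run_full_pipeline(tiny)
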