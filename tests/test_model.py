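from types import SimpleNamespace

import numpy as np
import pandas as pd
import pytest

import mlogitdiag as m
from mlogitdiag.model import SurveyMultinomialLogit, predict_probs

from conftest import draw_multinomial_rows


class TestBuildDesign:
    def test_reference_coding_example(self):
        frame = pd.DataFrame({"sex": ["female", "male", "male"]})
        design = m.build_design(frame, m.ModelSpec(terms=["sex"]))
        np.testing.assert_array_equal(design.X, [[1, 0], [1, 1], [1, 1]])
        assert design.columns == ["intercept", "sex[male]"]

    def test_intercept_only(self):
        frame = pd.DataFrame({"sex": ["female"] * 3})
        design = m.build_design(frame, m.ModelSpec(terms=[]))
        np.testing.assert_array_equal(design.X, [[1], [1], [1]])

    def test_unknown_term_rejected(self):
        with pytest.raises(m.ValidationError):
            m.ModelSpec(terms=["galaxy"])
        frame = pd.DataFrame({"sex": ["female"]})
        with pytest.raises(m.SchemaError):
            m.build_design(frame, m.ModelSpec(terms=["twin"]))

    def test_absent_level_warns_and_keeps_column(self):
        frame = pd.DataFrame({"twin": ["no"] * 5})
        with pytest.warns(UserWarning, match="inestimable"):
            design = m.build_design(frame, m.ModelSpec(terms=["twin"]))
        assert design.X.shape == (5, 2)

    def test_column_order_deterministic(self, small_data):
        data, _ = small_data
        spec = m.ModelSpec(terms=["twin", "sex"])
        design = m.build_design(data, spec)
        assert design.columns == ["intercept", "twin[yes]", "sex[male]"]


class TestEstimator:
    def test_intercept_only_closed_form(self):
        """Intercept MLE equals the log share ratios of the category counts."""
        counts = {"LBW": 1940, "NBW": 8428, "HBW": 1312}
        y = np.repeat(list(counts), list(counts.values()))
        X = np.ones((len(y), 1))
        est = SurveyMultinomialLogit(
            categories=["LBW", "NBW", "HBW"], reference="LBW",
            fit_intercept=False,
        ).fit(X, y)
        np.testing.assert_allclose(
            est.beta_[:, 0],
            [np.log(8428 / 1940), np.log(1312 / 1940)],
            atol=1e-8,
        )

    def test_balanced_categories_give_zero(self):
        y = np.repeat([0, 1, 2], 40)
        est = SurveyMultinomialLogit(reference=0, fit_intercept=False).fit(
            np.ones((120, 1)), y
        )
        np.testing.assert_allclose(est.beta_, 0.0, atol=1e-8)

    def test_single_category_is_separation(self):
        with pytest.raises(m.SeparationError):
            SurveyMultinomialLogit(categories=[0, 1, 2], reference=0).fit(
                np.random.default_rng(0).normal(size=(50, 2)),
                np.zeros(50, dtype=int),
            )

    def test_score_identity_at_optimum(self, medium_fit):
        """With unit weights the weighted score vanishes columnwise."""
        data, spec, _ = medium_fit
        res = m.fit(data, spec, weighting="none")
        Y = (res.y_idx[:, None] == np.array([1, 2])[None, :]).astype(float)
        Pn = res.fitted_probs[:, [1, 2]]
        score = (Y - Pn).T @ res.X
        assert np.abs(score).max() < 1e-6

    def test_matches_statsmodels_on_small_data(self):
        sm = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(3)
        X = rng.normal(size=(300, 2))
        eta = np.column_stack(
            [np.zeros(300), 0.4 + 0.8 * X[:, 0], -0.3 - 0.5 * X[:, 1]]
        )
        P = np.exp(eta) / np.exp(eta).sum(1, keepdims=True)
        y = draw_multinomial_rows(rng, P)
        est = SurveyMultinomialLogit(categories=[0, 1, 2], reference=0).fit(X, y)
        ref = sm.MNLogit(y, sm.add_constant(X)).fit(
            method="newton", disp=0, tol=1e-10
        )
        np.testing.assert_allclose(est.beta_, ref.params.T, atol=1e-6)
        assert np.isclose(est.loglik_, ref.llf, atol=1e-8)

    def test_binary_reduction_matches_logistic(self):
        """Merging NBW+HBW reduces the model to binary logistic regression."""
        sm = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(5)
        X = rng.normal(size=(400, 2))
        p = 1 / (1 + np.exp(-(0.3 + 0.9 * X[:, 0] - 0.6 * X[:, 1])))
        y = (rng.random(400) < p).astype(int)
        est = SurveyMultinomialLogit(categories=[0, 1], reference=0).fit(X, y)
        ref = sm.Logit(y, sm.add_constant(X)).fit(disp=0, tol=1e-10)
        np.testing.assert_allclose(est.beta_[0], ref.params, atol=1e-6)

    def test_weight_scale_invariance(self, small_data, small_spec):
        data, _ = small_data
        w = m.compute_weights(data)
        a = m.fit(data, small_spec, w)
        b = m.fit(data, small_spec, m.normalize_weights(w, "mean_one"))
        np.testing.assert_allclose(a.beta, b.beta, atol=1e-8)
        # raw-weight pseudo-log-likelihood scales with the weights
        assert a.loglik == pytest.approx(b.loglik * w.mean(), rel=1e-9)

    def test_literal_weighting_changes_the_model(self, small_data, small_spec):
        data, _ = small_data
        a = m.fit(data, small_spec, weighting="pseudo")
        b = m.fit(data, small_spec, weighting="literal")
        assert not np.allclose(a.beta, b.beta)

    def test_sklearn_params_clone(self):
        from sklearn.base import clone

        est = SurveyMultinomialLogit(reference="LBW", tol=1e-6)
        est2 = clone(est)
        assert est2.get_params()["reference"] == "LBW"
        assert est2.get_params()["tol"] == 1e-6


class TestPredictProbs:
    def test_zero_beta_uniform(self):
        P = predict_probs(np.zeros((2, 1)), np.ones((4, 1)))
        np.testing.assert_allclose(P, 1 / 3)

    def test_overflow_guarded(self):
        B = np.array([[900.0], [0.0]])
        P = predict_probs(B, np.ones((2, 1)), reference=0)
        assert np.isfinite(P).all()
        np.testing.assert_allclose(P[:, 1], 1.0)

    def test_hand_evaluated_softmax(self):
        # ref LBW; eta_NBW = log 2, eta_HBW = 0 -> (0.25, 0.5, 0.25)
        B = np.array([[np.log(2.0)], [0.0]])
        P = predict_probs(B, np.ones((1, 1)), reference=0)
        np.testing.assert_allclose(P[0], [0.25, 0.5, 0.25])

    def test_rows_sum_to_one(self, medium_fit):
        _, _, res = medium_fit
        np.testing.assert_allclose(res.fitted_probs.sum(axis=1), 1.0,
                                   atol=1e-10)


class TestJackknife:
    def _replicated_clusters(self, k=4, seed=0):
        """k clusters with identical records (same stratum, same weights)."""
        rng = np.random.default_rng(seed)
        base = pd.DataFrame({
            "sex": rng.choice(["female", "male"], size=12),
            "outcome": rng.choice(["LBW", "NBW", "HBW"], size=12,
                                  p=[0.3, 0.5, 0.2]),
        })
        frames = []
        for c in range(k):
            f = base.copy()
            f["child_id"] = [f"c{c}-{i}" for i in range(12)]
            f["cluster_id"] = f"c{c}"
            f["stratum"] = "rural"
            frames.append(f)
        rec = pd.concat(frames, ignore_index=True)
        for cov, levels in m.COVARIATE_LEVELS.items():
            if cov not in rec.columns:
                rec[cov] = levels[0]
        rec["residence"] = "rural"
        rec["birth_weight_grams"] = np.nan
        clu = pd.DataFrame({
            "cluster_id": [f"c{c}" for c in range(k)],
            "stratum": "rural",
            "population_size": 120,
            "sample_size": 12,
        })
        rec = rec.drop(columns=["birth_weight_grams"])
        rec["birth_weight_grams"] = np.nan
        return m.SurveyDataset.from_frames(rec, clu, validate=False)

    def test_identical_clusters_zero_variance(self):
        data = self._replicated_clusters()
        spec = m.ModelSpec(terms=["sex"])
        w = m.compute_weights(data)
        res = m.fit(data, spec, w)
        V = m.jackknife_vcov(data, spec, w, res)
        assert np.abs(V).max() < 1e-10

    def test_two_cluster_hand_formula(self):
        """Two replicates, one stratum: V = (1/2) sum (b_c - b)(b_c - b)'."""
        rec = pd.DataFrame({
            "outcome": (["LBW"] * 3 + ["NBW"] * 5 + ["HBW"] * 2
                        + ["LBW"] * 1 + ["NBW"] * 6 + ["HBW"] * 3),
            "cluster_id": ["a"] * 10 + ["b"] * 10,
            "stratum": "rural",
        })
        rec["child_id"] = [str(i) for i in range(20)]
        for cov, levels in m.COVARIATE_LEVELS.items():
            rec[cov] = levels[0]
        rec["residence"] = "rural"
        rec["birth_weight_grams"] = np.nan
        clu = pd.DataFrame({
            "cluster_id": ["a", "b"], "stratum": "rural",
            "population_size": [200, 50], "sample_size": [10, 10],
        })
        data = m.SurveyDataset.from_frames(rec, clu, validate=False)
        spec = m.ModelSpec(terms=[])
        w = m.compute_weights(data)
        res = m.fit(data, spec, w)
        V = m.jackknife_vcov(data, spec, w, res)

        def intercepts(counts):
            return np.array([np.log(counts[1] / counts[0]),
                             np.log(counts[2] / counts[0])])

        # deleting a cluster leaves the other; intercept-only weighted MLE
        # is the log weighted share ratio (weights constant within cluster)
        b_del_a = intercepts([1, 6, 3])
        b_del_b = intercepts([3, 5, 2])
        w_a, w_b = 20.0, 5.0
        full = intercepts([3 * w_a + 1 * w_b, 5 * w_a + 6 * w_b,
                           2 * w_a + 3 * w_b])
        expected = 0.5 * (np.outer(b_del_a - full, b_del_a - full)
                          + np.outer(b_del_b - full, b_del_b - full))
        np.testing.assert_allclose(V, expected, atol=1e-7)

    def test_single_cluster_stratum_errors(self, small_data, small_spec):
        data, _ = small_data
        rec = data.records.copy()
        clu = data.clusters.copy()
        only = clu["cluster_id"].iloc[0]
        keep = rec["cluster_id"] == only
        rec, clu = rec[keep], clu[clu["cluster_id"] == only]
        sub = m.SurveyDataset.from_frames(rec, clu, validate=False)
        w = m.compute_weights(sub)
        res = m.fit(sub, small_spec, w)
        with pytest.raises(m.ValidationError, match="single cluster"):
            m.jackknife_vcov(sub, small_spec, w, res)

    def test_vcov_symmetric_psd(self, medium_fit):
        data, spec, res = medium_fit
        V = m.jackknife_vcov(data, spec, res.w, res)
        np.testing.assert_allclose(V, V.T, atol=1e-12)
        assert np.linalg.eigvalsh(V).min() > -1e-8


class TestSelectModel:
    def test_tie_broken_by_position(self, small_data, small_spec):
        data, _ = small_data
        sel = m.select_model(data, [small_spec, small_spec])
        assert sel.best_index == 0

    def test_true_effect_wins_by_aic(self):
        spec = m.ModelSpec(terms=["sex"])
        B = m.intercept_calibrated_beta(spec)
        B[:, 1] = [-0.8, -1.2]  # strong sex effect
        cfg = m.SyntheticConfig(n_clusters=120, cluster_size_range=(15, 25),
                                model=spec, true_beta=B, seed=17)
        data, _ = m.generate(cfg)
        sel = m.select_model(data, [m.ModelSpec(terms=[]), spec])
        assert sel.best_index == 1
        assert sel.table["aic"].iloc[1] < sel.table["aic"].iloc[0]

    def test_empty_list_errors(self, small_data):
        data, _ = small_data
        with pytest.raises(m.ValidationError):
            m.select_model(data, [])


class TestGoodnessOfFit:
    def test_perfect_fit(self):
        diag = SimpleNamespace(pearson=np.zeros((10, 3)))
        fit_stub = SimpleNamespace(n_params=4)
        stat, df, p = m.goodness_of_fit(diag, fit_stub)
        assert stat == 0.0 and p == 1.0 and df == 16

    def test_saturated_model_errors(self):
        diag = SimpleNamespace(pearson=np.zeros((2, 3)))
        fit_stub = SimpleNamespace(n_params=4)
        with pytest.raises(m.ValidationError):
            m.goodness_of_fit(diag, fit_stub)

    def test_statistic_is_sum_of_squared_pearson(self, medium_fit):
        _, _, res = medium_fit
        obs = m.compute_obs_diagnostics(res)
        stat, _, _ = m.goodness_of_fit(obs, res)
        assert stat == (obs.pearson ** 2).sum()

    def test_mean_statistic_calibrated_under_truth(self):
        """E[X^2] is close to n(J-1) for well-specified data."""
        spec = m.ModelSpec(terms=["sex"])
        stats_ = []
        for s in range(30):
            cfg = m.SyntheticConfig(n_clusters=25, cluster_size_range=(15, 25),
                                    model=spec, seed=900 + s)
            data, _ = m.generate(cfg)
            res = m.fit(data, spec, weighting="none")
            obs = m.compute_obs_diagnostics(res)
            stat, df, _ = m.goodness_of_fit(obs, res)
            stats_.append(stat / (data.n_records * 2))
        mean_ratio = np.mean(stats_)
        assert abs(mean_ratio - 1.0) < 0.1
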