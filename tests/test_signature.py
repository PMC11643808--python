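"""LASSO signature fitting, leave-one-out scoring, and evaluation."""

import numpy as np
import pandas as pd
import pytest
from sklearn.linear_model import Lasso

from dietsig.signature import (SignatureModel, SignatureScores, _cd_lasso_gram,
                               apply_signature, evaluate_signature, fit_lasso,
                               loocv_training_scores, summarize_classes)


def toy_problem(n, p, seed, beta=None, noise=1.0):
    rng = np.random.default_rng(seed)
    X = pd.DataFrame(rng.standard_normal((n, p)),
                     columns=[f"sp{j}" for j in range(p)])
    if beta is None:
        beta = np.zeros(p)
    y = X.to_numpy() @ beta + noise * rng.standard_normal(n)
    return X, y


class TestFitLasso:
    def test_full_shrinkage_limit(self):
        X, y = toy_problem(50, 5, 0)
        m = fit_lasso(X, y + 3.0, "fixed", lambda_=100.0)
        assert m.weights.empty
        assert m.intercept == pytest.approx(np.mean(y + 3.0))

    def test_lambda_zero_matches_ols(self):
        beta = np.array([1.0, -2.0, 0.5])
        X, y = toy_problem(30, 3, 1, beta, noise=0.3)
        m = fit_lasso(X, y, "fixed", lambda_=1e-10)
        A = np.column_stack([np.ones(30), X.to_numpy()])
        ols = np.linalg.lstsq(A, y, rcond=None)[0]
        np.testing.assert_allclose(m.weights.reindex(X.columns, fill_value=0.0),
                                   ols[1:], atol=1e-6)
        assert m.intercept == pytest.approx(ols[0], abs=1e-6)

    def test_planted_single_species_selected(self):
        rng = np.random.default_rng(2)
        X = pd.DataFrame(rng.standard_normal((50, 5)),
                         columns=[f"sp{j}" for j in range(5)])
        y = 2.0 * X["sp0"].to_numpy() + 0.01 * rng.standard_normal(50)
        m = fit_lasso(X, y, "fixed", lambda_=0.05)
        assert m.selected_species == ["sp0"]
        assert m.weights["sp0"] == pytest.approx(2.0, abs=0.1)

    def test_cv_rules(self):
        beta = np.zeros(12); beta[0] = 1.5
        X, y = toy_problem(80, 12, 3, beta, noise=0.5)
        m_min = fit_lasso(X, y, "cv_min", seed=0)
        m_1se = fit_lasso(X, y, "cv_1se", seed=0)
        assert m_1se.lambda_ >= m_min.lambda_
        assert "sp0" in m_min.selected_species
        assert m_min.training_meta["lambda_rule"] == "cv_min"

    def test_degenerate_inputs(self):
        X, y = toy_problem(30, 3, 4)
        with pytest.raises(ValueError, match="zero variance"):
            fit_lasso(X, np.ones(30), "fixed", lambda_=0.1)
        with pytest.raises(ValueError, match="n > 20"):
            fit_lasso(X.iloc[:10], y[:10], "fixed", lambda_=0.1)
        with pytest.raises(ValueError, match="lambda"):
            fit_lasso(X, y, "fixed")


class TestGramSolver:
    """The covariance-mode coordinate-descent solver used by the LOO refits
    must agree with an independent LASSO implementation."""

    @pytest.mark.parametrize("n,p,lam,seed", [
        (40, 8, 0.05, 0), (60, 25, 0.1, 1), (35, 60, 0.2, 2), (100, 10, 0.01, 3),
    ])
    def test_matches_sklearn(self, n, p, lam, seed):
        rng = np.random.default_rng(seed)
        X = rng.standard_normal((n, p))
        beta = np.zeros(p); beta[: min(4, p)] = [1.5, -1.0, 0.5, 0.0][: min(4, p)]
        y = X @ beta + 0.5 * rng.standard_normal(n)
        Xc = X - X.mean(0)
        yc = y - y.mean()
        mine = _cd_lasso_gram(Xc.T @ Xc, Xc.T @ yc, n * lam, np.zeros(p))
        ref = Lasso(alpha=lam, max_iter=100_000, tol=1e-12).fit(X, y).coef_
        np.testing.assert_allclose(mine, ref, atol=1e-6)


class TestLoocv:
    def test_matches_per_subject_refits(self):
        """Each LOO score equals an explicit n-1 refit with the reference
        implementation (consistency of the downdating harness)."""
        rng = np.random.default_rng(5)
        X = pd.DataFrame(rng.standard_normal((30, 8)),
                         columns=[f"sp{j}" for j in range(8)])
        y = 1.2 * X["sp1"].to_numpy() + 0.8 * rng.standard_normal(30)
        lam = 0.08
        got = loocv_training_scores(X, y, lam).scores.to_numpy()
        for i in range(30):
            keep = np.arange(30) != i
            ref = Lasso(alpha=lam, max_iter=100_000, tol=1e-12).fit(
                X.to_numpy()[keep], y[keep])
            assert got[i] == pytest.approx(float(X.to_numpy()[i] @ ref.coef_), abs=1e-6)

    def test_null_scores_center_near_zero(self):
        """Pure-noise panels: LOO score-index correlation is centred at 0
        across replicates (empty signatures count as zero association)."""
        rs = []
        for seed in range(20):
            X, y = toy_problem(60, 10, 100 + seed)
            m = fit_lasso(X, y, "cv_min", seed=seed, n_folds=5)
            s = loocv_training_scores(X, y, m.lambda_).scores.to_numpy()
            rs.append(0.0 if np.std(s) == 0 else float(np.corrcoef(s, y)[0, 1]))
        assert abs(np.mean(rs)) < 0.1

    def test_in_sample_beats_loo_on_average(self):
        """Overfit ordering: in-sample scores correlate at least as well as
        honest leave-one-out scores, on average over seeds."""
        diffs = []
        for seed in range(5):
            beta = np.zeros(15); beta[:3] = 0.25
            X, y = toy_problem(80, 15, 200 + seed, beta)
            m = fit_lasso(X, y, "cv_min", seed=seed, n_folds=5)
            if m.weights.empty:
                continue
            loo = loocv_training_scores(X, y, m.lambda_).scores.to_numpy()
            ins = apply_signature(m, X).scores.to_numpy()
            r_in = np.corrcoef(ins, y)[0, 1]
            r_loo = 0.0 if np.std(loo) == 0 else np.corrcoef(loo, y)[0, 1]
            diffs.append(r_in - r_loo)
        assert np.mean(diffs) > 0

    def test_small_n_rejected(self):
        X, y = toy_problem(8, 3, 6)
        with pytest.raises(ValueError, match="n >= 10"):
            loocv_training_scores(X, y, 0.1)


class TestApplyEvaluate:
    def test_weighted_sum_and_linearity(self):
        model = SignatureModel(weights=pd.Series({"a": 0.5, "b": -1.0}),
                               intercept=3.0, lambda_=0.1)
        X1 = pd.DataFrame({"a": [2.0, 0.0], "b": [0.0, 1.0], "c": [9.0, 9.0]})
        s1 = apply_signature(model, X1).scores
        assert s1.tolist() == [1.0, -1.0]  # intercept never enters the score
        X2 = pd.DataFrame({"a": [1.0, 1.0], "b": [2.0, 0.0], "c": [0.0, 0.0]})
        s12 = apply_signature(model, 2.0 * X1 + 3.0 * X2).scores
        np.testing.assert_allclose(
            s12, 2.0 * s1 + 3.0 * apply_signature(model, X2).scores)

    def test_empty_model_scores_zero(self):
        model = SignatureModel(weights=pd.Series(dtype=float), intercept=0.0, lambda_=1.0)
        assert (apply_signature(model, pd.DataFrame({"a": [1.0, 2.0]})).scores == 0).all()

    def test_missing_species_error(self):
        model = SignatureModel(weights=pd.Series({"a": 1.0, "zz": 2.0}),
                               intercept=0.0, lambda_=0.1)
        with pytest.raises(KeyError, match="zz"):
            apply_signature(model, pd.DataFrame({"a": [1.0]}))

    def test_pearson_identities(self):
        y = np.array([1.0, 2.0, 4.0, 4.5, 7.0])
        s = SignatureScores(pd.Series(y), "direct_test")
        assert evaluate_signature(s, y)["pearson_r"] == pytest.approx(1.0)
        s_neg = SignatureScores(pd.Series(-y), "direct_test")
        assert evaluate_signature(s_neg, y)["pearson_r"] == pytest.approx(-1.0)

    def test_pearson_hand_computed(self):
        x = np.array([1.0, 3.0, 2.0, 5.0, 4.0])
        y = np.array([2.0, 2.5, 1.0, 6.0, 4.0])
        r = evaluate_signature(SignatureScores(pd.Series(x), "direct_test"), y)
        cov = np.mean((x - x.mean()) * (y - y.mean()))
        assert r["pearson_r"] == pytest.approx(cov / (x.std() * y.std()))
        assert r["n"] == 5

    def test_degenerate_pairs(self):
        with pytest.raises(ValueError, match="zero variance"):
            evaluate_signature(SignatureScores(pd.Series([1.0, 1.0, 1.0]), "x"),
                               np.array([1.0, 2.0, 3.0]))

    def test_model_round_trip(self, tmp_path):
        m = SignatureModel(weights=pd.Series({"a": 0.5, "b": -0.25}), intercept=5.5,
                           lambda_=0.07, training_meta={"n": 100, "seed": 3})
        m.save(tmp_path / "model")
        m2 = SignatureModel.load(tmp_path / "model")
        pd.testing.assert_series_equal(m.weights, m2.weights, check_names=False)
        assert (m2.intercept, m2.lambda_) == (5.5, 0.07)


class TestClassSummary:
    def test_percentages(self):
        meta = pd.DataFrame({"lipid_class": ["TG", "TG", "PC", "PE-O"]},
                            index=["a", "b", "c", "d"])
        m = SignatureModel(weights=pd.Series({"a": 1.0, "b": -1.0, "c": 2.0, "d": 0.5}),
                           intercept=0, lambda_=0.1)
        out = summarize_classes(m, meta)
        assert out.loc["TG", "percent"] == pytest.approx(50.0)
        assert out.loc["PC", "percent"] == pytest.approx(25.0)
        assert out["percent"].sum() == pytest.approx(100.0)

    def test_planted_counts(self):
        counts = {"TG": 13, "PC": 11, "PE-O": 6, "SM": 27}
        names, classes = [], []
        for cls, k in counts.items():
            for i in range(k):
                names.append(f"{cls}_{i}")
                classes.append(cls)
        meta = pd.DataFrame({"lipid_class": classes}, index=names)
        m = SignatureModel(weights=pd.Series(1.0, index=names), intercept=0, lambda_=0.1)
        out = summarize_classes(m, meta)
        assert out.loc["TG", "percent"] == pytest.approx(100 * 13 / 57, abs=0.05)
        assert out.loc["PC", "percent"] == pytest.approx(100 * 11 / 57, abs=0.05)
        assert out.loc["PE-O", "percent"] == pytest.approx(100 * 6 / 57, abs=0.05)

    def test_empty_model(self):
        m = SignatureModel(weights=pd.Series(dtype=float), intercept=0, lambda_=1.0)
        assert summarize_classes(m, pd.DataFrame({"lipid_class": []})).empty
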