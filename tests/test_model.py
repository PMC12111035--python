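"""SVR calibration core, CV fitness and metric contracts."""

import json
import subprocess

import numpy as np
import pytest

from flourspec.model import (
    ConstantInputError,
    SvrHyperparams,
    cv_fitness,
    evaluate_model,
    fit_svr,
    pearson_r,
    rmse,
    rpd,
)


@pytest.fixture
def linear_data(rng):
    X = rng.normal(size=(40, 3))
    y = X @ np.array([1.0, -0.5, 0.25])
    return X, y


class TestFitSvr:
    def test_separable_regression_near_exact(self, linear_data):
        X, y = linear_data
        h = SvrHyperparams(C=1e4, epsilon=0.001, gamma=0.1)
        m = fit_svr(X, y, h, kernel="linear")
        assert rmse(y, m.predict(X)) < 0.01

    def test_constant_target_within_epsilon(self, rng):
        X = rng.normal(size=(20, 4))
        y = np.full(20, 3.0)
        m = fit_svr(X, y, SvrHyperparams(C=1.0, epsilon=0.1, gamma=0.1))
        assert np.max(np.abs(m.predict(X) - 3.0)) <= 0.1 + 1e-9

    def test_matches_independent_libsvm_wrapper(self, rng):
        """Cross-implementation oracle: identical predictions from R's
        e1071 epsilon-SVR on the same 30-sample problem."""
        X = rng.normal(size=(30, 5))
        y = X @ np.array([1.0, 0.5, -0.3, 0.2, 0.0]) + rng.normal(0, 0.1, 30)
        h = SvrHyperparams(C=10.0, epsilon=0.1, gamma=0.2)
        pred_py = fit_svr(X, y, h).predict(X)
        script = (
            'X <- matrix(scan("stdin", quiet=TRUE), ncol=6, byrow=TRUE);'
            "y <- X[,6]; X <- X[,1:5];"
            "suppressMessages(library(e1071));"
            'm <- svm(X, y, type="eps-regression", kernel="radial",'
            "cost=10, epsilon=0.1, gamma=0.2, scale=FALSE);"
            'cat(sprintf("%.12e\\n", as.numeric(predict(m, X))))'
        )
        payload = "\n".join(
            " ".join(repr(float(v)) for v in row) for row in np.column_stack([X, y])
        )
        out = subprocess.run(
            ["Rscript", "-e", script], input=payload, capture_output=True, text=True
        )
        pred_r = np.array([float(v) for v in out.stdout.split()])
        assert np.max(np.abs(pred_py - pred_r)) < 1e-6

    def test_shape_and_finite_errors(self, rng):
        h = SvrHyperparams(C=1.0, epsilon=0.1, gamma=0.1)
        with pytest.raises(ValueError):
            fit_svr(rng.normal(size=(5, 2)), np.zeros(4), h)
        with pytest.raises(ValueError):
            fit_svr(np.array([[np.inf, 0.0]] * 3), np.zeros(3), h)

    def test_invalid_hyperparams_rejected(self):
        for bad in [dict(C=-1, epsilon=0.1, gamma=0.1), dict(C=1, epsilon=-0.1, gamma=0.1),
                    dict(C=1, epsilon=0.1, gamma=0.0)]:
            with pytest.raises(ValueError):
                SvrHyperparams(**bad)


class TestCvFitness:
    def test_noiseless_linear_low_fitness(self, linear_data):
        X, y = linear_data
        h = SvrHyperparams(C=100.0, epsilon=0.001, gamma=0.1)
        assert cv_fitness(X, y, h, folds=5, seed=0, kernel="linear") < 0.05

    def test_pure_noise_fitness_near_target_sd(self, rng):
        errs = []
        for rep in range(20):
            r = np.random.default_rng(rep)
            X = r.normal(size=(50, 5))
            y = r.normal(size=50)  # no relation to X
            h = SvrHyperparams(C=1.0, epsilon=0.1, gamma=0.1)
            errs.append(cv_fitness(X, y, h, folds=5, seed=rep) / y.std())
        assert abs(np.mean(errs) - 1.0) < 0.25

    def test_deterministic(self, linear_data):
        X, y = linear_data
        h = SvrHyperparams(C=1.0, epsilon=0.1, gamma=0.1)
        assert cv_fitness(X, y, h, seed=7) == cv_fitness(X, y, h, seed=7)

    def test_loo_equals_brute_force(self, rng):
        """folds=n must equal the mean of n single-hold-out RMSEs."""
        X = rng.normal(size=(12, 3))
        y = X @ np.array([1.0, 0.5, -1.0]) + rng.normal(0, 0.2, 12)
        h = SvrHyperparams(C=5.0, epsilon=0.05, gamma=0.3)
        from sklearn.svm import SVR

        brute = []
        for i in range(12):
            tr = np.delete(np.arange(12), i)
            m = SVR(kernel="rbf", C=5.0, epsilon=0.05, gamma=0.3).fit(X[tr], y[tr])
            brute.append(abs(y[i] - m.predict(X[i : i + 1])[0]))
        assert cv_fitness(X, y, h, folds=12, seed=0) == pytest.approx(np.mean(brute), abs=1e-12)

    def test_too_many_folds_raises(self, linear_data):
        X, y = linear_data
        with pytest.raises(ValueError):
            cv_fitness(X, y, SvrHyperparams(C=1, epsilon=0.1, gamma=0.1), folds=100)


class TestMetrics:
    def test_pearson_exact_cases(self):
        assert pearson_r([1, 2, 3], [2, 4, 6]) == pytest.approx(1.0)
        assert pearson_r([1, 2, 3], [3, 2, 1]) == pytest.approx(-1.0)

    def test_pearson_against_brute_force(self, rng):
        a, b = rng.normal(size=50), rng.normal(size=50)
        za = (a - a.mean()) / a.std()
        zb = (b - b.mean()) / b.std()
        assert pearson_r(a, b) == pytest.approx(np.mean(za * zb), abs=1e-12)

    def test_pearson_constant_raises(self):
        with pytest.raises(ConstantInputError):
            pearson_r([1, 1, 1], [1, 2, 3])

    def test_rmse_cases(self, rng):
        assert rmse([1, 2, 3], [1, 2, 3]) == 0.0
        assert rmse([0, 0], [2, 2]) == pytest.approx(2.0)
        a, b = rng.normal(size=100), rng.normal(size=100)
        assert rmse(a, b) == pytest.approx(np.sqrt(np.sum((a - b) ** 2) / 100), abs=1e-12)

    def test_rpd_definition_and_table_consistency(self):
        assert rpd(1.0, 0.5) == pytest.approx(2.0)
        # back-solved consistency of published SV and FN report rows
        assert rpd(0.96518, 0.2138) == pytest.approx(4.5144, abs=1e-3)
        assert rpd(0.9358, 0.2930) == pytest.approx(3.1940, abs=1e-3)
        with pytest.raises(ZeroDivisionError):
            rpd(1.0, 0.0)

    def test_metrics_invariant_to_sample_order(self, rng):
        a, b = rng.normal(size=30), rng.normal(size=30)
        perm = rng.permutation(30)
        assert pearson_r(a, b) == pytest.approx(pearson_r(a[perm], b[perm]), abs=1e-12)
        assert rmse(a, b) == pytest.approx(rmse(a[perm], b[perm]), abs=1e-12)


class TestEvaluateModel:
    def _split_xy(self, rng, noise):
        X = rng.normal(size=(80, 4))
        y = X @ np.array([1.0, 0.8, -0.6, 0.4]) + rng.normal(0, noise, 80)
        return X[:64], y[:64], X[64:], y[64:]

    def test_noiseless_high_r(self, rng):
        Xtr, ytr, Xte, yte = self._split_xy(rng, 0.0)
        h = SvrHyperparams(C=1e3, epsilon=0.001, gamma=0.1)
        rep = evaluate_model(Xtr, ytr, Xte, yte, h, kernel="linear")
        assert rep.r_p > 0.999

    def test_rpd_identity_holds_exactly(self, rng):
        Xtr, ytr, Xte, yte = self._split_xy(rng, 0.3)
        h = SvrHyperparams(C=10.0, epsilon=0.1, gamma=0.2)
        rep = evaluate_model(Xtr, ytr, Xte, yte, h)
        assert rep.rpd * rep.rmse_p == pytest.approx(np.std(yte, ddof=1), abs=1e-9)

    def test_shuffled_target_r_near_zero(self):
        rs = []
        for rep in range(20):
            r = np.random.default_rng(1000 + rep)
            X = r.normal(size=(80, 4))
            y = r.permutation(X @ np.array([1.0, 0.8, -0.6, 0.4]))
            h = SvrHyperparams(C=1.0, epsilon=0.1, gamma=0.1)
            out = evaluate_model(X[:64], y[:64], X[64:], y[64:], h)
            rs.append(out.r_p)
        assert abs(np.mean(rs)) < 0.15  # sampling error around zero

    def test_prediction_rmse_improves_as_noise_vanishes(self, rng):
        h = SvrHyperparams(C=100.0, epsilon=0.01, gamma=0.2)
        errs = []
        for noise in (1.0, 0.3, 0.0):
            Xtr, ytr, Xte, yte = self._split_xy(np.random.default_rng(2), noise)
            errs.append(evaluate_model(Xtr, ytr, Xte, yte, h).rmse_p)
        assert errs[0] > errs[1] > errs[2]

    def test_report_serialization(self, rng):
        Xtr, ytr, Xte, yte = self._split_xy(rng, 0.2)
        rep = evaluate_model(Xtr, ytr, Xte, yte, SvrHyperparams(C=10, epsilon=0.1, gamma=0.2))
        d = json.loads(rep.to_json())
        assert set(d) >= {"R_CV", "RMSE_CV", "R_P", "RMSE_P", "RPD"}
        assert "SOA-SVR" in rep.to_csv_row()
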