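"""Epsilon-SVR calibration core, cross-validated fitness, and report metrics.

The calibration model is epsilon-insensitive support vector regression:
minimize ``1/2 ||w||^2 + C * sum(xi_i + xi_i*)`` subject to the epsilon tube,
with hyperparameters C (regularization weight), epsilon (tube half-width)
and gamma (RBF kernel width). Fitting delegates to scikit-learn's SVR; the
surrounding contract — seeded 5-fold fitness, Pearson R, RMSE and RPD as
reported for calibration tables — lives here.

All modeling is done in standardized space. A report can additionally carry
back-transformed errors in the reference units (mL for sedimentation value,
s for falling number) when a fitted standardizer is supplied.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as _stats
from sklearn.model_selection import KFold
from sklearn.svm import SVR

from .spectra import StandardizerParams

__all__ = [
    "SvrHyperparams",
    "ModelReport",
    "fit_svr",
    "cv_fitness",
    "pearson_r",
    "rmse",
    "rpd",
    "evaluate_model",
    "ConstantInputError",
]

KERNELS = ("rbf", "linear", "poly", "sigmoid")


class ConstantInputError(ValueError):
    """Pearson correlation is undefined for a constant input."""


@dataclass(frozen=True)
class SvrHyperparams:
    """(C, epsilon, gamma) point in the SVR search space."""

    C: float
    epsilon: float
    gamma: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.C) and self.C > 0):
            raise ValueError(f"C must be finite and > 0, got {self.C}")
        if not (np.isfinite(self.epsilon) and self.epsilon >= 0):
            raise ValueError(f"epsilon must be finite and >= 0, got {self.epsilon}")
        if not (np.isfinite(self.gamma) and self.gamma > 0):
            raise ValueError(f"gamma must be finite and > 0, got {self.gamma}")

    def as_dict(self) -> dict[str, float]:
        return {"C": self.C, "epsilon": self.epsilon, "gamma": self.gamma}


def _check_Xy(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if X.ndim != 2:
        raise ValueError("X must be 2-D")
    if X.shape[0] != y.size:
        raise ValueError(f"X has {X.shape[0]} rows but y has {y.size} values")
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite values in X or y")
    return X, y


def fit_svr(
    X: np.ndarray, y: np.ndarray, h: SvrHyperparams, kernel: str = "rbf"
) -> SVR:
    """Fit an epsilon-SVR; deterministic for identical inputs."""
    if kernel not in KERNELS:
        raise ValueError(f"kernel must be one of {KERNELS}")
    X, y = _check_Xy(X, y)
    if X.shape[0] < 2:
        raise ValueError("need at least 2 training samples")
    model = SVR(kernel=kernel, C=h.C, epsilon=h.epsilon, gamma=h.gamma)
    model.fit(X, y)
    return model


def cv_fitness(
    X: np.ndarray,
    y: np.ndarray,
    h: SvrHyperparams,
    folds: int = 5,
    seed: int = 0,
    kernel: str = "rbf",
) -> float:
    """Mean held-out RMSE over a seeded k-fold partition.

    Folds are shuffled contiguous blocks of near-equal size drawn from a
    seeded permutation; per-fold RMSEs are averaged arithmetically. This is
    the fitness the hyperparameter search minimizes.
    """
    X, y = _check_Xy(X, y)
    n = X.shape[0]
    if not 2 <= folds <= n:
        raise ValueError(f"folds must lie in [2, n={n}], got {folds}")
    kf = KFold(n_splits=folds, shuffle=True, random_state=seed)
    fold_errors = []
    for train_idx, test_idx in kf.split(X):
        model = fit_svr(X[train_idx], y[train_idx], h, kernel=kernel)
        fold_errors.append(rmse(y[test_idx], model.predict(X[test_idx])))
    return float(np.mean(fold_errors))


def pearson_r(y_ref: np.ndarray, y_hat: np.ndarray) -> float:
    """Pearson product-moment correlation; raises on constant input."""
    a = np.asarray(y_ref, dtype=float).ravel()
    b = np.asarray(y_hat, dtype=float).ravel()
    if a.size != b.size:
        raise ValueError("inputs must have equal length")
    if a.size < 2:
        raise ValueError("need at least 2 points")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ConstantInputError("correlation undefined for constant input")
    return float(_stats.pearsonr(a, b).statistic)


def rmse(y_ref: np.ndarray, y_hat: np.ndarray) -> float:
    """Root mean square error."""
    a = np.asarray(y_ref, dtype=float).ravel()
    b = np.asarray(y_hat, dtype=float).ravel()
    if a.size != b.size:
        raise ValueError("inputs must have equal length")
    if a.size == 0:
        raise ValueError("empty input")
    return float(np.sqrt(np.mean((a - b) ** 2)))


def rpd(sd_ref: float, rmse_p: float) -> float:
    """Relative percent deviation: SD of the prediction-set reference
    values divided by the prediction RMSE. RPD > 3 is conventionally taken
    as suitable for quality control."""
    if rmse_p <= 0:
        raise ZeroDivisionError("RPD undefined for non-positive RMSE")
    return float(sd_ref) / float(rmse_p)


@dataclass
class ModelReport:
    """One calibration-table row: CV and prediction performance plus the
    optimal hyperparameters.

    ``rmse_p_original`` / ``rmse_cv_original`` are the back-transformed
    errors in reference units when a target standardizer was used; RPD is
    scale-invariant so it is reported once.
    """

    r_cv: float
    rmse_cv: float
    r_p: float
    rmse_p: float
    rpd: float
    hyperparams: SvrHyperparams
    n_wavelengths: int
    training_time_s: float = 0.0
    rmse_cv_original: float | None = None
    rmse_p_original: float | None = None
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.rmse_cv < 0 or self.rmse_p < 0:
            raise ValueError("RMSE values must be >= 0")
        if abs(self.r_cv) > 1 + 1e-12 or abs(self.r_p) > 1 + 1e-12:
            raise ValueError("|R| must be <= 1")
        if self.rpd <= 0:
            raise ValueError("RPD must be > 0")

    def to_json(self) -> str:
        d = {
            "R_CV": self.r_cv,
            "RMSE_CV": self.rmse_cv,
            "R_P": self.r_p,
            "RMSE_P": self.rmse_p,
            "RPD": self.rpd,
            "hyperparams": self.hyperparams.as_dict(),
            "n_wavelengths": self.n_wavelengths,
            "training_time_s": self.training_time_s,
            "RMSE_CV_original_units": self.rmse_cv_original,
            "RMSE_P_original_units": self.rmse_p_original,
        }
        d.update(self.extra)
        return json.dumps(d, indent=2)

    def to_csv_row(self, label: str = "SOA-SVR") -> str:
        """Calibration-table-shaped CSV row (header + one line)."""
        header = (
            "model,n_wavelengths,C,epsilon,gamma,R_CV,RMSE_CV,R_P,RMSE_P,RPD,"
            "training_time_s"
        )
        h = self.hyperparams
        row = (
            f"{label},{self.n_wavelengths},{h.C:.4f},{h.epsilon:.4f},"
            f"{h.gamma:.4f},{self.r_cv:.4f},{self.rmse_cv:.4f},{self.r_p:.4f},"
            f"{self.rmse_p:.4f},{self.rpd:.4f},{self.training_time_s:.4f}"
        )
        return header + "\n" + row + "\n"


def evaluate_model(
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_test: np.ndarray,
    y_test: np.ndarray,
    h: SvrHyperparams,
    kernel: str = "rbf",
    folds: int = 5,
    seed: int = 0,
    standardizer: StandardizerParams | None = None,
) -> ModelReport:
    """Full evaluation of one hyperparameter point.

    R_CV / RMSE_CV are arithmetic means of per-fold Pearson R / RMSE on the
    held-out folds of the training set; R_P / RMSE_P come from a final fit on
    all training samples applied to the prediction set; RPD is the sample SD
    (n-1 denominator) of the prediction-set reference divided by RMSE_P.
    """
    X_train, y_train = _check_Xy(X_train, y_train)
    X_test, y_test = _check_Xy(X_test, y_test)
    if X_train.shape[1] != X_test.shape[1]:
        raise ValueError("train and prediction sets differ in wavelength count")
    if X_test.shape[0] < 2:
        raise ValueError("prediction set needs at least 2 samples")

    t0 = time.perf_counter()
    kf = KFold(n_splits=folds, shuffle=True, random_state=seed)
    fold_r, fold_rmse = [], []
    for tr, te in kf.split(X_train):
        m = fit_svr(X_train[tr], y_train[tr], h, kernel=kernel)
        pred = m.predict(X_train[te])
        fold_rmse.append(rmse(y_train[te], pred))
        fold_r.append(pearson_r(y_train[te], pred))
    final = fit_svr(X_train, y_train, h, kernel=kernel)
    elapsed = time.perf_counter() - t0

    y_hat = final.predict(X_test)
    rmse_p = rmse(y_test, y_hat)
    sd_ref = float(np.std(y_test, ddof=1))
    rmse_cv = float(np.mean(fold_rmse))

    rmse_cv_orig = rmse_p_orig = None
    if standardizer is not None and standardizer.target_scale is not None:
        rmse_cv_orig = rmse_cv * standardizer.target_scale
        rmse_p_orig = rmse_p * standardizer.target_scale

    return ModelReport(
        r_cv=float(np.mean(fold_r)),
        rmse_cv=rmse_cv,
        r_p=pearson_r(y_test, y_hat),
        rmse_p=rmse_p,
        rpd=rpd(sd_ref, rmse_p),
        hyperparams=h,
        n_wavelengths=X_train.shape[1],
        training_time_s=elapsed,
        rmse_cv_original=rmse_cv_orig,
        rmse_p_original=rmse_p_orig,
    )
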