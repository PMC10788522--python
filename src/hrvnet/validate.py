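"""SVR-based validation that connectivity values predict HRV group/score.

A polynomial-kernel support vector regressor (gamma fixed at 0.25) is
tuned by grid search over integer settings 1..10 for both the
polynomial degree and the regularisation strength C, using a 75/25
train/test split; the reported accuracy is then the 10-fold
cross-validation accuracy with the selected hyperparameters.  For group
(label) targets a prediction counts as correct when it rounds to the
true label; for continuous targets, when it falls within half a target
standard deviation of the truth.  The overall accuracy must exceed the
fixed 0.75 threshold, which is reported next to a 95 % highest-density
interval of the pooled connectivity-value distribution (normal model).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from sklearn.model_selection import GridSearchCV, KFold, train_test_split
from sklearn.svm import SVR

__all__ = [
    "SVRParams",
    "PredictionReport",
    "fit_svr",
    "credible_threshold",
]


@dataclass
class SVRParams:
    gamma: float = 0.25
    degree_grid: tuple = tuple(range(1, 11))
    c_grid: tuple = tuple(range(1, 11))
    train_fraction: float = 0.75
    n_folds: int = 10
    accuracy_threshold: float = 0.75
    sd_scale: float = 0.5  # continuous-target tolerance, in target sds
    target_kind: str = "auto"  # "group" | "continuous" | "auto"


@dataclass
class PredictionReport:
    fold_accuracies: list
    overall_accuracy: float
    test_accuracy: float
    train_fraction: float
    kernel_params: dict
    credible_interval: tuple
    accuracy_threshold: float
    passed: bool

    def as_dict(self) -> dict:
        return {
            "fold_accuracies": [float(a) for a in self.fold_accuracies],
            "overall_accuracy": float(self.overall_accuracy),
            "test_accuracy": float(self.test_accuracy),
            "train_fraction": self.train_fraction,
            "kernel_params": self.kernel_params,
            "credible_interval": [float(v) for v in self.credible_interval],
            "accuracy_threshold": self.accuracy_threshold,
            "passed": bool(self.passed),
        }


def _is_group_target(y: np.ndarray, kind: str) -> bool:
    if kind == "group":
        return True
    if kind == "continuous":
        return False
    uniq = np.unique(y)
    return uniq.size <= 3 and np.allclose(uniq, np.round(uniq))


def _accuracy(y_true, y_pred, group: bool, labels: np.ndarray, tol: float) -> float:
    if group:
        snapped = labels[np.argmin(np.abs(y_pred[:, None] - labels[None, :]), axis=1)]
        return float(np.mean(snapped == y_true))
    return float(np.mean(np.abs(y_pred - y_true) < tol))


def fit_svr(
    features: np.ndarray,
    target: np.ndarray,
    params: SVRParams = None,
    seed: int = 0,
) -> PredictionReport:
    """Fit, tune and cross-validate the polynomial-kernel SVR."""
    if params is None:
        params = SVRParams()
    X = np.asarray(features, dtype=float)
    y = np.asarray(target, dtype=float)
    if X.ndim != 2 or X.shape[0] != y.size:
        raise ValueError("features must be subjects x values matching target length")
    if X.shape[0] < 10:
        raise ValueError("need at least 10 subjects")
    if np.isnan(X).any() or np.isnan(y).any():
        raise ValueError("missing values not allowed")
    group = _is_group_target(y, params.target_kind)
    labels = np.unique(y)
    if group and labels.size < 2:
        raise ValueError("group target has a single class")
    sd = y.std(ddof=1)
    if not group and sd == 0:
        raise ValueError("constant continuous target")
    tol = params.sd_scale * sd

    def scorer(est, Xs, ys):
        return _accuracy(ys, est.predict(Xs), group, labels, tol)

    X_train, X_test, y_train, y_test = train_test_split(
        X,
        y,
        train_size=params.train_fraction,
        random_state=seed,
        stratify=y if group else None,
    )
    inner_folds = min(params.n_folds, X_train.shape[0])
    search = GridSearchCV(
        SVR(kernel="poly", gamma=params.gamma),
        {"degree": list(params.degree_grid), "C": list(params.c_grid)},
        scoring=scorer,
        cv=KFold(inner_folds, shuffle=True, random_state=seed),
    )
    search.fit(X_train, y_train)
    best = search.best_estimator_
    test_accuracy = scorer(best, X_test, y_test)

    # reported accuracy: 10-fold CV over all subjects with the tuned model
    outer = KFold(min(params.n_folds, X.shape[0]), shuffle=True, random_state=seed)
    fold_acc = []
    for tr, te in outer.split(X):
        model = SVR(kernel="poly", gamma=params.gamma, **search.best_params_)
        model.fit(X[tr], y[tr])
        fold_acc.append(_accuracy(y[te], model.predict(X[te]), group, labels, tol))
    overall = float(np.mean(fold_acc))

    if X.size >= 20 and np.ptp(X) > 0:
        interval, _ = credible_threshold(X.ravel())
    else:
        interval = (float("nan"), float("nan"))
    return PredictionReport(
        fold_accuracies=fold_acc,
        overall_accuracy=overall,
        test_accuracy=test_accuracy,
        train_fraction=params.train_fraction,
        kernel_params={"gamma": params.gamma, **search.best_params_},
        credible_interval=interval,
        accuracy_threshold=params.accuracy_threshold,
        passed=overall > params.accuracy_threshold,
    )


def credible_threshold(values: np.ndarray, mass: float = 0.95) -> tuple:
    """Highest-density interval of pooled connectivity values.

    A normal model is fit to the pooled values; its HDI at the stated
    mass (symmetric for a normal) is returned together with the fixed
    0.75 accuracy threshold.  ``mass >= 1`` degenerates to the data
    range.
    """
    values = np.asarray(values, dtype=float).ravel()
    if values.size < 20:
        raise ValueError("need at least 20 values")
    if not 0 < mass <= 1:
        raise ValueError("mass must lie in (0, 1]")
    sd = values.std(ddof=1)
    if np.ptp(values) == 0 or sd == 0:
        raise ValueError("degenerate (constant) value distribution")
    if mass >= 1.0:
        return (float(values.min()), float(values.max())), 0.75
    half = sps.norm.ppf((1 + mass) / 2) * sd
    mean = values.mean()
    return (float(mean - half), float(mean + half)), 0.75
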