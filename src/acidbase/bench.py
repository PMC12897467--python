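"""Benchmarking protocol: how well does each acid-base framework explain pH?

Three feature sets — traditional (PaCO2, HCO3, AGc), Stewart (PaCO2, SIDa,
ATOT, SIG) and partitioned base excess (PaCO2, BECl, BEAlb, BELac, BEGap) —
are compared as predictors of arterial pH under one linear model with
classical diagnostics (OLS with adjusted R2, Durbin-Watson, coefficient CIs,
Shapley/LMG predictor-importance shares) and three fixed-hyperparameter
machine-learning algorithms (random forest, XGBoost, RBF support vector
regression). The protocol around every algorithm is identical: a seeded
80/20 train/test split, 10-fold cross-validation with all preprocessing fit
inside each training fold, calibration metrics on the held-out predictions,
feature importance (tree impurity + exact Shapley values for tree models,
permutation importance for SVR), and paired-fold ablation of the
framework-specific unmeasured-ion index.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from itertools import combinations
from typing import Optional

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.ensemble import RandomForestRegressor
from sklearn.inspection import permutation_importance
from sklearn.linear_model import LinearRegression
from sklearn.metrics import mean_absolute_error, mean_squared_error, r2_score
from sklearn.model_selection import KFold, train_test_split
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVR
from statsmodels.stats.stattools import durbin_watson

from .shapley import mean_abs_shap

__all__ = [
    "FRAMEWORKS",
    "ABLATION_FEATURE",
    "ALGORITHMS",
    "HYPERPARAMETERS",
    "Calibration",
    "CVSummary",
    "ModelReport",
    "AblationResult",
    "feature_table",
    "make_model",
    "fit_mlr",
    "fit_ml",
    "crossvalidate",
    "calibration_metrics",
    "composite_importance",
    "run_ablation",
]

#: Framework feature sets, in the order they are always reported.
FRAMEWORKS: dict[str, list[str]] = {
    "traditional": ["paco2_mmhg", "hco3_mmol_l", "agc"],
    "stewart": ["paco2_mmhg", "sida", "atot", "sig"],
    "partitioned_be": ["paco2_mmhg", "becl", "bealb", "belac", "begap"],
}

#: The unmeasured-ion index removed in each framework's ablation experiment.
ABLATION_FEATURE = {"traditional": "agc", "stewart": "sig", "partitioned_be": "begap"}

ALGORITHMS = ("mlr", "rf", "xgb", "svr")

#: Fixed hyperparameters, never searched; recorded in every run config.
HYPERPARAMETERS = {
    "rf": {"n_estimators": 500, "min_samples_leaf": 5},
    "xgb": {"n_estimators": 300, "learning_rate": 0.1, "max_depth": 6},
    "svr": {"kernel": "rbf", "C": 10.0, "epsilon": 0.01},
}

PERMUTATION_REPEATS = 20
#: Shapley-value evaluation is capped at this many held-out rows; exact
#: per-row values are averaged, so the cap only bounds compute, not bias.
SHAP_EVAL_ROWS = 200


def feature_table(records: pd.DataFrame, panels: pd.DataFrame) -> pd.DataFrame:
    """Measured and derived columns side by side, ready for modelling."""
    return pd.concat([records.reset_index(drop=True), panels.reset_index(drop=True)], axis=1)


@dataclass(frozen=True)
class Calibration:
    in_the_large: float
    slope: Optional[float]
    intercept: Optional[float]
    brier_mse: float

    def to_dict(self):
        return {
            "in_the_large": self.in_the_large,
            "slope": self.slope,
            "intercept": self.intercept,
            "brier_mse": self.brier_mse,
        }


@dataclass(frozen=True)
class CVSummary:
    k: int
    r2_mean: float
    r2_sd: float
    rmse_mean: float
    rmse_sd: float
    mae_mean: float
    mae_sd: float

    def to_dict(self):
        return {
            "k": self.k,
            "r2": [self.r2_mean, self.r2_sd],
            "rmse": [self.rmse_mean, self.rmse_sd],
            "mae": [self.mae_mean, self.mae_sd],
        }


@dataclass
class ModelReport:
    """Fit, calibration, CV and importance results for one model."""

    algorithm: str
    features: list[str]
    seed: int
    r2: float
    rmse: float
    mae: float
    adjusted_r2: Optional[float] = None
    durbin_watson: Optional[float] = None
    coefficients: Optional[dict[str, dict[str, float]]] = None
    predictor_importance: Optional[dict[str, float]] = None
    calibration: Optional[Calibration] = None
    cv: Optional[CVSummary] = None
    importance: dict[str, dict[str, float]] = field(default_factory=dict)
    model: object = None  # fitted estimator, not serialized

    def to_dict(self):
        d = {
            "algorithm": self.algorithm,
            "features": self.features,
            "seed": self.seed,
            "r2": self.r2,
            "rmse": self.rmse,
            "mae": self.mae,
        }
        if self.adjusted_r2 is not None:
            d["adjusted_r2"] = self.adjusted_r2
        if self.durbin_watson is not None:
            d["durbin_watson"] = self.durbin_watson
        if self.coefficients is not None:
            d["coefficients"] = self.coefficients
        if self.predictor_importance is not None:
            d["predictor_importance"] = self.predictor_importance
        if self.calibration is not None:
            d["calibration"] = self.calibration.to_dict()
        if self.cv is not None:
            d["cv"] = self.cv.to_dict()
        if self.importance:
            d["importance"] = self.importance
        return d


@dataclass(frozen=True)
class AblationResult:
    framework: str
    algorithm: str
    removed: str
    full_r2: float
    ablated_r2: float
    fold_hash: str

    @property
    def delta_r2(self) -> float:
        return self.full_r2 - self.ablated_r2

    def to_dict(self):
        return {
            "framework": self.framework,
            "algorithm": self.algorithm,
            "removed": self.removed,
            "full_r2": self.full_r2,
            "ablated_r2": self.ablated_r2,
            "delta_r2": self.delta_r2,
            "fold_hash": self.fold_hash,
        }


def make_model(algorithm: str, seed: int = 42):
    """Fresh estimator with the protocol's fixed hyperparameters.

    SVR is wrapped in a pipeline with feature standardization so that any
    fold-wise fit scales inside the training data only.
    """
    algorithm = algorithm.lower()
    if algorithm == "mlr":
        return LinearRegression()
    if algorithm == "rf":
        return RandomForestRegressor(random_state=seed, n_jobs=1, **HYPERPARAMETERS["rf"])
    if algorithm == "xgb":
        from xgboost import XGBRegressor

        return XGBRegressor(
            random_state=seed, n_jobs=1, tree_method="hist",
            verbosity=0, **HYPERPARAMETERS["xgb"],
        )
    if algorithm == "svr":
        return make_pipeline(StandardScaler(), SVR(**HYPERPARAMETERS["svr"]))
    raise ValueError(f"unknown algorithm {algorithm!r}; expected one of {ALGORITHMS}")


def _metrics(y_true, y_pred):
    return (
        float(r2_score(y_true, y_pred)),
        float(np.sqrt(mean_squared_error(y_true, y_pred))),
        float(mean_absolute_error(y_true, y_pred)),
    )


def _subset_r2(X: np.ndarray, y: np.ndarray, cols: tuple[int, ...]) -> float:
    if not cols:
        return 0.0
    A = np.column_stack([np.ones(len(y)), X[:, cols]])
    resid = y - A @ np.linalg.lstsq(A, y, rcond=None)[0]
    sst = float(np.sum((y - y.mean()) ** 2))
    return 1.0 - float(np.sum(resid**2)) / sst


def _lmg_shares(X: np.ndarray, y: np.ndarray, names: list[str]) -> dict[str, float]:
    """Shapley (LMG) decomposition of R2 over predictors, normalized to sum 1."""
    import math

    p = X.shape[1]
    r2 = {s: _subset_r2(X, y, s) for k in range(p + 1) for s in combinations(range(p), k)}
    lmg = np.zeros(p)
    for i in range(p):
        others = [j for j in range(p) if j != i]
        for k in range(p):
            w = math.factorial(k) * math.factorial(p - k - 1) / math.factorial(p)
            for s in combinations(others, k):
                lmg[i] += w * (r2[tuple(sorted(s + (i,)))] - r2[s])
    total = lmg.sum()
    if total <= 0:
        raise ValueError("LMG decomposition degenerate: total R2 <= 0")
    return {name: float(v / total) for name, v in zip(names, lmg)}


def fit_mlr(X: pd.DataFrame, y: pd.Series, seed: int = 42) -> ModelReport:
    """Ordinary least squares with the classical diagnostic battery.

    Reports in-sample R2/adjusted R2/RMSE/MAE, the Durbin-Watson statistic of
    the residual sequence, coefficient estimates with 95% CIs, and
    predictor-importance shares from the Shapley/LMG decomposition of R2
    (each predictor's average marginal R2 contribution over all orderings,
    normalized to sum to one).
    """
    names = list(X.columns)
    n, p = X.shape
    if n <= p + 1:
        raise ValueError(f"need n > p + 1 (got n={n}, p={p})")
    if np.linalg.matrix_rank(np.column_stack([np.ones(n), X.to_numpy()])) < p + 1:
        raise np.linalg.LinAlgError("design matrix is rank deficient (collinear features)")
    design = sm.add_constant(X.to_numpy())
    fit = sm.OLS(np.asarray(y, dtype=float), design).fit()
    ci = fit.conf_int(alpha=0.05)
    coeffs = {
        name: {"coef": float(fit.params[j + 1]),
               "ci_low": float(ci[j + 1, 0]), "ci_high": float(ci[j + 1, 1])}
        for j, name in enumerate(names)
    }
    coeffs["intercept"] = {"coef": float(fit.params[0]),
                           "ci_low": float(ci[0, 0]), "ci_high": float(ci[0, 1])}
    pred = np.asarray(fit.fittedvalues)
    yarr = np.asarray(y, dtype=float)
    r2, rmse, mae = _metrics(yarr, pred)
    return ModelReport(
        algorithm="mlr",
        features=names,
        seed=seed,
        r2=r2,
        rmse=rmse,
        mae=mae,
        adjusted_r2=float(fit.rsquared_adj),
        durbin_watson=float(durbin_watson(fit.resid)),
        coefficients=coeffs,
        predictor_importance=_lmg_shares(X.to_numpy(dtype=float), yarr, names),
        calibration=calibration_metrics(yarr, pred),
        model=fit,
    )


def _tree_and_shap_importance(algorithm, model, X_test, names, seed):
    tree = {n: float(v) for n, v in zip(names, model.feature_importances_)}
    rows = np.asarray(X_test, dtype=float)[:SHAP_EVAL_ROWS]
    if algorithm == "xgb":
        import xgboost

        contribs = model.get_booster().predict(
            xgboost.DMatrix(rows, feature_names=[f"f{i}" for i in range(rows.shape[1])]),
            pred_contribs=True,
        )
        sabs = np.abs(contribs[:, :-1]).mean(axis=0)
    else:
        sabs = mean_abs_shap(model, rows)
    shap = {n: float(v) for n, v in zip(names, sabs)}
    combined = composite_importance(
        np.array(list(tree.values())), np.array(list(shap.values()))
    )
    return {
        "tree": tree,
        "shap_mean_abs": shap,
        "combined": {n: float(v) for n, v in zip(names, combined)},
    }


def fit_ml(
    algorithm: str,
    X: pd.DataFrame,
    y: pd.Series,
    seed: int = 42,
    test_size: float = 0.2,
) -> ModelReport:
    """Train one ML model on a seeded 80/20 split and evaluate held out.

    Metrics and calibration come from the 20% test partition. Tree models
    report impurity importance, exact Shapley importance and their composite;
    SVR reports permutation importance (mean R2 drop over
    ``PERMUTATION_REPEATS`` shuffles). Deterministic under ``seed``.
    """
    algorithm = algorithm.lower()
    if algorithm not in ("rf", "xgb", "svr", "mlr"):
        raise ValueError(f"unknown algorithm {algorithm!r}")
    names = list(X.columns)
    X_train, X_test, y_train, y_test = train_test_split(
        X.to_numpy(dtype=float), np.asarray(y, dtype=float),
        test_size=test_size, random_state=seed,
    )
    model = make_model(algorithm, seed)
    model.fit(X_train, y_train)
    pred = model.predict(X_test)
    r2, rmse, mae = _metrics(y_test, pred)
    report = ModelReport(
        algorithm=algorithm, features=names, seed=seed,
        r2=r2, rmse=rmse, mae=mae,
        calibration=calibration_metrics(y_test, pred),
        model=model,
    )
    if algorithm in ("rf", "xgb"):
        report.importance = _tree_and_shap_importance(algorithm, model, X_test, names, seed)
    elif algorithm == "svr":
        perm = permutation_importance(
            model, X_test, y_test, n_repeats=PERMUTATION_REPEATS,
            random_state=seed, scoring="r2",
        )
        report.importance = {
            "permutation": {n: float(v) for n, v in zip(names, perm.importances_mean)}
        }
    return report


def predict_with(report: ModelReport, X) -> np.ndarray:
    """Predictions from a fitted :class:`ModelReport` on new feature rows."""
    if report.model is None:
        raise ValueError("report carries no fitted model")
    Xa = np.asarray(X, dtype=float)
    if report.algorithm == "mlr":
        return np.asarray(report.model.predict(sm.add_constant(Xa, has_constant="add")))
    return np.asarray(report.model.predict(Xa))


def evaluate_external(report: ModelReport, X, y) -> dict:
    """Replay a fitted model on an unseen cohort: metrics plus calibration."""
    pred = predict_with(report, X)
    yarr = np.asarray(y, dtype=float)
    r2, rmse, mae = _metrics(yarr, pred)
    return {
        "r2": r2, "rmse": rmse, "mae": mae,
        "calibration": calibration_metrics(yarr, pred).to_dict(),
        "n": int(len(yarr)),
    }


def crossvalidate(
    algorithm: str, X: pd.DataFrame, y: pd.Series, k: int = 10, seed: int = 42
) -> CVSummary:
    """k-fold cross-validation; folds seeded, preprocessing fit per fold.

    All scaling lives inside the estimator (SVR's scaler is part of its
    pipeline), so each fold's transform is learned from its training part
    only.
    """
    n = len(y)
    if k < 2:
        raise ValueError("need k >= 2 folds")
    if k > n:
        raise ValueError(f"k={k} exceeds n={n}")
    Xa, ya = X.to_numpy(dtype=float), np.asarray(y, dtype=float)
    r2s, rmses, maes = [], [], []
    for train_idx, test_idx in KFold(k, shuffle=True, random_state=seed).split(Xa):
        model = make_model(algorithm, seed)
        model.fit(Xa[train_idx], ya[train_idx])
        r2, rmse, mae = _metrics(ya[test_idx], model.predict(Xa[test_idx]))
        r2s.append(r2)
        rmses.append(rmse)
        maes.append(mae)
    return CVSummary(
        k=k,
        r2_mean=float(np.mean(r2s)), r2_sd=float(np.std(r2s, ddof=1)),
        rmse_mean=float(np.mean(rmses)), rmse_sd=float(np.std(rmses, ddof=1)),
        mae_mean=float(np.mean(maes)), mae_sd=float(np.std(maes, ddof=1)),
    )


def calibration_metrics(observed, predicted) -> Calibration:
    """Calibration of predictions against observations.

    in_the_large = mean(observed - predicted); slope/intercept from the
    least-squares regression of observed on predicted (undefined and reported
    missing when predictions are constant); brier_mse = mean squared error.
    Identity predictions give exactly (0, 1, 0, 0).
    """
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape or obs.ndim != 1 or len(obs) < 2:
        raise ValueError("observed and predicted must be equal-length vectors, n >= 2")
    if np.array_equal(obs, pred) and np.ptp(pred) > 0:
        # short-circuit the identity so the calibration identities are exact
        return Calibration(in_the_large=0.0, slope=1.0, intercept=0.0, brier_mse=0.0)
    itl = float(np.mean(obs - pred))
    mse = float(np.mean((obs - pred) ** 2))
    if np.ptp(pred) == 0.0:
        return Calibration(in_the_large=itl, slope=None, intercept=None, brier_mse=mse)
    slope, intercept = np.polyfit(pred, obs, 1)
    return Calibration(
        in_the_large=itl, slope=float(slope), intercept=float(intercept), brier_mse=mse
    )


def composite_importance(tree_scores, shap_scores, normalize: bool = True) -> np.ndarray:
    """Combine tree-impurity and Shapley importance into one ranking.

    With ``normalize`` (default) each vector is scaled to sum to one before
    averaging, so the output is a share vector summing to one. With
    ``normalize=False`` the raw vectors are averaged directly — the
    convention under which published combined-importance tables reproduce
    from their printed TreeImp and SHAP columns.
    """
    t = np.asarray(tree_scores, dtype=float)
    s = np.asarray(shap_scores, dtype=float)
    if t.shape != s.shape or t.ndim != 1:
        raise ValueError("score vectors must be 1-D and the same length")
    if np.any(t < 0) or np.any(s < 0):
        raise ValueError("importance scores must be non-negative")
    if normalize:
        if t.sum() == 0 or s.sum() == 0:
            raise ValueError("cannot normalize an all-zero score vector")
        t = t / t.sum()
        s = s / s.sum()
    return (t + s) / 2.0


def run_ablation(
    framework: str,
    algorithm: str,
    X: pd.DataFrame,
    y: pd.Series,
    seed: int = 42,
    removed: str | None = None,
    k: int = 10,
) -> AblationResult:
    """Paired-fold ablation of one framework feature.

    Fits the full and the reduced feature set under the *same* 10-fold
    assignment (asserted via a fold hash) and reports the cross-validated R2
    drop. ``removed`` defaults to the framework's unmeasured-ion index.
    """
    features = FRAMEWORKS[framework]
    removed = removed or ABLATION_FEATURE[framework]
    if removed not in features:
        raise ValueError(f"{removed!r} is not a feature of {framework!r}")
    reduced = [f for f in features if f != removed]
    if not reduced:
        raise ValueError("ablation would leave no features")
    Xa = X[features].to_numpy(dtype=float)
    ya = np.asarray(y, dtype=float)
    folds = list(KFold(k, shuffle=True, random_state=seed).split(Xa))
    fold_hash = hashlib.sha256(
        b"".join(np.sort(test).tobytes() for _, test in folds)
    ).hexdigest()
    keep = [features.index(f) for f in reduced]

    def cv_r2(columns):
        scores = []
        for train_idx, test_idx in folds:
            model = make_model(algorithm, seed)
            model.fit(Xa[np.ix_(train_idx, columns)], ya[train_idx])
            scores.append(r2_score(ya[test_idx], model.predict(Xa[np.ix_(test_idx, columns)])))
        return float(np.mean(scores))

    return AblationResult(
        framework=framework,
        algorithm=algorithm,
        removed=removed,
        full_r2=cv_r2(list(range(len(features)))),
        ablated_r2=cv_r2(keep),
        fold_hash=fold_hash,
    )
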