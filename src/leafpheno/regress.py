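"""Regression of leaf traits on image features, scored by R^2, MAE and ATPA.

Three model families are compared under seeded tenfold cross-validation:

* simple nonlinear regression (SNR): model A, the quadratic
  ``y = a + b x + c x**2`` (ordinary least squares), and model B, the power
  law ``y = a x**b`` (nonlinear least squares initialised from the log-log
  line; a pure log-log fit is available for multiplicative-error data);
* random forests (default 300 trees, mtry = max(1, p/3), with a helper that
  sweeps ntree over 100..500 in steps of 50);
* gradient-boosted trees (learning rate 0.04, 2000 iterations, squared-error
  loss).

ATPA (average testing prediction accuracy) is the headline comparison
statistic:

    ATPA = (1 - mean(|y_true - y_pred| / y_true)) * 100

It is unbounded below; rows with ``y_true == 0`` are excluded with a warning
because the relative error is undefined there.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.optimize import curve_fit
from sklearn.ensemble import HistGradientBoostingRegressor, RandomForestRegressor

__all__ = [
    "FitResult",
    "CvResult",
    "atpa",
    "metrics",
    "fit_snr",
    "fit_ensemble",
    "sweep_ntree",
    "cross_validate",
    "run_combinations",
    "remove_outliers",
    "STANDARD_COMBINATIONS",
]

# The M1-M7 input combinations of the three headline predictors.
STANDARD_COMBINATIONS = {
    "M1": ["SCA1"],
    "M2": ["SSC"],
    "M3": ["SPA1"],
    "M4": ["SCA1", "SPA1"],
    "M5": ["SCA1", "SSC"],
    "M6": ["SPA1", "SSC"],
    "M7": ["SCA1", "SSC", "SPA1"],
}


def atpa(y_true, y_pred) -> float:
    """Average testing prediction accuracy, in percent.

    ``(1 - mean(|T_A - T_P| / T_A)) * 100`` over rows with ``T_A != 0``.
    """
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal length")
    keep = y_true != 0
    if not keep.any():
        raise ValueError("all true values are zero: ATPA undefined")
    if not keep.all():
        warnings.warn(f"excluding {int((~keep).sum())} rows with zero true value")
    rel = np.abs(y_true[keep] - y_pred[keep]) / np.abs(y_true[keep])
    return float((1.0 - rel.mean()) * 100.0)


def metrics(y_true, y_pred) -> dict:
    """R^2, MAE and ATPA for one prediction vector."""
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    ss_tot = float(np.sum((y_true - y_true.mean()) ** 2))
    if ss_tot == 0:
        warnings.warn("constant y_true: R^2 undefined")
        r2 = float("nan")
    else:
        r2 = 1.0 - float(np.sum((y_true - y_pred) ** 2)) / ss_tot
    return {
        "r2": r2,
        "mae": float(np.mean(np.abs(y_true - y_pred))),
        "atpa": atpa(y_true, y_pred),
    }


@dataclass
class FitResult:
    """A fitted model: SNR coefficients or an ensemble handle, plus metadata."""

    model_type: str            # A | B | rf | gbt
    coef: tuple | None = None  # (a, b[, c]) for SNR models
    model: object = None       # fitted sklearn estimator for ensembles
    meta: dict = field(default_factory=dict)

    def predict(self, X):
        if self.model_type == "A":
            a, b, c = self.coef
            x = np.asarray(X, dtype=float).ravel()
            return a + b * x + c * x**2
        if self.model_type == "B":
            a, b = self.coef
            x = np.asarray(X, dtype=float).ravel()
            return a * np.power(x, b)
        return self.model.predict(np.asarray(X, dtype=float))


def fit_snr(x, y, model_type: str, fit_b: str = "nls") -> FitResult:
    """Fit a simple nonlinear regression model.

    Model A (``y = a + b x + c x**2``) by ordinary least squares on
    ``(1, x, x^2)``.  Model B (``y = a x**b``) by nonlinear least squares
    initialised from the log-log OLS line (``fit_b='loglog'`` returns the
    log-log estimate itself, appropriate under multiplicative error).
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if model_type == "A":
        if x.size < 3:
            raise ValueError("model A needs at least 3 points")
        design = np.column_stack([np.ones_like(x), x, x**2])
        coef, *_ = np.linalg.lstsq(design, y, rcond=None)
        return FitResult("A", tuple(float(v) for v in coef), meta={"n": x.size})
    if model_type == "B":
        if x.size < 2:
            raise ValueError("model B needs at least 2 points")
        if np.any(x <= 0) or np.any(y <= 0):
            raise ValueError("model B requires strictly positive x and y")
        slope, intercept = np.polyfit(np.log(x), np.log(y), 1)
        a0, b0 = float(np.exp(intercept)), float(slope)
        if fit_b == "loglog":
            return FitResult("B", (a0, b0), meta={"n": x.size, "fit_b": "loglog"})
        popt, _ = curve_fit(lambda xx, a, b: a * np.power(xx, b), x, y,
                            p0=(a0, b0), maxfev=20000)
        return FitResult("B", (float(popt[0]), float(popt[1])),
                         meta={"n": x.size, "fit_b": "nls"})
    raise ValueError(f"unknown SNR model type {model_type!r}")


def _make_estimator(family: str, n_features: int, seed: int, config: dict):
    config = dict(config or {})
    if family == "rf":
        ntree = int(config.pop("ntree", 300))
        mtry = int(config.pop("mtry", max(1, n_features // 3)))
        return RandomForestRegressor(
            n_estimators=ntree, max_features=mtry,
            random_state=seed, **config), {"ntree": ntree, "mtry": mtry}
    if family == "gbt":
        lr = float(config.pop("learning_rate", 0.04))
        iters = int(config.pop("iterations", 2000))
        return HistGradientBoostingRegressor(
            learning_rate=lr, max_iter=iters, loss="squared_error",
            early_stopping=False, random_state=seed, **config), {
                "learning_rate": lr, "iterations": iters}
    raise ValueError(f"unknown ensemble family {family!r}")


def fit_ensemble(X, y, family: str, config: dict | None = None,
                 seed: int = 0) -> FitResult:
    """Fit a random forest or gradient-boosted tree regressor.

    Defaults: rf with ntree=300 and mtry=max(1, p/3); gbt with learning rate
    0.04, 2000 iterations, squared-error loss.  Deterministic per seed.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(y, dtype=float)
    if X.shape[0] < 20:
        raise ValueError("need at least 20 rows for an ensemble fit")
    est, hyper = _make_estimator(family, X.shape[1], seed, config)
    est.fit(X, y)
    return FitResult(family, model=est,
                     meta={"n": X.shape[0], "seed": seed, **hyper})


def sweep_ntree(X, y, ntrees=range(100, 501, 50), folds: int = 10,
                seed: int = 0, mtry: int | None = None) -> pd.DataFrame:
    """Cross-validated R^2 / MAE / ATPA for each forest size.

    The conventional tuning report behind the choice of ntree = 300.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    rows = []
    table = pd.DataFrame(X, columns=[f"x{i}" for i in range(X.shape[1])])
    table["y"] = y
    for ntree in ntrees:
        config = {"ntree": int(ntree)}
        if mtry is not None:
            config["mtry"] = mtry
        cv = cross_validate(table, "y",
                            {"family": "rf", **config},
                            folds=folds, seed=seed,
                            features=[c for c in table.columns if c != "y"])
        rows.append({"ntree": int(ntree), **cv.summary_flat()})
    return pd.DataFrame(rows)


@dataclass
class CvResult:
    """Per-fold metrics of a cross-validated model plus fold assignments."""

    per_fold: pd.DataFrame      # columns fold, r2, mae, atpa, n_test
    fold_of_row: np.ndarray     # fold index per table row
    seed: int
    model_spec: dict
    predictions: pd.DataFrame   # columns row, y_true, y_pred

    def summary(self) -> dict:
        out = {}
        for m in ("r2", "mae", "atpa"):
            vals = self.per_fold[m].to_numpy(dtype=float)
            out[m] = {
                "mean": float(np.nanmean(vals)),
                "median": float(np.nanmedian(vals)),
                "min": float(np.nanmin(vals)),
                "max": float(np.nanmax(vals)),
            }
        return out

    def summary_flat(self) -> dict:
        s = self.summary()
        return {f"{m}_{k}": v for m, d in s.items() for k, v in d.items()}


def _fit_predict(family, config, X_train, y_train, X_test, seed):
    if family in ("A", "B"):
        if X_train.shape[1] != 1:
            raise ValueError("SNR models take exactly one feature")
        fit = fit_snr(X_train[:, 0], y_train, family,
                      **({"fit_b": config["fit_b"]} if "fit_b" in config else {}))
        return fit.predict(X_test[:, 0])
    est, _ = _make_estimator(family, X_train.shape[1], seed, config)
    est.fit(X_train, y_train)
    return est.predict(X_test)


def cross_validate(table: pd.DataFrame, trait: str, model_spec: dict,
                   folds: int = 10, seed: int = 0,
                   features=None) -> CvResult:
    """Seeded k-fold cross-validation with R^2 / MAE / ATPA per fold.

    The fold split is a seeded shuffle followed by a contiguous partition, so
    it depends only on ``(n, folds, seed)`` -- model runs with the same seed
    share folds exactly (paired comparisons).  ``model_spec`` is a dict with
    ``family`` in {A, B, rf, gbt} plus hyperparameters.
    """
    spec = dict(model_spec)
    family = spec.pop("family")
    if features is None:
        features = spec.pop("features")
    n = len(table)
    if n < folds:
        raise ValueError("fewer rows than folds")
    for name in features:
        if name not in table.columns:
            raise KeyError(f"unknown feature {name!r}")
    X = table[list(features)].to_numpy(dtype=float)
    y = table[trait].to_numpy(dtype=float)

    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    fold_of_row = np.empty(n, dtype=int)
    records, preds = [], []
    for fold_idx, test_idx in enumerate(np.array_split(order, folds)):
        fold_of_row[test_idx] = fold_idx
        train_idx = np.setdiff1d(order, test_idx)
        y_pred = _fit_predict(family, spec, X[train_idx], y[train_idx],
                              X[test_idx], seed)
        y_true = y[test_idx]
        if np.ptp(y_true) == 0:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                m = metrics(y_true, y_pred)
        else:
            m = metrics(y_true, y_pred)
        records.append({"fold": fold_idx, **m, "n_test": len(test_idx)})
        preds.append(pd.DataFrame({"row": test_idx, "y_true": y_true,
                                   "y_pred": y_pred}))
    return CvResult(
        per_fold=pd.DataFrame(records),
        fold_of_row=fold_of_row,
        seed=seed,
        model_spec={"family": family, **spec, "features": list(features)},
        predictions=pd.concat(preds, ignore_index=True),
    )


def run_combinations(table: pd.DataFrame, trait: str, inputs: dict,
                     model_spec: dict, folds: int = 10,
                     seed: int = 0) -> dict:
    """One CvResult per named feature combination, on identical folds.

    ``inputs`` maps combination names (e.g. M1..M7) to feature-name lists;
    because the fold split depends only on (n, folds, seed), every
    combination is evaluated on the same partition.
    """
    out = {}
    for name, feats in inputs.items():
        out[name] = cross_validate(table, trait, model_spec, folds=folds,
                                   seed=seed, features=list(feats))
    return out


def remove_outliers(table: pd.DataFrame, trait: str, features,
                    alpha: float = 0.05, min_rows: int = 10):
    """Iterative Bonferroni outlier pruning on studentized residuals.

    A baseline linear model of the trait on ``features`` is fitted; the row
    with the most extreme externally studentized residual is removed while
    its Bonferroni-adjusted two-sided p-value is below ``alpha``.  Returns
    ``(filtered_table, removed_index_labels)``.
    """
    features = list(features)
    if not features:
        raise ValueError("empty feature set")
    work = table.copy()
    removed = []
    while True:
        X = sm.add_constant(work[features].to_numpy(dtype=float))
        fit = sm.OLS(work[trait].to_numpy(dtype=float), X).fit()
        test = np.asarray(fit.outlier_test(method="bonf"))
        worst = int(np.argmax(np.abs(test[:, 0])))
        if test[worst, 2] >= alpha:
            break
        if len(work) - 1 < min_rows:
            raise ValueError("outlier removal would leave too few rows")
        removed.append(work.index[worst])
        work = work.drop(index=work.index[worst])
    return work, removed
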