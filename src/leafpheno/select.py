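"""Predictor selection: correlation ranking, permutation importance, and
cross-validated choice of how many predictors to keep.

Two rankings are offered.  Pearson correlation ranks features by |r| against
the target trait (two-sided p-values via the t transform are reported, no
multiple-testing correction).  Permutation importance follows the
randomForest %IncMSE semantics: the increase in out-of-fold MSE when one
feature column is permuted, averaged over repeats and folds, floored at zero
and rescaled so the percentages sum to 100 (raw values are retained).

``choose_k_by_cv`` walks the ranked list, evaluates cross-validated MAE with
the top-1, top-2, ... predictors, and by default keeps the smallest k whose
MAE is within one standard error of the curve minimum.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import clone
from sklearn.ensemble import RandomForestRegressor
from sklearn.linear_model import LinearRegression
from sklearn.model_selection import KFold

__all__ = [
    "RankedPredictors",
    "correlation_rank",
    "importance_rank",
    "choose_k_by_cv",
]

TRAITS = ("LN", "LFW", "LAI")


@dataclass(frozen=True)
class RankedPredictors:
    """Ordered predictors with their scores.

    ``score_kind`` is ``pearson_r`` (ordered by |r| descending, p-values in
    ``extra['p_value']``) or ``importance_pct`` (percent of total importance,
    summing to 100, raw values in ``extra['raw']``).
    """

    names: tuple
    scores: tuple
    score_kind: str
    extra: dict

    def top(self, k: int) -> list:
        return list(self.names[:k])

    def as_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"feature": self.names, "score": self.scores})
        for key, vals in self.extra.items():
            df[key] = [vals.get(n, np.nan) for n in self.names]
        return df


def _split_xy(table: pd.DataFrame, trait: str, features=None):
    if trait not in table.columns:
        raise KeyError(f"trait column {trait!r} missing from table")
    if features is None:
        features = [c for c in table.columns
                    if c not in TRAITS and
                    pd.api.types.is_numeric_dtype(table[c])]
    X = table[list(features)].to_numpy(dtype=float)
    y = table[trait].to_numpy(dtype=float)
    return X, y, list(features)


def correlation_rank(table: pd.DataFrame, trait: str,
                     features=None) -> RankedPredictors:
    """Rank features by |Pearson r| against the trait.

    Constant features have undefined r; they are ranked last (score NaN)
    with a warning.
    """
    X, y, names = _split_xy(table, trait, features)
    if X.shape[0] < 3:
        raise ValueError("need at least 3 complete rows")
    rs, ps = {}, {}
    for idx, name in enumerate(names):
        col = X[:, idx]
        if np.std(col) == 0 or np.std(y) == 0:
            warnings.warn(f"constant feature {name!r}: Pearson r undefined")
            rs[name], ps[name] = np.nan, np.nan
        else:
            r, p = stats.pearsonr(col, y)
            rs[name], ps[name] = float(r), float(p)
    order = sorted(names, key=lambda n: (np.isnan(rs[n]), -abs(rs[n])
                                         if not np.isnan(rs[n]) else 0.0))
    return RankedPredictors(
        names=tuple(order),
        scores=tuple(rs[n] for n in order),
        score_kind="pearson_r",
        extra={"p_value": ps},
    )


def importance_rank(table: pd.DataFrame, trait: str, features=None,
                    n_estimators: int = 300, n_repeats: int = 10,
                    folds: int = 5, seed: int = 0) -> RankedPredictors:
    """Permutation importance (%IncMSE style) rescaled to percent of total.

    For each CV fold a random forest is fitted on the training part; each
    feature column of the held-out part is permuted ``n_repeats`` times and
    the mean increase in held-out MSE is recorded.  Negative raw importances
    are floored at 0 before rescaling; raw values are kept in ``extra``.
    """
    X, y, names = _split_xy(table, trait, features)
    if np.std(y) == 0:
        raise ValueError("trait is constant: importance undefined")
    if X.shape[0] < 2 * folds:
        raise ValueError("too few rows to fit the forest")
    rng = np.random.default_rng(seed)
    model = RandomForestRegressor(
        n_estimators=n_estimators,
        max_features=max(1, X.shape[1] // 3),
        random_state=int(rng.integers(2**31 - 1)),
    )
    raw = np.zeros(len(names))
    kf = KFold(n_splits=folds, shuffle=True,
               random_state=int(rng.integers(2**31 - 1)))
    for train, test in kf.split(X):
        fitted = clone(model).fit(X[train], y[train])
        base = np.mean((fitted.predict(X[test]) - y[test]) ** 2)
        for idx in range(len(names)):
            inc = 0.0
            for _ in range(n_repeats):
                Xp = X[test].copy()
                Xp[:, idx] = rng.permutation(Xp[:, idx])
                inc += np.mean((fitted.predict(Xp) - y[test]) ** 2) - base
            raw[idx] += inc / n_repeats
    raw /= folds
    floored = np.maximum(raw, 0.0)
    total = floored.sum()
    pct = floored / total * 100.0 if total > 0 else np.zeros_like(floored)
    order = np.argsort(-pct, kind="stable")
    return RankedPredictors(
        names=tuple(names[i] for i in order),
        scores=tuple(float(pct[i]) for i in order),
        score_kind="importance_pct",
        extra={"raw": {names[i]: float(raw[i]) for i in order}},
    )


def _cv_mae(X, y, model, folds, seed):
    kf = KFold(n_splits=folds, shuffle=True, random_state=seed)
    maes = []
    for train, test in kf.split(X):
        fitted = clone(model).fit(X[train], y[train])
        maes.append(float(np.mean(np.abs(fitted.predict(X[test]) - y[test]))))
    return np.asarray(maes)


def choose_k_by_cv(ranked: RankedPredictors, table: pd.DataFrame, trait: str,
                   folds: int = 10, seed: int = 0, model=None,
                   rule: str = "1se", max_k: int | None = None):
    """Pick how many top-ranked predictors to keep from the CV error curve.

    Evaluates CV MAE with the top-1, top-2, ... predictors (common folds).
    ``rule='1se'`` returns the smallest k whose mean MAE is within one
    standard error of the curve minimum (ties break toward smaller k);
    ``rule='min'`` returns the argmin; ``rule='fixed:<k>'`` forces k.
    Returns ``(k, selected_names, curve)`` where ``curve`` is a DataFrame of
    per-k mean MAE and its standard error.
    """
    if not ranked.names:
        raise ValueError("ranked predictor list is empty")
    names = list(ranked.names)
    if max_k is not None:
        names = names[:max_k]
    if rule.startswith("fixed:"):
        k = int(rule.split(":", 1)[1])
        return k, names[:k], None
    if rule not in ("1se", "min"):
        raise ValueError(f"unknown rule {rule!r}")
    if model is None:
        model = LinearRegression()
    y = table[trait].to_numpy(dtype=float)
    means, ses = [], []
    for k in range(1, len(names) + 1):
        X = table[names[:k]].to_numpy(dtype=float)
        maes = _cv_mae(X, y, model, folds, seed)
        means.append(maes.mean())
        ses.append(maes.std(ddof=1) / np.sqrt(len(maes)))
    means = np.asarray(means)
    ses = np.asarray(ses)
    best = int(np.argmin(means))
    if rule == "min":
        k = best + 1
    else:
        threshold = means[best] + ses[best]
        k = int(np.nonzero(means <= threshold)[0][0]) + 1
    curve = pd.DataFrame({"k": np.arange(1, len(names) + 1),
                          "mae": means, "se": ses})
    return k, names[:k], curve
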