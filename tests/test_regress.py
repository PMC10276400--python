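"""ATPA, SNR fitting, ensembles, cross-validation, combinations, outliers."""

import numpy as np
import pandas as pd
import pytest

from leafpheno.regress import (
    STANDARD_COMBINATIONS,
    atpa,
    cross_validate,
    fit_ensemble,
    fit_snr,
    metrics,
    remove_outliers,
    run_combinations,
)
from leafpheno.synth import generate_regression_dataset


def test_atpa_worked_examples():
    assert atpa([3.0, 7.0], [3.0, 7.0]) == 100.0
    assert atpa([10.0, 20.0], [9.0, 22.0]) == pytest.approx(90.0)
    assert atpa([10.0], [25.0]) == pytest.approx(-50.0)   # unbounded below


def test_atpa_zero_handling():
    with pytest.warns(UserWarning, match="zero"):
        v = atpa([0.0, 10.0], [5.0, 11.0])
    assert v == pytest.approx(90.0)        # zero-truth row excluded
    with pytest.raises(ValueError):
        atpa([0.0, 0.0], [1.0, 2.0])
    with pytest.raises(ValueError):
        atpa([1.0, 2.0], [1.0])


def test_metrics_examples():
    m = metrics([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
    assert m == {"r2": 1.0, "mae": 0.0, "atpa": 100.0}
    y = np.array([1.0, 2.0, 3.0])
    m = metrics(y, np.full(3, y.mean()))
    assert m["r2"] == pytest.approx(0.0)
    m = metrics([1.0, 2.0, 3.0], [2.0, 2.0, 2.0])
    assert m["mae"] == pytest.approx(2 / 3)
    with pytest.warns(UserWarning, match="constant"):
        m = metrics([2.0, 2.0], [1.0, 3.0])
    assert np.isnan(m["r2"])


def test_fit_snr_exact_recovery():
    x = np.linspace(1.0, 5.0, 10)
    fit = fit_snr(x, 1 + 2 * x + 3 * x**2, "A")
    assert fit.coef == pytest.approx((1.0, 2.0, 3.0), abs=1e-9)
    fit = fit_snr(x, 2 * x**1.5, "B")
    assert fit.coef == pytest.approx((2.0, 1.5), abs=1e-9)
    # loglog estimator agrees on noise-free data
    fit = fit_snr(x, 2 * x**1.5, "B", fit_b="loglog")
    assert fit.coef == pytest.approx((2.0, 1.5), abs=1e-9)


def test_fit_snr_domain_errors():
    with pytest.raises(ValueError):
        fit_snr([-1.0, 1.0, 2.0], [1.0, 2.0, 3.0], "B")
    with pytest.raises(ValueError):
        fit_snr([1.0, 2.0], [1.0, 2.0], "A")     # underdetermined


def test_fit_snr_noisy_power_law_recovery():
    df = generate_regression_dataset("B", (4.57, 1.12), (20.0, 1200.0),
                                     1000, 0.05, seed=5)
    fit = fit_snr(df["x"], df["y"], "B")
    assert fit.coef[0] == pytest.approx(4.57, rel=0.1)
    assert fit.coef[1] == pytest.approx(1.12, abs=0.05)


def test_ensembles_learn_deterministic_signal(rng):
    x = rng.uniform(0, 10, 500)
    y = 3.0 * x
    X = x[:, None]
    for family, config in (("rf", {"ntree": 100}),
                           ("gbt", {"iterations": 300})):
        fit = fit_ensemble(X, y, family, config=config, seed=0)
        pred = fit.predict(X)
        assert metrics(y, pred)["r2"] > 0.95
        if family == "rf":
            assert pred.min() >= y.min() and pred.max() <= y.max()
        refit = fit_ensemble(X, y, family, config=config, seed=0)
        assert np.array_equal(pred, refit.predict(X))


def _quad_table(rng, n=100, noise=0.0):
    x = rng.uniform(1.0, 10.0, n)
    y = 1 + 2 * x + 3 * x**2
    if noise:
        y = y * (1 + rng.normal(0, noise, n))
    return pd.DataFrame({"x": x, "LN": y})


def test_cross_validate_partition_and_determinism(rng):
    table = _quad_table(rng, n=100, noise=0.05)
    cv = cross_validate(table, "LN", {"family": "A"}, folds=10, seed=4,
                        features=["x"])
    assert len(cv.per_fold) == 10
    assert (cv.per_fold["n_test"] == 10).all()
    assert sorted(cv.predictions["row"]) == list(range(100))
    cv2 = cross_validate(table, "LN", {"family": "A"}, folds=10, seed=4,
                         features=["x"])
    assert np.array_equal(cv.fold_of_row, cv2.fold_of_row)
    assert cv.per_fold.equals(cv2.per_fold)


def test_cross_validate_oracle_model(rng):
    """Noise-free quadratic data: the quadratic SNR model is the oracle."""
    table = _quad_table(rng, n=60, noise=0.0)
    cv = cross_validate(table, "LN", {"family": "A"}, folds=10, seed=0,
                        features=["x"])
    assert np.allclose(cv.per_fold["atpa"], 100.0, atol=1e-6)
    assert np.allclose(cv.per_fold["r2"], 1.0, atol=1e-9)


def test_cross_validate_validates_inputs(rng):
    table = _quad_table(rng, n=5)
    with pytest.raises(ValueError):
        cross_validate(table, "LN", {"family": "A"}, folds=10, features=["x"])
    with pytest.raises(KeyError):
        cross_validate(_quad_table(rng), "LN", {"family": "A"},
                       features=["bogus"])


def _combo_table(rng, n=150):
    df = pd.DataFrame({
        "SCA1": rng.uniform(20, 1200, n),
        "SPA1": rng.uniform(20, 900, n),
        "SSC": rng.uniform(0.7, 0.97, n),
    })
    return df


def test_combinations_share_folds_and_nesting(rng):
    df = _combo_table(rng)
    # all three features informative
    df["LAI"] = (0.002 * df["SCA1"] + 0.002 * df["SPA1"] + 3 * df["SSC"]
                 ) * (1 + rng.normal(0, 0.05, len(df)))
    res = run_combinations(df, "LAI", STANDARD_COMBINATIONS,
                           {"family": "rf", "ntree": 60}, folds=5, seed=2)
    folds = {name: tuple(cv.fold_of_row) for name, cv in res.items()}
    assert len(set(folds.values())) == 1          # identical partitions
    m1 = res["M1"].summary()["atpa"]["mean"]
    m7 = res["M7"].summary()["atpa"]["mean"]
    se = res["M1"].per_fold["atpa"].std(ddof=1) / np.sqrt(5)
    assert m7 >= m1 - se
    # duplicate combination gives identical results
    dup = run_combinations(df, "LAI", {"a": ["SCA1"], "b": ["SCA1"]},
                           {"family": "rf", "ntree": 60}, folds=5, seed=2)
    assert dup["a"].per_fold.equals(dup["b"].per_fold)


def test_combinations_planted_signal(rng):
    df = _combo_table(rng)
    df["LAI"] = 50 * df["SSC"] ** 2 * (1 + rng.normal(0, 0.02, len(df)))
    res = run_combinations(df, "LAI",
                           {k: STANDARD_COMBINATIONS[k] for k in
                            ("M1", "M2", "M3")},
                           {"family": "rf", "ntree": 60}, folds=5, seed=0)
    atpas = {k: v.summary()["atpa"]["mean"] for k, v in res.items()}
    assert atpas["M2"] == max(atpas.values())     # SSC alone carries signal


def test_remove_outliers(rng):
    n = 200
    x = rng.uniform(0, 10, n)
    y = 2 + 3 * x + rng.normal(0, 0.5, n)
    table = pd.DataFrame({"x": x, "LN": y})
    clean, removed = remove_outliers(table, "LN", ["x"])
    assert len(removed) <= 2                      # near-null behaviour
    table.loc[50, "LN"] += 10 * 0.5 * 10          # ~100-sigma outlier
    clean, removed = remove_outliers(table, "LN", ["x"])
    assert removed == [50]
    with pytest.raises(ValueError):
        remove_outliers(table, "LN", [])


def test_remove_outliers_min_rows(rng):
    x = rng.uniform(0, 10, 10)
    table = pd.DataFrame({"x": x, "LN": 3 * x})
    table.loc[0, "LN"] += 1000.0
    with pytest.raises(ValueError, match="too few rows"):
        remove_outliers(table, "LN", ["x"], min_rows=10)


def test_heldout_not_better_than_training(rng):
    """Held-out R^2 should not beat training R^2 beyond sampling slack."""
    gaps = []
    for seed in range(5):
        r = np.random.default_rng(seed)
        x = r.uniform(1, 10, 120)
        y = x**1.3 * (1 + r.normal(0, 0.1, 120))
        table = pd.DataFrame({"x": x, "LN": y})
        cv = cross_validate(table, "LN", {"family": "rf", "ntree": 60},
                            folds=5, seed=seed, features=["x"])
        fit = fit_ensemble(x[:, None], y, "rf", {"ntree": 60}, seed=seed)
        train_r2 = metrics(y, fit.predict(x[:, None]))["r2"]
        gaps.append(train_r2 - cv.summary()["r2"]["mean"])
    assert np.mean(gaps) > -0.05
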