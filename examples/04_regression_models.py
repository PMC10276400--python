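"""Fit the three regression families and compare them with ATPA.

First a power-law (model B) refit of data simulated from the published
LAI ~ SCA1 model (y = 4.57 x^1.12): the recovered coefficients should land
within the printed uncertainties.  Then a tenfold cross-validated comparison
of SNR vs random forest vs gradient boosting on the same synthetic table,
plus the M1-M7 input-combination study: ATPA (average testing prediction
accuracy, percent) is the headline number -- higher is better, 100 is a
perfect fit.
"""

import numpy as np
import pandas as pd

from leafpheno.regress import (
    STANDARD_COMBINATIONS,
    cross_validate,
    fit_snr,
    run_combinations,
)
from leafpheno.synth import generate_regression_dataset

df = generate_regression_dataset("B", (4.57, 1.12), (20, 1200), 1000,
                                 noise_cv=0.05, seed=1)
fit = fit_snr(df["x"], df["y"], "B")
print(f"power-law refit of y=4.57*x^1.12 (5% noise, n=1000): "
      f"a={fit.coef[0]:.3f} b={fit.coef[1]:.3f}")

rng = np.random.default_rng(0)
n = 200
table = pd.DataFrame({
    "SCA1": rng.uniform(20, 1200, n),
    "SPA1": rng.uniform(20, 900, n),
    "SSC": rng.uniform(0.7, 0.97, n),
})
table["LAI"] = (4.57 * table["SCA1"] ** 1.12 / 1000 + 3 * table["SSC"]
                ) * (1 + rng.normal(0, 0.05, n))

print("\ntenfold CV, trait LAI (same folds for every model):")
for label, spec, feats in (
        ("SNR model B (SCA1)", {"family": "B"}, ["SCA1"]),
        ("random forest", {"family": "rf", "ntree": 300}, ["SCA1", "SSC", "SPA1"]),
        ("gradient boosting", {"family": "gbt", "iterations": 500},
         ["SCA1", "SSC", "SPA1"])):
    cv = cross_validate(table, "LAI", spec, folds=10, seed=7, features=feats)
    s = cv.summary()
    print(f"  {label:22s} ATPA={s['atpa']['mean']:6.2f}% "
          f"R2={s['r2']['mean']:.3f} MAE={s['mae']['mean']:.3f}")

print("\nM1-M7 combinations (random forest):")
res = run_combinations(table, "LAI", STANDARD_COMBINATIONS,
                       {"family": "rf", "ntree": 100}, folds=10, seed=7)
for name, cv in res.items():
    feats = "+".join(cv.model_spec["features"])
    print(f"  {name} ({feats:18s}) ATPA={cv.summary()['atpa']['mean']:6.2f}%")
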