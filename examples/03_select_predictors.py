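"""Rank image traits against a leaf parameter and pick how many to keep.

Builds a small feature table from synthetic scenes, ranks the 92 traits by
|Pearson r| against leaf fresh weight, and selects the predictor count by
the one-standard-error rule on the cross-validated MAE curve.  The top-ranked
traits should be the area-like side-view features, mirroring the strong
CA1/PA1/SC correlations the field study reports.
"""

import warnings

from leafpheno.features import catalog_names
from leafpheno.pipeline import PipelineConfig, build_feature_table
from leafpheno.select import choose_k_by_cv, correlation_rank

cfg = PipelineConfig(n_plants=4, sampling_days=tuple(range(14, 98, 12)),
                     width_px=128, height_px=128, seed=2)
with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    table, _ = build_feature_table(cfg)
    ranked = correlation_rank(table, "LFW", features=catalog_names())

print("top 6 traits by |Pearson r| vs LFW:")
for name, r in zip(ranked.names[:6], ranked.scores[:6]):
    print(f"  {name:7s} r={r:+.3f}  p={ranked.extra['p_value'][name]:.2e}")

k, selected, curve = choose_k_by_cv(ranked, table, "LFW", folds=5, seed=0,
                                    max_k=10)
print(f"\n1-SE rule keeps k={k}: {', '.join(selected)}")
print(curve.head(6).to_string(index=False))
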