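"""End-to-end orchestration: simulate -> segment -> extract -> select ->
fit -> growth, with one global seed fanned out into named per-stage
substreams so every stage is independently reproducible.

``run_pipeline`` returns a manifest (plain dict, JSON-serialisable) that
records every stage's parameters and metrics; re-running with the same
config reproduces the manifest bit-identically.
"""

from __future__ import annotations

import dataclasses
import logging
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import features as feat
from . import regress, select, synth
from .segment import evaluate_pair, segment

__all__ = ["PipelineConfig", "StageError", "run_pipeline", "build_feature_table"]

log = logging.getLogger("leafpheno")

_STAGES = ("simulate", "segment", "extract", "select", "fit", "growth")
TRAITS = ("LN", "LFW", "LAI")


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass(frozen=True)
class PipelineConfig:
    """Declarative configuration of the demo pipeline.

    Serialisable round-trip: ``from_dict(to_dict(c)) == c``.
    """

    n_plants: int = 20
    sampling_days: tuple = tuple(range(14, 98, 7))   # 12 weekly dates
    width_px: int = 256
    height_px: int = 256
    frame_width_cm: float = 64.0
    scene: dict = field(default_factory=dict)        # SceneConfig overrides
    segment_method: str = "reference"                # reference | ground_truth
    folds: int = 10
    model: dict = field(default_factory=lambda: {"family": "rf", "ntree": 300})
    k_rule: str = "1se"
    max_k: int = 12
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "sampling_days",
                           tuple(float(d) for d in self.sampling_days))
        if self.segment_method not in ("reference", "ground_truth"):
            raise ValueError(f"unknown segment_method {self.segment_method!r}")

    def scene_config(self) -> synth.SceneConfig:
        return synth.SceneConfig(width_px=self.width_px,
                                 height_px=self.height_px,
                                 frame_width_cm=self.frame_width_cm,
                                 **self.scene)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["sampling_days"] = list(d["sampling_days"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "sampling_days" in d:
            d["sampling_days"] = tuple(d["sampling_days"])
        return cls(**d)

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def load(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def _substream(seed: int, stage: str) -> int:
    """A stable, independent integer seed per named stage (< 2**31)."""
    idx = _STAGES.index(stage)
    state = np.random.SeedSequence([int(seed), idx]).generate_state(1)[0]
    return int(state % (2**31 - 1))


def build_feature_table(config: PipelineConfig):
    """Stages simulate+segment+extract: one feature row per plant per date.

    Returns ``(table, segmentation_scores)`` where the table holds the
    92-trait catalog plus plant_id, day and the true LN/LFW/LAI, and the
    scores are per-view IOU/PA/Recall of the configured segmenter against
    ground truth.
    """
    scene_cfg = config.scene_config()
    sim_seed = _substream(config.seed, "simulate")
    plant_seeds = [int(s % (2**31 - 1)) for s in
                   np.random.SeedSequence(sim_seed)
                   .generate_state(config.n_plants)]
    rows, scores = [], []
    for plant_id, pseed in enumerate(plant_seeds):
        for day in config.sampling_days:
            scene = synth.generate_scene(scene_cfg, day, pseed)
            calib = feat.calibrate_scale(scene.plate_mask,
                                         scene_cfg.plate_diameter_cm)
            views = synth.render_all_views(scene)
            top_vec, side_vecs = None, []
            for name, rgb, truth in views:
                if config.segment_method == "reference":
                    pred = segment(rgb)
                else:
                    pred = truth
                scores.append({"plant_id": plant_id, "day": day, "view": name,
                               **evaluate_pair(pred, truth)})
                prefix = "T" if name == "top" else "S"
                vec = feat.extract_view(rgb, pred, calib, prefix)
                if prefix == "T":
                    top_vec = vec
                else:
                    side_vecs.append(vec)
            agg = feat.aggregate_views(top_vec, side_vecs)
            row = {"plant_id": plant_id, "day": day,
                   "LN": scene.true_LN, "LFW": scene.true_LFW,
                   "LAI": scene.true_LAI}
            row.update(agg.to_dict())
            rows.append(row)
    return pd.DataFrame(rows), pd.DataFrame(scores)


def run_pipeline(config: PipelineConfig, outdir=None) -> dict:
    """Run all six stages; returns the manifest.

    Any stage failure raises ``StageError`` naming the stage.  If ``outdir``
    is given, the feature table and manifest are written there.
    """
    manifest = {"config": config.to_dict(), "stages": []}
    t_start = time.perf_counter()

    def record(stage, **info):
        log.info("stage %s done in %.1fs", stage,
                 time.perf_counter() - t_start)
        manifest["stages"].append({"stage": stage, **info})

    try:
        table, seg_scores = build_feature_table(config)
    except Exception as err:
        raise StageError(f"stage 'simulate/segment/extract' failed: {err}") from err
    record("simulate", n_scenes=int(config.n_plants * len(config.sampling_days)),
           seed=_substream(config.seed, "simulate"))
    record("segment", method=config.segment_method,
           mean_iou=float(seg_scores["iou"].mean()),
           mean_pa=float(seg_scores["pa"].mean()),
           mean_recall=float(seg_scores["recall"].mean()))
    record("extract", n_rows=int(len(table)),
           n_features=len(feat.catalog_names()))

    feature_names = feat.catalog_names()
    sel_seed = _substream(config.seed, "select")
    selected, sel_info = {}, {}
    try:
        for trait in TRAITS:
            ranked = select.correlation_rank(table, trait,
                                             features=feature_names)
            k, names, _curve = select.choose_k_by_cv(
                ranked, table, trait, folds=config.folds, seed=sel_seed,
                rule=config.k_rule, max_k=config.max_k)
            selected[trait] = names
            sel_info[trait] = {"k": k, "selected": names,
                               "top_r": float(ranked.scores[0])}
    except Exception as err:
        raise StageError(f"stage 'select' failed: {err}") from err
    record("select", rule=config.k_rule, seed=sel_seed, per_trait=sel_info)

    fit_seed = _substream(config.seed, "fit")
    cv_results, fit_info = {}, {}
    try:
        for trait in TRAITS:
            cv = regress.cross_validate(table, trait, dict(config.model),
                                        folds=config.folds, seed=fit_seed,
                                        features=selected[trait])
            cv_results[trait] = cv
            fit_info[trait] = cv.summary()
    except Exception as err:
        raise StageError(f"stage 'fit' failed: {err}") from err
    record("fit", model=dict(config.model), folds=config.folds,
           seed=fit_seed, per_trait=fit_info)

    growth_info = {}
    try:
        from .growth import fit_logistic

        for trait in TRAITS:
            cv = cv_results[trait]
            joined = cv.predictions.copy()
            joined["day"] = table["day"].to_numpy()[joined["row"].to_numpy()]
            series = joined.groupby("day")["y_pred"].mean()
            gfit = fit_logistic(series.index.to_numpy(), series.to_numpy())
            growth_info[trait] = {"L": gfit.L, "k": gfit.k, "t0": gfit.t0,
                                  "r2": gfit.r2}
    except Exception as err:
        raise StageError(f"stage 'growth' failed: {err}") from err
    record("growth", per_trait=growth_info)

    if outdir is not None:
        from pathlib import Path

        from .io import write_features, write_json

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_features(outdir / "features.csv", table)
        write_json(outdir / "manifest.json", manifest)
    return manifest
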