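"""Synthetic soybean scenes with known ground truth.

A single-plant imaging rig is emulated at desk scale: each plant is a set of
elliptical leaves arranged around a vertical axis, photographed as one top
view and six side views (60 degree steps), next to a circular white reference
plate of known physical diameter that fixes the cm-per-pixel scale.  The three
target traits -- leaf number (LN), leaf fresh weight (LFW, g) and leaf-area
ratio (LAI) -- are generated with known values so every downstream stage
(segmentation, trait extraction, predictor selection, regression, growth-curve
fitting) can be tested against ground truth.

Trait model
-----------
LN and total leaf area follow logistic curves in days after sowing,
``L / (1 + exp(-k (t - t0)))``.  LFW is allometric in total leaf area,
``LFW = c * area**d`` with lognormal noise, so feature--trait relations are
power-law-like.  LAI is total leaf area divided by the floor (pot) area.
Every scene keeps at least one leaf, so the realised leaf-count mean is
``mu + exp(-mu)`` where ``mu`` is the logistic value (the correction is
negligible except within the first days after sowing).

All randomness flows through ``numpy.random.default_rng`` seeded from the
caller's integers; every output is bit-reproducible for a fixed seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Logistic",
    "Leaf",
    "SceneConfig",
    "PlantScene",
    "logistic",
    "generate_scene",
    "render_view",
    "rasterize_leaf",
    "rasterize_leaves",
    "generate_regression_dataset",
    "generate_growth_series",
    "SIDE_ANGLES",
]

SIDE_ANGLES = (0.0, 60.0, 120.0, 180.0, 240.0, 300.0)

# Rendering palette.  Plant pixels must be strictly green-dominant
# (2G - R - B > 0) and background/plate pixels must not be, including the
# per-pixel noise; the bounds below guarantee that by construction.
_BG_COLOR = (118, 112, 120)     # 2G-R-B = -14, noise range +-3 keeps it < 0
_PLATE_COLOR = (250, 243, 249)  # 2G-R-B = -13, stays < 0 under +-3 noise
_PLANT_COLOR = (55, 150, 60)    # 2G-R-B = +185, stays > 0 under +-20 noise
_BG_NOISE = 3
_PLANT_NOISE = 20


def logistic(t, L, k, t0):
    """Three-parameter logistic ``L / (1 + exp(-k (t - t0)))``."""
    t = np.asarray(t, dtype=float)
    return L / (1.0 + np.exp(-k * (t - t0)))


@dataclass(frozen=True)
class Logistic:
    """Logistic growth-curve parameters: asymptote, rate (1/day), inflection day."""

    L: float
    k: float
    t0: float

    def __call__(self, t):
        return logistic(t, self.L, self.k, self.t0)


def _cosd(deg):
    """Cosine of degrees, exact at multiples of 90.

    Exactness at the cardinal angles makes mirrored scene geometry (and hence
    the rasterised masks) bit-identical under a 180 degree view change, which
    the symmetry tests rely on.
    """
    deg = np.asarray(deg, dtype=float)
    out = np.cos(np.deg2rad(deg))
    rem = np.mod(deg, 360.0)
    out = np.where(rem == 0.0, 1.0, out)
    out = np.where(rem == 180.0, -1.0, out)
    out = np.where((rem == 90.0) | (rem == 270.0), 0.0, out)
    return out


def _sind(deg):
    return _cosd(np.asarray(deg, dtype=float) - 90.0)


@dataclass(frozen=True)
class Leaf:
    """One leaf: an axis-aligned ellipse positioned around the stem.

    azimuth_deg : compass direction of the leaf from the stem axis
    radius_cm   : horizontal distance of the leaf centre from the stem
    rel_height  : leaf attachment height as a fraction of plant height
    area_cm2    : one-sided leaf blade area (pi * semi_major * semi_minor)
    aspect      : semi-major / semi-minor axis ratio
    """

    azimuth_deg: float
    radius_cm: float
    rel_height: float
    area_cm2: float
    aspect: float

    @property
    def semi_major_cm(self) -> float:
        return float(np.sqrt(self.area_cm2 * self.aspect / np.pi))

    @property
    def semi_minor_cm(self) -> float:
        return self.semi_major_cm / self.aspect


@dataclass(frozen=True)
class SceneConfig:
    """Study conditions for the synthetic plant generator.

    The frame spans ``frame_width_cm`` horizontally; pixels are square, so the
    physical scale is ``frame_width_cm / width_px`` cm per pixel.  The white
    reference plate (default 30 cm diameter, as on the imaging turntable)
    must fit inside the frame.
    """

    width_px: int = 512
    height_px: int = 512
    frame_width_cm: float = 64.0
    plate_diameter_cm: float = 30.0
    ln_curve: Logistic = field(default_factory=lambda: Logistic(30.0, 0.15, 40.0))
    area_curve: Logistic = field(default_factory=lambda: Logistic(1500.0, 0.12, 45.0))
    lfw_c: float = 0.02
    lfw_d: float = 1.05
    lfw_cv: float = 0.08
    floor_area_cm2: float = 490.9   # 25 cm diameter pot
    trait_cv: float = 0.10
    leaf_area_cv: float = 0.35
    aspect_range: tuple = (1.4, 2.2)
    radius_frac_range: tuple = (0.15, 0.55)
    rel_height_range: tuple = (0.15, 0.95)
    height_per_sqrt_area: float = 1.1
    seed: int = 0

    def __post_init__(self):
        if self.width_px <= 0 or self.height_px <= 0:
            raise ValueError("image dimensions must be positive")
        if self.frame_width_cm <= 0 or self.plate_diameter_cm <= 0:
            raise ValueError("physical dimensions must be positive")
        if self.plate_diameter_cm >= min(self.frame_width_cm, self.frame_height_cm):
            raise ValueError("reference plate does not fit inside the frame")

    @property
    def cm_per_px(self) -> float:
        return self.frame_width_cm / self.width_px

    @property
    def frame_height_cm(self) -> float:
        return self.height_px * self.frame_width_cm / self.width_px

    def replace(self, **kw) -> "SceneConfig":
        return dataclasses.replace(self, **kw)


@dataclass(frozen=True)
class PlantScene:
    """A generated plant with its ground truth.

    ``plant_mask`` is the top-view mask and equals, bit-exactly, the union of
    the per-leaf rasters (``rasterize_leaves``); ``leaf_shapes`` carries a
    polygonal (64-gon) outline of each leaf ellipse for serialisation.
    """

    config: SceneConfig
    leaves: tuple
    leaf_shapes: tuple
    plant_mask: np.ndarray
    plate_mask: np.ndarray
    true_LN: int
    true_LFW: float
    true_LAI: float
    day: float
    seed: int
    plant_height_cm: float

    @property
    def cm_per_px(self) -> float:
        return self.config.cm_per_px


def _ellipse_mask(shape, cy, cx, ry, rx):
    """Pixels whose centre lies inside the axis-aligned ellipse.

    The inclusion test squares the signed offsets, so it is exactly symmetric
    under mirroring of the geometry (IEEE negation and squaring are exact).
    """
    h, w = shape
    rows = np.arange(h, dtype=float)[:, None] + 0.5
    cols = np.arange(w, dtype=float)[None, :] + 0.5
    return ((cols - cx) / rx) ** 2 + ((rows - cy) / ry) ** 2 <= 1.0


def rasterize_leaf(shape, cy, cx, ry, rx) -> np.ndarray:
    """Rasterise one leaf ellipse (pixel units) to a boolean mask."""
    return _ellipse_mask(shape, cy, cx, ry, rx)


def _top_geometry(config: SceneConfig, leaf: Leaf):
    s = config.cm_per_px
    cx = config.width_px / 2.0 + leaf.radius_cm * float(_cosd(leaf.azimuth_deg)) / s
    cy = config.height_px / 2.0 + leaf.radius_cm * float(_sind(leaf.azimuth_deg)) / s
    return cy, cx, leaf.semi_minor_cm / s, leaf.semi_major_cm / s


def _side_geometry(config: SceneConfig, leaf: Leaf, plant_height_cm: float,
                   angle_deg: float):
    s = config.cm_per_px
    base_row = 0.92 * config.height_px
    u = leaf.radius_cm * float(_cosd(leaf.azimuth_deg - angle_deg))
    cx = config.width_px / 2.0 + u / s
    cy = base_row - leaf.rel_height * plant_height_cm / s
    return cy, cx, leaf.semi_minor_cm / s, leaf.semi_major_cm / s


def rasterize_leaves(scene: PlantScene, view: str = "top",
                     angle: float = 0.0) -> np.ndarray:
    """Union of per-leaf rasters for a view; the canonical mask definition."""
    shape = (scene.config.height_px, scene.config.width_px)
    mask = np.zeros(shape, dtype=bool)
    for leaf in scene.leaves:
        if view == "top":
            geom = _top_geometry(scene.config, leaf)
        else:
            geom = _side_geometry(scene.config, leaf, scene.plant_height_cm, angle)
        mask |= rasterize_leaf(shape, *geom)
    return mask


def _leaf_polygon(cy, cx, ry, rx, n_vertices=64):
    t = np.linspace(0.0, 2.0 * np.pi, n_vertices, endpoint=False)
    return np.column_stack([cx + rx * np.cos(t), cy + ry * np.sin(t)])


def _disc_mask(shape, cy, cx, r):
    return _ellipse_mask(shape, cy, cx, r, r)


def generate_scene(config: SceneConfig, day: float, seed: int) -> PlantScene:
    """Generate one plant scene at ``day`` days after sowing.

    Deterministic for fixed ``(config, day, seed)``.  Raises ``ValueError``
    if a requested leaf cannot be placed fully inside the frame (no silent
    clipping).
    """
    if day < 0:
        raise ValueError("day must be nonnegative")
    rng = np.random.default_rng([int(seed), int(round(day * 1000)), config.seed])

    mu = float(config.ln_curve(day))
    n_leaves = max(1, int(rng.poisson(mu)))

    sigma = config.trait_cv
    area_total = float(config.area_curve(day)) * float(
        np.exp(rng.normal(-0.5 * sigma**2, sigma))
    )
    area_total = max(area_total, 1.0)

    weights = rng.lognormal(0.0, config.leaf_area_cv, n_leaves)
    leaf_areas = area_total * weights / weights.sum()
    aspects = rng.uniform(*config.aspect_range, n_leaves)
    azimuths = rng.uniform(0.0, 360.0, n_leaves)
    canopy_radius = float(np.sqrt(area_total / np.pi))
    radii = rng.uniform(*config.radius_frac_range, n_leaves) * canopy_radius
    rel_heights = rng.uniform(*config.rel_height_range, n_leaves)
    plant_height_cm = max(5.0, config.height_per_sqrt_area * np.sqrt(area_total))

    leaves = tuple(
        Leaf(float(az), float(r), float(z), float(a), float(asp))
        for az, r, z, a, asp in zip(azimuths, radii, rel_heights, leaf_areas, aspects)
    )

    half_w = config.frame_width_cm / 2.0
    margin = 2.0 * config.cm_per_px
    base_cm = 0.92 * config.frame_height_cm
    for leaf in leaves:
        extent = leaf.radius_cm + leaf.semi_major_cm
        if extent > half_w - margin:
            raise ValueError(
                f"frame too small: leaf extends {extent:.1f} cm from axis, "
                f"half-frame is {half_w:.1f} cm"
            )
        top_cm = base_cm - leaf.rel_height * plant_height_cm - leaf.semi_minor_cm
        if top_cm < margin:
            raise ValueError("frame too small: plant taller than the frame")

    shape = (config.height_px, config.width_px)
    plant_mask = np.zeros(shape, dtype=bool)
    shapes = []
    for leaf in leaves:
        geom = _top_geometry(config, leaf)
        plant_mask |= rasterize_leaf(shape, *geom)
        shapes.append(_leaf_polygon(*geom))

    plate_r_px = config.plate_diameter_cm / 2.0 / config.cm_per_px
    plate_mask = _disc_mask(shape, config.height_px / 2.0,
                            config.width_px / 2.0, plate_r_px)

    lfw = config.lfw_c * area_total**config.lfw_d * float(
        np.exp(rng.normal(-0.5 * config.lfw_cv**2, config.lfw_cv))
    )
    lai = area_total / config.floor_area_cm2

    return PlantScene(
        config=config,
        leaves=leaves,
        leaf_shapes=tuple(shapes),
        plant_mask=plant_mask,
        plate_mask=plate_mask,
        true_LN=n_leaves,
        true_LFW=float(lfw),
        true_LAI=float(lai),
        day=float(day),
        seed=int(seed),
        plant_height_cm=float(plant_height_cm),
    )


def _paint(rgb, mask, base, amplitude, rng):
    n = int(mask.sum())
    if n == 0:
        return
    for ch in range(3):
        noise = rng.integers(-amplitude, amplitude + 1, n)
        rgb[..., ch][mask] = np.clip(base[ch] + noise, 0, 255).astype(np.uint8)


def render_view(scene: PlantScene, view: str, angle: float = 0.0):
    """Render one view of a scene; returns ``(rgb_uint8, ground_truth_mask)``.

    Plant pixels are strictly green-dominant (2G - R - B > 0); plate and
    background pixels are not, which is the contract the reference excess-green
    segmenter relies on.
    """
    if view not in ("top", "side"):
        raise ValueError(f"unknown view {view!r}")
    if not (0.0 <= angle < 360.0):
        raise ValueError("angle must be in [0, 360)")
    config = scene.config
    shape = (config.height_px, config.width_px)
    rng = np.random.default_rng(
        [scene.seed, int(round(scene.day * 1000)),
         0 if view == "top" else 1, int(round(angle * 16))]
    )

    rgb = np.empty(shape + (3,), dtype=np.uint8)
    bg = np.ones(shape, dtype=bool)
    _paint(rgb, bg, _BG_COLOR, _BG_NOISE, rng)

    if view == "top":
        plate = scene.plate_mask
        mask = scene.plant_mask
    else:
        plate_r_px = config.plate_diameter_cm / 2.0 / config.cm_per_px
        plate = _ellipse_mask(shape, 0.95 * config.height_px,
                              config.width_px / 2.0, 4.0, plate_r_px)
        mask = rasterize_leaves(scene, "side", angle)

    _paint(rgb, plate & ~mask, _PLATE_COLOR, _BG_NOISE, rng)
    _paint(rgb, mask, _PLANT_COLOR, _PLANT_NOISE, rng)
    return rgb, mask


def render_all_views(scene: PlantScene):
    """Top view plus the six 60-degree side views, as (name, rgb, mask)."""
    out = [("top", *render_view(scene, "top"))]
    for ang in SIDE_ANGLES:
        out.append((f"side{int(ang):03d}", *render_view(scene, "side", ang)))
    return out


def snr_curve(model_type: str, coef, x):
    """Evaluate a simple nonlinear regression curve.

    Model A is the quadratic ``y = a + b x + c x**2``; model B the power law
    ``y = a x**b``.
    """
    x = np.asarray(x, dtype=float)
    if model_type == "A":
        a, b, c = coef
        return a + b * x + c * x**2
    if model_type == "B":
        a, b = coef
        if np.any(x <= 0):
            raise ValueError("model B requires strictly positive x")
        return a * np.power(x, b)
    raise ValueError(f"unknown model type {model_type!r}")


def generate_regression_dataset(model_type: str, coef, x_range, n: int,
                                noise_cv: float, seed: int) -> pd.DataFrame:
    """Sample ``(x, y)`` pairs from an SNR curve with multiplicative noise.

    ``y = f(x) * (1 + eps)`` with ``eps ~ Normal(0, noise_cv)`` independently
    per row.  Model B requires a strictly positive ``x_range``.
    """
    if noise_cv < 0:
        raise ValueError("noise_cv must be nonnegative")
    lo, hi = float(x_range[0]), float(x_range[1])
    if model_type == "B" and lo <= 0:
        raise ValueError("model B requires a strictly positive x_range")
    rng = np.random.default_rng(seed)
    x = rng.uniform(lo, hi, int(n))
    y = snr_curve(model_type, coef, x)
    if noise_cv > 0:
        y = y * (1.0 + rng.normal(0.0, noise_cv, int(n)))
    return pd.DataFrame({"x": x, "y": y})


def generate_growth_series(L: float, k: float, t0: float, sampling_days,
                           noise_cv: float = 0.0, seed: int = 0) -> pd.DataFrame:
    """Logistic trait time series with multiplicative Gaussian noise."""
    days = np.asarray(sampling_days, dtype=float)
    if days.ndim != 1 or np.any(np.diff(days) < 0):
        raise ValueError("sampling_days must be ascending")
    y = logistic(days, L, k, t0)
    if noise_cv > 0:
        rng = np.random.default_rng(seed)
        y = y * (1.0 + rng.normal(0.0, noise_cv, days.size))
    return pd.DataFrame({"day": days, "value": y})
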