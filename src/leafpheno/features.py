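"""Image trait catalog: morphology from masks, colour from masked RGB,
texture from grayscale, physical scale calibration, and multi-view
aggregation.

The default catalog holds 92 named traits split across the two view prefixes
(``T`` = top view, ``S`` = side view): 39 top + 53 side, which by category is
46 morphological + 12 colour + 34 texture.  The side view carries the extra
height-dependent morphology (fractional-height widths, centroid height), since
plants grow upward and the side silhouette encodes stature.

Trait semantics for the named members referenced throughout the pipeline:

* ``PA1`` projected plant area (plant-pixel count, cm^2)
* ``CA1`` convex-hull area of the plant region (cm^2); the hull is taken over
  the corners of occupied pixel unit squares, so single pixels and collinear
  masks still have positive hull area
* ``SC``  compactness (solidity), PA1 / CA1
* ``MW2_5`` horizontal plant extent at two fifths of plant height, measured
  bottom-up (the "2/5 MW" predictor)

Every registry entry records a formula string so a substitute definition is a
data change, not a code change.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import ConvexHull
from scipy.stats import skew
from skimage.measure import label as sk_label
from skimage.measure import regionprops

__all__ = [
    "ScaleCalibration",
    "FeatureDef",
    "REGISTRY",
    "catalog_names",
    "calibrate_scale",
    "extract_morphological",
    "extract_color",
    "extract_texture",
    "extract_view",
    "aggregate_views",
    "hull_of_mask",
    "exposed_edge_count",
    "masked_glcm",
]


@dataclass(frozen=True)
class ScaleCalibration:
    """Physical scale of an image in cm per pixel."""

    cm_per_px: float
    source: str = "manual"

    def __post_init__(self):
        if not self.cm_per_px > 0:
            raise ValueError("cm_per_px must be positive")


@dataclass(frozen=True)
class FeatureDef:
    code: str
    category: str   # morphological | color | texture
    unit: str       # cm2 | cm | 1
    formula: str
    views: tuple    # view prefixes the default catalog uses this code in


_MORPH_DEFS = [
    ("PA1", "cm2", "plant pixel count * s^2", ("T", "S")),
    ("PA2", "cm2", "largest connected component area * s^2", ("T", "S")),
    ("A2R", "1", "PA2 / PA1", ("S",)),
    ("CA1", "cm2", "convex hull area of pixel unit squares * s^2", ("T", "S")),
    ("CA2", "cm2", "convex hull area of largest component * s^2", ("S",)),
    ("SC", "1", "PA1 / CA1 (solidity)", ("T", "S")),
    ("SC2", "1", "PA2 / CA2", ("S",)),
    ("H", "cm", "bounding box height * s", ("T", "S")),
    ("W", "cm", "bounding box width * s", ("T", "S")),
    ("AR", "1", "W / H", ("T", "S")),
    ("BBA", "cm2", "bounding box area * s^2", ("T", "S")),
    ("EXT", "1", "PA1 / BBA (extent)", ("T", "S")),
    ("P", "cm", "exposed pixel-edge count * s", ("T", "S")),
    ("CP", "cm", "convex hull perimeter * s", ("T", "S")),
    ("RND", "1", "4 pi PA1 / P^2 (roundness)", ("T", "S")),
    ("ECC", "1", "region eccentricity", ("T", "S")),
    ("MAL", "cm", "major axis length * s", ("S",)),
    ("MIL", "cm", "minor axis length * s", ("S",)),
    ("ELO", "1", "MAL / MIL (elongation)", ("S",)),
    ("ORI", "1", "region orientation (rad)", ("S",)),
    ("ED", "cm", "equivalent disc diameter * s", ("T", "S")),
    ("FAR", "1", "PA1 / hole-filled area", ("T", "S")),
    ("NCC", "1", "number of connected components", ("T", "S")),
    ("CHR", "1", "centroid height above base / plant height", ("S",)),
    ("MWX", "cm", "maximum row width * s", ("S",)),
    ("MW1_5", "cm", "row width at 1/5 plant height (bottom-up) * s", ("S",)),
    ("MW2_5", "cm", "row width at 2/5 plant height (bottom-up) * s", ("S",)),
    ("MW3_5", "cm", "row width at 3/5 plant height (bottom-up) * s", ("S",)),
    ("MW4_5", "cm", "row width at 4/5 plant height (bottom-up) * s", ("S",)),
    ("HWR", "1", "height of widest row / plant height", ("S",)),
]

_COLOR_DEFS = [
    ("RM", "1", "mean R over plant pixels", ("T", "S")),
    ("GM", "1", "mean G over plant pixels", ("T", "S")),
    ("BM", "1", "mean B over plant pixels", ("T", "S")),
    ("RS", "1", "sd of R over plant pixels", ()),
    ("GS", "1", "sd of G over plant pixels", ()),
    ("BS", "1", "sd of B over plant pixels", ()),
    ("RN", "1", "mean of R/(R+G+B) over plant pixels", ()),
    ("GN", "1", "mean of G/(R+G+B) over plant pixels", ()),
    ("BN", "1", "mean of B/(R+G+B) over plant pixels", ()),
    ("NGR", "1", "(GM-RM)/(GM+RM)", ("T", "S")),
    ("NGB", "1", "(GM-BM)/(GM+BM)", ("T", "S")),
    ("NRB", "1", "(RM-BM)/(RM+BM)", ("T", "S")),
]

_TEXTURE_DEFS = [
    ("CON", "1", "GLCM contrast, mean over 4 angles", ("T", "S")),
    ("DIS", "1", "GLCM dissimilarity, mean over 4 angles", ("T", "S")),
    ("HOM", "1", "GLCM homogeneity, mean over 4 angles", ("T", "S")),
    ("ENE", "1", "GLCM angular second moment, mean over 4 angles", ("T", "S")),
    ("COR", "1", "GLCM correlation, mean over 4 angles", ("T", "S")),
    ("ENT", "1", "GLCM entropy (bits), mean over 4 angles", ("T", "S")),
    ("CONR", "1", "GLCM contrast, range over 4 angles", ("T", "S")),
    ("DISR", "1", "GLCM dissimilarity, range over 4 angles", ("T", "S")),
    ("HOMR", "1", "GLCM homogeneity, range over 4 angles", ("T", "S")),
    ("ENER", "1", "GLCM ASM, range over 4 angles", ("T", "S")),
    ("CORR", "1", "GLCM correlation, range over 4 angles", ("T", "S")),
    ("ENTR", "1", "GLCM entropy, range over 4 angles", ("T", "S")),
    ("FOM", "1", "first-order mean gray level", ("T", "S")),
    ("FOSD", "1", "first-order gray sd", ("T", "S")),
    ("FOSK", "1", "first-order gray skewness", ("T", "S")),
    ("FOSM", "1", "smoothness 1 - 1/(1 + var/255^2)", ("T", "S")),
    ("FOE", "1", "first-order entropy over 32 gray bins (bits)", ("T", "S")),
]

REGISTRY = {
    code: FeatureDef(code, cat, unit, formula, views)
    for cat, defs in (
        ("morphological", _MORPH_DEFS),
        ("color", _COLOR_DEFS),
        ("texture", _TEXTURE_DEFS),
    )
    for code, unit, formula, views in defs
}


def catalog_names() -> list:
    """The default 92-name trait catalog (39 T-prefixed + 53 S-prefixed)."""
    names = []
    for prefix in ("T", "S"):
        for defs in (_MORPH_DEFS, _COLOR_DEFS, _TEXTURE_DEFS):
            for code, _unit, _formula, views in defs:
                if prefix in views:
                    names.append(prefix + code)
    return names


def _as_mask(mask) -> np.ndarray:
    mask = np.asarray(mask).astype(bool)
    if mask.ndim != 2:
        raise ValueError("mask must be 2-D")
    return mask


def _require_nonempty(mask):
    if not mask.any():
        raise ValueError("empty mask: no plant pixels")


def calibrate_scale(plate_mask, plate_diameter_cm: float = 30.0) -> ScaleCalibration:
    """Physical scale from the circular white reference plate.

    The measured pixel diameter is the mean of the bounding-box width and
    height of the single plate component.
    """
    mask = _as_mask(plate_mask)
    _require_nonempty(mask)
    labels, n = sk_label(mask, return_num=True)
    if n != 1:
        raise ValueError(f"plate mask must be one connected component, found {n}")
    rows = np.any(mask, axis=1).nonzero()[0]
    cols = np.any(mask, axis=0).nonzero()[0]
    diam_px = 0.5 * ((rows[-1] - rows[0] + 1) + (cols[-1] - cols[0] + 1))
    return ScaleCalibration(plate_diameter_cm / diam_px, source="plate")


def _boundary_corners(mask) -> np.ndarray:
    """Unit-square corner points (x, y) of the region's boundary pixels."""
    interior = ndimage.binary_erosion(mask, structure=np.array(
        [[0, 1, 0], [1, 1, 1], [0, 1, 0]]), border_value=0)
    rows, cols = np.nonzero(mask & ~interior)
    x = np.concatenate([cols, cols + 1, cols, cols + 1]).astype(float)
    y = np.concatenate([rows, rows, rows + 1, rows + 1]).astype(float)
    return np.unique(np.column_stack([x, y]), axis=0)


def hull_of_mask(mask):
    """Convex hull over occupied-pixel unit squares: (area_px2, perimeter_px).

    Taking unit-square corners (not pixel centres) keeps single-pixel and
    collinear masks at positive hull area (one pixel -> area 1).
    """
    mask = _as_mask(mask)
    _require_nonempty(mask)
    pts = _boundary_corners(mask)
    hull = ConvexHull(pts)
    return float(hull.volume), float(hull.area)


def exposed_edge_count(mask) -> int:
    """Crack-boundary perimeter: number of pixel edges facing background."""
    mask = _as_mask(mask)
    padded = np.pad(mask, 1)
    count = 0
    for shift in ((1, 0), (-1, 0), (0, 1), (0, -1)):
        count += int(np.sum(padded & ~np.roll(padded, shift, axis=(0, 1))))
    return count


def _row_width(mask, row, cm_per_px) -> float:
    cols = np.nonzero(mask[row])[0]
    if cols.size == 0:
        return 0.0
    return (cols[-1] - cols[0] + 1) * cm_per_px


def extract_morphological(mask, calib: ScaleCalibration, view: str) -> dict:
    """Morphological trait subset of one view's binary mask (view-prefixed)."""
    mask = _as_mask(mask)
    _require_nonempty(mask)
    s = calib.cm_per_px
    out = {}

    area_px = int(mask.sum())
    hull_area, hull_perim = hull_of_mask(mask)
    labels, ncc = sk_label(mask, return_num=True)
    sizes = np.bincount(labels.ravel())[1:]
    big = int(np.argmax(sizes)) + 1
    big_mask = labels == big
    big_area = int(sizes[big - 1])
    big_hull_area, _ = hull_of_mask(big_mask)

    rows = np.any(mask, axis=1).nonzero()[0]
    cols = np.any(mask, axis=0).nonzero()[0]
    rmin, rmax = int(rows[0]), int(rows[-1])
    h_px = rmax - rmin + 1
    w_px = int(cols[-1] - cols[0] + 1)

    props = regionprops(mask.astype(np.uint8))[0]
    perim_px = exposed_edge_count(mask)
    filled = int(ndimage.binary_fill_holes(mask).sum())
    widths_px = mask.sum(axis=1)
    widest_row = int(np.argmax(widths_px))

    out["PA1"] = area_px * s**2
    out["PA2"] = big_area * s**2
    out["A2R"] = big_area / area_px
    out["CA1"] = hull_area * s**2
    out["CA2"] = big_hull_area * s**2
    out["SC"] = area_px / hull_area
    out["SC2"] = big_area / big_hull_area
    out["H"] = h_px * s
    out["W"] = w_px * s
    out["AR"] = w_px / h_px
    out["BBA"] = h_px * w_px * s**2
    out["EXT"] = area_px / (h_px * w_px)
    out["P"] = perim_px * s
    out["CP"] = hull_perim * s
    out["RND"] = 4.0 * np.pi * area_px / perim_px**2
    out["ECC"] = float(props.eccentricity)
    out["MAL"] = float(props.axis_major_length) * s
    out["MIL"] = float(props.axis_minor_length) * s
    out["ELO"] = (out["MAL"] / out["MIL"]) if out["MIL"] > 0 else 1.0
    out["ORI"] = float(props.orientation)
    out["ED"] = 2.0 * np.sqrt(area_px / np.pi) * s
    out["FAR"] = area_px / filled
    out["NCC"] = float(ncc)
    out["CHR"] = (rmax + 0.5 - float(props.centroid[0])) / h_px
    out["MWX"] = _row_width(mask, widest_row, s)
    for frac, code in ((0.2, "MW1_5"), (0.4, "MW2_5"),
                       (0.6, "MW3_5"), (0.8, "MW4_5")):
        row = rmax - int(round(frac * (h_px - 1)))
        out[code] = _row_width(mask, row, s)
    out["HWR"] = (rmax - widest_row) / (h_px - 1) if h_px > 1 else 0.0
    return {view + k: float(v) for k, v in out.items()}


def extract_color(masked, mask, view: str) -> dict:
    """Colour trait subset over plant pixels of a masked RGB image."""
    mask = _as_mask(mask)
    _require_nonempty(mask)
    masked = np.asarray(masked)
    px = masked[mask].astype(float)           # (n, 3)
    means = px.mean(axis=0)
    sds = px.std(axis=0)
    sums = px.sum(axis=1)
    valid = sums > 0
    if valid.any():
        norm = (px[valid] / sums[valid, None]).mean(axis=0)
    else:
        norm = np.full(3, np.nan)

    def nd(a, b):
        return (a - b) / (a + b) if (a + b) != 0 else 0.0

    rm, gm, bm = means
    out = {
        "RM": rm, "GM": gm, "BM": bm,
        "RS": sds[0], "GS": sds[1], "BS": sds[2],
        "RN": norm[0], "GN": norm[1], "BN": norm[2],
        "NGR": nd(gm, rm), "NGB": nd(gm, bm), "NRB": nd(rm, bm),
    }
    return {view + k: float(v) for k, v in out.items()}


_GLCM_ANGLES = (0.0, 45.0, 90.0, 135.0)


def masked_glcm(gray, mask, levels: int = 32):
    """Normalised symmetric co-occurrence matrices over plant pixels.

    Gray values in [0, 256) are quantised into ``levels`` fixed-width bins;
    only pixel pairs where both pixels are inside the mask contribute.  One
    matrix per angle at offset 1 px: 0, 45, 90 and 135 degrees.  Raises if
    any angle has no co-occurring pair (e.g. single-pixel region).
    """
    mask = _as_mask(mask)
    _require_nonempty(mask)
    gray = np.asarray(gray, dtype=float)
    q = np.zeros(mask.shape, dtype=np.int32)
    q[mask] = np.clip((gray[mask] * levels / 256.0).astype(np.int32), 0, levels - 1) + 1

    offsets = {0.0: (0, 1), 45.0: (-1, 1), 90.0: (-1, 0), 135.0: (-1, -1)}
    mats = {}
    for ang, (dr, dc) in offsets.items():
        rs = slice(max(0, -dr), q.shape[0] - max(0, dr))
        rd = slice(max(0, dr), q.shape[0] - max(0, -dr))
        cs = slice(max(0, -dc), q.shape[1] - max(0, dc))
        cd = slice(max(0, dc), q.shape[1] - max(0, -dc))
        i = q[rs, cs].ravel()
        j = q[rd, cd].ravel()
        keep = (i > 0) & (j > 0)
        i, j = i[keep] - 1, j[keep] - 1
        mat = np.zeros((levels, levels), dtype=float)
        np.add.at(mat, (i, j), 1.0)
        mat = mat + mat.T          # symmetric
        total = mat.sum()
        if total == 0:
            raise ValueError(f"no co-occurring pixel pairs at {ang} degrees")
        mats[ang] = mat / total
    return mats


def glcm_stats(mat: np.ndarray) -> dict:
    """Contrast, dissimilarity, homogeneity, ASM, correlation, entropy."""
    levels = mat.shape[0]
    i = np.arange(levels, dtype=float)[:, None]
    j = np.arange(levels, dtype=float)[None, :]
    diff = i - j
    mu_i = float((i * mat).sum())
    mu_j = float((j * mat).sum())
    var_i = float(((i - mu_i) ** 2 * mat).sum())
    var_j = float(((j - mu_j) ** 2 * mat).sum())
    if var_i > 0 and var_j > 0:
        cor = float((((i - mu_i) * (j - mu_j) * mat).sum())
                    / np.sqrt(var_i * var_j))
    else:
        cor = 1.0
    nz = mat[mat > 0]
    return {
        "CON": float((diff**2 * mat).sum()),
        "DIS": float((np.abs(diff) * mat).sum()),
        "HOM": float((mat / (1.0 + diff**2)).sum()),
        "ENE": float((mat**2).sum()),
        "COR": cor,
        "ENT": float(-(nz * np.log2(nz)).sum()),
    }


def extract_texture(gray, mask, view: str, levels: int = 32) -> dict:
    """Texture trait subset: GLCM statistics plus first-order statistics."""
    mask = _as_mask(mask)
    _require_nonempty(mask)
    gray = np.asarray(gray, dtype=float)
    mats = masked_glcm(gray, mask, levels=levels)
    per_angle = {k: [] for k in ("CON", "DIS", "HOM", "ENE", "COR", "ENT")}
    for ang in _GLCM_ANGLES:
        stats = glcm_stats(mats[ang])
        for k, v in stats.items():
            per_angle[k].append(v)
    out = {}
    for k, vals in per_angle.items():
        out[k] = float(np.mean(vals))
        out[k + "R"] = float(np.max(vals) - np.min(vals))

    vals = gray[mask]
    var = float(np.var(vals))
    out["FOM"] = float(np.mean(vals))
    out["FOSD"] = float(np.sqrt(var))
    out["FOSK"] = float(skew(vals)) if var > 0 else 0.0
    out["FOSM"] = 1.0 - 1.0 / (1.0 + var / 255.0**2)
    hist, _ = np.histogram(vals, bins=levels, range=(0.0, 256.0))
    p = hist[hist > 0] / vals.size
    out["FOE"] = float(-(p * np.log2(p)).sum())
    return {view + k: float(v) for k, v in out.items()}


def extract_view(rgb, mask, calib: ScaleCalibration, view: str) -> dict:
    """All traits of one view: morphology, colour and texture combined."""
    from .segment import apply_mask, to_gray

    if view not in ("T", "S"):
        raise ValueError("view must be 'T' or 'S'")
    masked = apply_mask(rgb, mask)
    gray = to_gray(masked)
    out = {}
    out.update(extract_morphological(mask, calib, view))
    out.update(extract_color(masked, mask, view))
    out.update(extract_texture(gray, mask, view))
    return out


def aggregate_views(top: dict, sides) -> pd.Series:
    """One FeatureVector per plant: top values kept, side values averaged.

    ``sides`` must hold the six 60-degree side-view vectors with a common
    name set; the result is indexed by the default 92-name catalog.
    """
    sides = list(sides)
    if len(sides) != 6:
        raise ValueError(f"expected 6 side views, got {len(sides)}")
    names = set(sides[0])
    for sv in sides[1:]:
        if set(sv) != names:
            raise ValueError("side views do not share a name set")
    merged = dict(top)
    for name in names:
        merged[name] = float(np.mean([sv[name] for sv in sides]))
    cat = catalog_names()
    missing = [n for n in cat if n not in merged]
    if missing:
        raise ValueError(f"missing catalog features: {missing[:5]}...")
    return pd.Series({n: merged[n] for n in cat})
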