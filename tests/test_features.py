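"""Trait extraction: geometry oracles, scale behaviour, catalog contract."""

import numpy as np
import pytest
from shapely.geometry import box
from shapely.ops import unary_union

from leafpheno.features import (
    REGISTRY,
    ScaleCalibration,
    aggregate_views,
    calibrate_scale,
    catalog_names,
    extract_color,
    extract_morphological,
    extract_texture,
    extract_view,
    hull_of_mask,
    masked_glcm,
)

UNIT = ScaleCalibration(1.0)


def shapely_hull(mask):
    """Independent oracle: union of unit squares, then its convex hull."""
    squares = [box(c, r, c + 1, r + 1) for r, c in zip(*np.nonzero(mask))]
    hull = unary_union(squares).convex_hull
    return hull.area, hull.length


def loop_perimeter(mask):
    """Independent oracle: exposed pixel edges counted one by one."""
    h, w = mask.shape
    count = 0
    for r in range(h):
        for c in range(w):
            if not mask[r, c]:
                continue
            for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                rr, cc = r + dr, c + dc
                if not (0 <= rr < h and 0 <= cc < w) or not mask[rr, cc]:
                    count += 1
    return count


def test_calibration_examples():
    # a plate whose bounding box spans exactly 300 px
    plate = np.zeros((400, 400), bool)
    plate[50:350, 50:350] = True
    assert calibrate_scale(plate, 30.0).cm_per_px == pytest.approx(0.1)
    assert calibrate_scale(plate, 15.0).cm_per_px == pytest.approx(0.05)


def test_calibration_rasterized_disc():
    size = 2 * 110
    rr, cc = np.ogrid[:size, :size]
    disc = ((rr + 0.5 - 110) ** 2 + (cc + 0.5 - 110) ** 2) <= 100.5**2
    cal = calibrate_scale(disc, 20.1)
    measured_diam_px = 20.1 / cal.cm_per_px
    assert abs(measured_diam_px - 201) <= 1.0


def test_calibration_rejects_fragmented():
    mask = np.zeros((10, 10), bool)
    mask[1, 1] = mask[8, 8] = True
    with pytest.raises(ValueError):
        calibrate_scale(mask)
    with pytest.raises(ValueError):
        calibrate_scale(np.zeros((5, 5), bool))


def test_full_square_morphology():
    mask = np.zeros((12, 12), bool)
    mask[1:11, 1:11] = True
    f = extract_morphological(mask, UNIT, "S")
    assert f["SPA1"] == 100.0
    assert f["SCA1"] == pytest.approx(100.0)
    assert f["SSC"] == pytest.approx(1.0)
    for code in ("SMW1_5", "SMW2_5", "SMW3_5", "SMW4_5", "SMWX"):
        assert f[code] == 10.0
    assert f["SH"] == 10.0 and f["SW"] == 10.0
    assert f["SP"] == 40.0  # 4 sides x 10 exposed edges


def test_l_shape_hull():
    mask = np.zeros((4, 4), bool)
    mask[0, 0] = mask[0, 1] = mask[1, 0] = True
    f = extract_morphological(mask, UNIT, "S")
    assert f["SPA1"] == 3.0
    assert f["SCA1"] == pytest.approx(3.5)
    assert f["SSC"] == pytest.approx(6 / 7)
    area, length = shapely_hull(mask)
    assert f["SCA1"] == pytest.approx(area)


def test_geometry_against_brute_force(rng):
    """PA1 / CA1 / perimeter match independent oracles on random masks."""
    for _ in range(60):
        mask = rng.random((9, 9)) < 0.4
        if not mask.any():
            mask[4, 4] = True
        f = extract_morphological(mask, UNIT, "S")
        area, length = shapely_hull(mask)
        assert f["SPA1"] == mask.sum()
        assert f["SCA1"] == pytest.approx(area, rel=1e-9)
        assert f["SCP"] == pytest.approx(length, rel=1e-9)
        assert f["SP"] == loop_perimeter(mask)
        assert f["SSC"] <= 1.0 + 1e-12
        assert f["SCA1"] >= f["SPA1"] - 1e-12


def test_empty_mask_raises():
    with pytest.raises(ValueError, match="empty"):
        extract_morphological(np.zeros((5, 5), bool), UNIT, "S")


def test_scale_equivariance(midseason_scene):
    mask = midseason_scene.plant_mask
    f1 = extract_morphological(mask, ScaleCalibration(0.2), "S")
    f2 = extract_morphological(mask, ScaleCalibration(0.1), "S")
    for code, fdef in REGISTRY.items():
        if fdef.category != "morphological":
            continue
        a, b = f1["S" + code], f2["S" + code]
        if fdef.unit == "cm2":
            assert b == pytest.approx(a / 4, rel=1e-9)
        elif fdef.unit == "cm":
            assert b == pytest.approx(a / 2, rel=1e-9)
        else:
            assert b == pytest.approx(a, rel=1e-9)


def test_rotation_invariance(midseason_scene):
    mask = midseason_scene.plant_mask
    rot = np.rot90(mask)
    f = extract_morphological(mask, UNIT, "S")
    g = extract_morphological(rot, UNIT, "S")
    for code in ("SPA1", "SCA1", "SSC"):
        assert g[code] == pytest.approx(f[code], rel=1e-9)
    assert g["SH"] == f["SW"] and g["SW"] == f["SH"]


def test_color_features():
    mask = np.zeros((4, 4), bool)
    mask[:2] = True
    img = np.zeros((4, 4, 3), np.uint8)
    img[mask] = (100, 150, 200)
    f = extract_color(img, mask, "T")
    assert f["TRM"] == 100 and f["TGM"] == 150 and f["TBM"] == 200
    assert f["TNGR"] == pytest.approx(50 / 250)
    # invariance to background pixel values
    img2 = img.copy()
    img2[~mask] = (7, 91, 13)
    f2 = extract_color(img2, mask, "T")
    assert f == f2


def test_texture_constant_region():
    mask = np.zeros((6, 6), bool)
    mask[1:5, 1:5] = True
    gray = np.full((6, 6), 77.0)
    f = extract_texture(gray, mask, "T")
    assert f["TENE"] == pytest.approx(1.0)
    assert f["TCON"] == pytest.approx(0.0)
    assert f["TENT"] == pytest.approx(0.0)
    assert f["TFOSD"] == 0.0 and f["TFOSK"] == 0.0


def test_texture_checkerboard_contrast():
    """Two-level checkerboard: horizontal contrast is the squared bin gap."""
    n = 8
    mask = np.ones((n, n), bool)
    gray = np.zeros((n, n))
    gray[(np.add.outer(np.arange(n), np.arange(n)) % 2) == 1] = 255.0
    mats = masked_glcm(gray, mask, levels=32)
    from leafpheno.features import glcm_stats
    # levels 0 and 31: every 0-degree neighbour pair differs by 31 bins
    assert glcm_stats(mats[0.0])["CON"] == pytest.approx(31.0**2)


def test_texture_background_invariance(midseason_scene):
    mask = midseason_scene.plant_mask
    rng = np.random.default_rng(0)
    gray = rng.uniform(0, 255, mask.shape)
    f1 = extract_texture(gray, mask, "S")
    gray2 = gray.copy()
    gray2[~mask] += 31.0
    f2 = extract_texture(gray2, mask, "S")
    assert f1 == f2


def test_texture_single_pixel_fails():
    mask = np.zeros((5, 5), bool)
    mask[2, 2] = True
    with pytest.raises(ValueError):
        extract_texture(np.zeros((5, 5)), mask, "T")


def test_catalog_contract():
    names = catalog_names()
    assert len(names) == 92
    assert len([n for n in names if n.startswith("T")]) == 39
    assert len([n for n in names if n.startswith("S")]) == 53
    counts = {"morphological": 0, "color": 0, "texture": 0}
    for name in names:
        counts[REGISTRY[name[1:]].category] += 1
    assert counts == {"morphological": 46, "color": 12, "texture": 34}
    for trait in ("SCA1", "SPA1", "SSC", "TCA1", "TPA1", "TSC",
                  "SPA2", "SMW2_5"):
        assert trait in names
    # every registry entry documents its formula
    assert all(REGISTRY[n[1:]].formula for n in names)


def test_aggregate_views(midseason_scene):
    from leafpheno.synth import render_view

    calib = ScaleCalibration(0.5)
    rgb, mask = render_view(midseason_scene, "top")
    top = extract_view(rgb, mask, calib, "T")
    rgb, mask = render_view(midseason_scene, "side", 0.0)
    side = extract_view(rgb, mask, calib, "S")

    sides = [dict(side) for _ in range(6)]
    for i, sv in enumerate(sides):
        sv["SCA1"] = float(i + 1)            # 1..6 -> mean 3.5
    agg = aggregate_views(top, sides)
    assert agg["SCA1"] == pytest.approx(3.5)
    assert set(agg.index) == set(catalog_names())
    # identical sides reproduce any one of them; top survives permutation
    same = aggregate_views(top, [dict(side)] * 6)
    for k, v in side.items():
        if k in same.index:
            assert same[k] == pytest.approx(v)
    perm = aggregate_views(top, sides[::-1])
    for name in agg.index:
        if name.startswith("T"):
            assert perm[name] == agg[name]
    with pytest.raises(ValueError):
        aggregate_views(top, sides[:5])
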