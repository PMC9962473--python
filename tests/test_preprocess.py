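"""Plant extraction: averaging, differencing, Otsu, components, cropping.

Independent oracles: a second-path per-pixel mean, an exhaustive 256-level
between-class-variance search for Otsu, and a hand-coded flood fill for
connected components.
"""

import numpy as np
import pytest

from monoleaf import plantgen as pg
from monoleaf import preprocess as pre


def _rand_rgb(rng, h=24, w=24):
    return rng.integers(0, 256, size=(h, w, 3)).astype(np.uint8)


# ------------------------------------------------------------ average_background


def test_average_of_identical_images_is_identity():
    rng = np.random.default_rng(0)
    img = _rand_rgb(rng)
    assert np.array_equal(pre.average_background([img] * 50), img)


def test_average_simple_arithmetic():
    zeros = np.zeros((4, 4, 3), np.uint8)
    twos = np.full((4, 4, 3), 2, np.uint8)
    assert np.array_equal(pre.average_background([zeros, twos]), np.ones((4, 4, 3), np.uint8))


def test_average_matches_mean_oracle():
    rng = np.random.default_rng(1)
    images = [_rand_rgb(rng) for _ in range(50)]
    got = pre.average_background(images)
    oracle = np.stack([im.astype(np.float64) for im in images]).mean(axis=0)
    assert np.max(np.abs(got.astype(float) - oracle)) <= 1.0  # rounding only


def test_average_rejects_bad_input():
    with pytest.raises(ValueError):
        pre.average_background([])
    with pytest.raises(ValueError):
        pre.average_background(
            [np.zeros((4, 4, 3), np.uint8), np.zeros((5, 4, 3), np.uint8)]
        )


# ------------------------------------------------------------- difference_image


def test_difference_identity_and_arithmetic():
    rng = np.random.default_rng(2)
    img = _rand_rgb(rng)
    assert pre.difference_image(img, img).sum() == 0
    a = np.zeros((1, 1, 3), np.uint8)
    b = np.zeros((1, 1, 3), np.uint8)
    a[0, 0] = (100, 100, 100)
    b[0, 0] = (90, 110, 100)
    assert tuple(pre.difference_image(a, b)[0, 0]) == (10, 10, 0)


def test_difference_covers_plant_mask(plant_render):
    diff = pre.difference_image(plant_render.image, pg.render_background(plant_render.spec))
    gray = pre.to_gray(diff)
    assert (gray[plant_render.plant_mask] > 0).mean() >= 0.95


# --------------------------------------------------------------------- to_gray


def test_gray_constants_and_weights():
    white = np.full((3, 3, 3), 255, np.uint8)
    assert (pre.to_gray(white) == 255).all()
    for v in (0, 17, 128, 254):
        g = np.full((2, 2, 3), v, np.uint8)
        assert (pre.to_gray(g) == v).all()


def test_gray_matches_weighted_sum_oracle():
    rng = np.random.default_rng(3)
    img = _rand_rgb(rng, 32, 32)
    oracle = np.floor(
        0.299 * img[:, :, 0] + 0.587 * img[:, :, 1] + 0.114 * img[:, :, 2] + 0.5
    ).astype(np.uint8)
    assert np.array_equal(pre.to_gray(img), oracle)


# ---------------------------------------------------------------------- otsu


def _otsu_bruteforce(gray):
    """Exhaustive between-class-variance search over all 256 thresholds."""
    hist = np.bincount(gray.ravel(), minlength=256).astype(float)
    n = hist.sum()
    best_t, best_var = None, -1.0
    for t in range(256):
        w0 = hist[: t + 1].sum() / n
        w1 = 1.0 - w0
        if w0 == 0 or w1 == 0:
            continue
        mu0 = (hist[: t + 1] * np.arange(t + 1)).sum() / (w0 * n)
        mu1 = (hist[t + 1 :] * np.arange(t + 1, 256)).sum() / (w1 * n)
        var = w0 * w1 * (mu0 - mu1) ** 2
        if var > best_var + 1e-12:
            best_var, best_t = var, t
    return best_t


def test_otsu_separates_two_level_image():
    rng = np.random.default_rng(4)
    gray = np.where(rng.random((32, 32)) < 0.3, 200, 10).astype(np.uint8)
    mask, t = pre.otsu_binarize(gray, "bright")
    assert 10 <= t <= 199
    assert np.array_equal(mask == 1, gray == 200)


@pytest.mark.parametrize("seed", range(10))
def test_otsu_equals_exhaustive_search(seed):
    rng = np.random.default_rng(seed)
    gray = rng.integers(0, 256, size=(24, 24)).astype(np.uint8)
    assert pre.otsu_threshold(gray) == _otsu_bruteforce(gray)


def test_otsu_agrees_with_skimage_on_bimodal_images():
    from skimage.filters import threshold_otsu

    rng = np.random.default_rng(5)
    gray = np.clip(
        np.where(rng.random((64, 64)) < 0.4, rng.normal(60, 8, (64, 64)),
                 rng.normal(190, 8, (64, 64))),
        0, 255,
    ).astype(np.uint8)
    ours = pre.otsu_threshold(gray)
    theirs = int(threshold_otsu(gray, nbins=256))
    assert abs(ours - theirs) <= 1  # bin-center convention differs by <= 1 level


def test_otsu_polarity_symmetry():
    rng = np.random.default_rng(6)
    gray = rng.integers(0, 256, size=(16, 16)).astype(np.uint8)
    mask_bright, _ = pre.otsu_binarize(gray, "bright")
    mask_dark, _ = pre.otsu_binarize(255 - gray, "dark")
    assert np.array_equal(mask_bright, mask_dark)


def test_otsu_constant_image_errors():
    with pytest.raises(pre.ConstantImageError):
        pre.otsu_threshold(np.full((8, 8), 42, np.uint8))


# --------------------------------------------------------- connected components


def _flood_fill_components(mask, connectivity):
    """Independent labeling oracle via explicit stack-based flood fill."""
    mask = np.asarray(mask) != 0
    h, w = mask.shape
    labels = np.zeros((h, w), int)
    if connectivity == 8:
        nbrs = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
    else:
        nbrs = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    current = 0
    for r in range(h):
        for c in range(w):
            if mask[r, c] and labels[r, c] == 0:
                current += 1
                stack = [(r, c)]
                labels[r, c] = current
                while stack:
                    y, x = stack.pop()
                    for dy, dx in nbrs:
                        ny, nx = y + dy, x + dx
                        if 0 <= ny < h and 0 <= nx < w and mask[ny, nx] and labels[ny, nx] == 0:
                            labels[ny, nx] = current
                            stack.append((ny, nx))
    return labels, current


def test_components_empty_mask():
    assert len(pre.connected_components(np.zeros((5, 5), np.uint8))) == 0


def test_components_diagonal_connectivity():
    mask = np.zeros((4, 4), np.uint8)
    mask[1, 1] = mask[2, 2] = 1
    assert len(pre.connected_components(mask, connectivity=8)) == 1
    assert len(pre.connected_components(mask, connectivity=4)) == 2


@pytest.mark.parametrize("connectivity", [4, 8])
def test_components_match_flood_fill_oracle(connectivity):
    rng = np.random.default_rng(7)
    mask = (rng.random((30, 30)) < 0.4).astype(np.uint8)
    table = pre.connected_components(mask, connectivity)
    _, n_oracle = _flood_fill_components(mask, connectivity)
    assert len(table) == n_oracle
    areas = sorted(c.area_px for c in table.components)
    oracle_labels, _ = _flood_fill_components(mask, connectivity)
    oracle_areas = sorted(np.bincount(oracle_labels.ravel())[1:].tolist())
    assert areas == oracle_areas
    assert sum(areas) == int(mask.sum())


# --------------------------------------------------------- largest bbox + crop


def test_largest_bbox_half_open_convention():
    mask = np.zeros((10, 10), np.uint8)
    mask[2:5, 5:8] = 1
    box = pre.largest_component_bbox(pre.connected_components(mask))
    assert (box.row_min, box.col_min, box.row_max, box.col_max) == (2, 5, 5, 8)


def test_largest_bbox_picks_max_area():
    mask = np.zeros((20, 20), np.uint8)
    mask[0:2, 0:5] = 1  # area 10
    mask[10:15, 10:20] = 1  # area 50
    box = pre.largest_component_bbox(pre.connected_components(mask))
    assert (box.row_min, box.col_min) == (10, 10)


def test_largest_bbox_empty_errors():
    with pytest.raises(pre.NoPlantError):
        pre.largest_component_bbox(pre.connected_components(np.zeros((3, 3), np.uint8)))


def test_crop_resize_square_identity():
    rng = np.random.default_rng(8)
    img = rng.integers(0, 256, (299, 299, 3)).astype(np.uint8)
    assert np.array_equal(pre.crop_resize(img, pre.BoundingBox(0, 0, 299, 299)), img)


def test_crop_resize_pads_white():
    img = np.zeros((100, 50, 3), np.uint8)
    out = pre.crop_resize(img, pre.BoundingBox(0, 0, 100, 50), out_size=299)
    assert out.shape == (299, 299, 3)
    nonwhite_cols = np.where((out != 255).any(axis=(0, 2)))[0]
    assert 145 <= len(nonwhite_cols) <= 155  # ~150 content columns, rest padding
    assert (out[:, : nonwhite_cols[0], :] == 255).all()


def test_crop_resize_nearest_hand_case():
    tiny = np.array(
        [[[10, 10, 10], [20, 20, 20]], [[30, 30, 30], [40, 40, 40]]], np.uint8
    )
    out = pre.crop_resize(tiny, pre.BoundingBox(0, 0, 2, 2), out_size=4, interpolation="nearest")
    expected = np.array(
        [[10, 10, 20, 20], [10, 10, 20, 20], [30, 30, 40, 40], [30, 30, 40, 40]]
    )
    assert np.array_equal(out[:, :, 0], expected)


# ------------------------------------------------------------------- pipeline


def test_pipeline_output_shape(plant_render, avg_background):
    out = pre.preprocess_pipeline(plant_render.image, avg_background)
    assert out.shape == (299, 299, 3)


def test_pipeline_bbox_covers_plant(plant_render, avg_background):
    _, inter = pre.preprocess_pipeline(
        plant_render.image, avg_background, return_intermediates=True
    )
    box = inter["bbox"]
    mask = plant_render.plant_mask
    covered = mask[box.row_min : box.row_max, box.col_min : box.col_max].sum()
    assert covered / mask.sum() >= 0.99


def test_pipeline_rejects_plant_free_frame(avg_background):
    background_only = pg.render_background(pg.SyntheticPlantSpec(seed=99))
    with pytest.raises((pre.NoPlantError, pre.ConstantImageError)):
        pre.preprocess_pipeline(background_only, avg_background)


def test_pipeline_excludes_far_distractor_blob(avg_background):
    r = pg.render_plant_detailed(pg.SyntheticPlantSpec(leaf_count=4, seed=13))
    img = r.image.copy()
    # paint a ~40 px blob in the far top-right corner, away from the plant
    img[18:25, 480:486] = (95, 84, 70)
    _, inter = pre.preprocess_pipeline(img, avg_background, return_intermediates=True)
    box = inter["bbox"]
    assert not (box.row_min <= 21 < box.row_max and box.col_min <= 483 < box.col_max)


def test_pipeline_largest_area_monotone_under_plant_growth(avg_background):
    # painting extra leaf strokes onto the same frame never shrinks the
    # largest foreground component
    r = pg.render_plant_detailed(pg.SyntheticPlantSpec(leaf_count=3, seed=17))
    _, inter_small = pre.preprocess_pipeline(
        r.image, avg_background, return_intermediates=True
    )
    bigger = r.image.copy()
    extra = pg.render_plant_detailed(pg.SyntheticPlantSpec(leaf_count=6, seed=17))
    bigger[extra.plant_mask] = extra.image[extra.plant_mask]
    _, inter_big = pre.preprocess_pipeline(bigger, avg_background, return_intermediates=True)
    area_small = max(c.area_px for c in inter_small["components"].components)
    area_big = max(c.area_px for c in inter_big["components"].components)
    assert area_big >= area_small
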