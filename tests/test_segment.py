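"""Smoothing, thresholding, watershed separation and SKIZ tessellation."""

import numpy as np
import pytest
from skimage import measure as sk_measure

import tilestats as ts
from tilestats.segment import (
    BOUNDARY_LABEL,
    ObjectMask,
    binarize,
    preprocess,
    separate_touching,
    sigma_filter,
    tessellate,
)
from tilestats.simulate import FieldGeometry, GrayscaleImage

FIELD32 = FieldGeometry(32, 32, 40.0)


def _img(arr, px=40.0):
    arr = np.asarray(arr, dtype=float)
    return GrayscaleImage(
        pixels=arr, field=FieldGeometry(arr.shape[1], arr.shape[0], px)
    )


def _mask_from_binary(binary):
    labels, n = sk_measure.label(binary, connectivity=2, return_num=True)
    return ObjectMask(
        labels=labels,
        n_objects=n,
        foreground_fraction=float(binary.mean()),
        method="mean",
    )


def brute_force_skiz(labels):
    """Independent oracle: each background pixel joins the object with the
    nearest pixel (exact squared Euclidean distance); exact ties across
    different objects become the boundary sentinel."""
    out = labels.copy()
    coords = {
        l: np.argwhere(labels == l) for l in range(1, labels.max() + 1)
    }
    for y, x in np.argwhere(labels == 0):
        best, winners = None, []
        for l, c in coords.items():
            if len(c) == 0:
                continue
            d = ((c[:, 0] - y) ** 2 + (c[:, 1] - x) ** 2).min()
            if best is None or d < best:
                best, winners = d, [l]
            elif d == best:
                winners.append(l)
        out[y, x] = winners[0] if len(winners) == 1 else BOUNDARY_LABEL
    return out


# ---------------------------------------------------------------------------
# preprocessing


def test_sigma_filter_constant_image_unchanged():
    img = _img(np.full((24, 24), 7.0))
    out = preprocess(img)
    assert np.allclose(out.pixels, 7.0)


def test_sigma_filter_reduces_noise_variance():
    rng = np.random.default_rng(0)
    img = _img(100 + rng.normal(0, 5, (64, 64)))
    out = preprocess(img)
    assert out.pixels.var() < img.pixels.var()


def test_preprocess_preserves_step_edge_position():
    step = np.full((32, 32), 50.0)
    step[:, 16:] = 150.0
    out = preprocess(_img(step))
    for row in out.pixels:
        crossing = np.flatnonzero(np.diff(np.sign(row - 100.0)) != 0)
        assert len(crossing) == 1
        assert abs(crossing[0] + 0.5 - 15.5) <= 1.0


# ---------------------------------------------------------------------------
# thresholding


def test_mean_threshold_on_two_level_image():
    arr = np.zeros((32, 32))
    arr[:, 16:] = 100.0
    mask = binarize(_img(arr), method="mean")
    assert mask.foreground_fraction == 0.5
    assert mask.threshold == 50.0


def test_isodata_matches_intermeans_fixed_point():
    """skimage's isodata agrees with an independent iterative-intermeans
    fixed-point computation to within a histogram bin."""
    rng = np.random.default_rng(1)
    data = np.concatenate(
        [rng.normal(20, 4, 3000), rng.normal(120, 12, 1000)]
    ).clip(0)
    img = _img(data.reshape(50, 80))
    mask = binarize(_img(data.reshape(50, 80)), method="isodata")
    # brute-force fixed-point iteration of t = (mean_below + mean_above)/2
    t = data.mean()
    for _ in range(500):
        t_new = 0.5 * (data[data <= t].mean() + data[data > t].mean())
        if abs(t_new - t) < 1e-10:
            break
        t = t_new
    bin_width = (data.max() - data.min()) / 256
    assert abs(mask.threshold - t) <= bin_width
    assert mask.n_objects >= 1


def test_threshold_single_valued_image_errors():
    with pytest.raises(ValueError, match="single-valued"):
        binarize(_img(np.full((20, 20), 3.0)))


def test_threshold_methods_reproducible_but_may_disagree():
    rng = np.random.default_rng(2)
    img = _img(rng.gamma(2.0, 10.0, (48, 48)))
    thr = {m: binarize(img, m).threshold for m in ("isodata", "li", "mean")}
    thr2 = {m: binarize(img, m).threshold for m in ("isodata", "li", "mean")}
    assert thr == thr2


# ---------------------------------------------------------------------------
# watershed separation


def test_separation_skipped_below_fraction_threshold():
    binary = np.zeros((40, 40), bool)
    binary[5:10, 5:10] = True  # ~1.6% foreground
    mask = _mask_from_binary(binary)
    out = separate_touching(mask)
    assert out is mask


def test_overlapping_discs_separate_into_two_objects():
    yy, xx = np.mgrid[0:64, 0:64]
    binary = ((yy - 32) ** 2 + (xx - 22) ** 2 <= 14**2) | (
        (yy - 32) ** 2 + (xx - 42) ** 2 <= 14**2
    )
    mask = _mask_from_binary(binary)
    assert mask.foreground_fraction > 0.25
    assert mask.n_objects == 1
    out = separate_touching(mask)
    assert out.n_objects == 2


def test_empty_mask_passes_through():
    mask = _mask_from_binary(np.zeros((30, 30), bool))
    assert separate_touching(mask).n_objects == 0


# ---------------------------------------------------------------------------
# tessellation


def test_single_object_tile_covers_whole_image():
    binary = np.zeros((32, 32), bool)
    binary[10:13, 20:23] = True
    tiles = tessellate(_mask_from_binary(binary))
    assert tiles.n_tiles == 1
    assert np.all(tiles.tile_labels == 1)


def test_two_point_objects_give_voronoi_bisector():
    labels = np.zeros((32, 32), int)
    labels[16, 8] = 1
    labels[16, 24] = 2
    mask = ObjectMask(labels=labels, n_objects=2, foreground_fraction=2 / 1024, method="mean")
    tiles = tessellate(mask)
    t = tiles.tile_labels
    assert np.all(t[:, :16] == 1)
    assert np.all(t[:, 17:] == 2)
    assert np.all(t[:, 16] == BOUNDARY_LABEL)


def test_partition_and_containment_invariants():
    rng = np.random.default_rng(3)
    binary = rng.random((48, 48)) < 0.02
    binary[20:25, 10:18] = True
    mask = _mask_from_binary(binary)
    tiles = tessellate(mask)
    assert tiles.tiles["area_px"].sum() + tiles.n_boundary_px == 48 * 48
    # each object's pixels lie inside its own tile
    for l in range(1, mask.n_objects + 1):
        assert np.all(tiles.tile_labels[mask.labels == l] == l)


@pytest.mark.parametrize("seed", range(12))
def test_tessellation_matches_brute_force_oracle(seed):
    rng = np.random.default_rng(seed)
    shape = (int(rng.integers(20, 48)), int(rng.integers(20, 48)))
    binary = rng.random(shape) < 0.04
    if seed % 3 == 0:  # add an extended object
        y, x = rng.integers(5, shape[0] - 6), rng.integers(5, shape[1] - 6)
        binary[y : y + 4, x : x + 5] = True
    if not binary.any():
        binary[shape[0] // 2, shape[1] // 2] = True
    mask = _mask_from_binary(binary)
    tiles = tessellate(mask)
    assert np.array_equal(tiles.tile_labels, brute_force_skiz(mask.labels))


def test_skiz_respects_object_extent_vs_centroid_voronoi():
    """Tile boundaries run between object borders, so a large object's tile
    reaches beyond the centroid-Voronoi bisector and the object is never cut
    (the advantage over centroid-based tessellation)."""
    yy, xx = np.mgrid[0:64, 0:64]
    labels = np.zeros((64, 64), int)
    labels[(yy - 32) ** 2 + (xx - 20) ** 2 <= 12**2] = 1  # big disc, centroid x=20
    labels[32, 52] = 2  # point object
    mask = ObjectMask(labels=labels, n_objects=2, foreground_fraction=0.1, method="mean")
    tiles = tessellate(mask)
    centroid_voronoi_boundary = (20 + 52) / 2  # 36
    skiz_boundary = (32 + 52) / 2  # borders at x=32 and x=52
    row = tiles.tile_labels[32]
    last_of_tile1 = np.flatnonzero(row == 1).max()
    assert last_of_tile1 > centroid_voronoi_boundary
    assert abs(last_of_tile1 - skiz_boundary) <= 1.5
    assert np.all(tiles.tile_labels[labels == 1] == 1)


def test_tessellate_empty_mask_errors():
    mask = _mask_from_binary(np.zeros((20, 20), bool))
    with pytest.raises(ValueError, match="no objects"):
        tessellate(mask)
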