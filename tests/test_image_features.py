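"""Feature-extraction pipeline: crop, thresholding, colour, tiling."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from lintgrade.image_features import (
    FULL_FRAME,
    RIG_CROP,
    CropSpec,
    FEATURE_NAMES,
    balanced_histogram_threshold,
    crop_uniform_region,
    extract_features,
    histogram_256,
    rgb_to_xyz,
    segment_grid,
    to_grayscale,
    trash_mask,
    trash_percentage,
    xyz_to_hunter,
)
from lintgrade.synthetic_data import make_grade_model, synthesize_image


def balanced_threshold_oracle(hist):
    """Independent step-by-step simulation of histogram balancing.

    Recomputes both side masses from scratch every step instead of
    updating them incrementally, so it shares no code path with the
    implementation under test.
    """
    h = list(hist)
    occupied = [i for i, c in enumerate(h) if c > 0]
    left, right = occupied[0], occupied[-1]
    while left < right:
        centre = (left + right) // 2
        w_left = sum(h[left : centre + 1])
        w_right = sum(h[centre + 1 : right + 1])
        if w_left == w_right:
            break
        if w_left > w_right:
            left += 1
        else:
            right -= 1
    return (left + right) // 2


# ---------------------------------------------------------------------------
# crop
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "shape, spec, expected",
    [
        ((2448, 3264), RIG_CROP, (2448, 2965)),  # rig preset trims the long axis
        ((100, 80), FULL_FRAME, (100, 80)),
        ((512, 512), CropSpec(margin=10), (512, 492)),
    ],
)
def test_crop_shapes(shape, spec, expected):
    img = np.zeros((*shape, 3), dtype=np.uint8)
    assert crop_uniform_region(img, spec).shape[:2] == expected


def test_crop_is_centred():
    img = np.arange(10)[None, :, None].repeat(3, axis=2).repeat(4, axis=0)
    out = crop_uniform_region(img, CropSpec(target=6, axis=1))
    assert list(out[0, :, 0]) == [2, 3, 4, 5, 6, 7]


def test_crop_larger_than_image_rejected():
    with pytest.raises(ValueError):
        crop_uniform_region(np.zeros((50, 50, 3)), CropSpec(target=60, axis=0))


# ---------------------------------------------------------------------------
# grayscale
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "rgb, expected",
    [((255, 255, 255), 255), ((0, 0, 0), 0), ((255, 0, 0), 76)],
)
def test_grayscale_luma(rgb, expected):
    img = np.array([[rgb]], dtype=np.float64)
    assert round(float(to_grayscale(img)[0, 0])) == expected


def test_grayscale_rejects_wrong_channels():
    with pytest.raises(ValueError):
        to_grayscale(np.zeros((4, 4)))


# ---------------------------------------------------------------------------
# balanced histogram thresholding
# ---------------------------------------------------------------------------

def test_threshold_symmetric_bimodal():
    assert balanced_histogram_threshold([100, 0, 0, 0, 100]) == 2


def test_threshold_single_occupied_level():
    h = np.zeros(256, dtype=int)
    h[137] = 42
    assert balanced_histogram_threshold(h) == 137


def test_threshold_empty_histogram_rejected():
    with pytest.raises(ValueError):
        balanced_histogram_threshold(np.zeros(256, dtype=int))


@pytest.mark.parametrize("seed", range(50))
def test_threshold_matches_independent_simulation(seed):
    rng = np.random.default_rng(seed)
    hist = rng.integers(0, 100, size=32)
    if hist.sum() == 0:
        hist[rng.integers(32)] = 1
    assert balanced_histogram_threshold(hist) == balanced_threshold_oracle(hist)


@settings(max_examples=100, derandomize=True)
@given(st.lists(st.integers(0, 1000), min_size=1, max_size=64))
def test_threshold_within_occupied_range(counts):
    h = np.array(counts)
    if h.sum() == 0:
        h[0] = 1
    occ = np.flatnonzero(h)
    t = balanced_histogram_threshold(h)
    assert occ[0] <= t <= occ[-1]


# ---------------------------------------------------------------------------
# trash percentage
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "mask, expected",
    [
        (np.zeros((10, 10), bool), 0.0),
        (np.arange(100).reshape(10, 10) < 25, 25.0),
        (np.ones((3, 3), bool), 100.0),
    ],
)
def test_trash_percentage(mask, expected):
    assert trash_percentage(mask) == expected


def test_trash_percentage_empty_raster_rejected():
    with pytest.raises(ValueError):
        trash_percentage(np.zeros((0, 0), bool))


def test_uniform_image_has_no_trash():
    img = np.full((32, 32, 3), 180, dtype=np.uint8)
    assert trash_percentage(trash_mask(to_grayscale(img))) == 0.0


# ---------------------------------------------------------------------------
# colour conversions
# ---------------------------------------------------------------------------

def test_xyz_white_point():
    white = rgb_to_xyz(np.array([[[255, 255, 255]]], dtype=float))[0, 0]
    assert np.allclose(white, [95.047, 100.0, 108.883], atol=0.05)


def test_xyz_black_is_zero():
    assert np.allclose(rgb_to_xyz(np.zeros((1, 1, 3))), 0.0)


def test_xyz_matches_hand_matrix():
    # independent route: explicit sRGB linearisation + D65 matrix rows
    M = np.array(
        [
            [0.412453, 0.357580, 0.180423],
            [0.212671, 0.715160, 0.072169],
            [0.019334, 0.119193, 0.950227],
        ]
    )
    rng = np.random.default_rng(0)
    rgb = rng.integers(0, 256, size=(5, 3)).astype(float)
    s = rgb / 255.0
    lin = np.where(s <= 0.04045, s / 12.92, ((s + 0.055) / 1.055) ** 2.4)
    expected = lin @ M.T * 100.0
    got = rgb_to_xyz(rgb[None, :, :])[0]
    assert np.allclose(got, expected, atol=0.1)


def test_xyz_rejects_out_of_range():
    with pytest.raises(ValueError):
        rgb_to_xyz(np.full((1, 1, 3), 300.0))


@pytest.mark.parametrize(
    "xyz, expected",
    [
        ([95.047, 100.0, 108.883], (100.0, 0.0, 0.0)),  # white
        ([95.047 * 0.25, 25.0, 108.883 * 0.25], (50.0, 0.0, 0.0)),  # quarter
        ([0.0, 0.0, 0.0], (0.0, 0.0, 0.0)),  # black convention
    ],
)
def test_hunter_reference_points(xyz, expected):
    assert np.allclose(xyz_to_hunter(xyz), expected, atol=1e-9)


def test_hunter_rejects_negative_y():
    with pytest.raises(ValueError):
        xyz_to_hunter([10.0, -5.0, 10.0])


def test_gray_ramp_is_achromatic_and_monotone():
    levels = np.arange(0, 256, 5)
    ramp = np.stack([levels] * 3, axis=-1)[None, :, :].astype(float)
    lab = xyz_to_hunter(rgb_to_xyz(ramp))[0]
    assert np.all(np.abs(lab[:, 1]) < 1.0) and np.all(np.abs(lab[:, 2]) < 1.0)
    assert np.all(np.diff(lab[:, 0]) > 0)


# ---------------------------------------------------------------------------
# tiling
# ---------------------------------------------------------------------------

def test_grid_single_tile_is_whole_image():
    img = np.zeros((30, 20, 3))
    tiles = segment_grid(img, 1, 1)
    assert len(tiles) == 1 and tiles[0].shape == img.shape


def test_grid_equal_tiles():
    tiles = segment_grid(np.zeros((100, 100, 3)), 4, 4)
    assert len(tiles) == 16
    assert all(t.shape[:2] == (25, 25) for t in tiles)


def test_grid_partitions_with_remainder():
    tiles = segment_grid(np.zeros((103, 103, 3)), 4, 4)
    assert sum(t.shape[0] * t.shape[1] for t in tiles) == 103 * 103


def test_grid_exceeding_image_rejected():
    with pytest.raises(ValueError):
        segment_grid(np.zeros((3, 3, 3)), 4, 4)


# ---------------------------------------------------------------------------
# full records
# ---------------------------------------------------------------------------

def test_uniform_image_record():
    img = np.full((64, 64, 3), 200, dtype=np.uint8)
    rec = extract_features(img)
    assert rec.values.shape == (12,)
    stds = rec.values[[5, 7, 9, 11]]
    assert np.allclose(stds, 0.0)


def test_single_tile_grid_matches_whole_image():
    rng = np.random.default_rng(4)
    img = rng.integers(100, 255, size=(64, 64, 3)).astype(np.uint8)
    rec = extract_features(img, grid=(1, 1))
    # tile means equal whole-image values, stds zero
    assert rec.values[4] == pytest.approx(rec.values[0])
    assert np.allclose(rec.values[[6, 8, 10]], rec.values[1:4])
    assert np.allclose(rec.values[[5, 7, 9, 11]], 0.0)


def test_extracted_trash_matches_painted_ledger():
    model = make_grade_model(n_grades=7, seed=5)
    img = synthesize_image(model, grade=5, dims=(256, 256), seed=6)
    rec = extract_features(img.pixels)
    painted_pct = 100.0 * img.trash_pixels / (256 * 256)
    assert abs(rec.values[0] - painted_pct) < 0.5


def test_feature_name_count():
    assert len(FEATURE_NAMES) == 12
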