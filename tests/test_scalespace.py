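"""Unit and property tests for the scale-space pyramid and blob extraction."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import ndimage

from gazeface import scalespace as ss
from tests.conftest import gaussian_blob_image


# ---------------------------------------------------------------------------
# scale schedule and grids


def test_sigma_schedule_values():
    expected = [
        1.0,
        np.sqrt(2),
        2.0,
        2 * np.sqrt(2),
        4.0,
        4 * np.sqrt(2),
        8.0,
        8 * np.sqrt(2),
        16.0,
        16 * np.sqrt(2),
    ]
    got = [ss.sigma_at(k) for k in range(1, 11)]
    assert np.allclose(got, expected, rtol=0, atol=1e-12)


def test_sigma_doubles_every_two_levels():
    for k in range(1, 9):
        assert ss.sigma_at(k + 2) / ss.sigma_at(k) == pytest.approx(2.0, abs=1e-12)


def test_grid_downsample_schedule():
    assert [ss.grid_downsample_at(k) for k in range(1, 11)] == [
        1, 1, 2, 2, 4, 4, 8, 8, 16, 16,
    ]


def test_pyramid_grid_shapes_250():
    levels = ss.build_pyramid(np.random.default_rng(0).uniform(size=(250, 250)))
    assert len(levels) == 10
    assert levels[2].smoothed.shape == (125, 125)
    assert levels[3].smoothed.shape == (125, 125)
    assert levels[0].smoothed.shape == (250, 250)


def test_constant_image_zero_laplacian():
    levels = ss.build_pyramid(np.full((64, 64), 0.7))
    for lv in levels:
        assert np.abs(lv.laplacian).max() <= 1e-9  # dynamic range is O(1)


def test_too_small_image_rejected():
    with pytest.raises(ss.ImageTooSmallError):
        ss.build_pyramid(np.zeros((24, 100)))


def test_to_grayscale_luma_weights():
    rgb = np.zeros((2, 2, 3))
    rgb[..., 0] = 1.0
    assert np.allclose(ss.to_grayscale(rgb), 0.299)
    rgb = np.ones((2, 2, 3))
    assert np.allclose(ss.to_grayscale(rgb), 1.0)


def test_incremental_smoothing_matches_direct_convolution():
    """Pyramid level k equals direct sigma_k convolution within 1% (band-limited)."""
    rng = np.random.default_rng(3)
    img = ndimage.gaussian_filter(rng.normal(size=(128, 128)), 3.0)
    dyn = img.max() - img.min()
    for lv in ss.build_pyramid(img):
        direct = ndimage.gaussian_filter(img, lv.sigma, mode="reflect")
        ds = lv.grid_downsample
        h, w = lv.smoothed.shape
        gy, gx = np.mgrid[0:h, 0:w]
        samp = ndimage.map_coordinates(
            direct,
            [(gy * ds + (ds - 1) / 2.0).ravel(), (gx * ds + (ds - 1) / 2.0).ravel()],
            order=3,
            mode="reflect",
        ).reshape(h, w)
        assert np.abs(lv.smoothed - samp).max() / dyn < 0.01


# ---------------------------------------------------------------------------
# blob detection


def test_dark_blob_polarity_and_location():
    img = gaussian_blob_image(100, 36.3, 52.7, 3.0)
    pts = ss.extract_features(img)
    strongest = max(pts, key=lambda p: p.response)
    assert strongest.polarity == "dark"
    assert np.hypot(strongest.x - 36.3, strongest.y - 52.7) <= 2 * ss.grid_downsample_at(
        strongest.level
    )


def test_bright_blob_polarity():
    img = 1.0 - gaussian_blob_image(100, 50.2, 47.6, 3.0)
    pts = ss.extract_features(img)
    strongest = max(pts, key=lambda p: p.response)
    assert strongest.polarity == "bright"


def test_blob_width_matches_level():
    """A blob of width b peaks at the level whose sigma is nearest b."""
    for width, expected_level in [(2.0, 3), (4.0, 5), (8.0, 7)]:
        img = gaussian_blob_image(192, 97.3, 90.1, width)
        mx = [float(np.abs(lv.laplacian).max()) for lv in ss.build_pyramid(img)]
        assert int(np.argmax(mx)) + 1 == expected_level


def test_upsampling_shifts_argmax_level_by_two():
    from skimage.transform import resize

    img = gaussian_blob_image(128, 66.3, 71.7, 4.0)
    up = resize(img, (256, 256), order=3)
    mx = [float(np.abs(lv.laplacian).max()) for lv in ss.build_pyramid(img)]
    mx_up = [float(np.abs(lv.laplacian).max()) for lv in ss.build_pyramid(up)]
    assert int(np.argmax(mx_up)) - int(np.argmax(mx)) == 2


def test_rotation_equivariance_90deg():
    img = gaussian_blob_image(100, 36.3, 52.7, 3.0)
    strong = lambda pts: sorted(
        (round(p.y), round(99 - p.x), p.level) for p in pts if p.response > 0.05
    )
    p1 = strong(ss.extract_features(img))
    p2 = sorted(
        (round(p.x), round(p.y), p.level)
        for p in ss.extract_features(np.rot90(img))
        if p.response > 0.05
    )
    assert len(p1) == len(p2)
    for (x1, y1, l1), (x2, y2, l2) in zip(p1, p2):
        assert l1 == l2 and abs(x1 - x2) <= 1 and abs(y1 - y2) <= 1


def test_step_edge_rejected_by_definiteness_filter():
    img = np.zeros((64, 64))
    img[:, 32:] = 1.0
    for lv in ss.build_pyramid(img, n_levels=4):
        for p in ss.detect_extrema(lv):
            # any surviving point must not sit on the edge line
            assert abs(p.x - 31.5) > 3


def test_flat_image_no_extrema():
    levels = ss.build_pyramid(np.full((64, 64), 0.3), n_levels=4)
    assert all(ss.detect_extrema(lv) == [] for lv in levels)


def _brute_force_extrema(resp):
    """O(N*8) strict neighborhood scan (plateaus handled as in the contract)."""
    h, w = resp.shape
    out = set()
    for find_max in (True, False):
        r = resp if find_max else -resp
        for y in range(1, h - 1):
            for x in range(1, w - 1):
                neigh = [
                    r[y + dy, x + dx]
                    for dy in (-1, 0, 1)
                    for dx in (-1, 0, 1)
                    if (dy, dx) != (0, 0)
                ]
                if all(r[y, x] > v for v in neigh):
                    out.add((float(x), float(y), find_max))
    return out


def test_extrema_match_brute_force_scan():
    rng = np.random.default_rng(8)
    for _ in range(5):
        resp = ndimage.gaussian_filter(rng.normal(size=(40, 40)), 1.2)
        fast = set()
        for find_max in (True, False):
            for x, y in ss._extrema_mask(resp, find_max):
                if float(x).is_integer() and float(y).is_integer():
                    fast.add((float(x), float(y), find_max))
        brute = _brute_force_extrema(resp)
        assert fast == brute  # smooth noise has no exact plateaus


def test_plateau_yields_centroid():
    resp = np.zeros((11, 11))
    resp[4:6, 4:6] = 1.0  # 2x2 plateau
    pts = ss._extrema_mask(resp, True)
    assert pts == [(4.5, 4.5)]


# ---------------------------------------------------------------------------
# scale linking


def _fp(x, y, level, response, polarity="dark"):
    return ss.FeaturePoint(x=x, y=y, level=level, response=response, polarity=polarity)


def test_linking_keeps_strongest_of_chain():
    pts = [[_fp(50, 50, 4, 0.4)], [_fp(50.5, 50, 5, 0.9)], [_fp(49, 50, 6, 0.5)]]
    out = ss.link_scales(pts)
    assert len(out) == 1 and out[0].level == 5 and out[0].response == 0.9


def test_linking_single_point_identity():
    p = _fp(10, 20, 3, 0.2)
    assert ss.link_scales([[p]]) == [p]


def test_linking_distant_blobs_survive():
    pts = [[_fp(10, 10, 4, 0.4), _fp(90, 90, 4, 0.3)], [_fp(10, 10, 5, 0.5), _fp(90, 90, 5, 0.6)]]
    out = ss.link_scales(pts)
    assert len(out) == 2
    assert sorted(p.response for p in out) == [0.5, 0.6]


def test_linking_respects_polarity():
    pts = [[_fp(50, 50, 4, 0.4, "dark")], [_fp(50, 50, 5, 0.9, "bright")]]
    assert len(ss.link_scales(pts)) == 2


def test_linking_radius_uses_coarser_sigma():
    # linking radius between levels 4 and 5 is 2*sigma_5 = 8
    linked = ss.link_scales([[_fp(50, 50, 4, 0.4)], [_fp(57, 50, 5, 0.9)]])
    assert len(linked) == 1
    apart = ss.link_scales([[_fp(50, 50, 4, 0.4)], [_fp(59, 50, 5, 0.9)]])
    assert len(apart) == 2


def test_feature_point_validation():
    with pytest.raises(ValueError):
        _fp(0, 0, 1, 0.0)
    with pytest.raises(ValueError):
        _fp(0, 0, 1, 0.5, "gray")


def test_feature_csv_roundtrip(tmp_path):
    rows = [("img0", _fp(1.5, 2.5, 3, 0.25)), ("img1", _fp(7.0, 8.0, 5, 0.5, "bright"))]
    path = tmp_path / "features.csv"
    ss.write_feature_csv(path, rows)
    back = ss.read_feature_csv(path)
    assert back == rows
    header = path.read_text().splitlines()[0]
    assert header == "image_id,x,y,level,sigma,response,polarity"


# ---------------------------------------------------------------------------
# property tests


@given(st.integers(min_value=1, max_value=10))
def test_sigma_is_sqrt_power_of_two(k):
    assert ss.sigma_at(k) == pytest.approx(np.sqrt(2.0 ** (k - 1)))


@given(
    st.floats(min_value=30, max_value=70),
    st.floats(min_value=30, max_value=70),
    st.floats(min_value=0.1, max_value=0.8),
)
def test_feature_points_within_image_bounds(cx, cy, contrast):
    img = gaussian_blob_image(100, cx, cy, 3.0, contrast=contrast)
    for p in ss.extract_features(img, n_levels=6):
        assert 0 <= p.x < 100 and 0 <= p.y < 100
        assert p.response > 0
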