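"""Unit and property tests for the fixation-guided scale selection."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from gazeface import scale_selection as sel


def _summary(centers):
    c = np.asarray(centers, float).reshape(-1, 2)
    return sel.ClusterSummary(
        centers=c, n_clusters=len(c), davies_bouldin=0.0, inertia=0.0
    )


# ---------------------------------------------------------------------------
# cluster distance oracles


def test_cluster_distance_single_pair():
    a = _summary([[0.0, 0.0]])
    b = _summary([[0.5, 0.0]])
    assert sel.cluster_distance(a, b) == pytest.approx(0.5)


def test_cluster_distance_mean_of_nearest():
    feats = _summary([[0.0, 0.0], [1.0, 1.0]])
    fixes = _summary([[0.0, 0.0], [0.0, 1.0]])
    # first center distance 0, second center nearest fix at distance 1
    assert sel.cluster_distance(feats, fixes) == pytest.approx((0.0 + 1.0) / 2)
    fixes2 = _summary([[0.0, 0.0], [2.0, 2.0]])
    # second feature center is sqrt(2) from both options
    assert sel.cluster_distance(feats, fixes2) == pytest.approx((0.0 + np.sqrt(2)) / 2)


def test_cluster_distance_asymmetric():
    feats = _summary([[0.0, 0.0]])
    fixes = _summary([[0.0, 0.0], [5.0, 0.0]])
    assert sel.cluster_distance(feats, fixes) == pytest.approx(0.0)
    assert sel.cluster_distance(fixes, feats) == pytest.approx(2.5)


def test_cluster_distance_empty_rejected():
    with pytest.raises(ValueError):
        sel.cluster_distance(_summary(np.empty((0, 2))), _summary([[0, 0]]))


# ---------------------------------------------------------------------------
# profile minima


def _profile(values, levels=None):
    v = np.asarray(values, float)
    levels = list(levels) if levels is not None else list(range(1, len(v) + 1))
    return sel.ScaleAffinityProfile(
        levels=levels,
        per_scale_per_index=v[:, None],
        per_scale=v,
        per_scale_sd=np.zeros_like(v),
        n_repetitions=1,
    )


def test_select_scales_worked_example():
    # d = [5, 3, 4, 2, 3] over levels 1..5 -> minima at levels 2 and 4
    p = _profile([5, 3, 4, 2, 3])
    assert sel.select_scales(p) == [4, 2]
    assert p.selected_scales == [4, 2]


def test_select_scales_endpoints_qualify():
    assert sel.select_scales(_profile([1, 2, 3, 4])) == [1]
    assert sel.select_scales(_profile([4, 3, 2, 1])) == [4]


def test_select_scales_plateau_not_minimum():
    # equal neighbors are not *strictly* below; only the true dip survives
    assert sel.select_scales(_profile([3, 2, 2, 1, 5])) == [4]


def test_select_scales_usable_filter_and_empty():
    p = _profile([5, 3, 4, 2, 3])
    assert sel.select_scales(p, usable_levels=[2, 3, 5]) == [2]
    with pytest.raises(sel.EmptySelectionError):
        sel.select_scales(_profile([5, 3, 4, 2, 3]), usable_levels=[1, 3, 5])


def test_select_scales_short_profile_rejected():
    with pytest.raises(ValueError):
        sel.select_scales(_profile([1, 2]))


@given(st.lists(st.integers(0, 100), min_size=3, max_size=10, unique=True))
def test_select_scales_returns_descending_true_minima(values):
    p = _profile(values)
    out = sel.select_scales(p)
    assert out == sorted(out, reverse=True)
    d = list(map(float, values))
    for lvl in out:
        i = lvl - 1
        assert i == 0 or d[i] < d[i - 1]
        assert i == len(d) - 1 or d[i] < d[i + 1]


# ---------------------------------------------------------------------------
# fixation records


def _records():
    rows = []
    for obs in range(3):
        for idx in (1, 2, 3):
            rows.append(
                {
                    "observer_id": obs,
                    "image_id": "img0",
                    "fixation_index": idx,
                    "x": 0.1 * idx,
                    "y": 0.2,
                }
            )
    return pd.DataFrame(rows)


def test_partition_counts_and_padding():
    with pytest.warns(UserWarning):
        sets = sel.partition_fixations(_records())
    assert len(sets) == sel.MAX_FIXATION_INDEX
    assert [len(s) for s in sets[:4]] == [3, 3, 3, 0]
    assert np.allclose(sets[1], [[0.2, 0.2]] * 3)


def test_partition_drops_indices_beyond_max():
    df = _records()
    extra = df.iloc[:1].assign(fixation_index=13)
    with pytest.warns(UserWarning):
        sets = sel.partition_fixations(pd.concat([df, extra]))
    assert sum(len(s) for s in sets) == len(df)


def test_read_fixation_csv_roundtrip(tmp_path):
    path = tmp_path / "fix.csv"
    _records().to_csv(path, index=False)
    df = sel.read_fixation_csv(path)
    assert len(df) == 9
    raw = _records().assign(x=lambda d: d.x * 200, y=lambda d: d.y * 100)
    raw.to_csv(path, index=False)
    df2 = sel.read_fixation_csv(path, normalized=False, image_size=(200, 100))
    assert np.allclose(df2[["x", "y"]], _records()[["x", "y"]])
    with pytest.raises(ValueError):
        sel.read_fixation_csv(path, normalized=False)


def test_read_fixation_csv_missing_column(tmp_path):
    path = tmp_path / "bad.csv"
    _records().drop(columns=["x"]).to_csv(path, index=False)
    with pytest.raises(ValueError):
        sel.read_fixation_csv(path)


# ---------------------------------------------------------------------------
# clustering


def _blobs(means, n, sigma, seed):
    rng = np.random.default_rng(seed)
    return np.vstack([rng.normal(m, sigma, (n, 2)) for m in means])


def test_cluster_points_recovers_three_blobs():
    means = [(0.2, 0.2), (0.8, 0.2), (0.5, 0.8)]
    pts = _blobs(means, 60, 0.02, seed=0)
    summary = sel.cluster_points(pts, seed=1)
    assert summary.n_clusters == 3
    d = np.linalg.norm(
        summary.centers[:, None, :] - np.asarray(means)[None], axis=2
    ).min(1)
    assert (d < 0.02).all()


def test_cluster_points_identical_points_gives_k1():
    pts = np.full((50, 2), 0.4)
    summary = sel.cluster_points(pts, seed=3)
    assert summary.n_clusters == 1
    assert np.allclose(summary.centers[0], (0.4, 0.4))


def test_cluster_points_db_threshold_controls_k1():
    # one Gaussian blob: best multi-cluster DB is ~0.8, so a threshold below
    # that forces the single-cluster fallback while the default keeps k >= 2
    pts = _blobs([(0.5, 0.5)], 100, 0.03, seed=2)
    single = sel.cluster_points(pts, seed=3, db_single_threshold=0.5)
    assert single.n_clusters == 1
    assert np.allclose(single.centers[0], (0.5, 0.5), atol=0.02)
    multi = sel.cluster_points(pts, seed=3)
    assert multi.n_clusters >= 2


def test_cluster_points_k_range_respected():
    pts = _blobs([(0.1, 0.1), (0.9, 0.9)], 50, 0.01, seed=4)
    summary = sel.cluster_points(pts, k_range=(3, 5), seed=5)
    assert 3 <= summary.n_clusters <= 5


def test_cluster_points_permutation_invariant_centers():
    pts = _blobs([(0.2, 0.2), (0.8, 0.8)], 50, 0.01, seed=6)
    a = sel.cluster_points(pts, seed=7)
    b = sel.cluster_points(pts[::-1].copy(), seed=7)
    assert a.n_clusters == b.n_clusters
    ca = sorted(map(tuple, np.round(a.centers, 6)))
    cb = sorted(map(tuple, np.round(b.centers, 6)))
    assert np.allclose(ca, cb, atol=1e-4)


def test_cluster_points_empty_rejected():
    with pytest.raises(sel.InsufficientDataError):
        sel.cluster_points(np.empty((0, 2)))


# ---------------------------------------------------------------------------
# end-to-end profile on constructed geometry


def test_profile_orders_scales_by_fixation_affinity():
    """Features of one scale planted on the fixation clusters score lowest."""
    rng = np.random.default_rng(8)
    anchors = np.array([(0.3, 0.4), (0.7, 0.4), (0.5, 0.7)])
    fixation_sets = [
        _blobs(anchors, 40, 0.015, seed=10 + i) for i in range(3)
    ]
    features = {
        2: _blobs(anchors, 80, 0.015, seed=20),  # on the fixations
        3: _blobs(anchors + 0.12, 80, 0.015, seed=21),  # shifted
        4: _blobs(anchors + 0.24, 80, 0.015, seed=22),  # shifted more
    }
    profile = sel.scale_affinity_profile(features, fixation_sets, n_rep=2, seed=9)
    assert profile.levels == [2, 3, 4]
    assert profile.per_scale[0] < profile.per_scale[1] < profile.per_scale[2]
    assert profile.per_scale_per_index.shape == (3, 3)
    assert sel.select_scales(profile) == [2]


def test_profile_requires_data():
    with pytest.raises(sel.InsufficientDataError):
        sel.scale_affinity_profile({}, [np.zeros((5, 2))], n_rep=1)
    with pytest.raises(sel.InsufficientDataError):
        sel.scale_affinity_profile({1: np.zeros((5, 2))}, [np.empty((0, 2))], n_rep=1)


def test_profile_csv(tmp_path):
    p = _profile([5, 3, 4, 2, 3])
    path = tmp_path / "profile.csv"
    sel.profile_to_csv(path, p)
    back = pd.read_csv(path)
    assert list(back["level"]) == [1, 2, 3, 4, 5]
    assert np.allclose(back["d_k"], [5, 3, 4, 2, 3])
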