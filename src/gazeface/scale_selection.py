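"""Fixation-guided selection of the model's spatial scales.

Gaze fixations are partitioned by their ordinal index (first fixation, second
fixation, ...), each index set and each scale's pooled feature points are
clustered with k-means (10 restarts, cluster count chosen in [1, 7] by the
Davies-Bouldin index), and every scale is scored by the mean distance from
its feature cluster centers to the nearest fixation cluster centers, averaged
over fixation indices and over repetitions.  The model scales are the local
minima of that distance profile.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.exceptions import ConvergenceWarning
from sklearn.metrics import davies_bouldin_score

MAX_FIXATION_INDEX = 12
K_RANGE = (1, 7)
N_INIT = 10
N_REPETITIONS = 100
DB_SINGLE_CLUSTER_THRESHOLD = 1.5


class InsufficientDataError(ValueError):
    pass


class EmptySelectionError(ValueError):
    pass


@dataclass
class ClusterSummary:
    centers: np.ndarray  # (n_clusters, 2)
    n_clusters: int
    davies_bouldin: float
    inertia: float


@dataclass
class ScaleAffinityProfile:
    levels: list[int]
    per_scale_per_index: np.ndarray  # (n_scales, n_indices) mean d_{k,i}
    per_scale: np.ndarray  # d_k, averaged over indices and repetitions
    per_scale_sd: np.ndarray  # spread of d_k over repetitions
    n_repetitions: int
    selected_scales: list[int] = field(default_factory=list)


def read_fixation_csv(path, normalized: bool = True, image_size: tuple[int, int] | None = None) -> pd.DataFrame:
    """Read fixation records (observer_id,image_id,fixation_index,x,y[,duration_ms]).

    With ``normalized=False`` raw pixel coordinates are divided by
    ``image_size`` (width, height).
    """
    df = pd.read_csv(path)
    required = {"observer_id", "image_id", "fixation_index", "x", "y"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"fixation CSV missing columns: {sorted(missing)}")
    if not normalized:
        if image_size is None:
            raise ValueError("image_size required for raw-pixel fixation input")
        df = df.assign(x=df["x"] / image_size[0], y=df["y"] / image_size[1])
    return df


def partition_fixations(records: pd.DataFrame, max_index: int = MAX_FIXATION_INDEX) -> list[np.ndarray]:
    """Pool fixations by index over observers and images.

    Returns ``max_index`` point arrays; set i-1 holds the normalized (x, y)
    of every i-th fixation.  Indices above ``max_index`` are dropped.
    """
    sets = []
    for i in range(1, max_index + 1):
        sub = records[records["fixation_index"] == i]
        pts = sub[["x", "y"]].to_numpy(dtype=float).reshape(-1, 2)
        if len(pts) == 0:
            warnings.warn(f"fixation index {i} has no records", stacklevel=2)
        sets.append(pts)
    return sets


def cluster_points(
    points: np.ndarray,
    k_range: tuple[int, int] = K_RANGE,
    n_init: int = N_INIT,
    seed: int = 0,
    db_single_threshold: float = DB_SINGLE_CLUSTER_THRESHOLD,
) -> ClusterSummary:
    """k-means clustering with the cluster count chosen by Davies-Bouldin.

    Every k in ``k_range`` with enough points is fitted with ``n_init``
    seeded restarts and the k minimizing the Davies-Bouldin index wins.  The
    index is undefined at k=1, so the single-cluster solution is returned
    only when even the best multi-cluster fit scores worse than
    ``db_single_threshold`` (or when no multi-cluster fit is feasible).
    """
    points = np.asarray(points, dtype=float).reshape(-1, 2)
    if len(points) == 0:
        raise InsufficientDataError("no points to cluster")
    k_lo, k_hi = k_range
    best = None  # (db, summary)
    n_distinct = len(np.unique(points, axis=0))
    for k in range(max(k_lo, 2), k_hi + 1):
        if n_distinct < k or len(points) < k:
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            km = KMeans(n_clusters=k, n_init=n_init, random_state=seed).fit(points)
        if len(np.unique(km.labels_)) < 2:
            continue
        db = davies_bouldin_score(points, km.labels_)
        if best is None or db < best[0]:
            best = (
                db,
                ClusterSummary(
                    centers=km.cluster_centers_.copy(),
                    n_clusters=k,
                    davies_bouldin=float(db),
                    inertia=float(km.inertia_),
                ),
            )
    single = ClusterSummary(
        centers=points.mean(axis=0, keepdims=True),
        n_clusters=1,
        davies_bouldin=float("nan"),
        inertia=float(((points - points.mean(axis=0)) ** 2).sum()),
    )
    if k_lo > 1 and best is None:
        raise InsufficientDataError("no feasible cluster count in range")
    if best is None or (k_lo <= 1 and best[0] > db_single_threshold):
        return single
    return best[1]


def cluster_distance(feature_clusters: ClusterSummary, fixation_clusters: ClusterSummary) -> float:
    """Mean distance from each feature center to its nearest fixation center."""
    fc = np.asarray(feature_clusters.centers, dtype=float)
    xc = np.asarray(fixation_clusters.centers, dtype=float)
    if len(fc) == 0 or len(xc) == 0:
        raise ValueError("empty cluster center list")
    d = np.linalg.norm(fc[:, None, :] - xc[None, :, :], axis=2)
    return float(d.min(axis=1).mean())


def scale_affinity_profile(
    features_by_scale: dict[int, np.ndarray],
    fixation_sets: list[np.ndarray],
    n_rep: int = N_REPETITIONS,
    seed: int = 0,
    k_range: tuple[int, int] = K_RANGE,
    n_init: int = N_INIT,
) -> ScaleAffinityProfile:
    """The d_k profile: feature-to-fixation cluster distance per scale.

    Each repetition re-clusters every feature scale and every fixation index
    with fresh seeded initializations, forms the d_{k,i} matrix, averages over
    i, and the per-repetition d_k values are averaged (their standard
    deviation is recorded).
    """
    levels = sorted(k for k, pts in features_by_scale.items() if len(pts) > 0)
    fix_sets = [np.asarray(f, float).reshape(-1, 2) for f in fixation_sets]
    active_idx = [i for i, f in enumerate(fix_sets) if len(f) >= 2]
    if not levels or not active_idx:
        raise InsufficientDataError("need at least one non-empty feature scale and fixation set")
    rng = np.random.default_rng(seed)
    dk_matrix = np.zeros((n_rep, len(levels), len(active_idx)))
    for rep in range(n_rep):
        fix_clusters = [
            cluster_points(fix_sets[i], k_range, n_init, seed=int(rng.integers(2**31 - 1)))
            for i in active_idx
        ]
        for a, lvl in enumerate(levels):
            feat_clusters = cluster_points(
                features_by_scale[lvl], k_range, n_init, seed=int(rng.integers(2**31 - 1))
            )
            for b, fx in enumerate(fix_clusters):
                dk_matrix[rep, a, b] = cluster_distance(feat_clusters, fx)
    per_scale_per_index = dk_matrix.mean(axis=0)
    dk_per_rep = dk_matrix.mean(axis=2)  # (n_rep, n_scales)
    return ScaleAffinityProfile(
        levels=levels,
        per_scale_per_index=per_scale_per_index,
        per_scale=dk_per_rep.mean(axis=0),
        per_scale_sd=dk_per_rep.std(axis=0, ddof=0),
        n_repetitions=n_rep,
    )


def select_scales(profile: ScaleAffinityProfile, usable_levels=None) -> list[int]:
    """Local minima of the d_k profile, coarse-to-fine.

    Interior levels qualify when strictly below both neighbors; endpoints
    when strictly below their single neighbor.  The result is intersected
    with ``usable_levels`` and ordered coarse-to-fine (descending level).
    """
    d = np.asarray(profile.per_scale, dtype=float)
    if len(d) < 3:
        raise ValueError("profile must cover at least 3 scales")
    selected = []
    for i, lvl in enumerate(profile.levels):
        left_ok = i == 0 or d[i] < d[i - 1]
        right_ok = i == len(d) - 1 or d[i] < d[i + 1]
        if left_ok and right_ok:
            selected.append(lvl)
    if usable_levels is not None:
        usable = set(usable_levels)
        selected = [lvl for lvl in selected if lvl in usable]
    if not selected:
        raise EmptySelectionError("no local minimum among usable levels")
    selected = sorted(selected, reverse=True)
    profile.selected_scales = selected
    return selected


def profile_to_csv(path, profile: ScaleAffinityProfile) -> None:
    pd.DataFrame(
        {"level": profile.levels, "d_k": profile.per_scale, "sd": profile.per_scale_sd}
    ).to_csv(path, index=False)
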