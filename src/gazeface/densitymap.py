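"""Per-scale feature density maps over the normalized face frame.

Feature points extracted from many aligned face images are pooled per scale,
their spatial distribution is estimated with a binned Gaussian kernel density
estimate on a fixed grid over [0,1]^2, successive maps are compared with the
Bray-Curtis index and 1-JSD to monitor convergence, and the model points of a
scale are the local maxima of its map reaching at least 70% of the global
maximum.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.spatial.distance import braycurtis, jensenshannon

from .scalespace import FeaturePoint, extract_features

GRID_RESOLUTION = 128
MODEL_POINT_RATIO = 0.7


class InsufficientDataError(ValueError):
    pass


class DegenerateMapError(ValueError):
    pass


@dataclass
class FeatureDensityMap:
    """A 2-D probability density over the normalized face frame.

    ``grid[iy, ix]`` holds the density at cell (ix, iy); the grid integrates
    to 1 (sum * cell_area == 1).  ``model_points`` are normalized (x, y)
    coordinates of the selected strong local maxima.
    """

    level: int
    grid: np.ndarray
    n_images: int = 0
    bandwidth: float = 0.0
    model_points: list[tuple[float, float]] = field(default_factory=list)

    @property
    def resolution(self) -> int:
        return self.grid.shape[0]

    @property
    def cell_area(self) -> float:
        return 1.0 / (self.grid.shape[0] * self.grid.shape[1])


def normalize_points(points: list[FeaturePoint], image_shape: tuple[int, int]) -> np.ndarray:
    """Map feature-point pixel coordinates to the [0,1]^2 face frame."""
    h, w = image_shape
    return np.array([[p.x / w, p.y / h] for p in points], dtype=float).reshape(-1, 2)


def accumulate_features(
    feature_sets: list[tuple[list[FeaturePoint], tuple[int, int]]], level: int
) -> np.ndarray:
    """Multiset union of normalized positions of all points at ``level``.

    Each element of ``feature_sets`` is ``(points, (height, width))`` of the
    source image, so positions can be normalized per image.
    """
    chunks = [
        normalize_points([p for p in points if p.level == level], shape)
        for points, shape in feature_sets
    ]
    if not chunks:
        return np.empty((0, 2))
    return np.vstack(chunks)


def scott_bandwidth(points: np.ndarray) -> float:
    """Scott's rule bandwidth (normalized units), averaged over the two axes."""
    n = len(points)
    stds = points.std(axis=0, ddof=1)
    return float(n ** (-1.0 / 6.0) * stds.mean())


def default_bandwidth(points: np.ndarray, grid_resolution: int = GRID_RESOLUTION) -> float:
    """Bandwidth: Scott's rule capped at two grid cells.

    Scott's rule uses the global point spread, which for pooled face-feature
    maps is the width of the whole face; on large pooled samples it
    oversmooths the strongly multimodal structure (eyes, nostrils, mouth
    corners) into one plateau.  Capping at two grid cells resolves that
    structure while keeping the estimate smooth at the working resolution;
    small concentrated samples still get the (then smaller) Scott value.
    """
    return float(min(scott_bandwidth(points), 2.0 / grid_resolution))


def _linear_binning(points: np.ndarray, grid_resolution: int) -> np.ndarray:
    """Bilinear ("linear binning") histogram of points on the cell-center grid.

    Each point's unit mass is split over the four surrounding cell centers
    with bilinear weights, which removes most of the hard-binning
    discretization error of a plain histogram.
    """
    res = grid_resolution
    u = np.clip(points[:, 0], 0.0, 1.0) * res - 0.5
    v = np.clip(points[:, 1], 0.0, 1.0) * res - 0.5
    i0 = np.floor(u).astype(int)
    j0 = np.floor(v).astype(int)
    fu, fv = u - i0, v - j0
    hist = np.zeros((res, res))
    for dj, di, wgt in (
        (0, 0, (1 - fv) * (1 - fu)),
        (0, 1, (1 - fv) * fu),
        (1, 0, fv * (1 - fu)),
        (1, 1, fv * fu),
    ):
        jj = np.clip(j0 + dj, 0, res - 1)
        ii = np.clip(i0 + di, 0, res - 1)
        np.add.at(hist, (jj, ii), wgt)
    return hist


def estimate_density(
    points: np.ndarray,
    grid_resolution: int = GRID_RESOLUTION,
    level: int = 0,
    n_images: int = 0,
    bandwidth: float | None = None,
) -> FeatureDensityMap:
    """Binned Gaussian KDE of normalized points on a fixed grid.

    Points are histogrammed on the grid (with bilinear mass splitting, see
    :func:`_linear_binning`) and smoothed with a Gaussian whose
    bandwidth defaults to Scott's rule capped at two grid cells (see
    :func:`default_bandwidth`); the result is renormalized to
    integrate to 1, which also compensates the mass lost to truncation at
    the frame boundary.  Deterministic given points and bandwidth.
    """
    points = np.asarray(points, dtype=float).reshape(-1, 2)
    if len(points) < 2:
        raise InsufficientDataError("need at least 2 points for a density estimate")
    if bandwidth is None:
        bandwidth = default_bandwidth(points, grid_resolution)
    hist = _linear_binning(points, grid_resolution)
    sigma_cells = max(bandwidth * grid_resolution, 1e-6)
    grid = ndimage.gaussian_filter(hist, sigma_cells, mode="constant")
    total = grid.sum()
    if total <= 0:
        raise DegenerateMapError("density mass vanished")
    cell_area = 1.0 / grid_resolution**2
    grid = grid / (total * cell_area)
    return FeatureDensityMap(
        level=level, grid=grid, n_images=n_images, bandwidth=float(bandwidth)
    )


def _as_distribution(m: FeatureDensityMap) -> np.ndarray:
    v = m.grid.ravel()
    return v / v.sum()


def map_similarity(a: FeatureDensityMap, b: FeatureDensityMap, method: str = "bray_curtis") -> float:
    """Similarity in [0,1] between two density maps on identical grids.

    ``bray_curtis`` = 1 - sum|a-b| / sum(a+b);  ``one_minus_jsd`` = 1 - JSD
    with base-2 logarithm (so the divergence is bounded by 1).  Both are
    symmetric and equal 1 iff the maps coincide on the grid.
    """
    if a.grid.shape != b.grid.shape:
        raise ValueError(f"grid shapes differ: {a.grid.shape} vs {b.grid.shape}")
    p, q = _as_distribution(a), _as_distribution(b)
    if method == "bray_curtis":
        return float(1.0 - braycurtis(p, q))
    if method == "one_minus_jsd":
        with np.errstate(invalid="ignore"):
            jsd = jensenshannon(p, q, base=2) ** 2
        # round-off on (near-)identical maps can give a tiny negative argument
        # inside the square root, yielding NaN; that means divergence 0
        if np.isnan(jsd):
            jsd = 0.0
        return float(1.0 - min(max(jsd, 0.0), 1.0))
    raise ValueError(f"unknown method {method!r}")


def convergence_curve(
    image_stream,
    level: int,
    start_n: int = 25,
    grid_resolution: int = GRID_RESOLUTION,
    feature_extractor=extract_features,
):
    """Similarity between successive density maps as images accumulate.

    Starting from the map built on the first ``start_n`` images, each further
    image updates the pooled point set and the map; the similarity between
    the previous and updated maps is recorded for both indices.  Returns a
    list of ``(N, bray_curtis, one_minus_jsd)`` tuples where N is the number
    of images in the updated map.
    """
    images = list(image_stream)
    if len(images) <= start_n:
        raise InsufficientDataError(
            f"stream of {len(images)} images does not exceed start_n={start_n}"
        )
    per_image = []
    for img in images:
        img = np.asarray(img)
        pts = feature_extractor(img)
        per_image.append(normalize_points([p for p in pts if p.level == level], img.shape[:2]))

    pooled = np.vstack(per_image[:start_n])
    prev = estimate_density(pooled, grid_resolution, level=level, n_images=start_n)
    curve = []
    for n in range(start_n + 1, len(images) + 1):
        pooled = np.vstack([pooled, per_image[n - 1]])
        cur = estimate_density(pooled, grid_resolution, level=level, n_images=n)
        curve.append(
            (
                n,
                map_similarity(prev, cur, "bray_curtis"),
                map_similarity(prev, cur, "one_minus_jsd"),
            )
        )
        prev = cur
    return curve


def select_model_points(
    density_map: FeatureDensityMap, ratio: float = MODEL_POINT_RATIO
) -> list[tuple[float, float]]:
    """Local maxima of the map at >= ratio of its global maximum.

    Strict 8-neighborhood maxima (grid-border cells included, compared over
    their in-grid neighbors); the global maximum is always returned.  Stored
    into ``density_map.model_points``.
    """
    if not 0 < ratio <= 1:
        raise ValueError("ratio must be in (0, 1]")
    g = density_map.grid
    if np.allclose(g, g.flat[0]):
        raise DegenerateMapError("constant density map has no local maxima")
    footprint = np.ones((3, 3), bool)
    neigh_max = ndimage.maximum_filter(g, footprint=footprint, mode="constant", cval=-np.inf)
    is_max = g >= neigh_max
    gmax = g.max()
    keep = is_max & (g >= ratio * gmax)
    res_y, res_x = g.shape
    ys, xs = np.nonzero(keep)
    # collapse plateaus (adjacent equal maxima) to their centroids
    labels, n = ndimage.label(keep, structure=footprint)
    points = []
    for idx in range(1, n + 1):
        yy, xx = np.nonzero(labels == idx)
        points.append(((xx.mean() + 0.5) / res_x, (yy.mean() + 0.5) / res_y))
    # the argmax cell is always among the selected components by construction
    density_map.model_points = sorted(points, key=lambda p: (p[1], p[0]))
    return density_map.model_points


def save_density_map(path, m: FeatureDensityMap) -> None:
    """Serialize a density map (grid + metadata) to a portable .npz container."""
    np.savez(
        path,
        grid=m.grid,
        level=m.level,
        n_images=m.n_images,
        bandwidth=m.bandwidth,
        model_points=np.array(m.model_points, dtype=float).reshape(-1, 2),
    )


def load_density_map(path) -> FeatureDensityMap:
    d = np.load(path)
    m = FeatureDensityMap(
        level=int(d["level"]),
        grid=d["grid"],
        n_images=int(d["n_images"]),
        bandwidth=float(d["bandwidth"]),
    )
    m.model_points = [tuple(p) for p in d["model_points"]]
    return m


def export_heatmap_png(path, m: FeatureDensityMap) -> None:
    """Write the map as a PNG heatmap with model points marked."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4, 4))
    ax.imshow(m.grid, extent=(0, 1, 1, 0), cmap="inferno")
    if m.model_points:
        mp = np.array(m.model_points)
        ax.plot(mp[:, 0], mp[:, 1], "c+", markersize=10)
    ax.set_title(f"level {m.level} (N={m.n_images})")
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)
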