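"""Gaussian scale-space pyramid and Laplacian blob extraction.

A 10-level pyramid is built over the scale schedule sigma_k = sqrt(2^(k-1)),
k = 1..10, with the image grid halved every two levels so that the smoothing
kernel stays cheap at coarse scales.  Blobs are the spatial extrema of the
scale-normalized Laplacian t * (L_xx + L_yy), t = sigma_k^2; edge and saddle
responses are rejected with the Hessian definiteness test, and extrema that
persist across adjacent scales are linked, keeping the strongest response.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

MIN_IMAGE_SIDE = 25
N_LEVELS_DEFAULT = 10

# ITU-R BT.601 luma weights for RGB -> grayscale
_LUMA = np.array([0.299, 0.587, 0.114])


class ImageTooSmallError(ValueError):
    """Input image is smaller than the minimum analysable size."""


def sigma_at(level: int) -> float:
    """Gaussian standard deviation at pyramid level ``level`` (1-based)."""
    if level < 1:
        raise ValueError(f"level must be >= 1, got {level}")
    return float(np.sqrt(2.0 ** (level - 1)))


def grid_downsample_at(level: int) -> int:
    """Grid decimation factor at ``level``: the grid is halved every two levels."""
    return int(2 ** ((level - 1) // 2))


def to_grayscale(image: np.ndarray) -> np.ndarray:
    """Convert an image array to a float64 luminance image.

    RGB(A) input is reduced with the 0.299/0.587/0.114 luma weights; 2-D
    input is passed through as float64.
    """
    img = np.asarray(image, dtype=np.float64)
    if img.ndim == 3:
        img = img[..., :3] @ _LUMA
    if img.ndim != 2:
        raise ValueError(f"expected 2-D or RGB image, got shape {image.shape}")
    return img


@dataclass
class ScaleLevel:
    """One level of the pyramid.

    ``smoothed`` and ``laplacian`` live on the (possibly decimated) grid;
    ``grid_downsample`` maps grid coordinates back to native pixels.
    """

    index: int
    sigma: float
    grid_downsample: int
    smoothed: np.ndarray
    laplacian: np.ndarray | None = None


@dataclass(frozen=True)
class FeaturePoint:
    """A scale-space extremum in native-resolution pixel coordinates."""

    x: float
    y: float
    level: int
    response: float
    polarity: str  # "dark" (positive-definite Hessian) or "bright"

    def __post_init__(self):
        if self.response <= 0:
            raise ValueError("response must be positive")
        if self.polarity not in ("dark", "bright"):
            raise ValueError(f"invalid polarity {self.polarity!r}")


def _downsample2(img: np.ndarray) -> np.ndarray:
    """Factor-2 decimation by 2x2 area averaging (odd trailing row/col dropped)."""
    h, w = img.shape
    img = img[: h - h % 2, : w - w % 2]
    return 0.25 * (img[0::2, 0::2] + img[1::2, 0::2] + img[0::2, 1::2] + img[1::2, 1::2])


def build_pyramid(image: np.ndarray, n_levels: int = N_LEVELS_DEFAULT) -> list[ScaleLevel]:
    """Build the Gaussian pyramid with incremental smoothing and grid halving.

    Level k's ``smoothed`` image equals the input convolved with a Gaussian of
    standard deviation sigma_k (measured at native resolution), carried on a
    grid decimated by 2^floor((k-1)/2).  Laplacian responses are filled in for
    every level.

    Raises
    ------
    ImageTooSmallError
        If min(height, width) < 25.
    """
    img = to_grayscale(image)
    if min(img.shape) < MIN_IMAGE_SIDE:
        raise ImageTooSmallError(
            f"image sides {img.shape} below minimum {MIN_IMAGE_SIDE}"
        )
    if n_levels < 1:
        raise ValueError("n_levels must be >= 1")

    levels: list[ScaleLevel] = []
    current = img
    sigma_acc = 0.0  # cumulative blur of `current`, in native pixels
    ds = 1
    for k in range(1, n_levels + 1):
        target_ds = grid_downsample_at(k)
        if target_ds > ds:
            current = _downsample2(current)
            # the 2x2 box average is itself a small blur: variance 1/4 of the
            # squared input grid spacing per axis; book-keep it so cumulative
            # smoothing stays on the sigma_k schedule
            sigma_acc = np.sqrt(sigma_acc**2 + 0.25 * ds**2)
            ds = target_ds
        sigma_k = sigma_at(k)
        # incremental blur on the current grid to reach sigma_k at native res
        inc = np.sqrt(max(sigma_k**2 - sigma_acc**2, 0.0)) / ds
        if inc > 1e-12:
            current = ndimage.gaussian_filter(current, inc, mode="reflect")
        sigma_acc = sigma_k
        level = ScaleLevel(index=k, sigma=sigma_k, grid_downsample=ds, smoothed=current)
        laplacian_response(level)
        levels.append(level)
    return levels


def _stencil_gain(level_index: int) -> float:
    """Calibration of the discrete 5-point Laplacian for cross-level comparison.

    On a grid, the central-difference second derivative of a Gaussian of
    (grid) variance s^2 is attenuated by 2*s^2*(1 - exp(-1/(2*s^2))) relative
    to the true derivative.  A blob matched to level k appears with grid
    variance 2*(sigma_k/downsample_k)^2, which alternates between 2 and 4
    along the pyramid, so uncorrected responses of the decimated levels are
    systematically depressed.  Dividing by the attenuation at the level's own
    matched width makes normalized responses comparable across grids.
    """
    s2 = 2.0 * (sigma_at(level_index) / grid_downsample_at(level_index)) ** 2
    return 1.0 / (2.0 * s2 * (1.0 - np.exp(-1.0 / (2.0 * s2))))


def laplacian_response(level: ScaleLevel) -> np.ndarray:
    """Scale-normalized Laplacian t*(L_xx + L_yy), t = sigma^2.

    Second derivatives use central finite differences on the level's grid;
    dividing by grid_downsample^2 expresses them per native pixel before the
    t-normalization, and the per-level stencil gain (see ``_stencil_gain``)
    undoes the grid-dependent attenuation, so responses are comparable
    across levels.
    """
    L = level.smoothed
    pad = np.pad(L, 1, mode="reflect")
    lxx = pad[1:-1, 2:] - 2.0 * L + pad[1:-1, :-2]
    lyy = pad[2:, 1:-1] - 2.0 * L + pad[:-2, 1:-1]
    t = level.sigma**2
    gain = _stencil_gain(level.index)
    level.laplacian = (gain * t / level.grid_downsample**2) * (lxx + lyy)
    return level.laplacian


def _hessian_det(L: np.ndarray) -> np.ndarray:
    """Determinant of the Hessian of L per grid pixel (central differences)."""
    pad = np.pad(L, 1, mode="reflect")
    lxx = pad[1:-1, 2:] - 2.0 * L + pad[1:-1, :-2]
    lyy = pad[2:, 1:-1] - 2.0 * L + pad[:-2, 1:-1]
    lxy = 0.25 * (pad[2:, 2:] - pad[2:, :-2] - pad[:-2, 2:] + pad[:-2, :-2])
    return lxx * lyy - lxy**2


def _extrema_mask(resp: np.ndarray, find_max: bool) -> list[tuple[float, float]]:
    """Strict 8-neighborhood extrema; a same-valued plateau yields its centroid.

    A pixel (or plateau of equal values) qualifies when every pixel bordering
    it is strictly below (above, for minima).  Pixels within 1 px of the
    border are excluded.
    """
    r = resp if find_max else -resp
    ring_fp = np.ones((3, 3), bool)
    ring_fp[1, 1] = False
    neigh_max = ndimage.maximum_filter(r, footprint=ring_fp, mode="constant", cval=-np.inf)
    interior = np.zeros(r.shape, bool)
    interior[1:-1, 1:-1] = True

    strict = (r > neigh_max) & interior
    out: list[tuple[float, float]] = [
        (float(x), float(y)) for y, x in zip(*np.nonzero(strict))
    ]

    # plateaus: pixels tied with their neighborhood maximum
    tied = (r == neigh_max) & interior
    if tied.any():
        full_fp = np.ones((3, 3), bool)
        labels, n = ndimage.label(tied, structure=full_fp)
        objects = ndimage.find_objects(labels)
        for idx, sl in enumerate(objects, start=1):
            # widen the bounding box by 1 px for the surrounding ring
            y0 = max(sl[0].start - 1, 0)
            y1 = min(sl[0].stop + 1, r.shape[0])
            x0 = max(sl[1].start - 1, 0)
            x1 = min(sl[1].stop + 1, r.shape[1])
            sub_lab = labels[y0:y1, x0:x1] == idx
            sub_r = r[y0:y1, x0:x1]
            vals = sub_r[sub_lab]
            if vals.min() != vals.max():
                continue  # tied pixels at different values: not one plateau
            ring = ndimage.binary_dilation(sub_lab, structure=full_fp) & ~sub_lab
            # pixels at the image border (outside `interior`) also bound the plateau
            if ring.any() and sub_r[ring].max() >= vals[0]:
                continue
            ys, xs = np.nonzero(sub_lab)
            out.append((float(xs.mean() + x0), float(ys.mean() + y0)))
    return out


def detect_extrema(level: ScaleLevel) -> list[FeaturePoint]:
    """Spatial extrema of the normalized Laplacian, edge responses rejected.

    Dark blobs are maxima of the Laplacian with a positive-definite Hessian of
    L, bright blobs minima with a negative-definite one; points where the
    Hessian eigenvalue product is <= 0 (edges, saddles) are discarded.
    Coordinates are mapped back to native resolution.
    """
    if level.laplacian is None:
        laplacian_response(level)
    resp = level.laplacian
    det = _hessian_det(level.smoothed)
    ds = level.grid_downsample
    offset = (ds - 1) / 2.0  # centre of the ds x ds native block

    points: list[FeaturePoint] = []
    for find_max, polarity in ((True, "dark"), (False, "bright")):
        for gx, gy in _extrema_mask(resp, find_max):
            iy, ix = int(round(gy)), int(round(gx))
            if det[iy, ix] <= 0:
                continue
            val = abs(resp[iy, ix])
            if val <= 0:
                continue
            points.append(
                FeaturePoint(
                    x=gx * ds + offset,
                    y=gy * ds + offset,
                    level=level.index,
                    response=float(val),
                    polarity=polarity,
                )
            )
    return points


def link_scales(per_level_points: list[list[FeaturePoint]]) -> list[FeaturePoint]:
    """Chain extrema that persist across adjacent scales; keep the strongest.

    Two points at adjacent levels are linked when they share polarity and
    their native positions lie within 2*sigma of the coarser level.  Each
    resulting chain contributes its maximal-response member; unchained points
    pass through unchanged.
    """
    all_points = [p for lvl in per_level_points for p in lvl]
    n = len(all_points)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i: int, j: int) -> None:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[rj] = ri

    from scipy.spatial import cKDTree

    by_level: dict[int, list[int]] = {}
    for idx, p in enumerate(all_points):
        by_level.setdefault(p.level, []).append(idx)

    for lvl in sorted(by_level):
        if lvl + 1 not in by_level:
            continue
        radius = 2.0 * sigma_at(lvl + 1)  # coarser of the two levels
        for pol in ("dark", "bright"):
            fine = [i for i in by_level[lvl] if all_points[i].polarity == pol]
            coarse = [j for j in by_level[lvl + 1] if all_points[j].polarity == pol]
            if not fine or not coarse:
                continue
            tree = cKDTree([(all_points[j].x, all_points[j].y) for j in coarse])
            queries = tree.query_ball_point(
                [(all_points[i].x, all_points[i].y) for i in fine], r=radius
            )
            for i, hits in zip(fine, queries):
                for h in hits:
                    union(i, coarse[h])

    best: dict[int, int] = {}
    for idx in range(n):
        root = find(idx)
        if root not in best or all_points[idx].response > all_points[best[root]].response:
            best[root] = idx
    return [all_points[i] for i in sorted(best.values())]


def extract_features(image: np.ndarray, n_levels: int = N_LEVELS_DEFAULT) -> list[FeaturePoint]:
    """Full pipeline: pyramid -> per-level extrema -> scale linking."""
    levels = build_pyramid(image, n_levels)
    return link_scales([detect_extrema(lv) for lv in levels])


def write_feature_csv(path, rows: list[tuple[str, FeaturePoint]]) -> None:
    """Write (image_id, FeaturePoint) rows to CSV."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["image_id", "x", "y", "level", "sigma", "response", "polarity"])
        for image_id, p in rows:
            w.writerow([image_id, p.x, p.y, p.level, sigma_at(p.level), p.response, p.polarity])


def read_feature_csv(path) -> list[tuple[str, FeaturePoint]]:
    """Read rows written by :func:`write_feature_csv`."""
    out = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            out.append(
                (
                    row["image_id"],
                    FeaturePoint(
                        x=float(row["x"]),
                        y=float(row["y"]),
                        level=int(row["level"]),
                        response=float(row["response"]),
                        polarity=row["polarity"],
                    ),
                )
            )
    return out
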