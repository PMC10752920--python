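"""25x25 patch descriptors and the binary patch classifier.

Each patch is described by 9 histograms of oriented gradients laid out on a
3x3 grid of cells, 16 unsigned-orientation bins each, giving a 144-component
vector (L2-normalized with a small epsilon).  A linear max-margin classifier
(SVM, C=1) is trained per scale on descriptors at the scale's model points
(positives) versus descriptors at random positions in non-face images
(negatives); its output is the hard label {0, 1}.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.svm import LinearSVC

PATCH_SIZE = 25
N_CELLS = 3  # per axis -> 9 histograms
N_BINS = 16  # unsigned orientation bins over [0, 180)
DESCRIPTOR_LEN = N_CELLS * N_CELLS * N_BINS  # 144
_EPS = 1e-6


class DegenerateTrainingError(ValueError):
    pass


class ModelIncompleteError(ValueError):
    pass


@dataclass(frozen=True)
class PatchDescriptor:
    vector: np.ndarray
    source: tuple = ()  # (image_id, cx, cy, level)

    def __post_init__(self):
        if self.vector.shape != (DESCRIPTOR_LEN,):
            raise ValueError(f"descriptor must have {DESCRIPTOR_LEN} components")


@dataclass
class PatchClassifier:
    """Linear separator w.x + b > 0 -> face patch (label 1)."""

    level: int
    weights: np.ndarray
    bias: float
    n_pos: int = 0
    n_neg: int = 0
    seed: int = 0

    def decision(self, vectors: np.ndarray) -> np.ndarray:
        return np.asarray(vectors) @ self.weights + self.bias

    def classify(self, vectors: np.ndarray) -> np.ndarray:
        """Hard binary labels in {0, 1}."""
        return (self.decision(vectors) > 0).astype(int)


def extract_patch(image: np.ndarray, center: tuple[float, float], size: int = PATCH_SIZE) -> np.ndarray:
    """Square patch centered at (x, y); out-of-image pixels reflected."""
    if size % 2 == 0:
        raise ValueError("patch size must be odd")
    h, w = image.shape
    cx, cy = int(round(center[0])), int(round(center[1]))
    if not (0 <= cx < w and 0 <= cy < h):
        raise ValueError(f"patch center {center} outside image of shape {image.shape}")
    half = size // 2
    pad = np.pad(image, half, mode="reflect")
    return pad[cy : cy + size, cx : cx + size].copy()


def hog_descriptors_batch(patches: np.ndarray) -> np.ndarray:
    """HOG descriptors for a stack of patches, shape (n, size, size) -> (n, 144).

    Gradients are central differences inside each patch (one-sided at patch
    borders), orientation is unsigned over [0, 180) in 16 bins weighted by
    gradient magnitude, cells are a 3x3 partition of the patch, histograms are
    concatenated row-major and L2-normalized with epsilon 1e-6 (a gradient-free
    patch maps to the zero vector).
    """
    patches = np.asarray(patches, dtype=np.float64)
    if patches.ndim == 2:
        patches = patches[None]
    n, size, size2 = patches.shape
    if size != size2:
        raise ValueError("patches must be square")
    gy, gx = np.gradient(patches, axis=(1, 2))
    mag = np.hypot(gx, gy)
    ang = np.degrees(np.arctan2(gy, gx)) % 180.0
    bins = np.minimum((ang / 180.0 * N_BINS).astype(np.intp), N_BINS - 1)

    # cell index per pixel: 3 near-equal row/column bands
    bounds = np.linspace(0, size, N_CELLS + 1).round().astype(int)
    band = np.zeros(size, dtype=np.intp)
    for c in range(N_CELLS):
        band[bounds[c] : bounds[c + 1]] = c
    cell = band[:, None] * N_CELLS + band[None, :]  # (size, size)

    flat_idx = (
        np.arange(n, dtype=np.intp)[:, None, None] * DESCRIPTOR_LEN
        + cell[None] * N_BINS
        + bins
    )
    desc = np.bincount(
        flat_idx.ravel(), weights=mag.ravel(), minlength=n * DESCRIPTOR_LEN
    ).reshape(n, DESCRIPTOR_LEN)
    norms = np.linalg.norm(desc, axis=1, keepdims=True)
    return desc / (norms + _EPS)


def hog_descriptor(patch: np.ndarray, source: tuple = ()) -> PatchDescriptor:
    """Descriptor of a single 25x25 patch (see :func:`hog_descriptors_batch`)."""
    patch = np.asarray(patch, dtype=np.float64)
    if patch.shape != (PATCH_SIZE, PATCH_SIZE):
        raise ValueError(f"expected {PATCH_SIZE}x{PATCH_SIZE} patch, got {patch.shape}")
    return PatchDescriptor(vector=hog_descriptors_batch(patch[None])[0], source=source)


def build_training_set(
    positive_levels: list,
    negative_levels: list,
    model_points: list[tuple[float, float]],
    level: int,
    seed: int = 0,
) -> pd.DataFrame:
    """Labeled descriptor table for one scale.

    ``positive_levels`` / ``negative_levels`` are the pyramid ScaleLevel
    objects of that scale, one per training image.  For each positive image
    one patch per model point is taken on the level's grid (label 1); each
    negative image contributes the same number of patches at seeded uniform
    random positions (label 0).
    """
    if not model_points:
        raise ModelIncompleteError(f"no model points at level {level}")
    rng = np.random.default_rng(seed)
    rows, vecs = [], []
    for i, lv in enumerate(positive_levels):
        h, w = lv.smoothed.shape
        for mx, my in model_points:
            cx = min(max(mx * w, 0), w - 1)
            cy = min(max(my * h, 0), h - 1)
            patch = extract_patch(lv.smoothed, (cx, cy))
            vecs.append(hog_descriptors_batch(patch[None])[0])
            rows.append({"label": 1, "image_id": f"pos{i}", "cx": cx, "cy": cy, "level": level})
    n_per_image = len(model_points)
    for i, lv in enumerate(negative_levels):
        h, w = lv.smoothed.shape
        for _ in range(n_per_image):
            cx, cy = rng.uniform(0, w - 1), rng.uniform(0, h - 1)
            patch = extract_patch(lv.smoothed, (cx, cy))
            vecs.append(hog_descriptors_batch(patch[None])[0])
            rows.append({"label": 0, "image_id": f"neg{i}", "cx": cx, "cy": cy, "level": level})
    table = pd.DataFrame(rows)
    feat = pd.DataFrame(np.array(vecs), columns=[f"f{j}" for j in range(DESCRIPTOR_LEN)])
    return pd.concat([feat, table], axis=1)


def feature_matrix(table: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    cols = [f"f{j}" for j in range(DESCRIPTOR_LEN)]
    return table[cols].to_numpy(), table["label"].to_numpy()


def train_classifier(table: pd.DataFrame, seed: int = 0, C: float = 1.0) -> PatchClassifier:
    """Fit the linear SVM on a labeled descriptor table; deterministic per seed."""
    X, y = feature_matrix(table)
    classes = np.unique(y)
    if len(classes) < 2:
        raise DegenerateTrainingError("training table contains a single class")
    svm = LinearSVC(C=C, random_state=seed, dual=True, max_iter=20000)
    svm.fit(X, y)
    level = int(table["level"].iloc[0]) if "level" in table else 0
    return PatchClassifier(
        level=level,
        weights=svm.coef_.ravel().copy(),
        bias=float(svm.intercept_[0]),
        n_pos=int((y == 1).sum()),
        n_neg=int((y == 0).sum()),
        seed=seed,
    )
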