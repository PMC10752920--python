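"""Coarse-to-fine cascade detection with the trained multi-scale face model.

For each hypothesized face size the image is resized so the face would span
the model's reference size (32 px) at the coarsest scale; every pixel of that
working image is evaluated by the coarse patch classifier at the scale's
model-point offsets, and survivors are confirmed at each finer model scale on
a correspondingly larger working image.  A candidate passing all scales
becomes a square detection whose side is the hypothesized face size.  The
schedule of hypotheses is geometric with step sqrt(2), from the whole image
down to faces of the reference size, and stops when the working image would
fall below the patch size.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.transform import resize

from . import densitymap, descriptors, scalespace
from .descriptors import PATCH_SIZE, PatchClassifier, hog_descriptors_batch
from .scalespace import grid_downsample_at, sigma_at, to_grayscale

REFERENCE_FACE_PX = 32
VOTE_FRACTION = 0.5
_CHUNK = 4096  # descriptor batch size


@dataclass
class ScaleStage:
    level: int
    model_points: list[tuple[float, float]]
    classifier: PatchClassifier


@dataclass
class FaceModel:
    """Ordered coarse-to-fine detection model."""

    stages: list[ScaleStage]  # strictly decreasing level
    reference_face_px: int = REFERENCE_FACE_PX
    patch_size: int = PATCH_SIZE
    vote_fraction: float = VOTE_FRACTION
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        if not self.stages:
            raise ValueError("model needs at least one scale")
        levels = [s.level for s in self.stages]
        if any(a >= b for a, b in zip(levels[1:], levels)):
            raise ValueError("scales must be strictly decreasing (coarse to fine)")
        for s in self.stages:
            if not s.model_points:
                raise ValueError(f"scale {s.level} has no model points")
            if s.classifier is None:
                raise ValueError(f"scale {s.level} has no trained classifier")

    @property
    def scales(self) -> list[int]:
        return [s.level for s in self.stages]

    def face_span(self, level: int) -> float:
        """Face size in working pixels at ``level``'s stage.

        The coarsest stage uses the reference size; finer stages scale it by
        the pyramid's grid ratio, so the face appears at the same resolution
        as the training patches of that level.
        """
        coarse = self.stages[0].level
        return self.reference_face_px * grid_downsample_at(coarse) / grid_downsample_at(level)


@dataclass
class Detection:
    rect: tuple[float, float, float, float]  # x, y, w, h in original pixels
    score: int = 1
    coarsest_confirmed_level: int = 0


class UntrainedModelError(ValueError):
    pass


# ---------------------------------------------------------------------------
# training


def train_face_model(
    face_images,
    negative_images,
    scales: list[int],
    seed: int = 0,
    grid_resolution: int = densitymap.GRID_RESOLUTION,
    reference_face_px: int = REFERENCE_FACE_PX,
    n_levels: int = scalespace.N_LEVELS_DEFAULT,
) -> FaceModel:
    """Build density maps, select model points, and train per-scale classifiers.

    ``scales`` is the coarse-to-fine level list (e.g. [7, 4]).  Feature points
    are the linked scale-space extrema of every face image; positives are
    patches at each scale's model points on the pyramid grid, negatives
    equally many random patches from the negative images.
    """
    scales = sorted(set(scales), reverse=True)
    feature_sets = []
    pos_levels: dict[int, list] = {k: [] for k in scales}
    for img in face_images:
        img = to_grayscale(img)
        levels = scalespace.build_pyramid(img, n_levels)
        pts = scalespace.link_scales([scalespace.detect_extrema(lv) for lv in levels])
        feature_sets.append((pts, img.shape))
        for lv in levels:
            if lv.index in pos_levels:
                pos_levels[lv.index].append(lv)

    neg_levels: dict[int, list] = {k: [] for k in scales}
    for img in negative_images:
        levels = scalespace.build_pyramid(to_grayscale(img), n_levels)
        for lv in levels:
            if lv.index in neg_levels:
                neg_levels[lv.index].append(lv)

    stages = []
    for k in scales:
        pooled = densitymap.accumulate_features(feature_sets, k)
        dmap = densitymap.estimate_density(
            pooled, grid_resolution, level=k, n_images=len(feature_sets)
        )
        points = densitymap.select_model_points(dmap)
        table = descriptors.build_training_set(
            pos_levels[k], neg_levels[k], points, level=k, seed=seed + k
        )
        clf = descriptors.train_classifier(table, seed=seed + k)
        stages.append(ScaleStage(level=k, model_points=points, classifier=clf))
    return FaceModel(
        stages=stages,
        reference_face_px=reference_face_px,
        provenance={
            "n_faces": len(feature_sets),
            "n_negatives": len(neg_levels[scales[0]]),
            "seed": seed,
        },
    )


# ---------------------------------------------------------------------------
# detection


def resize_schedule(
    image_size: tuple[int, int], model: FaceModel, step: float = np.sqrt(2.0)
) -> list[float]:
    """Geometric sequence of resize factors for the face-size hypotheses.

    The first factor shrinks the whole image to the reference face size (the
    whole-image hypothesis); successive factors grow by ``step`` until faces
    of the reference size at native resolution are covered (factor 1).
    Returns an empty list when the image is below the patch size.
    """
    w, h = image_size
    if min(w, h) < model.patch_size:
        return []
    f0 = model.reference_face_px / min(w, h)
    if f0 >= 1.0:
        return [f0]
    factors = []
    f = f0
    while f <= 1.0 + 1e-9:
        factors.append(min(f, 1.0))
        f *= step
    return factors


def _working_image(img: np.ndarray, factor: float, level: int) -> np.ndarray:
    """Resize and blur so the working grid matches the level's training grid."""
    h, w = img.shape
    out_shape = (max(int(round(h * factor)), 1), max(int(round(w * factor)), 1))
    aa_native = max((1.0 / factor - 1.0) / 2.0, 0.0)
    work = resize(img, out_shape, anti_aliasing=aa_native > 0, preserve_range=True)
    target = sigma_at(level) / grid_downsample_at(level)
    extra = np.sqrt(max(target**2 - (aa_native * factor) ** 2, 0.0))
    if extra > 1e-6:
        work = ndimage.gaussian_filter(work, extra, mode="reflect")
    return work


def _stage_offsets(stage: ScaleStage, span: float) -> np.ndarray:
    """Model-point offsets (dy, dx) in working pixels around a candidate center."""
    return np.array(
        [
            (round((my - 0.5) * span), round((mx - 0.5) * span))
            for mx, my in stage.model_points
        ],
        dtype=int,
    )


def _classify_at(
    work: np.ndarray, centers: np.ndarray, stage: ScaleStage, span: float, vote_fraction: float
) -> np.ndarray:
    """Cascade vote at the given candidate centers (rows of (y, x) ints).

    Evaluates one patch per model-point offset per candidate and returns a
    boolean mask of candidates where at least ``vote_fraction`` of the
    patches classify positive.
    """
    offsets = _stage_offsets(stage, span)
    half = PATCH_SIZE // 2
    margin = half + int(np.abs(offsets).max(initial=0))
    pad = np.pad(work, margin, mode="reflect")
    windows = np.lib.stride_tricks.sliding_window_view(pad, (PATCH_SIZE, PATCH_SIZE))
    votes = np.zeros(len(centers), dtype=float)
    for dy, dx in offsets:
        ys = centers[:, 0] + margin + dy - half
        xs = centers[:, 1] + margin + dx - half
        labels = np.empty(len(centers), dtype=int)
        for lo in range(0, len(centers), _CHUNK):
            hi = min(lo + _CHUNK, len(centers))
            patches = windows[ys[lo:hi], xs[lo:hi]]
            desc = hog_descriptors_batch(patches)
            labels[lo:hi] = stage.classifier.classify(desc)
        votes += labels
    return votes >= vote_fraction * len(offsets)


def detect(image: np.ndarray, model: FaceModel) -> list[Detection]:
    """Run the coarse-to-fine cascade over all face-size hypotheses."""
    if not isinstance(model, FaceModel):
        raise UntrainedModelError("detect requires a trained FaceModel")
    img = to_grayscale(image)
    h, w = img.shape
    detections: list[Detection] = []
    coarse = model.stages[0]
    for factor in resize_schedule((w, h), model):
        work_c = _working_image(img, factor, coarse.level)
        hc, wc = work_c.shape
        ys, xs = np.mgrid[0:hc, 0:wc]
        centers = np.column_stack([ys.ravel(), xs.ravel()])
        keep = _classify_at(work_c, centers, coarse, model.face_span(coarse.level), model.vote_fraction)
        centers = centers[keep]
        if len(centers) == 0:
            continue
        # native (y, x) of the surviving candidate centers
        native = (centers + 0.5) / factor - 0.5
        for stage in model.stages[1:]:
            ratio = grid_downsample_at(coarse.level) / grid_downsample_at(stage.level)
            f_fine = factor * ratio
            work_f = _working_image(img, f_fine, stage.level)
            cf = np.rint((native + 0.5) * f_fine - 0.5).astype(int)
            cf[:, 0] = np.clip(cf[:, 0], 0, work_f.shape[0] - 1)
            cf[:, 1] = np.clip(cf[:, 1], 0, work_f.shape[1] - 1)
            keep = _classify_at(work_f, cf, stage, model.face_span(stage.level), model.vote_fraction)
            native = native[keep]
            if len(native) == 0:
                break
        side = model.reference_face_px / factor
        for cy, cx in native:
            rect = _clip_rect((cx - side / 2, cy - side / 2, side, side), w, h)
            if rect is not None:
                detections.append(
                    Detection(rect=rect, score=1, coarsest_confirmed_level=coarse.level)
                )
    return detections


def _clip_rect(rect, w, h, max_loss: float = 0.5):
    x, y, rw, rh = rect
    x0, y0 = max(x, 0.0), max(y, 0.0)
    x1, y1 = min(x + rw, float(w)), min(y + rh, float(h))
    if x1 <= x0 or y1 <= y0:
        return None
    if (x1 - x0) * (y1 - y0) < max_loss * rw * rh:
        return None
    return (x0, y0, x1 - x0, y1 - y0)


def merge_detections(
    detections: list[Detection], iou_merge: float = 0.3, enabled: bool = False
) -> list[Detection]:
    """Greedy duplicate merging; identity unless ``enabled``.

    Detections are visited in descending area order; each unabsorbed
    detection absorbs every remaining one overlapping it with IoU at or above
    ``iou_merge``.  Off by default: the published cascade emits duplicates.
    """
    if not enabled or not detections:
        return list(detections)
    from .evaluation import iou

    order = sorted(
        range(len(detections)),
        key=lambda i: detections[i].rect[2] * detections[i].rect[3],
        reverse=True,
    )
    absorbed = set()
    out = []
    for i in order:
        if i in absorbed:
            continue
        out.append(detections[i])
        for j in order:
            if j != i and j not in absorbed and iou(detections[i].rect, detections[j].rect) >= iou_merge:
                absorbed.add(j)
    return out


# ---------------------------------------------------------------------------
# model archive (versioned JSON container)

ARCHIVE_VERSION = 1


def save_model(path, model: FaceModel) -> None:
    payload = {
        "format": "gazeface-model",
        "version": ARCHIVE_VERSION,
        "reference_face_px": model.reference_face_px,
        "patch_size": model.patch_size,
        "vote_fraction": model.vote_fraction,
        "provenance": model.provenance,
        "stages": [
            {
                "level": s.level,
                "model_points": [list(p) for p in s.model_points],
                "weights": s.classifier.weights.tolist(),
                "bias": s.classifier.bias,
                "n_pos": s.classifier.n_pos,
                "n_neg": s.classifier.n_neg,
                "seed": s.classifier.seed,
            }
            for s in model.stages
        ],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def load_model(path) -> FaceModel:
    with open(path) as fh:
        payload = json.load(fh)
    if payload.get("format") != "gazeface-model":
        raise ValueError("not a gazeface model archive")
    stages = [
        ScaleStage(
            level=s["level"],
            model_points=[tuple(p) for p in s["model_points"]],
            classifier=PatchClassifier(
                level=s["level"],
                weights=np.array(s["weights"]),
                bias=s["bias"],
                n_pos=s["n_pos"],
                n_neg=s["n_neg"],
                seed=s["seed"],
            ),
        )
        for s in payload["stages"]
    ]
    return FaceModel(
        stages=stages,
        reference_face_px=payload["reference_face_px"],
        patch_size=payload["patch_size"],
        vote_fraction=payload["vote_fraction"],
        provenance=payload.get("provenance", {}),
    )
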