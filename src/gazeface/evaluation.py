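"""IoU-based detection scoring: greedy matching, precision/recall curves.

Detections and ground truths are axis-aligned rectangles (x, y, w, h) in a
half-open pixel convention.  A detection is a true positive when it is the
(one-to-one, greedy, descending-IoU) match of a truth with IoU at or above
the threshold (0.5 by default); duplicate detections of an already-matched
face count as false positives.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

IOU_THRESHOLD = 0.5

Rect = tuple[float, float, float, float]


@dataclass
class EvaluationResult:
    tp: int
    fp: int
    fn: int
    iou_threshold: float
    curves: list[tuple[float, float | None, float | None]] = field(default_factory=list)

    @property
    def precision(self) -> float | None:
        return self.tp / (self.tp + self.fp) if (self.tp + self.fp) > 0 else None

    @property
    def recall(self) -> float | None:
        return self.tp / (self.tp + self.fn) if (self.tp + self.fn) > 0 else None


def iou(a: Rect, b: Rect) -> float:
    """Intersection over union of two rectangles."""
    ax, ay, aw, ah = a
    bx, by, bw, bh = b
    if aw <= 0 or ah <= 0 or bw <= 0 or bh <= 0:
        raise ValueError("degenerate rectangle")
    ix = max(0.0, min(ax + aw, bx + bw) - max(ax, bx))
    iy = max(0.0, min(ay + ah, by + bh) - max(ay, by))
    inter = ix * iy
    union = aw * ah + bw * bh - inter
    return inter / union


def match_detections(
    detections: list[Rect], truths: list[Rect], threshold: float = IOU_THRESHOLD
) -> EvaluationResult:
    """Greedy one-to-one matching in descending IoU order.

    Pairs with IoU >= threshold are matched greedily; each truth and each
    detection participates in at most one match.  Matched detections are TP,
    the rest FP; unmatched truths are FN.
    """
    pairs = []
    for di, d in enumerate(detections):
        for ti, t in enumerate(truths):
            v = iou(d, t)
            if v >= threshold:
                pairs.append((v, di, ti))
    pairs.sort(key=lambda p: (-p[0], p[1], p[2]))
    used_d, used_t = set(), set()
    tp = 0
    for v, di, ti in pairs:
        if di in used_d or ti in used_t:
            continue
        used_d.add(di)
        used_t.add(ti)
        tp += 1
    return EvaluationResult(
        tp=tp, fp=len(detections) - tp, fn=len(truths) - tp, iou_threshold=threshold
    )


def pr_curve(
    detections_per_image: list[list[Rect]],
    truths_per_image: list[list[Rect]],
    thresholds: np.ndarray | None = None,
) -> pd.DataFrame:
    """Aggregate precision/recall over images for each IoU threshold."""
    if len(detections_per_image) != len(truths_per_image):
        raise ValueError("detections and truths must cover the same images")
    if len(detections_per_image) == 0:
        raise ValueError("need at least one image")
    if thresholds is None:
        thresholds = np.linspace(0.0, 1.0, 21)
    rows = []
    for t in thresholds:
        tp = fp = fn = 0
        for dets, truths in zip(detections_per_image, truths_per_image):
            r = match_detections(dets, truths, threshold=float(t))
            tp, fp, fn = tp + r.tp, fp + r.fp, fn + r.fn
        rows.append(
            {
                "threshold": float(t),
                "tp": tp,
                "fp": fp,
                "fn": fn,
                "precision": tp / (tp + fp) if tp + fp else None,
                "recall": tp / (tp + fn) if tp + fn else None,
            }
        )
    return pd.DataFrame(rows)


def ellipse_to_rect(ellipse: tuple[float, float, float, float, float]) -> Rect:
    """Axis-aligned bounding rectangle of a rotated ellipse.

    ``ellipse`` is (major_radius, minor_radius, angle_rad, cx, cy) — the
    annotation convention used by face benchmarks that mark faces as
    ellipses, where the major axis is vertical at angle 0.
    """
    ra, rb, theta, cx, cy = ellipse
    if ra <= 0 or rb <= 0:
        raise ValueError("ellipse radii must be positive")
    half_w = np.sqrt(ra**2 * np.sin(theta) ** 2 + rb**2 * np.cos(theta) ** 2)
    half_h = np.sqrt(ra**2 * np.cos(theta) ** 2 + rb**2 * np.sin(theta) ** 2)
    return (cx - half_w, cy - half_h, 2 * half_w, 2 * half_h)


def read_fddb_annotations(path) -> dict[str, list[Rect]]:
    """Read an FDDB-style annotation list into rectangles per image.

    Format: image name line, face count line, one face per line.  Lines with
    6 numeric fields are ellipses (major minor angle cx cy score) and are
    converted to bounding rectangles; 4- and 5-field lines are rectangles
    (left top width height [score]).
    """
    out: dict[str, list[Rect]] = {}
    with open(path) as fh:
        lines = [ln.strip() for ln in fh if ln.strip()]
    i = 0
    while i < len(lines):
        name = lines[i]
        count = int(lines[i + 1])
        i += 2
        rects = []
        for _ in range(count):
            fields = [float(v) for v in lines[i].split()]
            i += 1
            if len(fields) >= 6:
                rects.append(ellipse_to_rect(tuple(fields[:5])))
            else:
                rects.append(tuple(fields[:4]))
        out[name] = rects
    return out


def write_fddb_detections(path, detections_per_image: dict[str, list]) -> None:
    """Write detections in the FDDB detection-file dialect."""
    with open(path, "w") as fh:
        for name, dets in detections_per_image.items():
            fh.write(f"{name}\n{len(dets)}\n")
            for d in dets:
                x, y, w, h = d.rect if hasattr(d, "rect") else d[:4]
                score = d.score if hasattr(d, "score") else 1
                fh.write(f"{x:.2f} {y:.2f} {w:.2f} {h:.2f} {score}\n")
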