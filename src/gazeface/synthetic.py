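"""Procedural fixtures: face images, clutter negatives, scenes, and fixations.

The generators emulate the data regime the model is designed for: aligned
frontal face photographs (an oval face with dark eye/nostril/mouth blobs on a
textured background), cluttered non-face images, multi-face scenes with
rectangular ground truth, and per-observer gaze sequences that concentrate on
facial landmarks with a coarse-to-fine progression over the fixation index.
All generators are pure functions of their spec and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

DEFAULT_CANVAS = 250  # training fixture side, px


@dataclass(frozen=True)
class SyntheticFaceSpec:
    """Parameters of one synthetic face image.

    Landmark positions are in canvas-normalized coordinates; blob radii are
    Gaussian standard deviations in pixels at the default 250-px canvas and
    scale with the canvas.
    """

    canvas: int = DEFAULT_CANVAS
    face_center: tuple[float, float] = (0.5, 0.51)
    face_axes: tuple[float, float] = (0.40, 0.49)  # half-axes, normalized
    landmarks: dict = field(
        default_factory=lambda: {
            "left_eye": (0.35, 0.40),
            "right_eye": (0.65, 0.40),
            "nose": (0.50, 0.57),
            "mouth": (0.50, 0.72),
        }
    )
    blob_sigma: dict = field(
        default_factory=lambda: {
            "left_eye": 4.0,
            "right_eye": 4.0,
            "nose": 3.0,
            "mouth": 4.5,
        }
    )
    blob_contrast: dict = field(
        default_factory=lambda: {
            "left_eye": 0.55,
            "right_eye": 0.55,
            "nose": 0.35,
            "mouth": 0.50,
        }
    )
    mouth_half_width: float = 0.09  # mouth is a horizontal bar of blobs
    # fine facial microstructure (pupils, eye corners, nostrils, lip corners):
    # small dark dots that give the fine pyramid levels repeated features at
    # the landmarks, as real faces do
    micro_sigma: float = 1.4  # px at the default canvas
    micro_contrast: float = 0.30
    jitter: float = 0.008  # landmark position jitter, normalized units
    # identity variation of the head itself: real portrait sets vary in head
    # size and placement, so the head contour must not repeat pixel-exactly
    # across images (a frozen contour would build up spurious density ridges)
    head_center_jitter: float = 0.010  # normalized units
    head_axes_jitter: float = 0.030  # relative half-axis variation
    noise: float = 0.012  # texture std (spatially correlated, photo-like)
    noise_correlation: float = 3.2  # texture correlation length, px
    n_background_shapes: int = 3  # soft clutter blobs behind the face
    seed: int = 0


def _check_spec(spec: SyntheticFaceSpec) -> None:
    cx, cy = spec.face_center
    ax, ay = spec.face_axes
    for name, (lx, ly) in spec.landmarks.items():
        if ((lx - cx) / ax) ** 2 + ((ly - cy) / ay) ** 2 > 1.0:
            raise ValueError(f"landmark {name!r} lies outside the face oval")


def generate_face_image(spec: SyntheticFaceSpec | None = None, seed: int | None = None):
    """Render one aligned frontal face.

    Returns ``(image, truth)`` where ``image`` is a float array in [0, 1] and
    ``truth`` has the realized landmark positions (pixel coordinates), the
    face-oval bounding box ``(x, y, w, h)`` and the canvas size.
    """
    spec = spec or SyntheticFaceSpec()
    if seed is not None:
        spec = SyntheticFaceSpec(**{**spec.__dict__, "seed": seed})
    _check_spec(spec)
    rng = np.random.default_rng(spec.seed)
    n = spec.canvas
    yy, xx = np.mgrid[0:n, 0:n].astype(np.float64)

    hjx, hjy = rng.normal(0.0, spec.head_center_jitter, 2)
    sax, say = 1.0 + rng.normal(0.0, spec.head_axes_jitter, 2)
    cx, cy = (spec.face_center[0] + hjx) * n, (spec.face_center[1] + hjy) * n
    ax, ay = spec.face_axes[0] * sax * n, spec.face_axes[1] * say * n

    # background: mid gray, slow illumination gradient, a few soft clutter blobs
    img = 0.35 + 0.05 * (xx / n - 0.5) + 0.03 * (yy / n - 0.5)
    for _ in range(spec.n_background_shapes):
        bx, by = rng.uniform(0, n, 2)
        bs = rng.uniform(n / 8, n / 3)
        img += rng.uniform(-0.08, 0.08) * np.exp(
            -((xx - bx) ** 2 + (yy - by) ** 2) / (2 * bs**2)
        )
    # face oval: brighter skin, soft edge (a hard outline would put spurious
    # fine-scale structure on the head contour)
    r2 = ((xx - cx) / ax) ** 2 + ((yy - cy) / ay) ** 2
    oval = 1.0 / (1.0 + np.exp((r2 - 1.0) * 12.0))
    img = img * (1 - oval) + 0.72 * oval

    scale = n / DEFAULT_CANVAS
    truth_landmarks = {}
    for name, (lx, ly) in spec.landmarks.items():
        jx, jy = rng.normal(0.0, spec.jitter, 2)
        px, py = (lx + jx) * n, (ly + jy) * n
        truth_landmarks[name] = (px, py)
        s = spec.blob_sigma[name] * scale
        c = spec.blob_contrast[name]
        if name == "mouth":
            # horizontal bar: superpose blobs along the mouth line
            offsets = np.linspace(-spec.mouth_half_width, spec.mouth_half_width, 5) * n
            for dx in offsets:
                d2 = (xx - px - dx) ** 2 + (yy - py) ** 2
                img -= c * 0.55 * np.exp(-d2 / (2 * s**2))
        else:
            d2 = (xx - px) ** 2 + (yy - py) ** 2
            img -= c * np.exp(-d2 / (2 * s**2))

    # facial detail at every structure size, as in real faces: lash and
    # lip-line specks (~1 px), pupils / eye corners / mouth corners (~1.4 px),
    # nostrils and brows (~2 px), and broad bright regions (cheeks, forehead,
    # chin, ~5-8 px).  Each detail is offset from its landmark so the pyramid
    # keeps it as a feature of its own size instead of absorbing it into the
    # landmark blob, which is what distinguishes a face from flat texture at
    # every scale.
    ms = spec.micro_sigma * scale
    mc = spec.micro_contrast
    details = []  # (x, y, sigma_px, signed amplitude)
    for eye in ("left_eye", "right_eye"):
        ex, ey = truth_landmarks[eye]
        inward = 0.045 * n if eye == "left_eye" else -0.045 * n
        details += [
            (ex, ey - 0.035 * n, 1.0 * scale, -0.18),  # lash line
            (ex, ey, ms, -mc),  # pupil
            (ex + inward, ey + 0.01 * n, ms, -mc),  # inner corner
            (ex - inward, ey + 0.005 * n, 2.0 * scale, -0.22),  # outer corner
            (ex, ey - 0.070 * n, 2.0 * scale, -0.30),  # brow
        ]
    nx, ny = truth_landmarks["nose"]
    details += [
        (nx - 0.030 * n, ny + 0.025 * n, 2.0 * scale, -0.28),  # nostrils
        (nx + 0.030 * n, ny + 0.025 * n, 2.0 * scale, -0.28),
    ]
    mx, my = truth_landmarks["mouth"]
    details += [
        (mx - spec.mouth_half_width * n, my, ms, -mc),  # mouth corners
        (mx + spec.mouth_half_width * n, my, ms, -mc),
        (mx - 0.0225 * n, my - 0.018 * n, 1.0 * scale, -0.18),  # lip line
        (mx + 0.0225 * n, my - 0.018 * n, 1.0 * scale, -0.18),
        (mx, my + 0.028 * n, 2.0 * scale, -0.22),  # lower-lip shadow
    ]
    # bright regions (coarse structure; positive amplitude = brighter)
    details += [
        (cx - 0.17 * n * sax, cy + 0.09 * n * say, 5.5 * scale, +0.10),  # cheeks
        (cx + 0.17 * n * sax, cy + 0.09 * n * say, 5.5 * scale, +0.10),
        (cx, cy - 0.24 * n * say, 8.0 * scale, +0.10),  # forehead
        (cx, cy + 0.33 * n * say, 6.0 * scale, +0.08),  # chin
    ]
    for px, py, s, a in details:
        d2 = (xx - px) ** 2 + (yy - py) ** 2
        img += a * np.exp(-d2 / (2 * s**2))

    if spec.noise > 0:
        # spatially correlated texture: fine detail on the face (skin, hair),
        # heavily blurred background, emulating a portrait crop; iid pixel
        # noise would litter the fine scales with extrema in a way
        # photographs do not
        from scipy.ndimage import gaussian_filter

        fine = gaussian_filter(rng.normal(0.0, 1.0, img.shape), spec.noise_correlation)
        fine *= spec.noise / max(fine.std(), 1e-12)
        coarse = gaussian_filter(rng.normal(0.0, 1.0, img.shape), 4 * spec.noise_correlation)
        coarse *= 0.7 * spec.noise / max(coarse.std(), 1e-12)
        img = img + fine * oval + coarse * (1 - oval)
    img = np.clip(img, 0.0, 1.0)

    bbox = (cx - ax, cy - ay, 2 * ax, 2 * ay)
    truth = {"landmarks": truth_landmarks, "bbox": bbox, "canvas": n}
    return img, truth


def generate_face_set(n_images: int, canvas: int = DEFAULT_CANVAS, seed: int = 0):
    """A list of ``(image, truth)`` pairs with independent per-image seeds."""
    rng = np.random.default_rng(seed)
    seeds = rng.integers(0, 2**31 - 1, size=n_images)
    return [generate_face_image(SyntheticFaceSpec(canvas=canvas, seed=int(s))) for s in seeds]


def generate_negative_image(
    size: int | tuple[int, int] = DEFAULT_CANVAS,
    n_shapes: int = 25,
    noise: float = 0.04,
    mean_range: tuple[float, float] = (0.3, 0.6),
    seed: int = 0,
) -> np.ndarray:
    """Clutter image: random soft ellipses, bars and noise, no landmark triad."""
    rng = np.random.default_rng(seed)
    h, w = (size, size) if isinstance(size, int) else size
    yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)
    img = np.full((h, w), rng.uniform(*mean_range))
    for _ in range(n_shapes):
        cx, cy = rng.uniform(0, w), rng.uniform(0, h)
        sx, sy = rng.uniform(2, w / 4), rng.uniform(2, h / 4)
        theta = rng.uniform(0, np.pi)
        amp = rng.uniform(-0.35, 0.35)
        xr = (xx - cx) * np.cos(theta) + (yy - cy) * np.sin(theta)
        yr = -(xx - cx) * np.sin(theta) + (yy - cy) * np.cos(theta)
        img += amp * np.exp(-(xr**2 / (2 * sx**2) + yr**2 / (2 * sy**2)))
    if noise > 0:
        from scipy.ndimage import gaussian_filter

        tex = gaussian_filter(rng.normal(0.0, 1.0, img.shape), 1.5)
        img += tex * (noise / max(tex.std(), 1e-12))
    return np.clip(img, 0.0, 1.0)


def generate_scene(
    face_placements: list[dict] | None,
    canvas: tuple[int, int] = (240, 240),
    seed: int = 0,
):
    """Composite faces onto clutter; return ``(image, annotations)``.

    Each placement is ``{"x": left, "y": top, "size": side_px}`` for the
    pasted face canvas.  Annotations are ground-truth face rectangles
    ``(x, y, w, h)`` in scene pixels — the pasted face canvas, i.e. the same
    framing convention the training images use (face plus its portrait
    margin), so detector output and ground truth share one box convention.
    """
    rng = np.random.default_rng(seed)
    h, w = canvas
    scene = generate_negative_image((h, w), n_shapes=12, noise=0.02, seed=int(rng.integers(2**31 - 1)))
    annotations = []
    for placement in face_placements or []:
        side = int(placement["size"])
        x0, y0 = int(placement["x"]), int(placement["y"])
        face, truth = generate_face_image(
            SyntheticFaceSpec(canvas=side, seed=int(rng.integers(2**31 - 1)))
        )
        x1, y1 = min(x0 + side, w), min(y0 + side, h)
        scene[y0:y1, x0:x1] = face[: y1 - y0, : x1 - x0]
        annotations.append((float(x0), float(y0), float(x1 - x0), float(y1 - y0)))
    return scene, annotations


@dataclass(frozen=True)
class ObserverModel:
    """A simulated observer: landmark attraction shifting coarse-to-fine.

    Early fixations are drawn broadly around the face center; later fixations
    concentrate on eyes/nose/mouth with shrinking noise, mimicking the
    coarse-to-fine gaze pattern reported for natural viewing.
    """

    observer_id: str = "obs0"
    coarse_sigma: float = 0.10  # fixation scatter at index 1, normalized units
    fine_sigma: float = 0.03  # scatter at the last index
    bias: tuple[float, float] = (0.0, 0.0)  # idiosyncratic offset
    seed: int = 0

    def index_weights(self, i: int, n_fix: int, landmark_names: list[str]) -> np.ndarray:
        """Mixture weights over [center] + landmarks at fixation index i."""
        frac = (i - 1) / max(n_fix - 1, 1)  # 0 = first fixation, 1 = last
        w_center = max(1.0 - 1.6 * frac, 0.05)
        w_land = (1.0 - w_center) / len(landmark_names)
        w = np.array([w_center] + [w_land] * len(landmark_names))
        return w / w.sum()


def generate_fixations(
    landmarks: dict,
    observers: list[ObserverModel],
    image_ids: list[str],
    n_fixations: int = 12,
    seed: int = 0,
) -> "pd.DataFrame":
    """Simulated fixation records over a set of images.

    ``landmarks`` maps name -> (x, y) in the normalized face frame.  Returns a
    DataFrame with columns observer_id, image_id, fixation_index, x, y.
    """
    import pandas as pd

    names = list(landmarks)
    centers = np.array([[0.5, 0.55]] + [list(landmarks[k]) for k in names])
    rows = []
    for obs in observers:
        rng = np.random.default_rng((seed, obs.seed))
        for image_id in image_ids:
            for i in range(1, n_fixations + 1):
                frac = (i - 1) / max(n_fixations - 1, 1)
                sig = obs.coarse_sigma * (1 - frac) + obs.fine_sigma * frac
                wts = obs.index_weights(i, n_fixations, names)
                comp = rng.choice(len(centers), p=wts)
                x, y = centers[comp] + np.array(obs.bias) + rng.normal(0.0, sig, 2)
                rows.append(
                    {
                        "observer_id": obs.observer_id,
                        "image_id": image_id,
                        "fixation_index": i,
                        "x": float(np.clip(x, 0.0, 1.0)),
                        "y": float(np.clip(y, 0.0, 1.0)),
                    }
                )
    return pd.DataFrame(rows)


def default_observers(n_observers: int = 20, seed: int = 0) -> list[ObserverModel]:
    """A cohort of observers with idiosyncratic biases and scatter."""
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n_observers):
        out.append(
            ObserverModel(
                observer_id=f"obs{i:02d}",
                coarse_sigma=float(rng.uniform(0.08, 0.13)),
                fine_sigma=float(rng.uniform(0.02, 0.045)),
                bias=(float(rng.normal(0, 0.015)), float(rng.normal(0, 0.015))),
                seed=int(rng.integers(2**31 - 1)),
            )
        )
    return out
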