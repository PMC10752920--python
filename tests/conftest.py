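"""Shared fixtures: synthetic image sets and small trained models.

Everything is generated at runtime from seeds; no stored binary fixtures.
Session-scoped fixtures keep the expensive generation/extraction steps shared
across test modules.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from gazeface import detector, scalespace, synthetic

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    max_examples=60,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def face_set_60():
    """60 synthetic training faces (images only), fixed seed."""
    return [img for img, _ in synthetic.generate_face_set(60, seed=7)]


@pytest.fixture(scope="session")
def feature_sets_60(face_set_60):
    """Linked scale-space features of the 60-face set, with image shapes."""
    return [(scalespace.extract_features(img), img.shape) for img in face_set_60]


@pytest.fixture(scope="session")
def negatives_30():
    rng = np.random.default_rng(11)
    return [
        synthetic.generate_negative_image(seed=int(rng.integers(2**31 - 1)))
        for _ in range(30)
    ]


@pytest.fixture(scope="session")
def small_model_3scale(negatives_30):
    """A three-scale model trained on a small face set (for detector tests)."""
    faces = [img for img, _ in synthetic.generate_face_set(60, seed=11)]
    return detector.train_face_model(faces, negatives_30, [7, 4, 1], seed=3)


@pytest.fixture(scope="session")
def small_model(small_model_3scale):
    """The two-scale (coarse, mid) restriction of the small model."""
    return detector.FaceModel(
        stages=small_model_3scale.stages[:2],
        reference_face_px=small_model_3scale.reference_face_px,
    )


@pytest.fixture(scope="session")
def face_set_300():
    """The full-size training set used by the acceptance suite."""
    return [img for img, _ in synthetic.generate_face_set(300, seed=1)]


@pytest.fixture(scope="session")
def negatives_100():
    rng = np.random.default_rng(1)
    return [
        synthetic.generate_negative_image(seed=int(rng.integers(2**31 - 1)))
        for _ in range(100)
    ]


@pytest.fixture(scope="session")
def trained_model_300(face_set_300, negatives_100):
    """Two-scale detection model trained at full fixture size."""
    return detector.train_face_model(face_set_300, negatives_100, [7, 4], seed=1)


def gaussian_blob_image(n, cx, cy, width, contrast=0.6, background=0.8):
    """Dark Gaussian blob test image (shared helper)."""
    yy, xx = np.mgrid[0:n, 0:n].astype(float)
    return background - contrast * np.exp(
        -((xx - cx) ** 2 + (yy - cy) ** 2) / (2.0 * width**2)
    )
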