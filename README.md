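# gazeface

Human-attention-guided multi-scale face modeling and detection.

`gazeface` builds a face model from two ingredients: **scale-space blob
features** pooled over many aligned face images, and **human gaze fixations**
that decide which spatial scales the model should use.  The result is a small
set of per-scale "model points" (in practice: eyes, nose, mouth) with a
linear patch classifier per scale, applied as a coarse-to-fine cascade
detector.

## The idea

1. **Features.**  Each face image is embedded in a ten-level Gaussian scale
   space (sigma = 1 … 16·sqrt(2), doubling every two levels, grids decimated
   every two levels).  Blobs are extrema of the scale-normalized Laplacian,
   filtered by Hessian definiteness and linked across scales so every
   physical blob appears at exactly one level.
2. **Density maps.**  Per level, the normalized blob positions of all
   training faces are pooled into a binned Gaussian KDE on a 128×128 grid.
   As faces accumulate, successive maps converge (Bray–Curtis similarity
   above 0.99 past 200 images); the strong local maxima of a converged map
   (≥ 70% of its peak) are that level's model points.
3. **Scale selection from gaze.**  Fixations pooled by ordinal index are
   clustered (k-means, Davies–Bouldin choice of k) and compared with each
   level's feature clusters: a level scores the mean distance from its
   feature cluster centers to the nearest fixation cluster centers.  The
   levels at local minima of that profile — the scales whose features people
   actually look at — become the model scales.
4. **Detection.**  A linear SVM per selected scale classifies 25×25 HOG
   patches (3×3 cells × 16 orientation bins = 144 components) at the model
   points.  Detection runs coarse-to-fine over a sqrt(2) pyramid of
   face-size hypotheses: the coarse scale votes at every pixel, finer scales
   confirm the survivors at proportionally higher resolution.

All data used by the tests is synthetic and regenerated from seeds at
runtime: parametric portrait faces with multi-scale landmark detail, clutter
negatives, composite scenes, and a stylized coarse-to-fine fixation
simulator.  See [docs/methods.md](docs/methods.md) for models, parameters,
numerical choices, and the generator's limitations.

## Worked example

```python
import numpy as np
from gazeface import synthetic, scalespace, densitymap, detector, evaluation

# 1. generate training data
faces = [img for img, _ in synthetic.generate_face_set(60, seed=7)]
rng = np.random.default_rng(11)
negatives = [synthetic.generate_negative_image(seed=int(rng.integers(2**31 - 1)))
             for _ in range(30)]

# 2. inspect the level-4 feature density map
sets = [(scalespace.extract_features(img), img.shape) for img in faces]
pooled = densitymap.accumulate_features(sets, level=4)
dmap = densitymap.estimate_density(pooled, level=4, n_images=len(faces))
points = densitymap.select_model_points(dmap)
print(f"level 4: {len(pooled)} pooled feature points, "
      f"{len(points)} model points:")
for x, y in points:
    print(f"  ({x:.3f}, {y:.3f})")

# 3. train a two-scale model and detect in a cluttered scene
model = detector.train_face_model(faces, negatives, scales=[7, 4], seed=3)
scene, truths = synthetic.generate_scene(
    [{"x": 55, "y": 40, "size": 120}], canvas=(200, 200), seed=31)
dets = detector.merge_detections(detector.detect(scene, model), enabled=True)
result = evaluation.match_detections([d.rect for d in dets], truths)
print(f"\ntruth box:     {truths[0]}")
best = max(dets, key=lambda d: evaluation.iou(d.rect, truths[0]))
print(f"best detection: ({best.rect[0]:.1f}, {best.rect[1]:.1f}, "
      f"{best.rect[2]:.1f}, {best.rect[3]:.1f})")
print(f"IoU = {evaluation.iou(best.rect, truths[0]):.3f}   "
      f"tp={result.tp} fp={result.fp} fn={result.fn}")
```

Output (exact, seeds fixed):

```
level 4: 7856 pooled feature points, 3 model points:
  (0.652, 0.395)
  (0.348, 0.402)
  (0.496, 0.574)

truth box:     (55.0, 40.0, 120.0, 120.0)
best detection: (41.5, 28.2, 141.4, 141.4)
IoU = 0.720   tp=1 fp=0 fn=0
```

The three level-4 model points are the right eye, the left eye and the nose
— recovered from pooled blob statistics alone, with no labels beyond "this
is a face image".

## Command-line interface

The same pipeline is available as a CLI (`gazeface --help`):

```bash
gazeface synth --out-dir data --n-faces 300 --n-negatives 100 --seed 0
gazeface build-density --faces-dir data/faces --level 4 \
    --out map4.npz --heatmap map4.png
gazeface select-scales --faces-dir data/faces --fixations data/fixations.csv \
    --n-rep 100 --out profile.csv
gazeface train --faces-dir data/faces --negatives-dir data/negatives \
    --scales 7,4 --out model.json
gazeface detect --model model.json --images-dir data/scenes --merge \
    --out detections.txt
gazeface evaluate --detections detections.txt \
    --annotations data/scenes/annotations.txt --out pr.csv
```

Models are versioned JSON archives (text, portable); annotations and
detections use a plain name/count/boxes text dialect compatible with
ellipse-style face-benchmark lists.

## Package layout

```
src/gazeface/
  scalespace.py       pyramid, Laplacian blobs, scale linking, feature CSV
  densitymap.py       binned KDE maps, similarity, convergence, model points
  descriptors.py      25x25 HOG descriptors, per-scale linear SVM
  scale_selection.py  fixation partitioning, clustering, d_k profile, minima
  detector.py         training, coarse-to-fine cascade, model archive
  evaluation.py       IoU matching, PR curves, annotation I/O
  synthetic.py        face/negative/scene generators, fixation simulator
  cli.py              synth / build-density / select-scales / train / detect / evaluate
docs/methods.md       models, parameters, numerics, generator limitations
scripts/acceptance.py standalone convergence check
tests/                unit, property (hypothesis) and acceptance tests
```
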