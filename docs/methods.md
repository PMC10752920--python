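# Methods

This document records the models, parameter choices and numerical decisions
behind `gazeface`, and the known limitations of the bundled synthetic data
generator.

## 1. Scale-space pyramid (`gazeface.scalespace`)

Images are converted to grayscale luma (weights 0.299, 0.587, 0.114) and
embedded in a ten-level Gaussian scale space with

> sigma_k = sqrt(2^(k-1)),  k = 1 … 10,

so sigma runs from 1 px to 16·sqrt(2) px and doubles every two levels.  The
working grid is decimated by 2 (via 2×2 area averaging) every two levels:
levels 1–2 use the native grid, 3–4 half resolution, and so on.  Images
smaller than 25 px on a side are rejected.

**Incremental smoothing with variance bookkeeping.**  Each level is produced
from the previous one with an incremental Gaussian blur whose variance is the
difference of the target and the accumulated variance.  The 2×2 area average
itself acts as a small blur; its variance, 0.25·ds² in native pixels (ds is
the decimation step), is added to the accumulated variance so downsampling is
never double-counted.  On band-limited images the pyramid agrees with direct
convolution at the corresponding sigma to within ~0.1% of the dynamic range
(tested).

**Blob detection.**  Blobs are extrema of the scale-normalized Laplacian
t·(L_xx + L_yy) with t = sigma².  The finite-difference Laplacian stencil
underestimates the continuous operator at small sigma-per-grid-step; each
level's response is multiplied by the analytic gain factor
1/(2s²(1−exp(−1/(2s²)))), with s² = 2(sigma_k/d_k)², which equalizes the peak
response of an ideally matched blob across levels.  Extrema must be strict
over their 8-neighborhood; exact plateaus are collapsed to their centroid.
A Hessian positive/negative-definiteness filter (det > 0 with the matching
trace sign) removes edge and saddle responses.  Dark blobs are positive
maxima, bright blobs negative minima; grid coordinates are mapped back to
native pixels at the cell centers, x_native = x_grid·ds + (ds−1)/2.

**Scale linking.**  The same physical blob responds over several adjacent
levels.  Points of equal polarity at neighboring levels within a radius of
2·sigma(coarser level) are chained (union-find over a KD-tree); each chain
keeps only its strongest member.  Consequently every blob appears at exactly
one level of the linked feature set — which is why the synthetic generator
has to provide repeated structure separately at every fine scale
(section 7).

## 2. Per-scale feature density maps (`gazeface.densitymap`)

Feature positions are normalized by the image size into the unit square and
pooled over all training faces per level.  The spatial density is a binned
Gaussian KDE on a fixed 128×128 grid:

* Points are deposited with **linear (bilinear) binning**: each point's unit
  mass is split over the four nearest cell centers.  Plain hard binning left
  a half-cell discretization error that dominated the mirror-symmetry error
  budget of the fine-level maps; bilinear splitting removes most of it.
* The histogram is smoothed with a Gaussian whose bandwidth is **Scott's rule
  capped at two grid cells** (2/128).  Scott's rule measures the global
  spread of the pooled points — the width of the whole face — and on large
  samples oversmooths the strongly multimodal structure (eyes, nostrils,
  mouth corners) into a single plateau; the cap resolves that structure
  while staying smooth at the working resolution.
* The result is renormalized to integrate to 1, which also compensates mass
  truncated at the frame boundary.

**Map similarity** uses two indices on the flattened, normalized grids: the
Bray–Curtis similarity 1 − Σ|p−q| / Σ(p+q), and 1 − JSD with base-2
logarithms (so the divergence is bounded by 1).  Both are symmetric, lie in
[0, 1], and equal 1 iff the maps coincide.  A convergence curve evaluates
the similarity between the maps at N and N+1 pooled images, starting at
N = 25.

**Model points** of a level are the local maxima of its map reaching at
least 70% of the global maximum (strict 8-neighborhood, plateau centroids,
the global maximum always included).

## 3. Patch descriptors and classifiers (`gazeface.descriptors`)

Each candidate location is described by a 25×25 patch: gradients by central
differences, unsigned orientation over [0°, 180°) in 16 bins, magnitude
weighting, 3×3 cell partition, concatenation to 144 components, L2
normalization with epsilon 1e−6 (gradient-free patches map to the zero
vector).  The descriptor is invariant to affine intensity changes and
exactly equivariant to 90° rotations (cell grid rotates, bins roll by 8),
both of which are tested.

Per scale, a linear SVM (C = 1, seeded, hard {0, 1} output) separates
descriptors taken at the scale's model points on face images from
descriptors at random positions in non-face images (equal counts per image).
Weights and bias are stored in a versioned JSON archive, so the model file
is text and portable.

## 4. Fixation-guided scale selection (`gazeface.scale_selection`)

Fixations are pooled by ordinal index (1st, 2nd, …, up to 12) over observers
and images.  Each index set, and each scale's pooled feature points, is
clustered by k-means (10 restarts) with the cluster count k ∈ [1, 7] chosen
by the Davies–Bouldin index; since that index is undefined at k = 1, the
single-cluster solution is used only when the best multi-cluster fit scores
worse than 1.5 (or no multi-cluster fit is feasible).

A scale k is scored by d_k: the mean distance from each of its feature
cluster centers to the nearest fixation cluster center, averaged over
fixation indices, then over independent clustering repetitions (fresh seeds
per repetition; the spread over repetitions is reported).  The **selected
scales are the local minima** of the d_k profile — interior levels strictly
below both neighbors, endpoints strictly below their single neighbor —
returned coarse-to-fine.  Example: d = [5, 3, 4, 2, 3] over levels 1–5
selects levels 4 and 2.

## 5. Coarse-to-fine detection (`gazeface.detector`)

The trained model is an ordered list of scale stages (strictly decreasing
level), each holding its model points and patch classifier, plus a reference
face size of 32 px.

**Hypothesis schedule.**  Face-size hypotheses form a geometric sequence of
resize factors with step sqrt(2), from 32/min(w, h) (whole-image face) up to
factor 1 (reference-size faces at native resolution).

**Stage evaluation.**  For each factor the image is resized and blurred so
the working grid matches the stage's training grid (the anti-alias blur
applied by the resize is subtracted in variance from the target blur).  At
the coarse stage every pixel is a candidate center; the stage evaluates one
25×25 patch per model point, at offsets scaled by the face span, and keeps
centers where at least 50% of the patches classify positive.  Finer stages
re-evaluate the survivors on a working image larger by the **grid ratio**
between the stages' pyramid levels (e.g. level 7 → level 4 is 8/2 = 4×), so
the face appears at the resolution the finer classifier was trained on.

**Output framing.**  A surviving candidate becomes a square detection of
side 32/factor centered at the candidate — the same framing as the training
canvas (face plus its portrait margin).  The synthetic scene ground truth
uses the identical convention (the pasted face canvas), so detector output
and annotation share one box convention; mixing conventions (e.g. a tight
face-oval box versus the canvas square) puts correct detections near the
IoU = 0.5 boundary purely through the sqrt(2) size quantization.  An
optional greedy merge (largest-first, absorbing IoU ≥ 0.3) collapses
duplicate detections; it is off by default because the raw cascade emits
duplicates by design.

## 6. Evaluation (`gazeface.evaluation`)

Rectangles are (x, y, w, h) in a half-open pixel convention.  Matching is
greedy in descending IoU with one-to-one use of detections and truths at
threshold 0.5; matched detections are TP, the rest FP, unmatched truths FN,
so tp+fp = detections and tp+fn = truths always hold.  Greedy matching is a
heuristic: on random small instances it attains the exhaustive optimum in
>99% of cases and never exceeds it (tested against an optimal-assignment
oracle; rare suboptimal instances are logged as warnings).  Precision is
undefined (None) when there are no detections.  PR curves sweep the IoU
threshold over 21 points in [0, 1].  Ellipse annotations (major, minor,
angle, cx, cy; major axis vertical at angle 0) are converted to axis-aligned
bounding boxes with half-extents sqrt(ra²sin²θ + rb²cos²θ) horizontally and
sqrt(ra²cos²θ + rb²sin²θ) vertically; annotation files use the plain
name/count/boxes text dialect common to face benchmarks.

## 7. Synthetic data generator (`gazeface.synthetic`)

The generator renders aligned frontal "portrait" faces on a square canvas: a
bright head oval (with seeded center and axis jitter so the contour never
repeats pixel-exactly across images), dark Gaussian blobs for eyes, nose and
mouth, and — critically — **fine detail at several distinct scales around
the same landmarks** (pupils, eye corners, lashes, brows, nostrils, lip
line, mouth corners, plus broad bright cheek/forehead/chin patches).
Because scale linking assigns each blob to exactly one level, a face drawn
only with single-scale blobs would populate only one or two pyramid levels;
the multi-scale detail gives every fine level its own repeated structure at
the landmarks, as real faces do.  Landmark positions are jittered per image;
spatially correlated noise and soft background clutter are added.

Negatives are clutter images of random soft ellipses and bars with matched
texture, containing no eyes–nose–mouth triad.  Scenes composite face
canvases onto clutter; the ground-truth annotation is the pasted canvas
square (section 5).

Fixations are simulated per observer as draws from a mixture over the face
center and the landmarks whose center weight and scatter shrink with the
fixation index — a stylized coarse-to-fine gaze pattern.  Observers differ
in scatter and idiosyncratic bias.

**Limitations.**  Faces are frontal, aligned, grayscale, and share one
geometric template; there is no pose, illumination, occlusion or identity
texture variation, so classifier difficulty is far below real photographs.
The fixation model is a parametric mixture, not recorded gaze: it reproduces
the coarse-to-fine concentration onto landmarks but none of the temporal or
saccadic structure of human scanpaths.  Negatives are synthetic clutter,
which bounds what false-positive rates mean.  Results on this data
demonstrate the pipeline's mechanics, not real-world performance.

## 8. Reproducibility and numerics

All stochastic steps (generators, k-means restarts, SVM, negative patch
sampling) are seeded; the test suite regenerates every fixture from seeds at
runtime, and there are no stored binary fixtures.  All computation is
float64.  One known numerical sensitivity is documented here deliberately:
feature positions live on decimated grids, so a one-pixel parity change of
the decimation lattice (e.g. after mirroring an image) can shift coarse
features by ±1 native pixel; the density-map comparisons absorb this through
linear binning and the KDE bandwidth rather than through sub-pixel feature
refinement, which is out of scope.
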