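# Methods

`phenoseg` extracts quantitative phenotypes from single side-view photographs
of quadrupeds (the design target is dairy cattle sire-catalogue imagery) and
estimates the heritability of those phenotypes from pedigree records.  This
note documents the models, the geometric conventions, the numerical choices,
and what the synthetic test bed does and does not demonstrate.

## 1. Two-step segmentation

**Detection contract.**  The pipeline consumes, per image, the three classic
instance-detection outputs: a class label, a region of interest (RoI), and an
approximate binary mask.  The detector itself is pluggable.  The shipped
`oracle` backend serves fixture masks with configurable degradation (morphological
erosion, deletion of named parts, random pixel dropout), emulating the
characteristic failure of off-the-shelf detectors on animal imagery: the
body located correctly but tails, ears, noses and hooves clipped away.  A
pretrained deep detector is deliberately out of scope — requesting it raises
a capability error rather than downloading weights.

**Per-image unsupervised refinement.**  The RoI crop (default margin 10 px;
the margin protects extremities the coarse box may clip) is segmented by a
small convolutional pixel classifier trained *on that crop alone*:

1. forward pass: 3 conv layers (3x3 kernels, reflect padding; ReLU and
   per-channel normalization after each layer except the last, which is
   linear + normalization) map RGB to `C` cluster scores per pixel
   (defaults: `C = 32`, which also bounds the cluster count);
2. superpixel refinement: per-pixel argmax labels are snapped to
   precomputed superpixels (Felzenszwalb graph segmentation, scale 30,
   min size 12 — roughly 100–500 segments on a 128 px crop); each
   superpixel takes its modal label, which can only reduce the label count;
3. backward pass: the cross-entropy between the network scores and the
   snapped labels is backpropagated and parameters are updated by SGD with
   learning rate 0.1 and momentum 0.9.

The loop runs a fixed `T = 48` iterations (early stop if the label count
collapses to 2).  There is no objective that rewards many clusters: clusters
are only an intermediate representation for the fusion step.  The network is
implemented directly in numpy (im2col + BLAS matmuls in float32); at these
sizes a crop takes a few seconds on one CPU core and the whole computation
is bit-reproducible for a fixed seed.

**Fusion.**  Each 8-connected component of each final cluster votes: it
joins the refined mask iff at least `overlap_threshold = 0.5` of its pixels
lie inside the coarse mask.  Voting at component rather than whole-cluster
granularity matters: a color cluster may span both the coat and a remote,
similarly colored background region, and global voting would then discard
in-mask coat patches wholesale.  For connected clusters the two rules
coincide, and when the clusters reproduce the coarse partition exactly the
output equals the coarse mask.  Because a region that passes a higher
threshold also passes any lower one, the fused mask is monotone
non-increasing in the threshold.

**Cleaning.**  The fused mask is median-filtered (kernel 5 at 128 px, scaled
proportionally with crop size, always odd), then foreground islands and
background holes smaller than 1 % of the crop area are removed.  The
island/hole step is idempotent.  The mask is pasted back into the full image
frame at the crop offset.

## 2. Coat-color proportions

Foreground RGB pixels are clustered by k-means with k = 2 (10 restarts,
fixed seed).  If the centroids are closer than 30 RGB units the coat is
treated as monochrome.  Components are ordered by Rec. 601 luminance
(0.299 R + 0.587 G + 0.114 B); the reported `white_proportion` is the pixel
fraction of the lighter component (1.0 / 0.0 for a monochrome light / dark
coat, with the cutoff at luminance 127.5).  Only pixels inside the mask
enter the computation, so the summary is invariant to background content
and to pixel order.

## 3. Landmarks and conformation traits

The cleaned mask's outline is traced (largest component, Moore neighbour
tracing, after removing edge components below `min_object` pixels), and 13
named points are located by geometric rules on the right-facing silhouette.
The full rule table is in the `morphometry` module docstring; the anchors
are: hooves as the boundary points nearest the bottom image corners, nose
tip as the rightmost point, tail head as the leftmost upper-half point, and
a *neck cut* — the column of minimal vertical silhouette thickness between
the back and the head — from which the throat, neck top, and (midway to the
nose) jaw and muzzle points are taken.  The withers and the two underline
points (brisket, rear belly) are local extrema of the top and bottom
silhouette profiles.  A rule that cannot be satisfied (e.g. the head is
missing from the mask, so no thick region exists beyond the neck cut)
returns MISSING rather than guessing.

Fourteen traits are derived from the landmarks: axis-projected vertical
measures (heights relative to the hoof baseline, chest depth), horizontal
gait and body length, Euclidean head/face/neck measures, the maximal
deviation of the dorsal arc from the tail-to-withers chord, and two body
areas (triangle over withers/tail/brisket, and the shoelace area of the
five-point body cycle).  Traits are reported in raw pixels: catalogue
images carry no physical scale, so only relative comparisons across images
are meaningful, and no size normalisation is applied by default.  Any trait
with a MISSING input is flagged missing — exactly those, never more.

These landmark and trait definitions are this package's own documented
schema.  Published conformation metrics for cattle differ between studies
and the precise definitions used alongside any particular catalogue are
generally not reproducible from the images alone; numeric trait values are
therefore comparable only within runs of this package.

## 4. Pedigree genetics

The additive (numerator) relationship matrix A is built by the tabular
method in topological order: founders are unrelated, `A_ii = 1 + A_sd / 2`,
and off-diagonals average the parents' rows; unknown parents contribute
zero.  The implementation is validated element-wise (to 1e-12) against an
independent memoized kinship recursion.

Heritability is estimated one trait at a time from the intercept-only
animal model `y = 1 mu + a + e`, `a ~ N(0, A s2a)`, `e ~ N(0, I s2e)`, by
Gibbs sampling: a normal conditional for mu, single-site normal updates for
the breeding values using A⁻¹ (dense; the running vector A⁻¹a is updated
incrementally and refreshed every 100 sweeps), and scaled inverse
chi-square conditionals for both variances.  Priors are scaled-inv-chi2
with 5 degrees of freedom; by default the scales split the observed
phenotypic variance 50/50, mirroring common default-prior practice in
Bayesian animal-model software.  Defaults are 1000 iterations with 200
burn-in; parameter-recovery experiments in the test-suite use 3000
iterations, which on one CPU core takes ~15 s at n ≈ 900.  Individuals
without a phenotype still contribute through the pedigree: A is built on
the full pedigree and subsetted to phenotyped individuals for the fit.
A is Cholesky-factorised as a validity check, with at most 1e-8 jitter
added if numerically singular.

## 5. The synthetic test bed

Real sire-catalogue photographs are not redistributable, so correctness is
measured on generated scenes with exact ground truth:

* **Silhouettes** are unions of analytic shapes (torso with a withers bump
  expressed as a top-profile so no column splits into separate runs, neck
  band, head ellipse, four legs, tail, chest and belly bulges) rasterized
  without anti-aliasing on flat, gradient, or textured backgrounds.  The
  generator records the exact mask, per-part sub-masks, and landmark
  coordinates computed analytically from the part geometry — an
  independent path from the outline-based extractor that is later tested
  against it.
* **Coats** are two-tone: random light blobs on a dark base, with the blob
  scale bisected until the light fraction is within 0.005 of the requested
  target; the *achieved* fraction (recomputed from the rendered pixels) is
  what the ground truth stores.
* **Degradation** mimics detector behaviour: erosion radius 2 plus one
  dropped part is the standard test condition.
* **Pedigrees** are simulated by gene dropping (founders `a ~ N(0, s2a)`;
  offspring take the mean of known parents plus Mendelian noise of
  variance `s2a/2`, or `3 s2a/4` with one parent known, matching how an
  analyst would treat a record whose other parent is missing).  Default
  design: 100 founders, 4 overlapping generations, mean family size 2.6,
  ~900 individuals — family sizes of a few individuals reflect what sparse
  public catalogue pedigrees look like.

What passing these tests shows: the refinement loop genuinely improves
degraded masks (mean IoU gain ≥ 0.05), color proportions track truth
(R² ≥ 0.95 with true masks), landmarks are located to 3 px, A is exact,
and simulated heritabilities are recovered to ±0.10.  What it does not
show: robustness to photographic nuisance (lighting, occlusion by
handlers, motion blur, breeds whose coat matches the background), accuracy
of the trait *definitions* against manual measurement standards, or
behaviour on pedigrees with genotype data.  The synthetic silhouette is
deliberately stylized; its value is exactness, not realism.

## 6. Numerical conventions and edge cases

* Coordinates are 0-based, x rightward, y downward; RoIs are half-open.
* All randomness flows from explicit integer seeds; per-image seeds are
  derived from the global seed and a CRC of the image id, so batch results
  do not depend on batch composition or ordering.
* Crops below 16x16 px, empty coarse masks, masks with fewer than 100
  foreground pixels, phenotypes with non-finite values, and model fits with
  fewer than 10 records are rejected with explicit errors; batch drivers
  convert per-image errors into manifest rows (`ok` / `missing-target` /
  `failed`) and continue.
* Ties in landmark rules are broken deterministically (topmost for
  rightmost/leftmost rules, median column for topmost/bottommost rules).
* `orient_right(mode="auto")` flips when the horizontal centre of mass of
  the top third of the silhouette lies left of the whole-silhouette centre
  (the head and neck are carried high and forward).
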