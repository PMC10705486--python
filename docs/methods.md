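# Methods

## Problem setting

A depth camera looks straight down at broiler chickens from roughly 1 m
above the pen floor. Each pixel stores the camera-to-surface distance in
millimetres (16-bit "Z16" integers; 0 marks an invalid measurement).
Floor pixels read approximately the ground distance H; a bird appears as
a connected region of smaller distances — a valley carved into the flat
depth field. The pipeline turns each bird's mask and depth profile into
a feature vector and regresses body weight on it.

## Synthetic scenes and what they do (and do not) emulate

Real recordings with calibrated scales are expensive, so the package
ships a simulator whose ground truth is exact. A bird is a
half-ellipsoid dome: footprint semi-axes a, b (px), back height h (mm),
arbitrary orientation, giving the closed-form volume V = (2/3)·π·a·b·h.
Body weight follows the allometric link w = c·V·(1+ε) with
ε ~ N(0, σ_rel) truncated to keep w > 0; the default coefficient
c = 1.85·10⁻⁵ kg/(px²·mm) and a weight draw uniform on 0.87–2.35 kg
reproduce the range of finishing broilers, with back height growing from
70 to 105 mm across that range so that heavier birds are both taller and
wider. Scene defaults: 96×96 px, H = 1000 mm, additive Gaussian depth
noise σ = 2 mm truncated at ±3σ, 0.5% missing pixels, depths quantised
to whole mm as a Z16 sensor would deliver them (this also makes the PNG
round trip bit-faithful).

The footprint mask is the closed ellipse r² ≤ 1, including the rim where
the dome height is zero and the depth equals H exactly; this is what
makes the edge-referenced volume formula (below) consistent with the
closed form.

Deliberately not modelled: feathers and texture, head/leg/wing
articulation, posture variation, occlusion and touching birds,
sensor-specific noise (edge shadows, multi-path). Passing tests on these
scenes therefore demonstrate the *correctness of the measurement and
learning machinery*, not field performance on real animals — the
fixed-shape domes make weight almost perfectly recoverable from volume,
which real plumage and posture do not.

## Morphometric features

All 2-D features are computed on the outer boundary of the mask's
largest connected component, traced on pixel centres with
Moore-neighbour tracing and merged over collinear runs. Tracing on
centres means the enclosed (Green's-formula) area of a blob undershoots
its pixel count by about half the perimeter — documented, consistent,
and irrelevant to tree-based regression, which is invariant to any
monotone per-feature distortion.

* Projected area: shoelace evaluation of ∮ x dy (f01); equivalent-circle
  diameter f16 = √(4·f01/π).
* Perimeters and hulls: contour perimeter (f02), monotone-chain convex
  hull area/perimeter (f05, f09); hull vertices are contour vertices, so
  defects are well defined.
* Approximate contour: Douglas–Peucker at ε = 1% of the perimeter
  (f10, f11). The closed polygon is split at vertex 0 and the vertex
  farthest from it, each chain simplified, and a closing sweep removes
  survivors within ε of their neighbours' chord, so anchors on straight
  stretches do not persist. ε = 0 returns the input unchanged.
* Convexity defects (f14, f15): computed by default on the approximate
  contour (its name suggests the simplified polygon; a flag switches to
  the raw one). For each hull edge subtending at least one off-hull
  vertex, the defect depth is the maximal point-to-edge-line distance
  |A·x+B·y+C|/√(A²+B²); f15 is the sum over edges, f14 the maximum.
* Ellipse (f06–f08): axis lengths 4·√(eigenvalues) of the pixel
  coordinate covariance, the same normalisation scikit-image's
  regionprops uses (a filled disc of radius r yields its diameter);
  eccentricity √(1−(b/a)²), the standard ellipse definition.
* Boxes (f03, f04, f12): the axis-aligned bounding rectangle supplies
  width/height and the area ratio; minimum-rotated-rectangle sides are
  exported as diagnostics only, since which rectangle the width/height
  of a bird should come from is genuinely ambiguous.
* Depth statistics (f18–f25, mm): max, min, mean, range, population
  standard deviation (ddof 0), sum, and the min-to-mean and mean-to-max
  distances, over non-missing masked pixels.
* Approximate volume (f17, px²·mm):
  V = Area · max{D over contour pixels} − Σ masked D. The reference is
  the deepest *edge* pixel, approximately the floor distance. "Area"
  is the count of non-missing masked pixels — the correct discrete area
  for this Riemann sum; using the Green's-formula area (available via
  flag) would inflate the volume by ≈ perimeter/2 × H, i.e. tens of
  percent at H = 1000 mm. On the noiseless canonical dome (a = b = 40,
  h = 80) the measured volume agrees with (2/3)·π·a·b·h to < 0.1%;
  over random rotated domes the discretisation error stays below ~3%.

No metric calibration (px → cm) is attempted; 2-D features are in
px/px², depth features in mm. The head is left in the mask.

## Segmentation

The threshold segmenter keeps pixels more than τ mm above the floor
(default τ = 30 mm, comfortably above the ≤ 5 mm noise regime),
labels connected components (8-connectivity by default, so thin diagonal
necks stay whole), drops components below `min_area`, and orders
instances by size. It deliberately excludes each bird's sub-τ skirt; the
resulting above-τ volume is a stable monotone proxy of the full dome
volume. Any external learned segmenter (e.g. a served Mask R-CNN) plugs
in through `SegmenterAdapter`, which enforces shape agreement and
pairwise disjointness; training such a model is out of scope here.

## Learned features and fusion

The learned-feature block is a *contract*: 2048 finite values per
instance, from any provider. The bundled `default_embed` is a
deterministic stand-in — pooled multi-scale patch statistics of the
masked depth relief (histogram, order statistics, 4×4 and 8×8 block
means) pushed through a seeded Gaussian random projection to 2048 dims —
with the right interface and stable, collision-free behaviour, not a
trained network. Fusion is plain concatenation, morphometric block
first (the order is recorded in the column names), lossless and
invertible. Normalisation is min–max on training statistics only, with
test values clamped to [0, 1]; z-score is available by flag. Constant
columns pass through flagged. Tree ensembles are invariant to such
monotone scalings (tested), so normalisation matters only for
comparability with non-tree baselines.

## Gradient-boosted regression trees

Squared-loss stagewise boosting, written from scratch: f₀ = ȳ; per
round, the residuals y − f_{k−1}(x) are fitted by a binary regression
tree whose leaves predict their mean residual, and
f_k = f_{k−1} + ρ·tree_k. Trees grow best-first (leaf-wise): the leaf
whose best split most reduces squared error is expanded next, subject
simultaneously to a leaf cap (num_leaves) and a depth cap — honouring
both reference presets, one of which is leaf-wise with 15 leaves and the
other depth-wise with depth 5. Split candidates are midpoints of
consecutive sorted unique values (no histogram binning; problem sizes
here are a few thousand rows at most); the gain is computed from prefix
sums, exactly. Equal-gain ties break to the lowest feature index, then
the lowest threshold, making fitting deterministic. `min_child_weight`
is interpreted as a minimum leaf row count, which under unweighted
squared loss (hessian = count) matches both reference libraries'
semantics. Row subsampling draws without replacement per round from a
stream spawned deterministically from the config seed; column
subsampling is per tree. Models serialise to a documented JSON dump.

Not implemented: second-order (hessian-weighted) boosting, the
regularised objective (reg_alpha/reg_lambda), early stopping,
distributed/GPU training.

The `desk` preset (200 trees, depth 5, 15 leaves, no subsampling) is the
default for the synthetic studies: with ~200 training rows, 200 rounds
at ρ = 0.1 are past the point of diminishing returns, and full-size
presets (4000/2000 trees) add only runtime.

## Evaluation and experiment design

Metrics are MAE, MSE, RMSE = √MSE and R² = 1 − SSres/SStot (SStot about
the mean observed weight); R² is reported as an error when the truth is
constant with nonzero residuals. The weight-class report uses five
0.3 kg bins on 0.85–2.35 kg, half-open with the last bin closed; empty
bins are omitted; values outside the range either raise or, with
overflow bins enabled, collect into open-ended end bins. Splits are
seeded shuffles at a 70/30 ratio; when group labels (animal identities)
exist, whole groups stay on one side to prevent appearance leakage —
enabled by default in the experiment runner.

The recovery experiment (300 scenes, σ_rel = 3%, grouped 70/30, desk
preset) is the package's end-to-end check: the regressor must recover
the weights the simulator generated. Typical results: relative test MAE
≈ 2.5–3.3% of the mean weight (at the 3% injected noise floor) and
R² ≈ 0.98; with all noise switched off, R² > 0.99. Replacing the
learned block by 2048 pure-noise columns degrades MAE by only a few
percent, showing the fit is robust to the fused dimensionality.

## Numerical choices and edge cases

* Degenerate inputs raise informative errors: empty or sub-3-pixel
  masks, all-collinear point sets, all-missing depth regions, constant
  targets for R², both-empty masks for IoU, zero/degenerate JET ranges.
* A root with no gain-positive split yields a single-leaf tree, not an
  error; a flat scene segments to an empty list.
* The JET map is the classic piecewise-linear variant (r,g,b =
  clamp(1.5 − |4t − 3|, |4t − 2|, |4t − 1|)), frozen so renderings are
  bit-exact across runs; missing pixels render black.
* Depth PNG I/O is lossless for integer mm; a scale factor (e.g. 0.1 mm
  units) covers sensors with finer quantisation, since the unit
  convention of Z16 files varies between vendors.
* Problem sizes in the test and acceptance suites (300 scenes, 96×96 px,
  200 trees, 5 seeds) were chosen as the smallest at which the recovery
  statistics are stable from seed to seed.

## Known limitations

Synthetic domes are rigid and unoccluded; the threshold segmenter
assumes a planar floor and a known (or median-estimable) ground
distance; the volume feature is resolution-dependent (px²·mm) and not
calibrated to physical litres; the bundled embedding carries only
depth-relief statistics, far less than a trained CNN backbone would; and
absolute accuracy on real birds cannot be inferred from these synthetic
results.
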