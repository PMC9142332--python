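# Methods

This note documents the models and procedures implemented in pfv3d, the
parameters that matter, the numerical choices made where the design was
genuinely open, and what the synthetic experiments do and do not show.

## Conventions

Volumes are dense 3D grids of integer gray levels with axis order
(depth, height, width) = (z, y, x), 0-based. 8-bit intensities are the
default; 16-bit integer sources are preserved bit-exactly, and
floating-point sources (which carry no natural gray scale) are min–max
rescaled onto [0, 255] with half-up rounding. Slice directories are stacked
in lexicographic filename order, so slice i of the file listing becomes
depth index i.

## Adaptive median filter

The denoiser is the classical two-stage adaptive median filter. For each
voxel, with a cubic window of side w (starting at `initial_window`, default
3):

* **Stage A** — if the local median lies strictly between the local minimum
  and maximum, the median is trustworthy: go to stage B. Otherwise grow the
  window by 2 and repeat, up to `max_window` (default 7).
* **Stage B** — if the center voxel itself lies strictly between the local
  extremes it is not an impulse and is kept; otherwise it is replaced by the
  local median.
* If the window reaches `max_window` without a usable median (e.g. inside a
  constant patch, where min = median = max), the local median is output.
  This variant still removes an isolated impulse surrounded by a constant
  region — the behaviour wanted for salt-and-pepper noise — at the cost of
  smoothing sharp convex corners of piecewise-constant objects.

Borders use edge-including reflect padding. A per-slice 2D mode (square
windows) is available behind the `mode="2d"` flag for data whose slices
should not mix. Filtering never changes shape or bit depth.

## Contrast stretching

Linear remapping of the input intensity range [c, d] onto [a, b]:
O = (r − c)(b − a)/(d − c) + a, rounded half-up, optionally clipping inputs
outside [c, d] to the output limits. When [c, d] already equals [a, b] the
volume is returned unchanged (stretching is not required). The limits are
derived from the intensity histogram: c and d are the low/high percentiles
(defaults 1 and 99 — robust to a handful of outlier voxels), and the output
range is the full bit-depth range. A histogram concentrated on a single
value raises a degenerate-range error advising a passthrough, rather than
silently dividing by zero.

## CLAP wireframe extraction

The wireframe stage operates on a binarized volume (default threshold 128,
the 8-bit midpoint) and deletes *interior* voxels iteratively. A foreground
voxel is interior when every axis-aligned line of 3 voxels through its
3×3×3 window — 9 lines per axis, 27 in total — contains at least one
foreground voxel. This is the 3D generalization of "every row and every
column of the neighborhood is occupied": interior voxels of solid bodies
satisfy it, voxels on a free surface do not, so solid objects erode down to
their 1-voxel shell and already-thin structures are stable.

Two deliberate choices:

* **Synchronous deletion.** Each pass marks all currently-interior voxels
  and deletes them together at the end of the pass. In-scan deletion would
  make the result depend on raster direction; the synchronous rule is
  direction-invariant and idempotent at its fixpoint (re-running on the
  output deletes nothing).
* **Zero padding.** The world outside the volume is background, so object
  voxels touching the volume boundary are retained as shell.

Iteration stops when a pass deletes nothing, or after `max_iterations`
(default 100 — solid convex bodies of radius r need about r/2 passes, so the
default is far beyond any realistic depth). The vectorized pass (separable
max/min filters) is verified against a literal per-voxel window predicate in
the test suite.

## The corner-pattern vocabulary and the 3D-PFV

The 3×3×3 window's 27 cells are numbered 1–27 row-major within each slice,
front slice first; the center is cell 14 and has 26 neighbors. Only the 8
corner cells {1, 3, 7, 9, 19, 21, 25, 27} participate in pattern matching,
giving 2⁸ = 256 occupancy configurations. Patterns are grouped by how many
corners are absent — P (0) through X (8) — with group sizes equal to the
binomial coefficients C(8, k): 1, 8, 28, 56, 70, 56, 28, 8, 1.

The canonical pattern id is the occupancy bitmask: bit k set iff the k-th
corner in ascending cell order is foreground (so the all-present pattern P1
is id 255 and the all-absent pattern X is id 0). Any fixed assignment works
— what matters is that a pattern occupies the same index of the frequency
vector for every image — and the bitmask is self-describing and
permutation-free. Human-readable names list the *absent* corners:
`P1`, `Q1`, `R{1,3}`, … `X{1,3,7,9,19,21,25,27}`.

Extraction pads every axis up to the next multiple of 3 (background padding
by default, appended at the high end only, so coordinates of existing voxels
never shift), then slides the window in raster order with stride 3
(non-overlapping tiling; stride is exposed as a parameter). Each placement
increments one pattern count; consequently `sum(counts) = n_windows` for
every input, stride and pad value — a conservation law the tests enforce.
The 2D analogue uses the 8 neighbors of a 3×3 window, ordered by the
direction convention R, DR, D, DL, L, UL, U, UR.

Which volume is scanned is a pipeline choice: the wireframe mask by default
(the shell is where the shape information lives), with a config switch to
scan the raw binarized volume instead.

## Classification heads

Two heads are provided on a seeded pure-NumPy backend (im2col 3D
convolution, inverted dropout, Adam, soft-max cross-entropy), so the whole
train/predict path is deterministic given a seed:

* **pfv_mlp** (default): 256 → 128 hidden (ReLU, dropout) → m classes with
  soft-max. Before training, features are centered per component and scaled
  by one *pooled* standard deviation. Normalized pattern frequencies are
  tiny (order 1/256), so some rescaling is needed for the weight
  initialization to be on-scale; a single pooled scale is used rather than
  per-component standardization because it preserves the relative variance
  structure of the counts — components that genuinely vary stay large, and
  near-constant noise components are not inflated to unit scale.
* **alexnet3d**: 5 convolution layers (3×3×3 kernels, channel widths
  8-16-16-16-8, stride 1, shape-preserving padding) with max pooling of
  window 2 after convolutions 1, 2 and 5, then 3 fully connected layers
  (64, 32, m) — 8 weighted layers ending in a soft-max. Per-layer channel
  widths follow classical AlexNet proportions scaled to phantom-sized
  volumes; input dimensions must be divisible by 8 (three poolings).

Training defaults: 65 epochs, learning rate 0.001, dropout 0.20, batch size
128, a 90/10 train/validation split, and early stopping when validation
loss and accuracy are both constant (|Δ| < 1e-7) for 4 consecutive epochs.
With no held-out samples (degenerate tiny datasets) the training metrics
drive the stopping rule instead. Weight initialization is seeded
uniform-fan (Glorot); the optimizer is Adam at the stated learning rate
with standard moment constants.

## Evaluation

One-vs-rest confusion counts per class, and from them accuracy
(TP+TN)/(TP+TN+FP+FN), sensitivity TP/(TP+FN), specificity TN/(TN+FP),
precision TP/(TP+FP) and F1 = 2·precision·recall/(precision+recall). Every
0/0 case is defined as 0 and logged, so reports contain no NaNs. Macro
metrics are unweighted means over classes. The implementation is
cross-checked against scikit-learn's metrics in the test suite.

## Synthetic phantoms

Phantoms place a bright object (default gray 200) on a dark background
(default 30) — both far from the binarization threshold of 128, so the
preprocessing and pattern stages can be tested independently. Three shape
classes with distinct wireframe statistics: a solid ellipsoid (one shell
after wireframing), a hollow shell (outer plus inner cavity surface —
roughly twice the shell area), and a multi-focal cluster of small blobs
(many small shells, far fewer occupied windows). Noise is salt-and-pepper
with equal salt/pepper probability — the impulse regime the adaptive median
filter targets — at a default density of 5% for classification experiments.
Labelled datasets jitter object position (±10% of the extent) and size
(0.8–1.1×) per sample.

`plant_patterns` provides the exact oracle for PFV extraction: it writes
requested corner patterns into disjoint stride-3 grid cells and returns the
expected frequency vector by construction (planted counts plus the
all-absent pattern for untouched cells).

What the phantoms do **not** model: MRI physics (bias fields, Rician noise,
partial-volume effects), anatomy, inter-scanner variation, or anything
resembling real tumor morphology beyond gross shape topology. Passing the
end-to-end test therefore shows that the pipeline's stages compose
correctly and that the 3D-PFV separates objects whose wireframes differ in
shell area and fragmentation — not that the method reaches any particular
accuracy on clinical data.

## Problem sizes

The default experiment sizes keep every stage exactly testable: phantom
volumes of 24³–30³ voxels (a 24³ volume yields 512 stride-3 windows),
classification with 60 phantoms per class and an 80/20 split, brute-force
PFV cross-checks on volumes up to 15³, and wireframe oracle checks on 6³
masks where literal per-voxel enumeration is instant. These choices make
the whole suite run in seconds while leaving no stage covered only by its
own implementation.

## Known limitations

* The stride-3 corner sampling reads only a sub-lattice of the volume; thin
  (1-voxel) shells produce sparse hits, so the PFV of a small object has
  high variance under sub-voxel translations. Larger objects or stride 1
  reduce this at extraction cost.
* The interior criterion preserves shells but is not a topological thinning:
  it does not guarantee minimal skeletons for concave objects.
* The NumPy alexnet3d head is for small volumes; it is not a performance
  implementation.
* `ConfusionCounts` assumes single-label classification; no detection or
  segmentation scoring.
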