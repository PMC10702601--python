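# Methods

This note documents the models, parameter choices, numerical conventions
and known limitations of `canospec`. It states no empirical result that
the test suite or `scripts/acceptance.py` does not itself compute.

## The synthetic stand

The simulator is the package's stand-in for UAV survey data of a
*Pinus*-type plot, and its defaults define the study conditions used
throughout the tests.

**Geometry.** A 20 m × 20 m plot. Tree crowns are solids of revolution
(cones) sampled on the shell, with a 25% interior fraction mimicking
sub-canopy laser returns (multi-echo LiDAR sees inside crowns). Apex
heights draw from U(6, 10) m, crown radii U(1.5, 2.5) m, crown depths
U(3, 5) m; each canopy point belongs to exactly one tree. The ground is a
low-amplitude (0.3 m) sinusoidal surface with 3 cm roughness; grass grows
in a handful of random disk patches, 5–35 cm above the soil, bare land
covers the rest.

**Class point counts** default to (10886, 7572, 8301) for
tree/land/grass — one tenth of the densest
field-survey plot the pipeline is modeled on — giving ≈27k points
(≈67 pts/m²). Counts are generated exactly, trivially satisfying the ±5%
target tolerance.

**Spectra.** NIR is simulated in the survey's printed grayscale range
(≈7–14, dimensionless: the physical units of such resampled grayscale
values are not standardized). Canopy NIR decays linearly from each apex,
`NIR = 11.3 − 0.30 · d_apex + ε`, ε ~ N(0, 0.15²) — reproducing the
observed radial decay from the crown apex (in a noiseless scene the
Spearman correlation between NIR and apex distance is exactly −1, and
5-ring crown profiles are linear with R² > 0.99). Bare land is unimodal
N(7.96, 0.25²); grass is the two-component mixture
0.55·N(12.03, 0.25²) + 0.45·N(13.46, 0.25²). The mode ordering
land < canopy < grass matches the field pattern.

**Color–NIR coupling.** Point RGB is a class base color plus a linear
response to the point's NIR anomaly (gain 8/12/8 counts per NIR unit on
R/G/B) plus N(0, 5²) sensor noise, clipped to [0, 255]. This keeps the
color–NIR rank correlations in the band observed on real fused clouds
(≈0.25–0.99) and is what makes NIR pseudo-labels recoverable from
`(x, y, z, r, g, b)` at all. Without it, within-class labels would be pure
noise and no segmentation model could beat chance — a property of the real
data (where color and NIR share the vegetation signal), not of the model.

**Orthoimage rendering** assigns each cell the spectral values of its
maximum-Z point (verified cell-by-cell against an exhaustive argmax
oracle); empty cells hold nodata. The RE band is defined as 0.85·NIR —
a plumbing band; nothing downstream consumes it. Default desk-scale GSD
is 0.05 m (the survey's 0.01 m is kept for full-density data; the desk
stand has one tenth the point density, so the sampling ratio is
preserved). Viewpoints form a regular nadir grid at 80 m altitude with
10 m spacing (3 × 3 over the plot).

**What the simulator does not emulate:** radiative transfer, BRDF and
illumination effects, species mixtures, phenology/pest spectral anomalies,
georeferencing error, LiDAR intensity. Tests passing on this generator
show the pipeline's *mechanics* are correct (geometry, fusion exactness,
label recovery under realistic noise); they do not certify accuracy levels
on field data.

## Hidden point removal

Spherical inversion followed by a convex hull over the inverted points
plus the viewpoint. The radius exponent γ (R = 10^γ · max‖p − C‖)
controls the size of surface concavities that get hidden: larger R hides
less. The default **γ = 4.5** was set so that the hidden-concavity
tolerance sits below the point spacing of the default stand; with the 3 × 3
flight grid it retains ≈99% of the orthoimage winners (the per-cell
max-Z surface) while still discarding interior crown points. At γ = 2.5
the same filter loses ≈23% of the true surface — too aggressive for
ground clouds with centimeter roughness. On convex scenes HPR recall
against an independent ray-casting oracle (finite occluder radius = mean
nearest-neighbor spacing; test-only construct) is ≥ 0.95.

Degenerate inputs (< 4 points, coplanar clouds) fall back to all-visible
with a warning; a point coinciding with the viewpoint is an error. Only
the spherical-inversion formulation is implemented; normal-vector
visibility variants are out of scope.

## Fusion

The y-numerator of the collinearity equations uses the `b₂`/`c₂` rotation
row (the standard form); the camera convention is aerial: z-axis up,
scene below, so the projection denominator must be negative ("in front").
Ray invariance (any point on the ray C→P projects to the same image
coordinates within 1e−9) is property-tested.

Default fusion mode is the planimetric `ortho` lookup because stitched
orthomosaics have no single perspective center; `perspective` mode with a
full `CameraModel` exists for raw frames and agrees with ortho mode within
one pixel on flat scenes when the pixel pitch matches the GSD.
Nearest-neighbor resampling is the default because it preserves the
closed-loop identity — simulate → render → HPR → fuse returns every
surviving per-cell max-Z point its own NIR *exactly* (bit-equal floats;
no interpolation touches the value). Bilinear resampling is available and
propagates nodata. Points outside the raster or on nodata are silently
dropped and counted.

## Feature enhancement

**Isolation forest** — built in-house at the tree level: 100 trees,
subsample ψ = 256, height limit ⌈log₂ψ⌉, random axis + uniform split
within the subsample's range. `c(ψ)` uses the exact harmonic sum up to
n = 10⁶ (ln n + γ beyond); `c(2) = 1`, `c(ψ<2) = 0`. Features are
z-scored before cutting: the algorithm is scale-free per split, but mixed
units (meters vs color counts) would otherwise skew the random-split
budget across features. Removal takes the ⌈contamination·n⌉
highest-scoring records (default 5%); an absolute threshold `s ≥ s₀` is
available for the "score close to 1" reading. On planted 10σ outliers
recall is ≥ 0.9 (measured 1.0 at the test sizes).

**K-means / elbow** — 1-D Lloyd iterations, best of 10 seeded restarts,
stopping when centers are exactly unchanged; empty clusters are re-seeded
on the worst-fit value; per-iteration SSE is recorded and is
non-increasing. Centers are returned sorted, and pseudo-labels are the
rank of the nearest center (1 = lowest NIR); an exactly equidistant value
takes the lower label. The number of clusters is chosen at the knee of
SSE(k) over k ∈ [2, 12]. Two knee rules are provided. The default,
**max curvature of log SSE** (largest second difference), recovers the
mode count of clean mixtures: 3 for three separated Gaussians and 8 for an
8-mode NIR mixture. The Kneedle-style max-chord-distance rule is kept as
an option, but for 1-D mixtures its answer is provably pulled below the
mode count: the DP-optimal SSE(k) of an 8-mode mixture declines convexly,
which parks the chord knee at the coarse two-scale structure (k ≈ 4)
regardless of how the modes are arranged. Flat curves (no knee) fall back
to the smallest candidate K with a warning.

Clustering scope is configurable: `global` (one codebook for the whole
stand — with K = 4 the centers align with the land/canopy/grass spectral
modes) or `per_class` (one codebook and one model per land class, the
survey's K = 8 regime). The desk-scale pipeline defaults to global K = 4.

**Normalization** uses population (not sample) standard deviation for the
coordinate z-scores, zero-variance axes map to 0, RGB divides by the
declared sensor maximum (255). The 8:1:1 split gives test and validation
⌊n/10⌋ points each, remainder to train; a seeded permutation makes it
reproducible.

## Segmentation

The reference backbone is a pointwise shared MLP: per-point layers
6 → 32 → 64, symmetric max-pool over the block to a 64-d global feature,
concatenation back onto each point (128-d), one hidden classifier layer
(64) and a K-way softmax. Implemented in NumPy with hand-written
backpropagation; prediction is invariant to point order within a block
(exact, tested). Alternative architectures plug in through the
`backbone_factory` contract (forward/backward/sgd_step).

Training is plain SGD at the survey settings (lr 0.05, batch 4 blocks);
no scheduler, no momentum. Epochs default to 30 for desk-scale runs
(150 is the full-survey setting). Inputs are standardized internally per
feature before the first layer — the stored dataset keeps the
z-score/[0,1] convention, but at the network input the [0,1] colors would
otherwise carry ~30× less variance than the coordinates and train far
slower. Blocks are spatially contiguous grid tiles subsampled/padded to
`n_points` (4096 by default at survey scale; the desk pipeline uses 512 so
that a ~25k-point stand still yields a healthy number of SGD updates in 30
epochs), and they are **re-drawn every epoch**: with a fixed partition the
max-pooled global feature memorizes block composition and generalizes
poorly to new partitions. Un-batching resolves overlapping block votes by
per-point majority.

Metrics: confusion counts are exact; oAcc = trace/total;
mIoU = mean over non-empty classes of p_ii/(row_i + col_i − p_ii), with
empty classes skipped under a warning. Per-land-class figures restrict the
points to one class and compute oAcc/mIoU over the K NIR labels on that
restriction (the per-class mIoU definition for a label space shared across
classes).

## Reconstruction evaluation

Predicted labels decode to their cluster centers. Frequency curves are
histogram masses (64 bins by default) on the pooled true+predicted range,
so both curves share a grid; histogram rather than KDE keeps the bin width
explicit and peaks reproducible. Peaks are local maxima with prominence
≥ 5% of the curve maximum (the mass vector is zero-padded so single-bin
masses at the grid edge register). Matching is greedy closest-first until
the shorter list is exhausted; surplus peaks are reported separately
rather than force-matched, preserving the qualitative multi-peak
(overestimation) pattern of reconstructed curves. Note two consequences at
desk scale: (i) raw histograms of a few hundred samples carry spurious
noise peaks above the 5% prominence level, so true-curve peak lists can be
long; (ii) a small rate of cross-class label leakage puts a low spurious
peak on a predicted curve, and on some seeds its greedy match inflates the
reported maximum gap even though the dominant peaks coincide.

## Pipeline and reproducibility

Every stochastic stage consumes an explicit child seed derived from the
global seed via `SeedSequence` (all below 2³¹); the manifest records the
configuration (annotated survey-fixed vs chosen), the stage seeds, and
SHA-256 hashes of all artifacts. With a fixed seed the deterministic
artifacts are byte-identical across runs. Configuration keys are validated
against the schema; unknown keys raise an error naming the key. Stage
failures abort with the stage name.

Desk-scale problem sizes used by the tests and the acceptance script:
~27k-point stands (counts above), 0.05 m GSD, 9 viewpoints, 30 epochs,
n ≤ 2000 for the outlier experiment, 600/4000 samples for the elbow
experiments, 800 points for the convex-scene visibility oracle.

## Known limitations

* The NumPy backbone is CPU-scale; it is the reference implementation of
  the pointwise-MLP family, not a competitor to GPU point-cloud stacks.
* LAS support covers point formats 0–3 and 6–8 with the extra-bytes VLR;
  LAZ compression, waveform records and CRS VLRs are not handled.
* No lens distortion, bundle adjustment or multi-image blending in
  perspective fusion; no CRS reprojection.
* HPR quality depends on γ relative to point spacing; very sparse clouds
  may need a larger γ.
* Histogram-based peak calling is bin-width sensitive; for small samples
  prefer wider bins or the surplus-peak report over single-number gaps.
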