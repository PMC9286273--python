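# Methods

`nadder` decomposes 3D neuronal trace curves into fragments of intrinsic
dimensionality (1D line / 2D plane / fully 3D) across spatial scales, and
derives from those decompositions a per-point **local 3D scale** in
micrometers. This note documents the model, the numerical choices behind
it, and what the synthetic benchmark does and does not establish.

## Model

### Differential quantities

A trace branch is an open polyline γ(u) in μm. Curvature and torsion are
the classical Frenet quantities

    κ = ‖γ′ × γ″‖ / ‖γ′‖³,
    τ = ((γ′ × γ″) · γ‴) / ‖γ′ × γ″‖²,

computed with central finite differences in the sample index (one-sided at
the endpoints). Both formulas are invariant under smooth
reparameterization, so they remain physically meaningful (1/μm) for
polylines that are not perfectly uniformly spaced — which matters because
measurement noise inflates the polygonal arc length and makes exact
arc-length resampling of noisy input counterproductive. Curvature below a
floor of 1e−8/μm is treated as exactly zero: the radius of curvature
r_κ = 1/κ is reported infinite and τ is undefined there (the osculating
plane of a straight piece does not exist).

### Intrinsic-dimension indicators

A point is *linear* when κ ≤ ε_κ and *planar* when |τ| ≤ ε_τ. Because τ
is undefined on straight pieces, and a line lying in a plane must count as
planar, the working planarity mask is the planar-linear indicator
T = L ∪ H, with H inheriting L where τ is undefined. Defaults:
ε_κ = 0.01/μm (a curvature radius of 100 μm or more counts as straight)
and ε_τ = 0.015/μm. The torsion tolerance is slightly looser because the
third-derivative estimate is intrinsically noisier than the second; with
equal tolerances, the planar label is systematically lost on noisy input
long after the linear one has stabilized. The exact values are free
parameters of the method; the original publication does not print them.

### Scale space and micron indexing

The scale space is per-coordinate Gaussian convolution of the polyline
with standard deviation s in samples (kernel truncated at 4s,
renormalized). The Gaussian std is not physically meaningful, so analysis
scales are expressed as a radius of curvature r̂ in μm: for every point
whose base radius of curvature lies below r̂, the first grid scale s at
which its smoothed radius reaches r̂ is recorded. This per-point *crossing
scale* distribution ties the micron scale to the family of Gaussian
scales. The s grid is geometric (factor 1.15) from 0.5 samples to a third
of the curve's sample count, led by s = 0. Crossings are snapped to grid
scales rather than interpolated between them, because the stability search
below can only evaluate masks at scales that have actually been smoothed;
the geometric factor bounds the quantization at ~15 % in s.

**Working neighbourhood.** The decomposition at scale r̂ is stabilized
over a *neighbourhood* of Gaussian scales: the grid scales within ±3 steps
of the median of the crossing distribution — the regime in which the
curve's sub-r̂ detail has just been flattened. Using the entire crossing
set instead (also implemented, `scale_halfwidth=None`) was measured to
lose ~0.15 accuracy on the synthetic benchmark: the set stretches from the
noise-dominated regime (where every mask is empty) to the over-smoothed
regime (where everything is a line), and the stability vote then latches
onto one of those degenerate plateaus.

**Noise floor.** If the curve carries measurement noise (std σ estimated
robustly from second differences, or passed explicitly), the neighbourhood
is additionally floored at the smoothing scale where white noise stops
masquerading as curvature above ε_κ:

    κ_noise(s) ≈ σ / (√(2√π·s) · (s·h)²)  ≤  ε_κ / margin,

with h the sample spacing of the (fully smoothed) curve and a default
margin of 2. Without the margin the residual noise curvature sits exactly
at the tolerance and the indicator masks flicker maximally — the worst
operating point.

### Stable fragment combination

At each scale of the neighbourhood, maximal runs of the chosen mask are
extracted as fragments. Runs and complement gaps shorter than ε_ω are
removed first (majority filter at the ε_ω resolution, then gap filling and
short-run dropping): a two-sample hole in a long planar region is itself
an irrelevant small fragment, and removing it keeps the fragment *count*
stable across scales. ε_ω defaults to max(10 μm, r̂/2) inside
`decompose_at_scale` — structure shorter than the analysis scale cannot be
resolved at that scale.

Consecutive scales sharing the same fragment count form subintervals; the
heaviest subinterval wins (weights default to the per-scale count of
crossing points; ties go to the larger-s subinterval). A subinterval with
*zero* fragments is only eligible when every scale yields zero fragments:
"no fragments" is the degenerate all-3D outcome, not a combination, and
letting it compete means heavy noise always wins the vote. Within the
winning subinterval, fragments are matched across scales by their order
along the curve and each position is summarized by the *median* of its
start and end indices. Selecting the longest candidate instead (also
implemented, `candidate="longest"`) systematically absorbs the
most-smoothed variant whenever the winning subinterval brushes the
over-smoothed regime. Overlaps between selected fragments are split in
half.

The decomposition runs twice: pass 1 on the T mask yields planar-linear
regions versus 3D complement; pass 2 on the L mask, restricted to the
s-subinterval found by pass 1, nests 1D fragments inside those regions.
Assembled labels are cleaned once more by absorbing sub-ε_ω runs, and the
final fragments exactly tile the curve.

### Local 3D scale

For a grid of scales of interest (default 20 regularly spaced values from
1 μm — the sampling distance, below which scales are meaningless — to a
per-analysis maximum), the decomposition labels form a (scales × points)
matrix. The local 3D scale of a point is the first scale of the *longest*
run of non-3D labels along the scale axis; a point 3D at every probed
scale receives the grid maximum. Ties between equal-length runs go to the
smaller scale. A branch of length l cannot exhibit turns flatter than
l/π (a radius-r semicircle has length πr), which gives the
`max_scale_heuristic` for choosing the grid maximum.

### Whole arbors

An SWC reconstruction is cut into curves by leaf (one root-to-leaf curve
per terminal; the default, most stable because every curve has full
context), by node (segments between branching points), or by recursive
longest-branch extraction. Each curve is resampled at 1 μm with a
quadratic B-spline before analysis. Leaf curves whose terminal segment is
shorter than 5 μm are dropped (they duplicate a sibling path); per-node
values from overlapping curves are averaged, with the standard deviation
recorded. Mapping from resampled arc positions back to nodes is
nearest-arc-length, ties to the earlier node. Plane-crossing counts use
strict sign changes of one coordinate (touching the plane and returning
does not count; passing exactly through a sample point does).

## Synthetic benchmark

### Generator

Composite curves consist of up to five consecutive ~100 μm fragments of
random intrinsic dimension (consecutive dimensions distinct, so every
joint is a real ground-truth boundary), joined tangent-continuously with a
random twist, resampled to 1000 equidistant points, and corrupted with
isotropic white noise N(0, σ²), σ ∈ [1, 30] μm.

* 1D — straight segments in uniformly random orientations.
* 2D — active Brownian motion in a plane (Euler–Maruyama:
  φ += Ω·dt + √(2·D_R·dt)·N; x += v·cosφ·dt + √(2·D_T·dt)·N, y
  likewise), then a uniform random 3D rotation. Planarity is exact by
  construction.
* 3D — a spherical-angle extension in which φ and θ drift at rates
  cos Ω and sin Ω with shared rotational diffusion and unit-speed
  velocity (v·cosθ·sinφ, v·sinθ·sinφ, v·cosφ). Ω is kept away from
  multiples of π/2; otherwise one angle stops drifting and the printed
  equations degenerate to a near-planar arc.

Parameter defaults encode the benchmark's stated regime: feature radii of
the curved fragments are drawn from 20–50 μm, so that a fixed 20 μm
analysis scale does not deform the curve, analysis scales of 1–100 μm
genuinely probe the structure, and σ = 30 μm noise corrupts the local
detail of a 100 μm fragment. Rotational diffusion (D_R = 0.002 rad²/time
at v·dt = 1 μm steps) is kept well below the angular drift so fragments
are "random yet regular": a planar fragment never contains an accidental
multi-ten-μm straight stretch that would legitimately decompose as a
nested line. All randomness flows through a caller-supplied NumPy PCG64
generator; a fixed seed replays bit-identically.

### Evaluation

A decomposition is scored against ground truth as the mean, over true
fragments, of the best label-matched F1 overlap with any estimated
fragment, with precision = |ω ∩ ω̂|/|ω| and recall = |ω ∩ ω̂|/|ω̂| on
index sets. (The intersection is the only consistent reading: a union
overlap would exceed 1.) Benchmarks run either at the best-scoring
analysis scale per curve out of {1, 5, 10, …, 100} μm ("optimal") or at a
single fixed scale. Both the scale-space method and the baseline first
receive a light Savitzky–Golay pre-smoothing (window 31, order 3); the
raw noise estimate is handed to the decomposer so its noise floor stays
calibrated after pre-smoothing. The baseline is scale-space-free:
Menger curvature of a 7-sample window triplet for collinearity, then the
dihedral angle between consecutive window triangles per unit length (a
discrete torsion) for coplanarity, with the same run-length cleanup.

At 100 curves per condition the protocol gives, on one CPU in ~2½
minutes: ~0.95 mean accuracy at optimal scale for σ ∈ [1, 5] μm, ~0.83
for σ ∈ [20, 30] μm, ~0.84 at fixed 20 μm for σ = 5 μm and ~0.76 for
σ = 10 μm (seed-dependent within a few points; recomputed from scratch by
`scripts/acceptance.py` and asserted by `tests/test_acceptance.py`).

### What the benchmark does not establish

The generator produces piecewise-stationary fragments with clean
dimension changes, isotropic white noise, and no branching within a
curve. Real traces have smoothly varying geometry, spatially correlated
tracing errors, anisotropic z-resolution, and sampling that varies along
the arbor. Passing the benchmark therefore establishes that the
decomposition machinery is correct and noise-robust in a controlled
setting, not that the absolute accuracy figures transfer to any specific
microscope or tracing pipeline. The local 3D scale itself is also
sampling-dependent in its exact values (the 1 μm resampling standard is
part of the method definition), though relative spatial patterns are
robust.

## Numerical choices and degenerate inputs

* Smoothing boundary rule: coordinates are padded by linear extrapolation
  of end tangents (averaged over ~s samples) before convolving. Reflect
  padding — also available — creates artificial curvature and torsion at
  the curve ends and mislabels them 3D.
* Curves shorter than ε_ω yield a single 3D fragment with a warning;
  fewer than 4 points cannot support torsion and are rejected.
* A curve already flatter than r̂ everywhere is decomposed at s = 0
  (no smoothing needed).
* Points whose radius of curvature never reaches r̂ within the s grid
  contribute the grid maximum.
* Problem sizes: benchmark conditions use 100 curves × 1000 points;
  property tests run on single curves or small trees. These sizes give
  ±2–4 point sampling error on the accuracy means.

## Known limitations

* The stability vote is global per curve: a single working neighbourhood
  serves all fragments, so a curve mixing very fine and very coarse
  structure is decomposed at a compromise smoothing level.
* Fragment boundaries erode by up to the kernel support (±4s samples)
  when heavy smoothing is required; at σ = 30 μm this is the dominant
  accuracy cost.
* Gaussian smoothing shrinks curves; κ/τ are always measured on the
  smoothed geometry, which slightly biases the micron indexing at large s.
* The fixed-scale protocol is only meaningful for scales below the
  feature size of the structures of interest; at scales above it the
  "errors" are real scale-space simplification, not mistakes.
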