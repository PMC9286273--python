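# nadder

Scale-space analysis of 3D neuronal traces: intrinsic-dimension
decomposition and the per-point **local 3D scale**.

Neurite reconstructions (SWC files from NeuroMorpho.Org-style archives,
whole-brain atlases, or your own tracing) are usually analyzed with
global metrics — total length, branch counts, tortuosity — that average
away *where* along a trajectory an axon or dendrite is straight, planar,
or genuinely three-dimensional. `nadder` measures exactly that, locally
and across spatial scales, for people doing quantitative neuroanatomy on
traced arbors (and for anyone else with 3D polylines: migrating cells,
particle tracks).

## The method in brief

A trace branch is a curve γ(u) ⊂ ℝ³ (μm). From the Frenet quantities

    κ = ‖γ′ × γ″‖ / ‖γ′‖³        (curvature, 1/μm)
    τ = ((γ′ × γ″) · γ‴) / ‖γ′ × γ″‖²   (torsion, 1/μm)

a point is *linear* when κ ≤ ε_κ, and *planar-linear* when |τ| ≤ ε_τ or
the point is linear (T = L ∪ H: a line lies in a plane). A Gaussian
scale space γ_s (per-coordinate convolution, std s) is indexed in
micrometers through the radius of curvature r_κ = 1/κ: an analysis scale
r̂ (μm) maps to the set of Gaussian scales at which the curve's sub-r̂
detail is flattened. Around that working regime, the most *stable*
combination of fragments (the one persisting over the longest
sub-interval of scales) is selected, in two hierarchical passes — first
planar-linear regions versus 3D, then 1D fragments nested inside them —
yielding an exact tiling of the curve by fragments labelled 1/2/3.

Scanning r̂ over a grid gives, per point, the **local 3D scale**: the
smallest scale at which the curve around the point stops being 3D
(operationally, the first scale of the longest non-3D run along the
scale axis; points 3D everywhere receive the grid maximum). Straight
tract segments score a few μm; convoluted terminal arbors score
50–150 μm.

Whole arbors are handled by cutting the tree into root-to-leaf curves,
computing the profile per curve, and averaging per node over the
overlapping curves.

The package also ships the validation apparatus: an active-Brownian-
motion simulator producing ground-truth-labelled composite curves
(lines, exactly planar 2D paths, spherical-angle 3D paths, plus white
noise), the fragment-matching F1 accuracy metric, and a
collinearity/coplanarity baseline without scale space.

## Worked example

```python
import numpy as np
from nadder import decompose_at_scale, simulate_composite
from nadder.evaluate import decomposition_accuracy

rng = np.random.default_rng(0)
sim = simulate_composite(dims=[1, 2, 3], sigma=2.0, rng=rng)  # line, plane, 3D

dec = decompose_at_scale(sim.curve, r_hat=20.0)
print(dec.to_frame())
print(decomposition_accuracy(sim.truth_fragments(), dec.fragments))
```

prints

```
  start_um     end_um  label
  0.000000  12.943700      3
 13.225085  87.792052      1
 88.073436 176.428258      2
176.709643 281.103396      3
0.909
```

— at a 20 μm scale of interest the noisy curve splits into a ~75 μm
line (label 1), a ~88 μm planar stretch (label 2) and 3D remainder, and
the fragment-matching accuracy against the simulator's ground truth is
0.91. The short leading 3D fragment is boundary erosion where the noisy
line meets the start of the curve.

For the local 3D scale of a curve, an SWC arbor, or midline-crossing
counts, see the scripts in `examples/` — each builds a small input, runs
one capability and explains the numbers it prints. A thin CLI wraps the
same functions:

```sh
nadder simulate --n-fragments 3 --sigma 5 --seed 1 --out curve.csv
nadder decompose curve.csv --r-hat 20 --out fragments.csv
nadder local3d neuron.swc --max-scale 100 --out local3d.csv
nadder benchmark --n-curves 100 --sigmas 1,5,10,20,30 --mode optimal \
    --seed 0 --out report.csv
nadder crossings neuron.swc --axis x --offset 0
```

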