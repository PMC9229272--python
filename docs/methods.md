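# Methods

## The measurement model

A cell in an ODEP chip that self-rotates about an axis **in** the image
plane ("out-of-plane rotation") presents a periodically breathing
silhouette: modeling the cell as a triaxial ellipsoid with semi-axes
(a, b, c) rotating about the column axis, the projected outline is an
ellipse with semi-axes `u(θ) = √(a²cos²θ + c²sin²θ)` and `b`, so the
projected area `π·u(θ)·b` oscillates with the rotation angle θ. Any rigid
silhouette is mirror-symmetric under a half revolution, so *outline* area
is always π-periodic: one area cycle per **half** revolution. Internal
structure (dark organelle-like spots that segment out of the foreground,
or shape asymmetries) modulates the measured area with the **full**
period. The `symmetry_factor` (2 or 1) converts area-cycle frequency to
rotation frequency accordingly; it is an explicit user parameter because
whether a given cell's signal is half- or full-periodic is a property of
the specimen, not of the algorithm.

When the rotation axis is the optical axis ("in-plane"), the outline is
constant and the area signal is produced instead by counting foreground
pixels inside one fixed quadrant (top-left, by convention — any fixed
quadrant carries the same period) of the cell's minimal bounding box.

Speed follows from the trough spacing of the (smoothed) area curve:
`n_i = 60·f_fps / (ΔX_i · s)` rpm per adjacent trough pair, summarized as
mean ± maximum deviation over cycles, plus a pooled single-ratio estimate
`60·f_fps·K / ((X_last − X_first)·s)` which has lower quantization
sensitivity for many cycles.

## Pipeline and parameters

| parameter | default | units | rationale |
|---|---|---|---|
| `gamma` | 0.3 | – | tone-curve exponent; chosen so a ~35% quadratic corner falloff on a bright-center field loses ≥half its background std (the std ratio scales as `γ(255/B)^{1−γ}`); 0.5 provably caps out just *below* a 50% reduction |
| vignette route (videos) | entropy | – | a tone curve is monotone and can never re-order corner-background vs. cell pixels; only a multiplicative gain correction makes the *global* Otsu threshold separate cell from background under strong vignetting. The gain is fitted once per video on the first frame (the vignette belongs to the optics, not the frame) |
| gain model | `1 + c₁ρ² + c₂ρ⁴`, cᵢ ≥ 0 | – | even radial polynomial, ρ = r/r_corner; coefficients by Powell search minimizing log-luminance histogram entropy |
| `min_area` | 30 | px | ~quarter of a 24 px-diameter cell footprint; removes debris specks and broken-cell fragments |
| dilation | disk, radius 1 | px | single smoothing pass of the outline |
| `smooth_width` | 5 | frames | uniform kernel; **must be shorter than the shortest area cycle**: a width-w moving average has gain `sin(πw/P)/(w·sin(π/P))` at period P and annihilates P ≈ w. The benchmark analyses use width 3 because an 86 rpm half-period at 15 fps is ~5.2 frames |
| `min_separation` | 3 | frames | trough spacing floor; sets the detection limit (a half-period signal above ~150 rpm at 15 fps is unresolvable; a full-period signal is fine to beyond 155 rpm) |
| `min_prominence` | 2% of series mean | px | rejects noise wiggles between genuine cycle minima |
| association gate | 2 × bbox diagonal | px | prevents identity switches to neighboring cells |
| frame-difference threshold | max(Otsu, 3σ̂) | grey | σ̂ = MAD-based noise sigma of the difference image; moving pixels are a tiny fraction of the frame, so Otsu alone would split the noise distribution |

Numerical conventions: all enhancement arithmetic is floating point with a
single uint8 quantization at the end of the per-frame chain; Otsu ties
resolve to the smallest threshold; detections are ordered by bounding-box
origin; exact centroid-distance ties go to the lower label; frame numbers
are 0-based internally and 1-based in every user-facing output.

## Entropy objective

The shading fit minimizes the Shannon entropy of the histogram of the
log-mapped luminance `i(L) = 255·log(1+L)/log 256` (the log base cancels in
the ratio). Two details matter: the objective evaluates **unclipped** float
intensities, and the histogram uses **fixed unit-width bins** extended as
far as the data reach. A uniform gain then only shifts the log histogram,
leaving entropy unchanged; without this, saturating every pixel at 255
collapses the histogram and becomes a degenerate global minimum.

## What the synthetic scenes emulate — and what they do not

The generator reproduces the features the algorithm must be robust to:
quadratic radial vignetting (multiplicative gain `1 − s·(r/r_corner)²`),
low cell/background contrast (default 135 vs 95 grey levels), Gaussian
sensor noise (σ = 3), static bright specks and dim broken-cell fragments,
out-of-plane and in-plane rotation at 20–160 rpm, and linear or circular
drift. Rendering is deterministic given the seed; a pixel is foreground
iff its center lies inside the projected ellipse, so silhouette areas are
exact up to rasterization.

It deliberately omits: defocus and PSF blur, Brownian jitter, cell
deformation, photobleaching, and occlusions between cells. Passing tests
therefore demonstrate correctness of the *extraction algorithm* under the
modeled imaging conditions, not robustness to every optical artifact of a
real microscope; in particular, segmentation of strongly defocused or
touching cells is out of scope (the method assumes a well-separated cell
of interest, selected manually — the one manual step).

Benchmark problem sizes: 159-frame videos of 192×192 px with ~24 px cells
— small enough that the full 25-video speed sweep renders and analyzes in
tens of seconds, large enough that a cell of ~450 px area yields area
signals an order of magnitude above noise.

## Design choices where the design was open

- **Sweep scenes are in-plane spot-textured spheres (s = 1).** Outline
  area is π-periodic for *any* rigid body, so at 155 rpm/15 fps the
  half-period (~2.9 frames) sits below the 3-frame trough-separation
  floor; the full-revolution texture signal (~5.8 frames) does not. The
  out-of-plane case is covered separately by the 86 rpm reference run.
- **Tracking** is nearest-centroid association with a gate rather than a
  filter bank; the trajectory predictor is constant-velocity
  extrapolation, the minimal model that supports gating. Positions are
  refined to segmentation centroids because a frame-difference mask
  straddles vacated and newly covered ground and lags a fast mover by
  half a step.
- **Per-cycle mean vs pooled estimate.** Both are reported; the mean of
  per-cycle speeds matches the mean ± maximum-deviation error-bar
  convention, the pooled ratio is less quantization-biased at high speeds.

## Known limitations

- Trough frames are integer-quantized: single-cycle speeds at high rpm
  scatter strongly (e.g. 5- vs 6-frame half-cycles at 86 rpm → 90 vs 75
  rpm); only the multi-cycle mean is meaningful, and the quantization
  bias grows as cycles shorten toward the separation floor.
- A texture-free spherical cell rotating in-plane produces *no* area
  signal in either mode — rotational symmetry makes the rotation
  unobservable by area, which is a physical limit of the method, not an
  implementation one.
- The entropy fit assumes radially symmetric, center-anchored shading
  with g(0) = 1; off-center or non-radial illumination is approximated
  only to the extent the even-polynomial basis allows.
- AVI decoding requires an imageio video plugin; TIFF stacks and PNG
  directories are the bit-exact reference dialects.
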