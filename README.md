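# rotospin

Extracts the **self-rotation speed** (rpm) and **motion trajectory** of
individual cells from microscopy video of an optically induced
dielectrophoresis (ODEP) microfluidic chip, using the *area-change* method:
as a cell rotates out of the image plane, its projected silhouette area
oscillates, and the spacing of the area minima (troughs) gives the rotation
period.

It is written for experimentalists characterizing cell dielectric and
mechanical properties from rotation spectra, who today often time rotations
by eye with a stopwatch. Because real chip recordings are rarely shareable,
the package also ships a synthetic-scene generator that renders rotating,
translating cells under realistic chip imaging conditions (dark vignetted
corners, low contrast, sensor noise, debris) with exact ground truth, so
the whole pipeline is testable end to end.

## Method

Per frame: grayscale → shading removal → contrast stretch → Otsu
binarization → small-object removal + disk dilation → connected-domain
labeling. The cell of interest is seeded once, then followed by
nearest-centroid association within a gate. Its per-frame area `A_t` forms
the area-change curve, which is smoothed with a uniform moving-average
kernel; troughs `X_1 < X_2 < … < X_m` (local minima with a minimum
separation and prominence) give per-cycle speeds

```
n_i = 60 · f_fps / ((X_i − X_{i−1}) · s)        [rpm]
```

where `f_fps` is the frame rate and `s ∈ {1, 2}` the symmetry factor: a
texture-free convex cell projects the same silhouette every half
revolution (π-symmetry), so its outline-area signal repeats twice per turn
(`s = 2`); internal structure (spots, asymmetries) restores the full
period (`s = 1`). The reported speed is the mean of the per-cycle speeds
with the maximum absolute deviation as the error bar, plus a pooled
single-ratio estimate.

For **in-plane** rotation the outline never changes; instead the package
counts foreground pixels inside one fixed quadrant of the cell's bounding
box, which internal structure modulates once per revolution.

Shading removal offers two routes: a fast gamma tone curve (`γ = 0.3`
default) and an entropy-minimization fit of an explicit multiplicative
radial gain field `g(r) = 1 + c₁r² + c₂r⁴` — the log-luminance histogram
of a flat field is maximally concentrated, so the fitted gain is the one
that minimizes its Shannon entropy. Video pipelines default to the entropy
route with the gain fitted once on the first frame.

Trajectories come from frame differencing (moving-target detection) plus a
constant-velocity prediction gate, with the position refined to the
segmented-cell centroid.

## Worked example

```python
import rotospin as rs

# 159 frames at 15 fps: textured ellipsoid rotating out-of-plane at a
# true 86 rpm, with vignetting, noise and background debris
config = rs.replica_scene(rpm=86.0, seed=0)
stack, (truth,) = rs.render_video(config)

result, series = rs.measure_rotation(
    stack, seed=(96, 96),            # click on the cell of interest
    frame_window=(101, 159),         # stabilized tail of the recording
    smooth_width=3, symmetry_factor=2,
)
print(f"{result.mean_rpm:.1f} ± {result.max_deviation_rpm:.1f} rpm "
      f"over {result.n_cycles} cycles; troughs {result.trough_frames.tolist()}")
```

prints

```
85.5 ± 10.5 rpm over 10 cycles; troughs [102, 108, 113, 118, 123, 129, 134, 139, 144, 149, 155]
```

The true speed is 86 rpm; trough frames are integer-quantized, so adjacent
half-cycles of ~5.23 frames alternate between 5 and 6 frames — the
per-cycle speeds scatter (hence the ±10.5 deviation over single cycles)
while their mean lands within half an rpm of truth.

The same is available from the shell:

```
rotospin synth --scene replica --rpm 86 --out video.tif --truth truth.csv
rotospin measure video.tif --fps 15 --seed-point 96,96 \
        --frames 101:159 --smooth 3 --symmetry 2 --out results/
rotospin track video.tif --fps 15 --seed-point 96,96 --out trajectory.csv
```

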