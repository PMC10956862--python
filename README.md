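# spinelcm

Unsupervised spine segmentation and automatic Cobb-angle measurement for
anteroposterior (AP) spinal radiographs, built on the **local center of
mass** (LCM) clustering principle and a purely geometric chord/apex
construction of the Cobb angle.

Scoliosis severity is graded by the Cobb angle, and manual measurement on
radiographs is slow and observer-dependent. Supervised segmentation needs
labeled training data; the LCM approach needs none: it clusters pixels by
where their intensity-edge-weighted centers of mass accumulate, so it
adapts to each image individually. This package is aimed at researchers in
medical image analysis who want a fully inspectable, deterministic
measurement chain they can validate end-to-end on synthetic phantoms with
analytic ground truth.

## Method

**1D local center of mass.** For a signal f over positions Ω = {1..N},

    C_n = Σ_m w_{m,n} m / Σ_m w_{m,n},   w_{m,n} = exp(−|D_m − D_n|),
    D_n = α Σ_{i<n} |f_{i+1} − f_i|^p

The cumulative edge energy D is nondecreasing, so |D_m − D_n| is the total
edge magnitude between the two positions: positions separated by a strong
edge effectively stop seeing each other, and within a homogeneous interval
C_n points at the interval's center (C is nearly piecewise constant). The
naive sum is O(N²); monotonicity of D lets C be computed in O(N) with
forward/backward recurrences whose exponents are all ≤ 0, stable up to at
least α = 5000. The brute-force form is kept as an oracle and the two are
verified to agree to < 1e−6.

**2D segmentation.** The image is scanned with K families of parallel lines
(orientations evenly spaced over [0°, 180°)); along every scanline C_n − n
is a signed displacement toward the local segment center. Averaging the K
per-orientation displacement vectors gives a field V under which one tracker
per pixel is iterated: phase 1 advects x ← x + V(x); phase 2 consolidates
each tracker to the mean of its neighbors within a merge radius. Trackers
ending within a linkage distance of each other share a region label. The
procedure contains no randomness.

**Spine mask and center curve.** Labels darker than the midpoint of the
label-brightness range are subtracted as background; the largest connected
component of the rest is the spine mask. Canny edges of the mask give the
two walls, and the per-row midpoint of the leftmost/rightmost wall —
interpolated across gaps, smoothed by a centered moving average, and with
corner-sliver end rows replaced by extrapolation — is the center curve.

**Cobb construction.** With U/L the curve endpoints, M/N the chord–curve
crossings (the endpoints themselves, plus any interior crossings reported
for S-shaped curves), and C the point of maximum perpendicular deviation
from the chord, perpendiculars to MC at M and to NC at N meet at O; P is the
foot of O on MN. The reported angle (convention `mon`) is ∠MON; the
`eq5_printed` convention is its supplement. For a circular-arc center curve
of central angle φ the construction yields exactly φ/2, which is the
analytic oracle used throughout the tests. Curves whose maximum deviation
is below a threshold (default 3 px at 256×256) are labeled *no scoliosis*.

## Worked example

```python
from spinelcm import PhantomSpec, generate_phantom, PipelineConfig, measure_array

bundle = generate_phantom(PhantomSpec(
    curve_kind="circular_arc", arc_central_angle_deg=40.0,
    noise_sigma=0.02, seed=7))
rec = measure_array(bundle.image, PipelineConfig.desk())
print("truth", round(bundle.truth_angle_deg, 2),
      "measured", round(rec.result.angle_deg, 2),
      "n_regions", rec.n_regions)
```

prints

```
truth 20.0 measured 18.92 n_regions 3
```

A 40° circular arc has a construction truth of 20°; the full pipeline on the
noisy rendered phantom recovers 18.92° (1.1° error) after segmenting the
image into 3 regions. The same chain is available from the shell:

```
spinelcm fixtures phantoms/            # write a standard phantom set
spinelcm measure phantoms/phantom_02_circular_arc.png --desk --out out/
spinelcm batch phantoms/ out/ --desk   # routes into scoliosis / no_scoliosis
spinelcm evaluate pred_mask.png truth_mask.png
```

`--desk` selects the reduced-cost profile (K=8 orientations, 50 iterations);
the full-scale defaults are α=2000, K=180, 1000 iterations (250 of them
phase 2).

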