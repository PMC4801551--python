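# fruitfuse

Recognition of mature (red) fruit in canopy RGB images for robotic
harvesting, using only a low-cost color camera. The hard part of the
problem is robustness to the two disturbances that dominate real
greenhouse scenes: spatially varying illumination (strong sunlight washes
color toward white) and occlusion of the ripe fruit by clusters of pale
immature fruit whose hue overlaps the foliage.

`fruitfuse` implements a classical, fully deterministic pipeline:

1. **Feature extraction.** Two chrominance images are computed per frame:
   the a\* component of CIE L\*a\*b\* (red–green axis, computed from
   chromaticity coordinates r = R/(R+G+B), hence intensity-invariant) and
   the I component of NTSC YIQ (orange–cyan axis, linear in the raw 8-bit
   channels). Each is min–max normalized to [0, 1].
2. **Wavelet fusion.** Both features are decomposed with a 3-level 2-D
   DWT (db2, symmetric extension) and every coefficient subband is
   blended as C = (1 − d)·C₁ + d·C₂, where the weight
   d = max(L_max) − min(L_max) is the dynamic range of the elementwise
   maximum L_max of the two normalized features. The blend is
   reconstructed and clipped to [0, 1].
3. **Adaptive thresholding.** The fused image is mapped to the 0–255 gray
   scale and two global thresholds are computed: an iterative
   (ISODATA-style) class-mean fixed point T_m and Otsu's between-class
   variance maximizer T_n. The final threshold is T_f = min(T_m, T_n);
   pixels above T_f (the bright fruit) become foreground.
4. **Noise removal.** Connected components (8-connectivity) smaller than
   200 pixels are discarded.

Single-feature arms (a\*-only, I-only) and a plain pixel-mean fusion
baseline share the same thresholding and filtering, which makes
controlled method comparisons possible. A seeded synthetic scene
generator renders canopy scenes with per-object ground truth for the two
disturbance regimes, and an evaluation harness scores recognition by
intersection-over-union against the visible mature-fruit mask.

## Worked example

Generate a clean synthetic scene, segment it, and inspect the result:

```sh
$ fruitfuse synth --n 1 --disturbance none --seed 7 --out demo
wrote 1 scene(s) to demo
$ fruitfuse segment demo/scene_000.png --out demo/mask.png --debug-dir demo/debug
regions=1 t_f=51.0
```

One region survives the area filter. The threshold report in
`demo/debug/threshold_report.json` shows the adaptive rule at work: the
iterative threshold converged to T_m ≈ 118.0, Otsu's search returned
T_n = 51.0, and the min-combination picked T_f = 51.0 — low enough to
capture the radially shaded rim of the fruit. Scored against the ground
truth, the surviving region (2944 px) overlaps the true mature-fruit mask
with IoU ≈ 0.99:

```python
from fruitfuse import generate_batch, segment, evaluate
scene = generate_batch(1, "none", seed=7)[0]
result = segment(scene.image)
print([r.area for r in result.regions.regions])   # [2944]
print(evaluate([result], [scene]).best_ious)      # [0.988...]
```

The methods-by-disturbances contrast experiment prints a table of
recognition rates (fractions in [0, 1]):

```sh
fruitfuse experiment --n 100 --seed 1 --out table.csv
```

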