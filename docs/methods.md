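# Methods

## Color features

The pipeline uses two chrominance features chosen for complementary
robustness.

**a\* (CIE L\*a\*b\*, chromaticity-based).** The RGB pixel is first
reduced to chromaticity coordinates r = R/(R+G+B), g, b; a black pixel,
whose chromaticity is undefined, maps to the gray point (1/3, 1/3, 1/3)
so the conversion is total and continuous with dark grays. The
chromaticity triple is mapped to XYZ by a fixed 3×3 matrix whose rows
each sum to 1 — so any gray input lands exactly on X = Y = Z — and then
to L\*a\*b\* through the standard piecewise companding function
f(t) = t^(1/3) for t > 0.008856, else 7.787·t + 16/116 (continuous at the
breakpoint to ~1e−4). Because the input is chromaticity, a\* is invariant
to multiplicative intensity changes (shading, smooth illumination gain);
its weakness is additive desaturation — color washed toward white loses
its a\* signal — and chromaticity noise amplification in dark pixels.
No white-point adaptation, gamma linearization or ICC management is
applied: the conversion is the plain matrix-plus-companding chain above.

**I (NTSC YIQ).** A linear combination of the *raw* 8-bit channels,
I = 0.5957 R − 0.2745 G − 0.3213 B. Being luma-coupled, it preserves a
strong fruit/background gap under desaturation, but bright yellow-green
objects (immature fruit) acquire a non-trivial positive I. The YIQ matrix
is applied to raw channels, not chromaticities: that is the standard
definition, and the feature's useful dynamic range depends on it.

Each feature image is min–max normalized to [0, 1] before fusion
(constant images map to zero). Normalization is what makes the fusion
weight below a genuine convex mixing proportion. All arithmetic is double
precision; quantization to the 0–255 scale happens once, after fusion.

## Wavelet fusion and the range weight

Both normalized features are decomposed with a multilevel 2-D discrete
wavelet transform (default: db2, 3 levels, symmetric boundary extension,
via PyWavelets). The fusion weight is computed in the spatial domain:
L_max is the elementwise maximum of the two normalized images ("compare
the two matrices, keep the larger value per pixel"), and
d = max(L_max) − min(L_max) ∈ [0, 1] is its dynamic range. Every
coefficient subband is blended as C = (1 − d)·C₁ + d·C₂ and the result
reconstructed and clipped to [0, 1].

Two consequences of this rule are worth stating plainly:

* **Scalar-weight equivalence.** A single scalar applied to all
  coefficients of a linear, perfectly invertible transform commutes with
  reconstruction, so the fused image equals the pixelwise mixture
  (1 − d)·A + d·B to within reconstruction round-off (< 1e−6). The test
  suite uses this identity as the fusion module's main oracle. The
  wavelet path is retained because it is the specified mechanism and
  because a per-subband weight variant (`fusion.per_subband_weight`, off
  by default) genuinely needs it: there, each subband pair gets its own
  range-derived d, clamped to [0, 1].
* **The weight saturates near 1 on realistic scenes.** d = 1 − min(L_max),
  and min(L_max) is attained at the pixel that is darkest in *both*
  features simultaneously. Any canopy scene contains deep-shadow or dark
  foliage pixels that are near the minimum of a\* and of I at once, so in
  practice d ≈ 0.9–1.0 and the fused image lies close to the I feature
  with a small a\* admixture. The admixture is systematically helpful —
  it depresses immature-fruit pixels (low in a\*) and slightly raises
  mature-fruit pixels — but the fusion cannot move far from the I arm
  under this global rule. This is a property of the method as defined,
  not of the implementation; the per-subband option exists for users who
  want a weight that adapts locally.

A pixel-mean baseline (`simple_fusion`, effectively d fixed at 0.5) is
provided for comparison.

## Adaptive thresholding

The fused [0, 1] image is mapped to the 0–255 scale (×255, rounded)
because a global gray threshold is only meaningful at 8-bit resolution.
Two estimators run on the result:

* **Iterative (ISODATA-style) threshold T_m.** T⁰ = (T_max + T_min)/2;
  at each step the image splits into A = {values > T} and
  B = {values ≤ T} (ties to B, matching the binarization convention) and
  T ← (mean_A + mean_B)/2, iterating until |ΔT| < 0.5 gray levels —
  sub-quantization precision being meaningless for an 8-bit threshold.
  Convergence takes at most a few dozen steps (the trace is recorded and
  bounded at 256); a constant image returns the constant, flagged
  degenerate.
* **Otsu threshold T_n.** Exhaustive search over all 256 candidate
  levels for the maximizer of between-class variance w₀w₁(μ₀ − μ₁)²,
  ties broken by the lowest maximizing level (deterministic and
  pixel-order independent).

The final threshold is T_f = min(T_m, T_n). Foreground is *values above
T_f* by default (`threshold.polarity: high`): mature fruit is the bright
structure in the fused feature image. The literal low-side rule
(foreground = values ≤ T_f) is available as `polarity: low` for
completeness; the two conventions are exact complements.

## Post-processing

Connected components of the binary mask (8-connectivity by default, so
anti-aliased boundaries are not split) smaller than 200 pixels are
removed; components of exactly 200 pixels are retained (strict <). No
other morphology is applied — the area rule is the specified de-noising
step, and on the synthetic scenes it is what removes the bright
dried-leaf specks that pass the threshold.

## Synthetic scenes

The generator renders 388×260 RGB canopy scenes (the resolution of a
low-cost harvesting-robot CMOS camera) composed back-to-front: greenish
backdrop; ~200 foliage ellipses whose R and B channels are sampled as
0.40–0.52 of a green base, keeping leaves in a narrow chrominance band;
a handful of small (3–7 px axis) warm "dried leaf" specks whose I value
sits near the fruit's, exercising the area filter; radially shaded red
discs (mature fruit, R 160–230 / G 30–90 / B 30–70); pale yellow-green
discs (immature fruit, G = R + 10–30 with R 155–195) that may overlap a
mature fruit; and finally Gaussian pixel noise (σ = 2 by default).

Disturbances:

* **Illumination**: a random-direction linear ramp applies a
  multiplicative gain (1 ± 0.5·strength) *and* a desaturating blend
  toward white of up to 0.65·strength, plus specular highlight discs on
  fruit. The washout term is essential: a purely multiplicative gradient
  would leave chromaticity — and hence a\* — untouched, which is not how
  sunlight degrades real color segmentation.
* **Overlap**: immature fruit are attached to a mature host at center
  distance (1 − f)·(r_host + r_imm) with f the overlap fraction, their
  radius constrained to 0.6–0.9 of the host's so a moderate cluster can
  never hide the host's center. The mature ground-truth mask is the
  *visible* (non-occluded) disc, which is what a pixel classifier can
  recover.

Batch presets study each disturbance in isolation: the `none` and
`illumination` groups render no immature fruit; the `overlap` group uses
two occluders at f = 0.35 with no illumination gradient. Every scene is a
pure function of (config, seed); batches derive per-scene seeds as
seed + index.

What the generator does *not* model: 3-D canopy geometry, leaf occlusion
of fruit, specular anisotropy, chromatic camera noise, JPEG artifacts, or
natural variation in fruit ripeness. Passing tests on these scenes
demonstrate the pipeline's internal correctness and its qualitative
disturbance behavior, not field performance on greenhouse imagery.

## Evaluation

An image counts as recognized iff some surviving region overlaps a
mature-fruit mask with IoU ≥ 0.5 *and* no surviving region "recognizes"
an immature fruit instead — i.e. no region's best overlap is with an
immature mask at IoU ≥ 0.5. The guard operationalizes misidentification
(reporting an unripe fruit as the target) as failure while not letting a
few stray noise pixels that merely graze an immature mask void an
otherwise correct detection.

On the generator's default settings (100 scenes per disturbance group),
the observed ordering is stable across seeds: the fusion method matches
the I arm's perfect robustness to illumination (where the a\* arm drops
to ~0.8) and bounds the I arm from above under overlap (where the I arm
is weakest). Because the global range weight saturates near 1 (see
above), the fused image cannot also dominate the a\* arm under overlap —
the a\* arm, insensitive to the pale occluders' brightness, is stronger
there, and the pixel-mean baseline (d = 0.5) outscores the range-weighted
fusion in that group. A fusion rule intended to dominate both single
features in both regimes would need a weight that does not collapse to
the I endpoint; the per-subband variant is a starting point.

## Numerical conventions

* Double precision throughout; 8-bit quantization only at file output
  and at the threshold stage.
* Degenerate (constant) images: normalization returns zeros, thresholds
  return the constant with a degenerate flag, segmentation returns an
  empty region list rather than raising.
* Wavelet boundary handling: symmetric extension; reconstruction cropped
  to the source shape and clipped to [0, 1].
* All ties are deterministic: threshold ties to class B (≤), Otsu ties
  to the lowest level, region labels ordered by scan order.
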