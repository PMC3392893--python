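# Methods

## Model and procedure

The detector treats OD localization as two sub-problems: *where are the
vessels and which way do they run* (stage 1), and *where does the local
vessel pattern look like a disc* (stage 2).

### Stage 1: multiscale matched filtering

The green channel carries the best vessel contrast in fundus photography; it
is min–max normalized to [0, 1] inside the circular field of view (FOV),
estimated from the red channel by thresholding at 10% of its maximum,
keeping the largest connected component, and filling holes. Min–max
normalization (rather than percentile clipping) is used because the stage-2
intensity gate is an absolute cutoff at 0.9 on this scale; a constant
channel maps to all zeros by convention.

Vessels are dark ridges with an approximately Gaussian cross-section, so
each scale `s` gets a matched filter: a truncated Gaussian profile across
the vessel, constant over a length `L` along it, with the mean
`m = erf(t/√2)/(2 t s)` subtracted. The truncation half-width is
`ceil(t·s)` (the integer grid needs a discretization of the `|x| ≤ t·s`
support; `ceil` keeps at least the full analytic support). Two numerical
choices matter:

- **Rotation by analytic resampling.** Oriented kernels are produced by
  evaluating the analytic expression on a rotated coordinate grid rather
  than by interpolating a rotated array, so no resampling error compounds.
  Out-of-support samples are zero.
- **Exact re-centering.** `m` zeroes the *continuous* mean only; after
  discretization the residual mean over the support samples is subtracted
  so each kernel sums to zero exactly. Constant backgrounds then contribute
  exactly nothing to the response.

Orientation convention: θ ∈ [0, π) is the vessel direction measured from the
image vertical (row) axis, so the unrotated kernel (L rows × 2·ceil(t·s)+1
columns) responds maximally to a vertical vessel; bin k of 8 corresponds to
θ = (k−1)π/8. Vessels are undirected, hence the half-circle domain.

Responses use reflect padding, are sign-flipped (vessels are dark; the
filter as written responds to bright ridges), maximized over the 8
orientations per scale, and zeroed within one kernel radius of the FOV rim
to suppress rim artifacts.

**Scale production.** `P = R_i · R_j` multiplies the orientation-maximal
responses at two scales (the common scale-production reading; per-orientation
products would differ only at crossings). Structure present at both scales
is reinforced; uncorrelated noise is suppressed quadratically.

**Double thresholding.** Hysteresis on each product: strong pixels at or
above the `t_high_quantile` = 0.975 quantile of P over the FOV, weak pixels
at or above `t_low_fraction` = 0.5 of that value, weak kept only when
8-connected (transitively) to strong. Quantile anchoring makes the rule
robust to image-to-image brightness changes. Whether the original
formulation used hysteresis or two independent cutoffs is ambiguous;
hysteresis is implemented because it is the standard reading of "double
thresholding" and degrades gracefully. A constant product map yields all
background. Raising the high quantile can only remove pixels (monotonicity),
which the tests exercise.

The (s₁,s₂) and (s₃,s₄) maps are OR-combined, thinned
(`skimage.morphology.thin`, topology-preserving), and each centerline pixel
is labeled with the orientation of the globally maximal raw response across
all scale/orientation pairs. Per-scale response standardization before the
cross-scale argmax was measured to give no better orientation accuracy than
the raw argmax (both ~0.94 within one bin on synthetic scenes), so the
simpler rule is kept.

### Stage 2: VDMF matching

Centerline pixels with normalized intensity ≥ 0.9 become candidates, each
carrying a 51×51 window of the directional map (zero-padded at borders;
windows are exported for inspection, while scoring reads the full-extent
map). The gate applies to *centerline* pixels, not all bright pixels: the
matcher needs vessel patterns, and bright vessel-free lesions are rejected
by the matching itself.

The 9×9 base template encodes the vascular arch: the vessel through cell
offset (Δr, Δc) is modeled as belonging to the parabola family
`Δc = k·Δr²`, whose tangent direction is ∝ (Δr, 2·curvature·Δc). The center
column is vertical, the horizontal midline tends to horizontal, and the
field is mirror-symmetric up to orientation reflection. `arch_curvature`
(default 1.0, dimensionless) scales the bend rate. The original figure
defining the template's cell values is not machine-readable, so the grid is
generated from this explicit model; a verbatim 9×9 CSV can be supplied
instead (`build_templates(base=...)`).

The base grid is resized to 61×21 and 121×41 (covering small and
medium-to-large disc vessel maps) by corner-aligned bilinear interpolation
of the codes, giving real values in [1, 8]. Interpolating codes across the
1↔8 wrap is accepted as part of the method's definition.

Scoring uses the *circular* orientation distance
`d(a, b) = min(|a−b|, 8−|a−b|)·π/8`: orientation codes are angles modulo π,
so bins 1 and 8 are adjacent; a raw absolute code difference would make them
maximally distant, an artifact of the encoding. Per template, the distance
is averaged over cells coinciding with centerline pixels (mean rather than
sum, so sparse vessel coverage cannot trivially win); zero coinciding pixels
scores +∞. The two templates' means are summed, and the least total wins,
with lexicographic (row, col) tie-breaking for determinism. An all-infinite
or empty candidate set raises a diagnostic error.

## Parameters

| parameter | default | units | role |
|---|---|---|---|
| scales (s, L) | (1.5, 9), (1.8, 9), (2.0, 13), (2.4, 13) | px | matched vessel calibres |
| t | 3 | — | Gaussian truncation (> 99% mass) |
| n_orientations | 8 | — | orientation bins over [0, π) |
| pairings | (1,2), (3,4) | — | scale-production pairs, OR-combined |
| t_high_quantile | 0.975 | — | hysteresis strong threshold (FOV quantile) |
| t_low_fraction | 0.5 | — | weak threshold as fraction of strong |
| intensity_threshold | 0.9 | — | OD brightness gate on normalized green |
| window | 51 | px | candidate neighborhood size |
| template_dims | 61×21, 121×41 | px | VDMF working sizes |
| arch_curvature | 1.0 | — | bend rate of the template's arch model |

The hysteresis defaults were calibrated once on the reference synthetic
scene (seed 0) so the binary map covers ≥ 95% of the ground-truth
centerline; they are exposed in the configuration because real images vary.

## Synthetic scenes

The generator renders, at the 968×644 working resolution: a circular FOV
(radius 300 px), a background retina at 140/255, a vertical-oval disc
(radii 62×50 px) with a flat core at saturation and a logistic edge, six
vessels leaving the disc center (two thick temporal arcades, four thin
branches; cross-section std 2.9 and 1.4 px, so the thick class is ~3.5 px
wider at half depth), one bright vessel-free exudate blob, and additive
Gaussian noise (std 2, 8-bit units). Vessel paths bend away from vertical
with arc length, φ(t) = φmax·(1−exp(−t/τ)): parabolic near the disc, where
the VDMF's model is valid, straightening to a near-horizontal run far from
it — the local validity of the arch model is exactly why template size
matters. Vessel depth is 12/255 everywhere: the 0.9 gate on a min–max
normalized image admits a disc-crossing centerline pixel only when the
vessel depth is ≲ 10% of the dynamic range; real images satisfy this
because the disc is near-saturated and disc vessels have low contrast, and
the generator encodes the same arithmetic directly. Ground-truth
centerlines are thinned to one pixel, and each centerline pixel carries its
tangent's orientation bin.

What the scenes do **not** emulate: luminosity/contrast gradients, choroidal
and nerve-fiber texture, JPEG artifacts, pathology beyond one exudate, and
vessel calibre tapering. Consequently, passing the end-to-end tests shows
the mechanism is implemented correctly, not that real-image accuracy
matches any published figure. One consequence is measured directly by the
test suite: because only disc pixels pass the 0.9 gate in these clean
scenes, *every* stage-1 variant (including each single scale) localizes
within a few pixels, so the expected advantage of multiscale + OR over the
best single scale does not manifest here — the corresponding comparison in
`tests/test_acceptance.py` documents this as a genuine failed expectation
rather than being weakened to pass. The template-size sensitivity (scaling
the template dimensions by 1.5 in either direction degrading the mean
distance) does manifest, because it depends on the arch model's local
validity, which the scenes reproduce.

## Problem sizes

End-to-end experiments use 20 seeded scenes at 968×644 (the working
resolution after 0.5 downscaling of a 1936×1288 frame), with disc position,
vessel geometry, and exudate placement jittered per seed; the full suite,
including those experiments, runs in about a minute on one CPU.

## Known limitations

- The FOV estimator assumes a dark surround and a bright red channel inside
  the illuminated circle; masked or cropped images need a supplied mask.
- The 0.9 gate fails on images whose disc is not near the FOV intensity
  maximum (e.g. severe media opacity); the threshold is configurable.
- Orientation codes are compared after bilinear interpolation of the code
  grid, inheriting the wrap-interpolation artifact noted above.
- Detection resolution is limited to the candidate grid (integer pixels);
  no sub-pixel refinement is attempted.
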