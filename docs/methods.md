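# Methods

This note records the models, conventions and numerical choices behind
`choroidpipe`, and what the synthetic-data tests do and do not establish.

## Coordinate and unit conventions

Row 0 is the vitreous side; rows grow toward the sclera; indices are
0-based. Every scan carries a lateral (`scale_x`) and axial (`scale_y`)
pixel size in µm/px; all metrics are computed in micron space so
anisotropic pixels are handled throughout. When a Heidelberg lateral
scale is not supplied, 9000 µm / 768 px ≈ 11.72 µm/px is assumed (a 30°,
9 mm field over 768 columns); the axial scale must always be supplied.
Boundary traces use a half-pixel edge convention: a column whose region
pixels occupy rows r0..r1 has its RPE-C junction at r0 − 0.5 and its C-S
junction at r1 + 0.5, so the vertical extent equals the pixel count
exactly.

## Synthetic B-scans

The generator renders the qualitative anatomy needed to exercise every
stage: dark vitreous; a four-stratum retina whose inner surface dips at
the fovea (Gaussian pit, depth `fovea_pit_depth`, lateral sigma 350 µm);
a bright stroma band (`stroma_intensity` 0.8) whose micron thickness
varies smoothly (two low-frequency cosines, ±`choroid_thickness_variation`)
around `choroid_mean_thickness`; dark elliptical vessel lumina
(`vessel_intensity` 0.2) with random eccentricity and rotation, larger
radii biased toward the scleral side (Haller/Sattler stratification);
and a mid-grey sclera. Tilt shears the band's centre line; the vertical
extent is inflated by 1/cos(tilt) so the *locally perpendicular*
thickness equals the configured micron value, which is what the
thickness algorithm must recover. Speckle is multiplicative log-normal
with unit mean, applied after the masks are frozen, so the returned
masks are the exact pre-noise geometry.

Vessels are placed by rejection sampling: an ellipse is rejected when
more than 25 % of its in-band pixels are already vessel. This keeps the
union area close to the per-ellipse tally (so the planted fraction is
analytically tracked) and mimics real lumina, which abut rather than
overlap. The default density (140 vessels of radius 20–120 µm on a
768-px scan; 95 of 25–90 µm on the 192-px test phantom) puts the planted
vessel fraction in the physiological vascularity range of roughly
0.45–0.55.

What the generator does *not* model: A-scan physics, depth attenuation,
spatially correlated speckle, shadowing under large vessels, pathology,
or real boundary ambiguity at the C-S junction. Passing tests therefore
demonstrate algorithmic correctness on separable, well-posed images, not
clinical-grade accuracy; the reported Dice values on phantoms are upper
bounds on what real data would give.

## MMCQ vessel segmentation

`median_cut` follows the classical recursive quantizer: buckets are kept
in ascending value order; the bucket with the largest max−min range is
split (ties toward the darkest bucket) at its count median, the lower
`n//2` values going left; zero-range buckets never split. Ties between
equal values keep their original order (stable sort). This convention is
pinned against an independently coded brute-force oracle in the tests.

Local enhancement tiles the region bounding box with square patches at
three scales (defaults 96/48/24 px on a 768-wide scan; scale them with
the image), truncating edge patches. Within a patch, region pixels are
quantized to `2^quant_bits` = 8 cluster means, mapped through the
empirical CDF of the quantized values, and then min–max stretched over
the patch. The stretch (darkest cluster → 0, brightest → 1) is a
deliberate addition to plain equalization: CDF mapping alone drives any
distribution toward uniform and can *reduce* the contrast of an already
strongly bimodal vessel/stroma patch, whereas the stretched version is
rank-preserving and never decreases the standard deviation of the
region pixels. Scale maps are blended by unweighted mean; pixels no
scale touched (and everything outside the region) stay bit-identical to
the input.

Global labelling median-cuts the enhanced region pixels into
`n_global_clusters` = 8 and labels the darkest `n_vessel_clusters` = 4
clusters as vessel. On smooth intensity distributions median cut is
approximately count-balanced, so 4-of-8 labels roughly the darkest half
of the choroid — consistent with physiological vascularity ~0.5–0.65.
Both counts are configuration, not claims about the original algorithm's
unpublished constants.

The ground-truth ensemble applies 5 gamma-fixed mean brightnesses
(0.2–0.5) × 5 linear contrast factors (0.5–3) and takes a per-pixel
majority vote; the default threshold 15/25 reads the "3:2 majority" as a
3:2 ratio (60 %), with any other threshold available in configuration.
Gamma is solved by bisection in log space (γ ∈ [1e−3, 1e3], tolerance
1e−4 on the mean); contrast is `clip(mean + f·(I − mean))`.

## Niblack baseline

Vessel where `I < mean_w + k·std_w`, window 51, `k = −0.05`, strict
inequality, population (ddof 0) standard deviation, reflect-without-
repeat ("mirror") border padding. Window statistics use separable
uniform filters and are tested to 1e−10 against a direct per-pixel loop.

## U-Net

Depth 7; encoder widths (8, 32, 64, 64, 64, 64, 64) — the stated design
raises the width from 8 to 64 over the first three blocks, and 32 is the
geometric midpoint chosen for the unstated middle value. Blocks are two
3×3 convolutions each followed by BatchNorm and ReLU; downsampling is
2×2 max pooling. Up-blocks use a 1×1 convolution that reduces the
channel count to the skip level's width, followed by ×2 bilinear
interpolation (align_corners=False), concatenation with the skip, and
another convolution block; the mirrored decoder widths follow directly
from reading the 1×1 as the channel-reduction step. A final 1×1 maps to
three logit channels (region, vessel, fovea); sigmoids are applied at
prediction time.

The network is implemented in numpy: im2col + BLAS matrix products for
convolutions, explicit backward passes for every layer, verified by
finite-difference directional-derivative checks (exact to ~1e−8 in
float64). Training is float32 throughout; the `mixed_precision` flag is
reserved and currently a no-op. Loss is per-pixel binary cross-entropy
averaged over the three channels; optimization is AdamW (lr 5e−4, weight
decay 1e−8, β = 0.9/0.999) with the global gradient norm clamped to 3
before each step; the recorded post-clip norms are asserted ≤ 3 + 1e−6.
Augmentations (horizontal flip p = 0.5; independent brightness/contrast
factors U(0.5, 1.5), p = 0.95; rotation U(−25°, 25°) with shear
U(−15°, 15°), p = 1/3; isotropic scale U(0.8, 1.2), p = 1/3) are applied
in random order per sample; geometric transforms warp image and targets
identically (nearest for binary channels, linear for image and fovea
heat map) and carry the fovea column through. Peripapillary scans
(1536 × 768) train on 768-wide crops at random multiple-of-192 offsets.

The fovea target is a 51 × 19 window centred at the annotated fovea:
exact pixel 1.0, fovea column 0.95, columns at distance d at
0.95 − 0.1·d (floored at the 0.01 background, a one-sided label
smoothing that stabilises training). Extraction convolves the column
sums with a normalised 21-tap triangular kernel (zero padding) and takes
the argmax, ties toward the lower index. The fovea *row* — needed only
to place the target window — uses the same filter on row sums; this row
rule is this package's choice, as no published procedure exists.

Scaled-down problem sizes: the convergence checks train the default
architecture on eight 128 × 128 synthetic scans for 150 epochs (about
five minutes on one CPU core), reaching training region Dice ≥ 0.99 and
exact fovea columns; one seeded run is part of the acceptance script.
Note the absolute BCE keeps a floor from the fovea channel's 0.01
background smoothing, so loss ratios are a weak convergence indicator;
Dice and fovea error are asserted instead.

## Metrics

The region of interest is the ETDRS macular width: the fovea column
± round(3000 µm / scale_x) columns (round half away from zero),
inclusive bounds, clipped to the image; volume scans, which carry no
fovea, are centred on the middle column. Peripapillary scans get no ROI
metrics — only binarized masks, with the vessel threshold lowered to
0.25.

Thickness is measured at the three columns spanning the ROI. At each,
the RPE-C tangent comes from an ordinary least-squares line fit over ±15
columns in micron space on the raw (unsmoothed) trace — a local fit is
unbiased at trace ends where a moving average would not be — and the
inward normal ray is intersected with the piecewise-linear C-S trace by
marching (step = min pixel pitch / 4) plus bisection. A flat band is
recovered exactly; sheared bands up to 25° are recovered within 2 %
(raster staircase ±0.5 px is the dominant error). Rays that exit the
image produce NaN with a warning. The 15-column moving-average copies of
the traces are retained on the `Boundaries` object for display.

Area is pixel counting times `scale_x · scale_y · 1e−6` mm². The hard
CVI divides binarized vessel pixels (∧ region) by total region pixels
within the ROI — the conventional, 1-bounded index; a `literal_ratio`
option computes vessel/non-vessel instead. The soft CVI is
Σ(p_vessel·p_region)/Σ(p_region), chosen among the possible
"probability ratio" readings because it reduces *exactly* to the hard
index on binary maps and converges to it monotonically as maps sharpen
(both properties are tested). Region maps binarize at 0.5 (strict >).

Agreement statistics: Pearson/Spearman via scipy; MAE and median AE;
Bland–Altman limits mean ± 1.96·SD (ddof 1) of the differences; ICC is
the two-way random-effects, absolute-agreement, single-measurement form
ICC(2,1), computed from the ANOVA mean squares and cross-checked against
pingouin's ICC(A,1). Dice with both masks empty is defined as 1.0. AUC
is the rank-based (midrank ties) form, tested against exhaustive pair
counting.

## Device preprocessing

Triton scans (992 × 1024) are cropped by 32 columns — symmetrically by
default, since the original side split is unstated; `left`/`right` are
available — then bilinearly resized to 768 × 768 with the pixel scales
rescaled so physical extent is preserved. Images load with per-image
min–max normalisation to [0, 1] (robust to 8- vs 16-bit exports);
constant images load as zeros with a warning flag.

## Known limitations

- The numpy U-Net trains at research-demo scale only; full-resolution
  768 × 768 training at realistic dataset sizes needs a GPU framework.
- MMCQ's published constants are not public; the defaults here are this
  package's calibration and are all exposed in configuration.
- The synthetic generator's simplifications (above) mean phantom scores
  should not be quoted as expected clinical performance.
- Suprachoroidal space, choriocapillaris-specific analysis, volume-level
  maps and choroid-axis-aligned ROIs are out of scope.
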