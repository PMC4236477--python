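# Methods

## Problem and model

Leaf color integrates chlorophyll and nitrogen status: nitrogen-starved
rice foliage yellows, well-fertilized foliage is dark green. A nadir
photograph of the canopy taken ~1 m above the plants therefore carries the
same diagnostic signal as a chlorophyll meter, over a far larger sampling
area. The package implements that diagnostic chain: G−R threshold
segmentation, 13 color indices from the canopy-mean channel values, Pearson
screening of indices against nitrogen variables, and four ordinary
least-squares calibration models

    Model 1: LNC  = α·SPAD + β·DAT + γ
    Model 2: LNC  = α·b*   + β·DAT + γ
    Model 3: SPAD = α·b*   + β·DAT + γ
    Model 4: SPAD = α·b*   + γ

with leaf nitrogen concentration (LNC, g kg⁻¹), the SPAD-502 meter reading
(dimensionless), the CIELAB yellow–blue chroma b\*, and days after
transplanting (DAT) as the continuous development covariate. Developmental
stage labels (vegetative, tillering, jointing, booting) are carried as
metadata only; the models use DAT.

## Color conversion convention

Camera JPEGs do not state their colorimetry, and absolute L\*a\*b\* values
are convention-dependent. The package fixes a declared, configurable
convention: channels scaled to [0,1], the sRGB (IEC 61966-2-1) transfer
function, the sRGB primaries matrix, and the D65 2° white point with
Yn = 100. The conversion matrix rows are renormalized so the RGB white maps
*exactly* onto the white point; the published 7-digit coefficients miss it
by ~1e-7, which would otherwise give neutral grays a spurious nonzero a\*.
Consequences users should know:

* indices are computed from the canopy-mean R, G, B (one conversion per
  image), matching how per-image channel means are defined; a per-pixel
  mode (`per_pixel=True`) exists for sensitivity analysis, where nonlinear
  indices differ by Jensen-type gaps and hue is averaged arithmetically;
* degenerate inputs are flagged, not propagated as infinities: R+G+B=0
  gives r=g=b=1/3, zero chroma gives H=0, and b\*/a\* is NaN when
  |a\*| < 1e-9 (numerical neutrality tolerance);
* hue uses the standard hexcone piecewise formula with the natural branch
  order (R-max, G-max, B-max) and degrees in [0, 360);
* L\*a\*b\* values under a different convention (other primaries,
  chromatic-adaptation handling, camera profiles) are *not* comparable in
  absolute terms; chromatic adaptation and ICC handling are out of scope.

## Segmentation choices

The threshold on G−R defaults to Otsu's criterion evaluated exactly on the
integer G−R histogram (ties to the smallest threshold), because it adapts
across illumination regimes (sunny vs overcast acquisition) without
per-image tuning; a fixed threshold (default 0) is available. Canopy is the
strict upper side G−R > t, so boundary pixels at exactly t are background —
a deterministic, documented tie rule. Morphological cleanup (removal of
components smaller than a configured pixel count) and the white-spot
saturation filter (exclude pixels with all channels ≥ 250) are both off by
default since the core method is thresholding alone. Absolute coverage
values are convention-dependent (threshold method, cleanup), and shadows or
within-canopy illumination gradients are not modelled.

## Statistics conventions

* Calibration RMSE uses divisor n (not n−p), keeping the calibration and
  validation RMSE columns directly comparable; with n = 240 and p ≤ 3 the
  difference is below 1%.
* Validation R² is the squared Pearson correlation of predicted vs
  observed (configurable to 1 − SSE/SST via `validation_r2="sst"`); the
  correlation form is insensitive to a pure bias shift, which the separate
  NMB statistic is there to expose.
* NMB = 100·Σ(pred − obs)/Σobs, positive for over-prediction.
* Correlation screening uses pairwise Pearson r with two-sided p-values
  from the t transform (n−2 df), listwise deletion with logged counts, and
  significance markers at 0.05 / 0.01.
* Rank-deficient designs raise an error naming the collinear predictors.

## Synthetic data: what it emulates and what it does not

The generator defines the study conditions under which everything is
tested.

**Tables.** `simulate_dataset` follows the two-season field template:
calibration cultivars Liangyoupeijiu (DAT 16, 29, 51, 65; 18 records per
stage), Nanjing45 (16, 29, 51, 57; 18) and Nanjing46 (18, 35, 55, 75; 24) —
240 records — and validation cultivars Wuyunjing24 (25, 36, 50, 64),
Nanjing44 (22, 35, 49, 63) and Yangjing48 (22, 35, 49, 63) at 18 per stage —
216 records. Predictors are uniform: SPAD on [25, 45], b\* on [−10, 20].
These ranges are generator conventions chosen to give realistic response
spreads under the published coefficients; the study itself prints no
numeric index ranges. The response is the exact linear form plus
i.i.d. Gaussian noise whose sd defaults to the published calibration RMSE
of the chosen model. The response column a model does not involve is left
missing rather than invented from an auxiliary relation. Predictors are
drawn independently of DAT and cultivar; the real joint distribution of
b\* with development is only known from figures, so this independence is a
deliberate simplification — parameter-recovery results transfer to real
data only insofar as the linear model form holds there.

**Images.** `render_canopy_image` places randomly rotated ellipses with
aspect ratio ~1:4 (elongated blades, not botanically realistic) over a
uniform soil background (default RGB (120, 100, 80), satisfying G−R ≤ 0)
until the canopy fraction is within ±0.03 of target. Leaf pixels are the
configured CIELAB color converted to 8-bit RGB plus i.i.d. Gaussian channel
noise (default sd 5 digital numbers), clipped and quantized. White spots
overwrite a configured fraction of leaf pixels with G = 255 and R, B drawn
from [250, 255] — bright, slightly green-biased clipping, so spot pixels
have small positive G−R. Under a fixed-0 threshold they contaminate the
mask (and the saturation filter then demonstrably pulls recovered b\* back
toward the configured leaf value); under Otsu the split lands above the
spot cluster and excludes them anyway. Not modelled: sun angle, BRDF,
shadows, exposure variation — the renderer validates segmentation and
color-recovery logic, not radiometry, so passing tests say nothing about
illumination robustness in the field.

## Numerical choices

* Integer-histogram Otsu is implemented directly (vectorized cumulative
  sums over the unique G−R values, equivalent to an exhaustive scan of all
  511 integer thresholds) because library implementations bin continuously
  and cannot honour the integer tie rule; it is cross-checked against
  scikit-image's `threshold_otsu` in the test suite.
* The L\*a\*b\* forward/inverse pair round-trips XYZ to 1e-6 relative error
  above the linear-segment threshold, and 8-bit RGB→Lab→RGB round trips to
  within 1 digital number.
* Out-of-gamut Lab inputs to the inverse conversion are clipped with a
  warning (or raise, on request); the renderer requires its leaf color to
  be in gamut with G > R and refuses otherwise.
* All generators take explicit integer seeds (numpy `default_rng`); the
  pipeline writes no timestamps, so a rerun with the same configuration is
  byte-identical, and every output carries a SHA-256 configuration hash
  (output location excluded from the hash).

## Problem sizes

Rendered test scenes are 128×128 (96×96 for end-to-end runs) — large enough
that a scene holds dozens of leaf blades and segmentation IoU is measured
on thousands of boundary pixels, while keeping the full suite in seconds.
Recovery experiments use the full design size n = 240 with 200 replicates;
the end-to-end pipeline check uses 24 images, mirroring one cultivar-season
image set.

## Known limitations

* Absolute L\*a\*b\* values (hence fitted intercepts) shift under a
  different RGB→XYZ convention; only the declared-convention values are
  reproducible.
* The calibration models are pooled OLS; per-cultivar hierarchy, SLW
  correction and treatment ANOVA are out of scope.
* Validation R² conventions differ across the literature; both options are
  implemented and the choice is recorded in the model file.
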