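# Methods

## The simulated study

The object is a single axial slice (512×512 pixels, 500×500 mm field of
view, 0.9766 mm pixels, nominal 5 mm slice) through a water-equivalent
disk of 330 mm diameter holding sixteen 28 mm cylindrical inserts:
five iodine solutions (2.0, 5.0, 7.5, 10.0, 15.0 mg/mL) and eleven
tissue-mimicking rods (0.44–1.69 g/cm³). The hole assignment is not a
physical datum; the package's convention is an outer ring of twelve
inserts (r = 110 mm) and an inner ring of four (r = 55 mm), with dense
and light inserts interleaved so that high-attenuation inserts are
never adjacent (the physical analog of placing inserts to limit
beam-hardening artifacts).

Reference CT numbers: rods carry the same HU on both image types,
spanning −540 HU (lung rod, 0.44 g/cm³) to +1000 HU (dense bone,
1.69 g/cm³) via an approximately linear density→HU map. Iodine inserts
carry 25 HU per mg/mL on the 70 keV virtual monoenergetic image
(VMI70keV) and only a small residual (0.4 HU per mg/mL) on the virtual
unenhanced image (VUE), emulating iodine removal by material
decomposition.

## Platform surrogates

No X-ray physics is simulated. A platform is a 4-tuple of surrogates:

| parameter | default | meaning |
|---|---|---|
| `hu_bias` | N(0, 5 HU) per image type | global calibration offset |
| `hu_insert_deviation` | N(0, 15 HU) per insert (VMI70keV); ×2 for VUE | material-decomposition / spectrum differences |
| `noise_sd` | 10 HU | quantum/electronic noise before smoothing |
| `kernel_fwhm_px` | 2.0 px, jittered ±25% per platform | reconstruction-kernel point-spread surrogate |

Platform 1 is the reference: zero bias, zero deviations, unjittered
kernel — this anchors identifiability of the offsets. The VUE spread
being twice the VMI70keV spread encodes the empirical observation that
monoenergetic images are more consistent across vendors than virtual
unenhanced images; the factor is configurable. Per-insert spread
multipliers (`insert_spread_scale`) allow deliberately heterogeneous
platform offsets, which is the regime in which CT-number variability
and first-order feature robustness decouple across ROIs.

A scan is: rasterize the (possibly shifted) phantom at pixel centers
(insert > disk > air, air = −1000 HU), add i.i.d. Gaussian noise, then
convolve with the Gaussian kernel. Smoothing after noise yields
spatially correlated noise, as reconstruction does; it also blurs the
insert edges, which matters below. Repeat 1 is at nominal position;
later repeats translate the phantom by a uniform ±3 px per axis
(rotation is excluded: a phantom repositioned on a table does not
meaningfully rotate at this abstraction). Per-scan seeds derive from
the master seed via `numpy.random.SeedSequence(master, platform, type,
repeat)`, so any single scan regenerates independently.

## ROIs and registration

Each scan is registered to the analytically rasterized, unshifted
reference by translation only: the translation maximizing the
normalized cross-correlation of the disk-thresholded (> −500 HU)
zero-mean binary foregrounds, located by FFT correlation and refined to
sub-pixel precision by quadratic interpolation of the peak. Accuracy on
simulated scans is well under 0.1 px at 10 HU noise.

ROIs are circles of 26 px diameter at the transformed insert centers.
A pixel belongs to an ROI iff its center lies within 13 px of the ROI
center; the center is rounded to the nearest pixel and a single shared
stencil (529 pixels) is stamped there, so all sixteen masks have
identical pixel counts. Sub-pixel shifts move ROI centers — the image
is never resampled, so interpolation cannot contaminate texture
features.

## The 94-feature panel

19 first-order + 24 GLCM + 14 GLDM + 16 GLRLM + 16 GLSZM + 5 NGTDM,
named and defined after the IBSI-aligned conventions of the common
open-source extractors. Shape features are omitted by design (the ROIs
are fixed circles). Conventions that are genuinely choices:

* **Discretization**: fixed bin width 25 HU anchored at the ROI
  minimum, `level = floor((x − min)/width) + 1`. No resampling,
  filtering or normalization precedes it.
* **First-order count**: the panel includes Standard Deviation
  explicitly, bringing the first-order set to 19 names. Entropy and
  Uniformity use the discretized histogram; Total Energy multiplies
  Energy by the voxel volume (0.9766² × 5 mm³). Skewness and Kurtosis
  use population moments (Kurtosis is not excess-corrected); both are 0
  for zero-variance ROIs — degenerate ROIs never emit NaN.
* **GLCM/GLRLM**: symmetric matrices over the four in-plane directions
  at distance 1, no distance weighting, features computed per direction
  and then averaged. Correlation of a single-level matrix is 1; MCC of
  a one-level matrix is 1.
* **GLSZM**: zones are 8-connected components of equal level (via
  `scipy.ndimage.label`), one direction-free matrix.
* **GLDM**: dependence of a pixel = 1 + number of in-ROI 8-neighbors
  within `alpha` (default 0) of its level, so dependence sizes run 1–9.
* **NGTDM**: per-pixel mean over available in-ROI 8-neighbors; pixels
  with no in-ROI neighbor are excluded.

Every matrix builder is tested for exact integer equality against an
independent brute-force enumeration (direct pair walking, line walking,
flood fill, per-pixel neighborhood scans) on hundreds of random masked
grids, plus the conservation identities (normalized GLCM sums to 1;
Σ run-length·count = N; Σ zone-size·count = N; Σ dependence counts = N).

## Robustness statistics

All implemented from their defining formulas; library routines
(pingouin's ICC, scipy's spearmanr) appear only as cross-checks in the
test suite.

* **Bland–Altman**: differences are rescan − scan; limits of agreement
  are bias ± 1.96·SD (sample SD, n−1; the classical multiplier, not a
  t-quantile). A feature is repeatable when ≥ 90% of the 16 ROI
  differences lie within the limits. Zero SD ⇒ all points within
  (degenerate contract). The accompanying two-sided one-sample t-test
  of the differences against zero is per-feature; no multiple-testing
  correction is applied.
* **CV** = 100·SD(n−1)/|mean|; **QCD** = 100·(Q3−Q1)/|Q3+Q1| with
  quartiles by linear interpolation of order statistics. The absolute
  value in the QCD denominator is this package's choice (the bare form
  would let entirely negative-valued features pass the cutoff with a
  negative QCD); it mirrors the |mean| in CV. Near-zero denominators
  flag the value degenerate and map it to +inf, which fails every
  "< cutoff" test — degenerate features count as non-reproducible,
  never as missing.
* **ICC(A,1)** from the two-way ANOVA mean squares,
  (MSR − MSE)/(MSR + (k−1)MSE + (k/n)(MSC − MSE)); zero total variance
  returns 1 with a degeneracy flag applied downstream.
* **CCC** with population (1/n) moments: 2s_xy/(s_x² + s_y² +
  (x̄ − ȳ)²).
* **Spearman**: average ranks for ties, Pearson correlation of ranks,
  p from the t approximation with n−2 df; rho² is reported alongside
  rho. Constant inputs are an error at the statistic level and a
  flagged "undefined" row at the pipeline level.
* Cutoffs are strict (CV < 10, QCD < 10, ICC > 0.90, CCC > 0.90);
  boundary values fail.

Aggregation: inter-platform analyses use the first scan of each
platform by default (configurable to second/mean); rollups are
mean ± sample SD over exactly the platform set (repeatability), the 16
ROIs (dispersion) or the C(n,2) pairs (agreement). Mean CV/QCD rollups
average finite values only. Ranking ties break lexicographically by
feature name for reproducibility. The 14-feature "biomarker shortlist"
report defaults to a documented placeholder list of commonly reported
features and is fully configurable.

## What the generator does and does not emulate

It emulates: controlled per-platform CT-number offsets with
VUE > VMI70keV spread, correlated reconstruction noise, kernel-sharpness
differences between platforms, repositioning between repeats, and a
realistic HU range across inserts. Passing tests therefore show that
the pipeline detects exactly the variation injected — offsets are
recovered with unit slope, dispersion grows monotonically with the
configured spread, and CT-number variability predicts first-order
feature degradation with the expected negative sign.

It does not emulate: beam hardening or streaks, vendor decomposition
algorithms, 3D partial volume (a single slice is simulated), spatially
varying noise, or tissue texture (inserts are homogeneous). Percentages
computed here are therefore not comparable digit-for-digit with any
physical study; only counts, signs and orderings are.

One interaction deserves emphasis. The 26 px ROI reaches to within
~1.3 px of the insert edge, and the smoothing kernel bleeds the edge
step (up to ~1000 HU) into the outer ROI ring. Because ROI centers are
re-rounded to the pixel grid per scan (±0.5 px), this bleed differs
slightly between scan and rescan, proportionally to each insert's
contrast — producing heterogeneous, heavy-tailed Bland–Altman
differences. Under the default conditions this holds test–retest
repeatability to roughly 66–75% of features rather than the ~90% a
purely Gaussian noise model would give (with smoothing disabled the
pipeline measures ≈88–93%). A physical workflow that resamples images
during registration aligns ROIs at sub-pixel precision and largely
avoids this; resampling is deliberately excluded here to keep
interpolation out of the texture features. The headline orderings —
repeatability ≫ inter-platform reproducibility, VMI70keV ≥ VUE
first-order reproducibility, negative CT-number-variability correlation
— are insensitive to this effect.

## Problem sizes and determinism

The default study (10 platforms × 2 image types × 2 repeats = 40 scans,
640 ROI extractions, 8 460 pairwise agreement evaluations per metric)
runs in well under a minute on one CPU; the test suite uses 2–6
platform studies where the full factorial adds nothing. Every stage is
a pure function of (configuration, master seed): repeated runs write
byte-identical images, tables and reports.

## Known limitations

* Translation-only registration; rotation and deformation are out of
  scope by design.
* The GLDM/NGTDM neighborhood is fixed at distance 1; GLCM/GLRLM
  directions are the four in-plane ones of a single slice.
* No confidence intervals for ICC/CCC, and no multiple-testing
  correction for the per-feature t-tests.
* QCD is undefined (reported NaN) for studies with fewer than four
  platforms.
* The degenerate-value contracts (constant ROIs, zero-variance
  features) follow the reference-extractor conventions; other tools may
  emit NaN where this package emits 0 or 1.
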