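# Methods

## Scan geometry

A basal-lamina trace is an ordered polyline of (row, col) pixel
coordinates; image row 0 is the apical edge. The local tangent at a vertex
is the central difference of its neighbours (one-sided at the ends), and a
scan direction is the perpendicular with negative row component (pointing
apically); perpendicularity holds to machine precision by construction, and
on sinusoidal laminae sampled every 4 px the tangent errs from the analytic
derivative by well under 2° for wavelengths ≥ 40 px. Intensity is sampled
by bilinear interpolation at fixed steps (default one pixel) from the
apical end of the segment down to the basal anchor, so profiles run
apical → basal; sampling is exact on linear intensity fields. Scan length
is explicit for real images (the apical endpoint is length-derived, since
no apical-edge detector is assumed); for synthetic images the apical edge
is image row 0 by construction, so the pipeline also accepts
`length_um: auto`, the distance from the anchor to row 0 along the scan.
RGB input is collapsed to Rec.709 luminance before inversion; inversion is
`dtype_max − v` (integers) or `1 − v` (floats) and is tracked so it is
applied exactly once.

## Normalization and averaging

Each profile is normalized to its own maxima: depth to the scan length
(basal lamina at x = 1) and intensity to the profile peak. Scans are
averaged per animal by linear interpolation onto a uniform 500-point grid
on [0, 1] (endpoints included, spacing 1/(n−1)); the animal curve is then
renormalized to peak 1 — only intensity, not depth. Animal curves are
resampled onto a 100-point grid and averaged; the per-point SEM divides by
the number of animals (the biological unit), not the number of scans. The
group curve is deliberately *not* renormalized again, so its peak sits
slightly below 1 wherever animals peak at different depths. Averaging a
single profile reproduces it (linear resampling is exact on piecewise
linear data), and the result is invariant to profile order.

## Window statistics

Area integrals use the composite trapezoid over grid points inside
[x1, x2] with values linearly interpolated exactly at x1 and x2 inserted
as endpoints, which removes the O(grid-step) truncation bias; integrals
are additive across interior split points to machine precision. The
default window is the explicit (0.63, 0.93) basal band; alternatively
`derive_window` returns the outer half-max crossings of a marker curve and
refuses curves with no crossing or with multiple disjoint supra-half-max
regions. The KS comparison has two modes, always named in the output:
`pointwise_values` (default, the evident published-style procedure) treats
the two curves' values at window grid points as the two samples and
reports the asymptotic Kolmogorov p at effective n = n1·n2/(n1+n2);
`density_cdf` treats each curve as an unnormalized density over depth and
reports the sup-norm distance of the normalized cumulative integrals, with
no p-value (flagged). An exact small-sample permutation p
(`ks_exact_p`, n ≤ 10) is provided for verification.

## qPCR quantification

Technical replicates are collapsed by mean Ct before any difference.
Per sample, ΔCt = Ct(gene) − Ct(reference); the fold is 2^−ΔCt transformed
per sample first and then averaged with an SEM across biological samples
(so the reported value has the familiar "mean ± SEM of per-animal folds"
shape). With a calibrator group, ΔΔCt subtracts the calibrator's mean ΔCt
per gene. One-way ANOVA uses the standard sums-of-squares decomposition;
Tukey's HSD computes q = |mᵢ − mⱼ| / √(MSW/2·(1/nᵢ + 1/nⱼ)) with the
adjusted p from the studentized-range distribution at (k, df_within)
(scipy's numerical integration of its closed-form tail). Zero within-group
variance with unequal means is reported as p = 0 with a degeneracy flag
rather than an infinite F. The Tukey p agrees with a 10⁵-permutation
max-|q| reference within ±0.02, and the ANOVA attains 4.8% empirical
type-I error at α = 0.05 over 2000 Gaussian null simulations.

## The synthetic generator

The generator emulates a coronal section photographed at 0.372 µm/px: a
sinusoidal basal lamina (default baseline 160 px ≈ 59.5 µm deep, amplitude
8 px, one wavelength per kilopixel), layers as fixed depth fractions, a
background level (0.08) below every signal intensity, and additive
Gaussian pixel noise clipped to [0, 1]. Signal is rendered either as
uniform layer fill (continuous mode — every oracle is exact and noiseless
images reproduce the design profile pixel-for-pixel) or as cell bodies:
Gaussian-profile discs (σ = `blob_radius_um`) at Poisson-distributed
integer-pixel centers, combined by pointwise **maximum**, because
chromogenic stain saturates — overlapping cells do not add. Max
combination admits an exact mean: far from boundaries the expected field
is A·k/(k+1) with k = 2πλσ², and near layer boundaries the full
Boolean-model expectation (disc–strip exceedance integral,
`expected_blob_field`) captures the ~σ edge spread. All randomness flows
from one integer seed per call; identical inputs give byte-identical
images.

The three-probe preset mirrors a layered olfactory epithelium: `Gb1-like`
fills the whole neuron layer (depth 0.25–0.93), `Gg13-like` its upper
portion only, `GAP43-like` exactly the 0.63–0.93 marker band. The
upper/lower boundary m is solved by bisection so the expected windowed
integral ratio Gb1:Gg13 of the *normalized expected group curves* equals
the design target (2.0), under the configured rendering mode; with the
default dense somata (λ = 0.5/µm², σ = 1 µm, coverage k/(k+1) ≈ 0.76,
pixel noise 0.03) the recovered ratio across 20 simulated cohorts is
1.96 ± 0.05. Cohort studies use a trimmed canvas (224×768 px) that keeps
the full-size epithelium depth, pixel size and lamina curvature — only
unscanned canvas is removed; single-image demonstrations default to the
full 2048×2048 frame.

Designed Ct tables place the reference gene at mean Ct 18 and each target
at Ct 18 − log₂(fold), with one independent N(0, sd) draw per
(sample, gene, technical replicate) measurement; three technical
replicates per sample is the default, matching common qPCR practice.
Noiseless tables invert exactly to the designed folds under 2^−ΔCt.

### What the generator does not emulate

Optics (PSF), chromogenic stain spectra and saturation chemistry, section
artifacts (folds, tears, uneven hybridization), within-layer expression
gradients, and biological between-animal variability beyond what noise
induces. Passing tests therefore demonstrate the *pipeline's* correctness
on controlled truth, not robustness to every property of real
micrographs.

## Calibration findings and limitations

The pointwise KS mode reproduces the evident procedure of testing two
averaged traces' value distributions within the window, but those values
are not an i.i.d. sample: per-scan and per-animal max-normalization gives
each cohort curve a small shared offset (≈0.003 normalized units under the
null configuration) while a flat curve's ~30 window values spread only
≈0.008 and are positively correlated across depth. A shared offset of
half the spread inflates D, so under a frozen null configuration
(continuous mode, iid pixel noise, the full-neuron-layer probe in both
cohorts, 500 cohort pairs) the workflow rejects at α = 0.05 about 23% of
the time rather than ~5%. The inflation ratio is scale-invariant in the
noise level, and the cohort shape (3 animals × 4 scans) is part of the
study design, so this is a property of the procedure, not a tuning
accident: treat the pointwise KS p on averaged curves as descriptive, not
as a calibrated error rate. The `density_cdf` mode avoids the false
sample-size claim but defines no p-value. By contrast the ANOVA stage is
well calibrated (4.8% at α = 0.05), and the same KS machinery applied to
genuinely iid samples rejects at 4.0%.

Other limitations: no amplification-efficiency correction in the qPCR
stage (comparative Ct assumes ~100% efficiency); no multiple-testing
correction across probe pairs (single planned comparison); scan width is
fixed at one pixel; the designed-ratio solve assumes all signal layers of
a probe share one amplitude (the exact blob expectation is only
implemented for that case); and on laminae with strong slope the
depth-fraction oracle for internal boundaries holds exactly only where the
lamina is locally flat — tilted scans through a sloped lamina mix columns
of different depth, a real property of line scans through curved tissue.
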