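# Methods

`coagg` implements a surface-based dual-channel fluorescence assay readout:
protein aggregates captured on a well surface are imaged as
diffraction-limited bright particles in a red channel (α-synuclein, TRITC)
and a far-red channel (amylin, Cy7), and a co-aggregate is counted when a
red and a blue detection in the same field coincide spatially. This note
records the models, the free parameters and the design decisions, and what
the synthetic-data validation does and does not demonstrate.

## Image model of the synthetic generator

Each simulated field contains three independent Poisson-distributed spot
populations: true red/blue pairs (rate `lambda_pair`), red-only and
blue-only singletons. Centers follow a homogeneous spatial Poisson process
restricted to at least `3·psf_sigma_px` from the border, so no truncated
spot biases detection metrics (distributionally equivalent to redrawing
border spots). A paired blue center is its red center displaced by
isotropic Gaussian jitter (`registration_jitter_sd_px`, default 1 px),
emulating residual channel registration error in sequential two-channel
acquisition. Spots are 2-D Gaussians of width `psf_sigma_px` (default
1.5 px, a diffraction-limited particle at high magnification) with
log-normal peak amplitudes. The camera model is Poisson shot noise applied
to signal + background, then Gaussian read noise, then 16-bit quantization
with clipping — the standard CCD/sCMOS acquisition chain.

Default intensity scale: background 200 counts, read noise sd 10, median
peak amplitude 180. The total background noise sd is therefore
√(200 + 10²) ≈ 17.3 counts and the median peak-SNR is ≈ 10. Defaults of
50 red and 50 blue spots per 512×512 field fall in the sparse regime the
assay operates in; absolute densities are calibration choices, since the
assay itself fixes none.

What the generator does **not** emulate: antibody/sandwich chemistry and
its saturation behaviour, fluorophore photophysics (bleaching, blinking),
non-uniform illumination, focus drift, aggregate size heterogeneity beyond
the amplitude distribution, and autofluorescent debris. Passing validation
therefore demonstrates correctness of the counting pipeline under the
stated optical model, not robustness to every artifact of real plates.

## Detection

Detection runs per channel (never across channels: exposures differ per
channel, so cross-channel intensities are not comparable).

1. **Enhancement.** Global histogram equalization maps level v to
   `round(255·CDF(v))`; output depends only on the rank order of input
   levels. CLAHE is available as a variant.
2. **Contour branch.** The equalized image is band-passed with a matched
   Gaussian filter (`smooth_sigma_px`, default = PSF width) minus a 4×
   coarser background estimate. Threshold: Otsu's method floored at
   median + `noise_floor_k`·1.4826·MAD (default k = 5). The floor is what
   makes blank fields yield zero detections — on a pure-noise image Otsu
   *must* split the background mode somewhere, and with <1% true
   foreground Otsu's split can sit inside the background mode as well.
   Connected components are filtered by area (4–400 px) and circularity
   4πA/P² ≥ 0.5; centers are intensity-weighted sub-pixel centroids,
   radius √(A/π).
3. **Hough branch.** Canny edges of the band-passed image vote in circle
   space over radii 2–10 px. Hysteresis thresholds are scaled to the noise
   level estimated from the Sobel gradient magnitude (Rayleigh median
   relation, thresholds 3σ/5σ); circumference-normalized accumulator peaks
   above 0.55 are kept. Without noise-scaled thresholds, equalization's
   full-contrast background floods the edge map.
4. **Merge.** Union with greedy distance non-maximum suppression at
   `merge_dist_px` (default 3 px), contour geometry preferred; agreement is
   labelled `merged`. A Hough-only candidate within 2×`merge_dist_px` of a
   contour spot is discarded as a re-detection of the same particle (ring
   fits land a few pixels off the centroid), which removes most duplicate
   false positives without costing contour recall.

All detector defaults were calibrated on the synthetic model above
(measured: recall ≈ 0.96, precision ≈ 0.98 at peak-SNR 10); none are fixed
by the assay itself, and all are overridable through `DetectConfig`.

## Co-localization and the chance correction

"Overlap" is implemented as a center-distance criterion with default
`d_max_px = 3`: for diffraction-limited spots this is equivalent to circle
overlap and is robust to radius-estimation noise. Pairing is a
maximum-cardinality one-to-one bipartite matching, minimum total distance
among maximum matchings, solved as a rectangular assignment problem with
prohibitively costly infeasible edges — so the count is well-defined and
independent of spot ordering (a greedy matcher would not be).

Two unrelated particles can fall within `d_max` by chance. Under complete
spatial randomness the expected number of coincidental matches in the
dilute regime is

    E[chance] = n_red · n_blue · π · d_max² / A,

which the per-field summary subtracts (floored at zero) to give the
corrected co-aggregate count; the co-localization rate is reported out of
red (α-synuclein) detections. Both raw and corrected counts are always
reported, because whether any chance correction was applied in the original
analysis is unknown.

Channels are assumed registered (sequential acquisition at one stage
position); `register_shift` provides optional integer-shift
cross-correlation registration, off by default.

## Well aggregation, dilution linearity, batch QC

Counts are summed (not averaged) over a well's fields — sums preserve the
Poisson information — and normalized to densities per mm² from the pixel
size, making 60× and 63× platforms comparable. Both the total and the
density are available; density is primary.

A standard series (aggregate standard serially diluted 5-fold from
1 µg/mL) validates each batch. Linearity is the least-squares slope of
log(count) vs log(relative concentration) over quantifiable steps; steps
below 5 counts are excluded from the fit because the Poisson CV exceeds
45% there and conditioning on a nonzero observation biases log-counts
upward, systematically flattening the slope in the deep-dilution tail
(the floor is overridable). Batch failure rules: `poor_standard_curve`
when red counts are non-monotone with dilution, Spearman rank correlation
between concentration and count falls below 0.9, or the top standard does
not exceed the blank; `amylin_bleedthrough` when an α-synuclein-only
standard shows total blue signal above 10% of total red. "Poor" and
"massive" are not quantified by the assay protocol; 0.9 and 10% are
declared defaults chosen to separate the described pass/fail regimes, and
both are overridable. QC depends only on the standard series, never on
cohort data.

## Cohort statistics

Per-sample counts are compared with Student's t-test (equal-variance by
default, matching the stated analysis; Welch optional), or one-way ANOVA
with Tukey HSD for ≥3 groups. Diagnostic performance is ROC AUC computed
as the normalized Mann–Whitney statistic with half-credit for ties;
patients are coded positive and an AUC below 0.5 is reported as-is, never
flipped. The CI is a stratified percentile bootstrap (2000 replicates,
seeded) — the original report does not state its CI method, so this is a
declared choice. Spearman correlation uses mid-ranks with an exact
permutation p-value for n ≤ 9 and the t-approximation above; missing
covariates are handled by pairwise-complete deletion, logged. Only
bivariate Spearman is implemented; no partial-correlation adjustment.

## Binding kinetics

The SPR analysis uses the standard 1:1 Langmuir model: association
`R(t) = Req·(1 − e^{−(ka·C+kd)t})` with `Req = Rmax·C/(C+KD)`, dissociation
`R(t_a)·e^{−kd(t−t_a)}`, and the enforced identity `KD = kd/ka`. Fitting is
global nonlinear least squares over all concentrations with ka and kd in
log space (positivity), deterministic starting values from a coarse
plateau scan plus the log-linear dissociation tail, and tight tolerances
(xtol = ftol = gtol = 1e−14). Degeneracy (e.g. one concentration ≪ KD with
kd ≈ 0, where only the product ka·Rmax is identified) is flagged when the
Jacobian condition number exceeds 1e6; well-posed fits sit near 1e2.

## Validation studies and problem sizes

`coagg.validation` runs the production code path on synthetic data; the
same studies back `tests/test_acceptance.py` and `scripts/acceptance.py`.
Sizes are chosen to give tight Monte-Carlo error while completing in
minutes on one core:

- detection quality: 50 fields × 2 channels, 2-px match tolerance;
- chance null: 10⁴ CSR fields, 20 + 20 points, d_max 3 px, 512² field;
- co-localized-fraction recovery: 5 levels × 50 fields, 50 red spots and
  20 extra blue singletons per field;
- dilution: 100 series × 7 steps × 6 fields of 256², 50 red spots/field at
  the top step;
- type-I calibration: 2000 null cohorts of 20 + 20 samples;
- designed-AUC check: design value from 10⁵ generative draws vs the
  bootstrap CI on a 200 + 200 cohort;
- kinetics: 20 noisy (1% of Rmax) five-concentration simulate-then-fit
  round trips.

## Known limitations

- The contour detector resolves particles no closer than roughly the
  merge distance; at high densities nearby particles merge and counts
  saturate, so the assay's linear range ends where crowding begins.
- The chance-overlap formula is the dilute-regime first-order expectation;
  at high densities matched-pair counts fall below n_red·n_blue·πd²/A.
- The Hough branch reports integer-pixel centers and radii from a discrete
  radius grid.
- Clinical effect sizes (AUCs, correlations) measured on synthetic cohorts
  characterize the estimators, not the biology: real cohort data are not
  bundled.
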