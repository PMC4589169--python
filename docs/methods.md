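# Methods

This note records the models, conventions and numerical choices behind
`wmhpath`, and what the synthetic validation does and does not establish.

## Immunoreactivity quantification

A pixel is immunopositive iff each of R, G, B lies inside the marker's
inclusive range (AT8: R 25–170, G 27–156, B 11–126; 4G8: R 50–180,
G 20–168, B 8–139). Inclusivity at both ends is a convention choice: the
published ranges are printed without open/closed notation, and an inclusive
box is the natural reading of an integer threshold pair. Connected
components use 8-connectivity, the standard for blob quantification. The
100 µm² minimum-component filter is strict (`area < 100 µm²` removed) and
applied only for 4G8, where physiological APP staining produces small true
positives of the chromogen but false positives of the pathology; AT8 has
no size filter. ROI exclusion (white matter, meninges) removes pixels from
both numerator and denominator — percent area is relative to *measured*
tissue, not the raster.

Aggregation: the 24-location plan assigns 4 locations (one sulcus, two
midsection, one gyral tip) to each of six sections. The per-section split
is this package's choice — the protocol fixes the total (24) and the
location classes but not the split; 1 sulcus + 2 midsection + 1 gyrus
reflects the sulcus-to-gyrus burden gradient while keeping sections
balanced. Frontal pools prefrontal + midfrontal locations, temporal pools
entorhinal + temporal; the hemisphere total is the unweighted mean of the
four regional means (so frontal and temporal locations carry half the
per-location weight of parietal/occipital ones — a property of the stated
aggregation rule, not a bug).

Default acquisition geometry is 3×3 tiles of 512 px at 0.85 µm/px, making
the montage field 1.7046 mm² ≈ 1.7 mm². Alternate tile sizes preserve the
physical field (`pixel_size_for_field`); the validation suites and the
demo pipeline run at 256 px and 48–96 px tiles respectively, trading pixel
pitch for throughput while keeping the field area, the size-filter
semantics and every threshold identical.

## Sclerotic index

`SI = 1 − D_int/D_ext`. `measure_vessel` emulates interactive caliper
measurement: the wall is segmented by luminance (< 215/255 — eosinophilic
walls render far darker than lumen/background), and diameters are read on
bilinear profiles through the wall centroid along three orientations 60°
apart, edges taken at the half-level crossings. The per-vessel SI is the
mean of the three per-orientation SI values — averaging SIs rather than
diameters is a deliberate choice (the source protocol does not state the
combination rule); for the concentric similar ellipses the generator
renders, the two conventions coincide exactly. Eligibility (> 50 µm) is
tested on the *external* diameter, again a choice the protocol leaves open.
Sampling: eight vessels per WM block; the frontal region pools the pre-
and mid-frontal blocks (16 values); the total is the mean of the four
regional means. Severity bands are assigned half-open — normal ≤ 0.3 <
mild-moderate ≤ 0.5 < severe — because the published ranges overlap at the
boundaries.

Accuracy: on rendered annuli the measurement is within 2 px of the true
diameters, which propagates to an SI tolerance of
`Δ/D_ext + D_int·Δ/D_ext²` with `Δ = 2·pixel_size`. The acceptance grid
(D_ext 60–300 µm, SI 0.2–0.7, 0.5–2 µm/px) observes worst-case SI error
≈ 0.015.

## ARWMC rating

Lesions are sized by maximum caliper (Feret) diameter, computed as the
maximum pairwise distance between pixel centres (convex-hull accelerated;
exactly equal to the brute-force all-pairs maximum, which the tests use as
oracle). Scores: 0 no lesions; 1 all < 10 mm; 2 early confluent (any
lesion in [10, 20] mm inclusive); 3 confluent (> 20 mm). Diameters of
exactly 10 and 20 mm fall to the early-confluent class, following the
"multiple lesions 10–20 mm" phrasing of the taxonomy.

Bridges: a connection locally narrower than 3 mm is a bridge. Each
component is probed by erosion with a 1.5 mm-radius disk; if it splits,
the fragments are dilated back within the component (reconstructive
opening) and the component is scored by its *lobes*, so a pair of 12 mm
lesions joined by a hairline bridge rates early confluent (2) rather than
confluent (3), even though its overall span exceeds 20 mm. A lobe > 20 mm
still rates 3.

The parieto-occipital combination is the maximum of the two regional
scores (configurable to the mean — the combination rule is not published);
the total is the mean of frontal, temporal and parieto-occipital. This
module is a mask-based stand-in for human visual rating of T2 images; it
does not model MR intensity, registration or infratentorial subscales.

## Cohort statistics

* **Group contrasts** route on Shapiro–Wilk at α = 0.05 per group
  (parametric only if every group passes; n < 3 or constant groups route
  non-parametric with a flag). The pooled-variance t works from either raw
  samples or published summary statistics, which is how the cohort-table
  statistics (MMSE t(22) = 14.07, PMD t(33) = 0.34 under listwise deletion
  of the one missing case) are re-derived.
* **Mann–Whitney U** is reported as min(U₁, U₂) with midrank ties; exact
  p by enumeration when n₁·n₂ ≤ 400 and no ties are present, otherwise the
  tie-corrected normal approximation (exact enumeration under ties is not
  available in the scipy backend; at the cohort sizes involved the
  approximation error is negligible).
* **Partial correlation**: Pearson variant correlates OLS residuals of x
  and y on the covariates; Spearman variant applies the same procedure
  after midrank-transforming x, y *and* the covariates (the common SPSS
  behaviour). p from `t = r·sqrt(df/(1−r²))`, `df = n − 2 − k`; one-tailed
  p is directional with "positive association" as the default alternative.
  Under a Gaussian null the Pearson variant's t is exact; the rank variant
  is very slightly approximate but calibrates to 0.049–0.051 empirical
  size at n = 36 in the acceptance run. A constant covariate is a no-op
  control (rank-deficient designs resolve by least squares), leaving the
  simple correlation.
* **Forward stepwise regression** uses SPSS-convention defaults
  (entry p = 0.05, removal p = 0.10). Variables are z-scored so reported
  coefficients are standardized βs; model R², F and the would-be β/p of
  each excluded candidate are reported at the final step. Entry stops once
  the fit is numerically saturated (R² within 1e−12 of 1), where further
  entry p-values would be noise. Candidate sets with condition number
  above 1e8 are rejected, naming the most correlated pair. Note that with
  pure-noise co-candidates, forward selection admits a noise variable with
  probability ≈ 1 − (1 − entry_p)^k after the true predictor enters; the
  recovery property tracked in validation is therefore "true predictor
  selected, and selected first", which a correct implementation achieves
  essentially always at β = 0.8, n = 200.
* **Missing data**: pairwise deletion for correlations, listwise for
  regression.

## Synthetic generators

The generators are constructed as exact duals of the measurements:

* **Montages.** Positive structures (tangles: elongated ellipses,
  150–500 µm²; threads: thin dilated lines; plaques: discs, 200–1200 µm²;
  APP specks: dots strictly < 100 µm²) are painted with colors sampled
  uniformly from the *interior* of the marker's RGB box; the
  haematoxylin-like background keeps its red channel ≥ 185, above both
  markers' red upper bounds, so background can never classify positive.
  Structures are placed 8-disconnected from each other, non-speck
  structures are kept ≥ 110 µm² (safely above the filter) and specks
  ≤ 90 µm² (safely below), so the classify→filter→percent chain recovers
  the painted fraction *exactly*, and the speck-excluded fraction exactly
  when specks are present. The generator verifies the painted/classified
  mask identity before returning. Packing is refused above a 25 %
  target fraction.
* **Vessels.** Wall and lumen are concentric similar ellipses (equal
  eccentricity and orientation), so the diameter ratio — hence SI — is
  constant over orientations and the closed form is exact for any
  measurement direction.
* **Lesion fields.** Discs at ≥ 1 mm clearance (explicit overlapping
  centres without a requested bridge are an error); bridges are 2 mm-wide
  lines, below the 3 mm bridge limit, so the erosion probe always severs
  them.
* **Cohorts.** A 5-variate Gaussian copula over (age, HPτ, Aβ, SI, WMH)
  latents; default correlations (e.g. HPτ–WMH 0.45, Aβ–WMH 0.40, SI–WMH
  0.25, age–WMH 0.35) echo the magnitude of reported associations; AD
  cases (23 of 36 by default) receive latent shifts of +1.8 SD on both
  pathology burdens and +0.6 SD on WMH, with SI unshifted — matching the
  qualitative group pattern (pathology and WMH higher in AD, SVD similar).
  Latents map monotonically to observables: burdens via scaled
  exponentials (ctrl medians ≈ 1.5 % / 2.5 %), SI via a logistic into
  (0, 1) centred at 0.33, and ARWMC by fixed cutpoints (−0.2, 0.8, 1.6) on
  the regional WMH latent — a probit-style discretization chosen for
  simplicity, not a claim about the rating instrument. Regional values
  load 0.8 of their variance on the case latent. Totals are exact
  monotone transforms of the case latents, so rank-based statistics on
  totals see the latent correlation undistorted (up to ARWMC
  discretization).

What passing tests show: the measurement chain is internally correct and
calibrated on images that satisfy its assumptions exactly. What they do
not show: robustness to stain variability, uneven illumination,
out-of-box chromogen hues, overlapping or touching structures, irregular
vessel lumina, or real T2 lesion morphology — none of which the
generators emulate.

## Problem sizes in the validation runs

The duality suite uses 100 montages at 256 px tiles (field area preserved);
the vessel grid spans 27 rendered annuli; the null-calibration run draws
10,000 cohorts of n = 36; stepwise recovery uses 500 simulations at
n = 200; the end-to-end pipeline tests run 8-case studies at 48 px tiles.
These sizes keep the full validation under a few minutes while leaving
every Monte-Carlo standard error well below the asserted tolerances.

## Known limitations

* One vessel per field is assumed (mirroring manual vessel selection);
  there is no vessel detection in whole-slide images.
* The ARWMC stand-in rates masks, not MR intensities.
* Exact Mann–Whitney p-values are unavailable under ties (asymptotic
  fallback).
* The demo pipeline caps per-montage target burden at 10 % so extreme
  synthetic burdens stay inside the painter's packing limit; measured
  burdens above that cap are compressed.
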