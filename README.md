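# wmhpath

Quantitative neuropathology pipeline linking cortical hyperphosphorylated-tau
(HPτ) and amyloid-β (Aβ) burden and white-matter small-vessel disease (SVD)
to white-matter-hyperintensity (WMH) severity — built for methodologists who
want every step of that measurement chain as tested, reproducible code
exercised on synthetic ground truth.

Post-mortem studies of WMH typically combine four measurements per brain:

1. **Percent-area immunoreactivity.** DAB-stained cortical fields (AT8 for
   HPτ, 4G8 for Aβ) are segmented with inclusive RGB threshold boxes
   (AT8: R 25–170, G 27–156, B 11–126; 4G8: R 50–180, G 20–168, B 8–139).
   For 4G8 only, connected components smaller than 100 µm² are removed so
   physiological APP staining does not contribute false positives. Burden is
   `IR = 100 · positive / measured` pixels per 3×3-tile montage (1.7 mm²),
   24 sampling locations per case, averaged into frontal / temporal /
   parietal / occipital regional means and a hemisphere total.
2. **Sclerotic index.** For each white-matter arteriole (external diameter
   > 50 µm), `SI = 1 − D_int/D_ext`, measured along three orientations 60°
   apart and averaged; eight vessels per WM block, the two frontal blocks
   pooled. SI ≤ 0.3 is normal, 0.3–0.5 mild-to-moderate SVD, > 0.5 severe.
3. **ARWMC rating.** Regional lesion masks score 0 (none), 1 (punctate,
   < 10 mm), 2 (early confluent: 10–20 mm, or 10–20 mm lobes joined by thin
   connecting bridges), 3 (confluent, > 20 mm); parietal and occipital
   combine into one parieto-occipital score and the total is the mean of
   the three reported regions.
4. **Statistics.** Shapiro–Wilk-routed group contrasts (pooled t or
   Mann–Whitney U), age-controlled partial Spearman/Pearson correlations
   (one-tailed), and forward stepwise linear regression of ARWMC on the
   pathology measures.

Because no raw case data accompany such studies, `wmhpath` ships a
synthetic-data module whose generators are *exact duals* of the
measurements: montages whose painted pixels sit strictly inside the RGB
boxes, annuli with closed-form SI, lesion masks with known caliper
diameters, and Gaussian-copula cohorts with a configurable latent
correlation structure. Every pipeline stage can therefore be validated
against known truth.

## Worked example

```python
>>> from wmhpath import synthgen as sg
>>> from wmhpath.ihc_quant import DEFAULT_THRESHOLDS, quantify
>>> tile = 256
>>> truth = sg.make_ihc_montage(sg.IHCSceneSpec(
...     tile_px=tile, pixel_size=sg.pixel_size_for_field(tile),
...     n_structures=15, seed=1))
>>> res = quantify(truth.image, DEFAULT_THRESHOLDS["AT8"])
>>> round(res.percent_area, 4), round(100 * truth.true_fraction, 4)
(0.4756, 0.4756)
```

The classifier recovers the painted tau burden (0.4756 % of the 1.7 mm²
field) exactly — generator and classifier agree pixel for pixel.

```python
>>> from wmhpath.vessel_morphometry import measure_vessel, svd_band
>>> raster, true_si = sg.make_vessel_image(
...     sg.VesselSceneSpec(d_int=100, d_ext=200, pixel_size=1.0, seed=2))
>>> m = measure_vessel(raster, 1.0)
>>> round(m.si, 3), svd_band(m.si)
(0.496, 'mild_moderate')
```

A vessel rendered with SI 0.5 measures 0.496 — within the two-pixel caliper
tolerance — and lands in the mild-to-moderate SVD band.

An end-to-end run (synthesize a 36-case study — 23 AD, 13 control — then
quantify, measure, score and analyze it) is one command:

```bash
wmhpath run-all --outdir study --seed 1
```

which writes per-location/per-vessel/per-case CSVs, a tidy `results.csv`
of every statistic, and a checksummed `manifest.json`. Individual stages
(`generate`, `quantify-ihc`, `measure-vessels`, `score-wmh`, `analyze`)
are also exposed; `wmhpath write-config` emits the default YAML profile.

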