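# Methods

## Gap-fraction model and inversion

The estimator assumes a turbid-medium canopy: leaves are small, opaque and
randomly placed, so the gap fraction at view zenith angle θ is
P₀ = exp(−G(θ)·LAI/cos θ). At θ = 57.5° the leaf projection function G is
close to 0.5 whatever the leaf angle distribution, which removes the main
unknown of single-angle inversion. The package fixes G(57.5°) = 0.5,
giving k = 0.9306; `g_value` and `theta_deg` are parameters of
`InversionModel` so sensitivity to that choice can be probed, but the
default is the theoretical value and is not tuned.

Inversion is applied **per replicate image** and replicates are averaged
afterwards (arithmetic mean per vine, then per sampling area). Averaging
gap fractions first and inverting once would weight dense frames
differently; per-replicate inversion matches the four-replicate field
protocol semantics.

A fully vegetated frame has P₀ = 0 and an infinite LAI. `clamp_saturated`
floors the gap fraction at half of one pixel's worth, 1/(2·n_total), and
flags the record; the flag propagates to the replicate CSV so saturated
estimates can be excluded or inspected. The floor is the resolution limit
of the measurement, not a calibration constant.

## Segmentation rule

The sky/vegetation rule is intentionally simple and fully unsupervised:

1. convert RGB to HSB (identical to HSV; hue in degrees);
2. Otsu-threshold the brightness channel; pixels above the threshold are
   sky candidates;
3. reassign candidates with saturation > 0.5 and hue in the green band
   [60°, 180°] to vegetation (bright sunlit leaves);
4. if the brightness channel is constant (Otsu undefined), use a fixed
   cut at 0.75.

One numerical guard was added to step 2: the Otsu threshold is clipped
into the band [0.5, 0.85]. Otsu always splits a histogram, even a
unimodal one, so an almost-uniform frame (pure sky with sensor jitter, or
a closed canopy) would otherwise be cut through the middle of its single
mode and half of it mislabelled. Brightness above 0.85 is unambiguous sky
in upward shots and below 0.5 unambiguous vegetation, so constraining the
threshold to the ambiguous band makes the rule degrade gracefully while
leaving genuinely bimodal frames untouched. All thresholds are exposed in
`SegmentationParams`; classification is hard (no sub-pixel mixing), and a
3×3 median pre-filter for lossy-compression chroma noise is available but
off by default to keep the default pipeline bit-reproducible.

## Geometry conversions

`ProtocolGeometry` carries D (device-to-row distance), R (row spacing)
and V (vine spacing) and enforces 2D ≤ R (the device cannot see past the
mid-inter-row). Conversions are implemented literally:
LA = LAIp·2D·V, LAIv = LAIp·2D/R, and their inverses.

Two presets exist because the source material for this method is
internally inconsistent: the acquisition protocol states D = 0.4 m
(reference width 0.8 m), but the published worked conversions
(LAIv 2.84 ↔ LAIp 6.8 and 1.41 ↔ 3.4 with R = 2.4 m, V = 1.0 m) are only
consistent with a 1 m² per-plant reference area, i.e. a 1.0 m reference
width — with 0.8 m they would give 8.52 and 4.23. Rather than silently
reinterpreting the protocol, both parameterizations are reachable:
`ProtocolGeometry.field_protocol()` (0.8 m) and
`ProtocolGeometry.paper_discussion()` (1.0 m). The discrepancy is left
visible by design.

## Destructive reference and vigor index

SLA is computed from the pooled weight of the 40 leaf discs
(n_discs·disc_area/total weight), not as a mean of per-disc ratios,
because the protocol weighs the discs jointly. LAIv = W·SLA/(R·V) refers
the reconstructed per-plant leaf area to the per-vine ground area. The
theoretical leaf number TL = shoots × mean leaves per shoot is a plain
product; its mean-leaves factor is conventionally taken over a 5-shoot
sample. No dry-weight variant and no leaf-age stratification of SLA are
implemented.

## Agreement statistics

RRMSE (%, relative to the reference mean), MAE, modelling efficiency EF,
and the coefficient of residual mass CRM (positive = underestimation) are
computed exactly from their definitions; R² is the squared Pearson
correlation, reported alongside — not derived from — the OLS line of
estimate on reference. Significance is a two-sided test of zero
correlation flagged at α = 0.001, mirroring the convention of reporting a
single star; no multiple-testing correction is applied across method
pairs. Outlier handling is explicit-index removal only: automatic
detection would change the scientific meaning of a re-analysis that
excludes a known anomalous sampling area. Identical series short-circuit
R² to exactly 1 so that the optimum (RRMSE 0, MAE 0, EF 1, CRM 0, R² 1)
is hit without floating-point dust.

## NDVI mapping

Vigor classification defaults to equal-interval breaks between the
minimum and maximum valid NDVI (the deterministic reclassify convention
of desktop GIS tools); quantile and natural-breaks ("jenks", via 1-D
k-means with a fixed seed) modes are options. Calibration is ordinary
least squares LAIv = a·NDVI + b through the in-situ points — point NDVI
at the sampled locations, with a per-class-mean mode available, since
which of the two the original workflow used is not documented.
Reclassification maps every valid cell through the fitted line
(continuous map); a per-class-constant mode assigns each class the line's
value at its mean NDVI. Negative predictions are floored at zero (LAI is
non-negative) and counted in a warning. No-data cells are NaN in memory
and a sentinel (−9999) on disk; I/O formats are ESRI ASCII grid (always)
and plain TIFF.

## Synthetic scenes: what they emulate and what they don't

The renderer uses a Boolean model: opaque disks of radius r (default
12 px) dropped by a homogeneous Poisson process with intensity
λ = k·LAI/(π r²) per pixel², over a sky background, with centres drawn in
the image extended by one radius so edge pixels have the same coverage
law as interior ones. For this model the pixel gap probability is
*exactly* exp(−k·LAI) — the same law the inversion assumes — so
recovering the planted LAI validates the whole segmentation + inversion
chain against an honest closed-form oracle, not against itself. Colors
are drawn from a sky palette (hue 210° ± 12°, S 0.15 ± 0.05, B
0.95 ± 0.03) and a leaf palette (hue 120° ± 25°, S 0.80 ± 0.10, B
0.35 ± 0.08) with all randomness from one explicit seed.

A clumped variant groups the same expected number of disks in
Poisson-distributed shoot clusters (mean 8 disks, Gaussian scatter
σ = 18 px). Within-cluster overlap raises the gap fraction above
exp(−k·LAI), so inversion underestimates — the direction in which real
row canopies with leaves clumped in walls err, and the regime in which
dense unpruned canopies saturate the method.

What the renders deliberately do **not** emulate: perspective and the
57.5° projection geometry (the view angle enters only through k), mixed
boundary pixels, specular sky gradients, direct sunlight and shadows,
woody organs, and JPEG artifacts. Passing the recovery tests therefore
shows the chain is self-consistent and numerically correct, not that the
segmentation thresholds are optimal for arbitrary field photographs.

## Problem sizes and numerical choices

Recovery tests use 512×512 renders, 20 seeds per LAI level, LAI ∈
{0.25, 0.5, 1, 2} with a 10% tolerance on the mean, and the clumped
variant at LAI 4 for the saturation direction; smaller 64–256 px renders
back the protocol/CLI tests. The inversion round trip is checked to
1e−12, geometry round trips to 1e−12, the metric suite against
brute-force loops to 1e−10, and the mapping round trip to 1e−10. OLS
recovery under noise is asserted within 3 theoretical standard errors
computed from the known noise σ (the residual-based estimate is too
optimistic at n = 5–12 to serve as an oracle). Ties at class boundaries
go to the lower class except the global maximum, which belongs to the top
class.

## Known limitations

- Equivalence with any specific proprietary segmentation implementation
  cannot be asserted — only behavioural similarity on synthetic scenes;
  the original thresholds are unpublished.
- Single-angle inversion: no leaf-angle-distribution or clumping-index
  estimation, no multi-ring hemispherical processing.
- No correction for the 15 cm below-canopy mounting height, canopy
  height, or row orientation.
- Rasters carry cell size and origin but no projection; no radiometric
  calibration or inter-row soil masking is applied to NDVI inputs.
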