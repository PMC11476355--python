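# Methods

## Pipeline

A product is graded in a fixed order, each stage applied exactly once:

1. **Replicate averaging.** Replicate spectra are averaged pointwise;
   mismatched axes are linearly resampled onto the first replicate's axis,
   restricted to the common overlap. The internal axis convention is
   ascending wavenumber in cm⁻¹ everywhere; readers sort on load and collapse
   duplicated wavenumbers by their mean.
2. **Baseline subtraction.** A polynomial of degree 3 (configurable 0–6) is
   least-squares fitted on *anchor regions* assumed band-free — by default
   1550–1600 and 1800–2100 cm⁻¹ plus the outermost 10 cm⁻¹ at each end of the
   axis, all outside every assigned band window — and subtracted everywhere.
   Negative residual intensities are retained so fit residuals stay unbiased.
3. **Normalization.** Intensities are divided by the maximum of the whole
   collected interval (not of a sub-window), so the strongest signal becomes
   exactly 1. Normalizing before any cropping is deliberate and enforced by
   the `preprocess` driver: reordering would change the normalizer and hence
   every reported intensity.
4. **Deconvolution.** Three diagnostic windows are fitted as sums of
   pseudo-Voigt bands (see below): 850–950 cm⁻¹ (seeds at 887, 898 cm⁻¹),
   1150–1250 cm⁻¹ (seeds at 1192, 1204, 1215 cm⁻¹) and the carbonyl zone
   (seeds at the class centers 1706, 1719, 1728, 1733, 1738 cm⁻¹).
5. **Parameters, inversion, report.** Areal intensities give R₁ and R₂; the
   carbonyl centroid gives ν(C=O); inverting the three calibration curves
   gives n19 and two totals; composition, adulterant flag and (for batches
   of ≥ 2) comparative taste labels complete the report.

## Band model and fitting

"Gaussian–Lorentzian" is implemented as the *linear-combination* pseudo-Voigt
(not the product form), the standard shape in Raman band fitting: a
Lorentzian and a Gaussian of equal height sharing one center and one FWHM,
mixed by a Lorentzian fraction η ∈ [0, 1]. Its area is analytic:
`area = η·(π/2)·h·w + (1−η)·h·w·√(π/(4 ln 2))`.

Windows are fitted by trust-region nonlinear least squares
(`scipy.optimize.least_squares`, numerical Jacobian) over
(center, FWHM, height, η) per band. η is free per band; a shared-η variant
was considered and rejected as an extra coupling the data may not support.
Bounds: centers tethered to their seed ± 8 cm⁻¹ (± 4 cm⁻¹ in the carbonyl
zone, whose class centers sit only 5–13 cm⁻¹ apart); FWHM ∈ [4, 40] cm⁻¹;
height ≥ 0. Initialization comes from the seeds (heights from the data at
the seed center); there are no random restarts, so fits are deterministic
end to end and identical inputs give byte-identical reports.

Numerical choices that matter:

* **Per-window constant offset.** Each window fit includes one free constant
  background term. The global polynomial baseline, anchored far from the
  analytical windows, can leave behind an offset of order 0.1% of the
  normalized maximum; without the nuisance term that error leaks into the
  band η values and biases areal ratios by ~1%, with it the noiseless
  round-trip error drops to ~0.1%. The offset contributes to the model and
  residual but never to any band area.
* **Carbonyl zone fitted over 1640–1760 cm⁻¹.** The C16–C17 stretch at
  1670 cm⁻¹ has a Lorentzian wing that reaches well into the 1690–1760 cm⁻¹
  carbonyl window; fitting it jointly (one extra seed at 1670 cm⁻¹) prevents
  its tail from masquerading as low-wavenumber carbonyl area. Carbonyl
  statistics (centroid, composition) use only sub-bands with centers
  ≥ 1690 cm⁻¹.
* **Degenerate collapse.** Two components converging to within 0.5 cm⁻¹ are
  considered one band: the smaller is dropped and the window refitted, so
  every reported band keeps a self-consistent analytic area.
* **Area floors.** A fitted component carrying < 0.1% of its window's total
  area is a collapsed parameter, not a detection; the R₁/R₂ numerator and
  denominator lookups ignore such bands (the aglycone denominators at 898
  and 1204 cm⁻¹ must genuinely exist, else a missing-band error is raised).
  Carbonyl sub-bands below 0.5% of the zone total are likewise dropped from
  the centroid and the composition, whose fractions are renormalized to 1.

## Parameters and calibration

* ν(C=O) is the area-weighted mean center of the carbonyl sub-bands below
  1734 cm⁻¹. The ≥ 1734 cm⁻¹ *linked-carbonyl* class is excluded because that
  band reflects a modified-C17/C16 carbonyl rather than C19 glycosylation;
  including it would bias the C19 ring count upward. The threshold and the
  class centers live in one constants table
  (`reference_library.CARBONYL_CLASS_CENTERS`) so they can be re-anchored:
  the 0-ring (1706), 1-ring (1719) and linked (1738) centers are literature
  anchors, the 2-ring (1728) and 3-ring (1733) centers are interpolations.
* R₁ = I₈₈₇/I₈₉₈ and R₂ = (I₁₁₉₂+I₁₂₁₅)/I₁₂₀₄ use areal intensities, not
  peak heights.
* Calibration curves (ν(C=O) vs C19 rings on x ∈ [0, 3]; R₁ and R₂ vs total
  rings on x ∈ [2, 6]) are least-squares quadratics; if a fitted quadratic is
  not non-decreasing on a 0.01-step grid of its domain it falls back to
  isotonic regression with linear interpolation between the pooled means, so
  stored models are monotone by construction. Compounds sharing a ring count
  enter as separate points (no pre-averaging). Inversion is a bisection
  solve to 1e-9; parameter values outside the calibrated range clamp to the
  domain endpoint and raise an out-of-range flag instead of extrapolating.
  Ring estimates are reported as continuous values, never rounded to
  integers (internally full precision; reports print 2 decimals).
* The R₁-based total is canonical: `n13 = ntot_R1 − n19` and the C13/C19
  ratio derive from it; the R₂-based total is a consistency check. The ratio
  is reported as undefined when n19 ≤ 0.05.

## Adulterant screen

After the 850–950 cm⁻¹ fit, the residual is scanned around 869 ± 5 cm⁻¹ — a
position extraneous to every steviol assignment (the nearest, 887 cm⁻¹, is
18 cm⁻¹ away). A single pseudo-Voigt is fitted to the residual peak; the
flag raises when its center stays within the ± 5 cm⁻¹ gate and its area
reaches ≥ 1% of the window's total fitted area. The 1% floor suppresses
noise-level detections while keeping a "relatively weak yet visible" band
detectable. The attribution of this band to an added artificial sweetener
is tentative and the report says so.

## Comparative taste classification

Taste labels are strictly within-batch superlatives (≥ 2 products; no
absolute sweetness scale is invented): sweetness intensity ranks by the
R₁-based total ring count, sweet-onset speed inversely by the C13/C19
ratio, bitter-aftertaste duration inversely by the C19 ring count. Because
the inputs are continuous estimates, exact ties are meaningless; values are
clustered by single linkage with a relative gap threshold of 0.1 (sorted
neighbours closer than 10% share a rank), and clusters map to
{highest/intermediate/lowest}, {fastest/slow/slowest},
{shortest/long/longest}, middle clusters sharing the middle label. The
published label sets for reference products are reproduced at the level the
per-parameter rules support: the top product's three superlatives and the
grouping of the poorest products; a product whose ratio nearly ties a
poorer product's will share its onset label even if its other parameters
differ.

## Synthetic-spectrum generator

The generator stands in for measured spectra, none being publicly
deposited. It emulates:

* bands at the assigned centers, pseudo-Voigt with FWHM 8 cm⁻¹ and η = 0.5;
* aglycone band areas constant per molecule (every glycoside carries one
  steviol core); glucose-ring band areas proportional to the total ring
  count; one carbonyl band at the class center of the compound's C19 ring
  count (Steviolbioside additionally carries the 1738 cm⁻¹ linked band,
  reproducing its two-band anomaly);
* blends as fraction-weighted sums of component spectra, a polynomial
  background in the scaled axis coordinate, and i.i.d. Gaussian noise,
  deterministic per seed. Default noise σ = 5·10⁻⁴ a.u. — about 0.5% of the
  strongest band height, the regime of well-averaged high-resolution
  acquisitions. The default axis is 150–2150 cm⁻¹ sampled every 0.5 cm⁻¹
  (a generator choice on the order of the instrument-class resolution, not a
  claim about any instrument's digitization).

Injected truth (band areas, R₁, R₂, ν(C=O)) is returned with each spectrum.

What the generator does **not** emulate — and what passing tests therefore
do not show about real data: relative band intensities are plausible
inventions, not measured values, so the calibration slopes have no
instrumental meaning and must be re-fitted from real pure-compound spectra
before quantitative use (per-compound scatter around the ring-count trend,
visible in real measurements, is absent here, which is why the synthetic
calibrations fit almost exactly); no fluorescence, cosmic rays, detector
nonlinearity, wavenumber miscalibration, or temperature/laser-power effects;
no minor bands outside the assignment table (real spectra have many,
e.g. CH deformations at 1300–1500 cm⁻¹ — with real data the baseline
anchors must be checked against the full band inventory); Rebaudioside C's
rhamnose ring is treated as a full ring for intensity scaling, ignoring its
hydroxyl deficit.

## Problem sizes

The test suite and acceptance script run on 4001-point spectra
(150–2150 cm⁻¹ at 0.5 cm⁻¹), 12-compound calibration libraries, 100-window
fit-recovery ensembles and 10-replicate averages — desk-scale sizes chosen
to exercise every code path; the pipeline is O(points) per window fit and
handles longer axes unchanged.

## Known limitations

* At low signal-to-noise (weakest-band SNR near 20) the η–area degeneracy of
  truncated pseudo-Voigt windows degrades areal accuracy: in the
  fit-recovery ensemble at σ = 0.015 against heights ≥ 0.3, only ~87% of
  bands meet the 5% area tolerance (centers remain accurate). At the
  σ = 0.005 regime used throughout, > 98% do. Replicate averaging before
  fitting, as the pipeline does, is the practical mitigation.
* Carbonyl class centers 5 cm⁻¹ apart (1728 vs 1733) are at the edge of what
  the deconvolution separates in blends; compositions involving both 2- and
  3-ring classes should be read semi-quantitatively.
* Uncertainty is summarized only as calibration fit RMS; no bootstrap or
  error propagation onto ring counts.
* JCAMP-DX support is a deliberate subset: single-block AFFN
  `##XYDATA=(X++(Y..Y))` with uniform step; compressed (DIF/DUF) encodings
  and multi-block files are out of scope, as are vendor binary formats.
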