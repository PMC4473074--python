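# Methods

## The quantification model

The pipeline quantifies A-series gangliosides (GM3, GM2, GM1, GD1a; each
with d18:1 and d20:1 sphingoid backbones) in negative-mode MALDI imaging
mass spectrometry of coronal brain sections carrying a unilateral striatal
lesion. The measurement unit is the per-animal, per-ion channel ratio

r = AUC_ipsi / AUC_contra,

where each AUC is computed on the ROI-averaged spectrum after baseline
subtraction, integrated over a fixed window around the channel's
theoretical m/z. The contralateral ROI is the exact reflection of the
lesion ROI about the sagittal midline, so both regions come from the same
section, acquisition run and matrix coat.

The statistical rationale: per-section multiplicative distortions — tissue
heterogeneity, matrix application, ion-suppression level — enter both
hemispheres identically and cancel in the ratio. The pipeline therefore
applies *no* intensity normalization (no TIC scaling, no inter-section
calibration); normalizing would re-introduce the very cross-section
comparison the ratio design avoids. This cancellation is exact for
multiplicative gain (`test_global_gain_cancels_exactly`,
`test_gain_never_biases_ratios`) and holds to within a few percent for
shared additive backgrounds once the baseline is subtracted.

### Assumptions

- The intact hemisphere is a valid anatomical control for the lesioned
  one, i.e. ganglioside expression is symmetric in the absence of injury.
- ROIs are drawn (or supplied) in pixel space against an anatomical
  reference; midline position is supplied explicitly, not auto-detected.
- Spectra within a section share one m/z axis (continuous-mode imzML).
  Processed-mode files can be read but must be resampled before ROI
  averaging; resampling is out of scope.
- Peaks are integrated, not fitted: the monoisotopic peak is assumed to
  fall within the integration window, and isotope envelopes are not
  summed.

## Mass and adduct calculation

Theoretical masses are sums of dehydrated glycosyl residue masses
(Hex 162.0528, HexNAc 203.0794, NeuAc 291.0954 Da) over a ceramide
anchor, computed from an embedded IUPAC monoisotopic atomic-mass table.
The ceramide defaults to an 18:0 (stearoyl) N-acyl chain — the dominant
acyl of adult brain gangliosides and the conventional assignment for
these m/z channels in brain MSI — and is configurable per panel. The
d20:1 backbone adds one C2H4 (28.0313 Da) relative to d18:1.

Negative-mode ions are all singly charged. Mono-sialylated species
(GM1/GM2/GM3, one sialic acid, the presumed deprotonation site) are
quantified as [M−H]⁻. Di-sialylated GD1a is not observed as [M−2H]²⁻ in
tissue; it appears as the [M−2H+Na]⁻ and [M−2H+K]⁻ salt adducts, which
are treated as two separate channels because they can respond differently
to injury. The adduct offsets relative to [M−H]⁻ are the H-replacement
masses Na−H = 21.9819 and K−H = 37.9559 Da. Electron mass is included in
all ion masses (≈0.55 mDa, irrelevant at the 1e−4 Da tolerance but free
to get right).

The default panel is {GM3, GM2, GM1} × {d18:1, d20:1} × [M−H]⁻ plus
GD1a × {d18:1, d20:1} × {[M−2H+Na]⁻, [M−2H+K]⁻}: ten channels spanning
m/z 1179.7–1902.0. Panel construction rejects configurations whose
integration windows overlap.

## Spectral processing

**ROI masking.** A pixel belongs to an ROI when its center lies strictly
inside the polygon (even-odd rule; shapely's strict containment).
Coordinates are 0-based (x right, y down), matching imzML pixel indices.
Mirroring about a midline on an integer or half-integer x-coordinate maps
pixel centers onto pixel centers, so mirrored masks have equal size on a
symmetric grid.

**Averaging order.** The ROI pixels are averaged into one spectrum first;
baseline subtraction and integration follow. Because integration is
linear, averaging and integration commute (verified to 1e−9 relative);
averaging first is preferred because the baseline estimate is far more
stable on the √n-denoised mean spectrum.

**Baseline.** Moving low-percentile estimator: the baseline at each bin is
the 10th percentile of intensities within a 5 Da window, smoothed once
with a moving average of the same width; the subtracted spectrum is
clipped at zero. Both parameters are exposed in the pipeline
configuration. Properties: the output never exceeds the input and never
goes negative; an isolated peak on a flat or gently sloping background is
preserved to within 5% of its area. Known bias: on a linear ramp of slope
s the estimator under-sits the true baseline by about
(0.5 − percentile) · window · s, so very steep backgrounds (≫0.05
counts/Da at the defaults) would need a narrower window. Because the bias
is identical in both hemispheres of a section, its effect on the ratio is
second-order.

**Integration.** Plain trapezoid on the native axis over ±0.5 Da around
the theoretical m/z. The half-width isolates the monoisotopic peak at
reflectron-TOF resolution (peak σ ≈ 0.15 Da → window covers ±3.3σ)
without reaching a neighbor's +1 isotope. No centroiding, fitting or
recalibration.

**Detection floor.** A channel's area must exceed
3 × MAD × (2 × half-width), where the median absolute deviation is taken
from the baseline-subtracted residual in a signal-free region
(1250–1360 Da by default — between the GM3 and GM2 clusters) of the
contralateral averaged spectrum. A channel that fails in *any* animal of
a cohort is excluded cohort-wide with a warning, since group statistics
cannot use a channel with missing animals and a ratio with a noise-level
denominator is meaningless. Under the default generator settings this
removes exactly the GM3 d20:1 channel.

## Group statistics

Per ion channel and per timepoint, a one-way ANOVA across surgical groups
(control, sham, Aβ alone, ET-1 alone, combined Aβ/ET-1) followed by
Tukey's HSD over all pairs; α = 0.05. Each channel is its own planned
analysis — no additional multiplicity correction is applied across the
ten channels, which is a documented limitation of the per-panel design.
Ratios are analyzed on the natural scale by default (the scale on which
results are plotted); a log-scale option exists because ratios are
right-skewed in principle, though at the default noise level skew is
negligible.

The 3 d vs 21 d contrast for one group is implemented as the Tukey pair
between that group's two timepoint cells inside a one-way ANOVA over all
group × timepoint cells of the channel, sharing the pooled error with
the full design. The two timepoints' group ANOVAs are otherwise run
separately (the 21 d cohort typically has fewer groups).

Calibration properties verified in the suite: null type-I error of the
omnibus test is 0.05 ± 0.02 (1000 simulations at 5 groups × n = 4); the
Tukey-adjusted p never falls below the *pooled-variance* (Fisher-LSD)
unadjusted p for the same contrast — note that an unpooled two-sample
t-test is not a valid lower bound, since Tukey shares the error estimate
across all groups; and the ANOVA p agrees with a 2000-draw permutation
F-test within Monte-Carlo error.

Cell-count summaries use percent reduction,
100 × (mean_3d − mean_21d)/mean_3d, per group and stain.

## The synthetic generator

The generator emulates the acquisition this pipeline targets: 10 μm
coronal sections rasterized at 100 μm pitch in negative reflectron-TOF
mode, with an elliptical lesion in one striatum. Per pixel,

intensity(mz) = gain · [ baseline(mz) + Σ_ions A_i · f_i^{1{pixel ∈ lesion}} · N(mz; mz_i, σ) ] + ε,

with one log-normal gain draw per section and i.i.d. Gaussian ε per bin,
clipped at zero. The lesion region is defined as the pixel set inside the
same polygon that is exported as the ipsilateral ROI, so parameter
recovery isolates the spectral processing from ROI-placement error
(placement error is a real-data effect the generator deliberately does
not model).

Defaults, chosen once as a realistic operating point:

| parameter | default | rationale |
|---|---|---|
| grid | 26 × 18 px at 100 μm | striatum-scale field of view at the instrument's pitch |
| m/z axis | 1150–1930 Da, 0.1 Da steps | spans the panel with margin; ~8 bins across a peak |
| peak σ | 0.15 Da | reflectron-TOF-like width at m/z 1200–1900 |
| amplitudes | 25–100 counts (GM1 highest) | brain abundance ordering GM1 > GM3 ≈ GD1a > GM2 |
| GM3 d20:1 amplitude | 0.2 counts | deliberately below the detection floor |
| baseline | 25 → 15 counts, quadratic in m/z | slowly decaying chemical/matrix background |
| noise σ | 4 counts | peak SNR ~6–25 per pixel; ratio CV 1–3% after ROI averaging |
| gain σ (log-normal) | 0.2 | ±20%-scale section-to-section variability |
| fold changes | 1.8 (elevated), 0.6 (reduced) | invented magnitudes; the study conditions specify directions only |
| cell counts | NB, k = 50, n = 6; FJB 300→195 (combined), 300→105 (ET-1) | encodes the 35% / 65% reductions; NeuN 200→130 vs 200→180 |

The shipped effect table encodes the qualitative group × timepoint
pattern the pipeline is designed to detect: GM2 (both ceramides) elevated
ipsilaterally at 3 d after stroke with or without Aβ, persisting at 21 d
only with Aβ; GM3 d18:1 elevated at 3 d only in the combined group and in
both stroke groups by 21 d; GM1 elevated in the combined group (both
timepoints for d20:1, 3 d only for d18:1); the GD1a sodium adduct
transiently elevated in the combined group; the GD1a potassium adduct
depressed at 3 d after stroke alone, recovering by 21 d; control, sham
and Aβ-alone at 1 everywhere.

At these defaults the full loop recovers fold maps with ≤2% error
noiseless and well within 15% at default noise with n = 4 per group
(median over 50 replicates), and the injected effects are detected with
power far above 0.9 — the per-animal ratio variance is dominated by
spectral noise shrunk by ~90-pixel ROI averaging.

**What the generator does not model**, hence what passing tests do not
show about real data: between-animal biological variability in lesion
response (every animal in a cell shares one fold change; real cohorts
would add a variance component and lower power), ROI placement error,
anatomical asymmetry of the control hemisphere, spatially structured
matrix crystallization beyond the scalar gain, ion-suppression physics,
mass-calibration drift, and isotope envelopes. The recovery and power
results are therefore best-case calibrations of the computational
pipeline, not predictions of animal-study power.

## Numerical and design choices

- Problem sizes in the test suite and acceptance script (cohorts of 20
  sections, 50 recovery replicates, 500 cell-count replicates, 1000 null
  ANOVA simulations) were chosen to bound Monte-Carlo error comfortably
  below the tolerances being checked.
- Seeding: cohort members draw from `SeedSequence(master).spawn`, so any
  section is reproducible independently; two runs with one master seed
  produce byte-identical imzML (the file UUID is derived from content,
  not drawn randomly).
- Degenerate inputs fail loudly: empty ROI masks, heterogeneous axes,
  integration windows off the axis, groups with fewer than two animals,
  unknown group labels, duplicate design rows, overlapping panel windows,
  and lesions extending off-grid all raise typed errors naming the
  offender.
- Ion images map low → dark, high → light (gray colormap with an
  intensity bar); bar charts star a group only when it differs from
  *every* reference group (control and sham) at the Tukey-adjusted α.
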