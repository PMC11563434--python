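# Methods

`spectune` implements the quantitative chain used in studies of sensory
matching between animal coloration and visual sensitivity: skin
reflectance is characterised by spectrometry and calibrated photography,
retinal spectral sensitivity by flash electroretinography (ERG), and the
two are compared statistically. This note records the models, the
parameters that matter, the synthetic-data generator's assumptions, and
the design choices made where the procedure was genuinely open.

## Reflectance curve metrics

A reflectance curve is percent reflectance relative to a diffuse white
standard on a wavelength grid (typically 300–700 nm at 1 nm). Four
summary metrics feed the statistics:

- **peak** — wavelength of maximum reflectance. Ties are broken toward
  the lowest wavelength and flagged, so results are deterministic.
- **FWHM** — distance between the half-maximum crossings nearest the
  peak on each side, located by linear interpolation between grid
  samples. When a side never falls below half max the grid boundary is
  used and a clip flag is set (a flat curve on 300–700 nm therefore has
  FWHM = 400 nm with both flags). The half-max reference is half of the
  *global maximum*, not peak-minus-baseline.
- **AUC** — trapezoidal integral of the curve above a 0% baseline
  (units %·nm). A min-of-curve baseline is available as a config option;
  zero is the default because it is the only choice under which a flat
  curve's AUC equals mean × span.
- **average** — arithmetic mean of all samples.

On a 1 nm grid the interpolated FWHM of a Gaussian band (σ = 20 nm)
agrees with the analytic 2σ√(2 ln 2) = 47.10 nm to well under 0.5 nm,
and the trapezoidal AUC with Aσ√(2π) to ~0.1% (tails truncated at the
grid edges are negligible at this σ). Convergence to the analytic
bandwidth is verified at 5, 1, and 0.1 nm steps.

Group summary curves are per-wavelength mean ± SE; curves on unequal
grids are linearly re-interpolated to the intersection range, and SE is
reported as missing for n = 1.

## Area-scaled photographic reflectance

Each distinct marking on a photographed surface contributes its total
reflectance — the sum R+G+B of its calibrated mean color — weighted by
the *fraction* of the surface it occupies:

    score(surface) = Σ_markings (R+G+B) · area_mm² / total_area_mm²,

frog total = dorsal + lateral. Fractions (not raw mm²) are used because
only they keep the per-surface score on the bounded 0–765 a.u. scale the
scores are interpreted on. Area fractions are validated to sum to ≤ 1
(1% tolerance for segmentation slack); RGB values are assumed already
color-managed upstream (a data contract, not a processing step), and
unmarked skin contributes 0 unless the caller lists an explicit
background marking. The score is linear in area fraction and invariant
to splitting a marking into same-colored parts — both properties are
tested on randomized tables.

## ERG processing

1. **DC correction.** Sessions begin with no-light flashes; the
   time-averaged mean of their average is subtracted from all traces.
2. **Flash averaging.** Responses at one (wavelength, intensity) step
   are the pointwise mean of nominally four flashes. A trace whose
   pre-stimulus RMS (about its own pre-stimulus mean, so DC shifts do
   not trigger it) exceeds 5× the set's median RMS is rejected as
   spurious noise; at most one trace may be dropped and at least three
   must remain, otherwise the step is flagged for manual review. The 5×
   factor is a deterministic operationalisation of by-eye artifact
   exclusion and is configurable.
3. **b-wave measurement.** Default is trough-to-peak: minimum within
   60 ms of flash onset (a-wave trough) to the later maximum within
   20–200 ms (b-wave peak) — standard electrophysiology practice. A
   baseline-to-peak alternative is a config switch and is recorded in
   output metadata; if the peak does not follow the trough the
   measurement falls back to baseline-to-peak with a warning. The
   measurement windows are declared defaults, not estimates.
4. **Normalization.** Relative amplitude = b-wave / maximum b-wave
   within the normalization unit. The default unit is (animal,
   wavelength); a per-animal global mode exists because the two readings
   of "maximum for each animal" are both defensible, but the
   per-wavelength unit is the default since the sigmoid fit pins its
   upper asymptote at 1, which a globally normalized insensitive
   wavelength could never reach. Normalization is idempotent and the
   unit maximum is exactly 1.
5. **Boltzmann fit** per (animal, wavelength), with flash = log10
   intensity (μmol·m⁻²·s⁻¹):

       V(flash) = (A₁ − A₂) / (1 + exp((flash − flash₀)/τ)) + A₂,
       A₁ = 0, A₂ = 1 fixed,

   leaving the half-max intensity flash₀ and slope τ > 0 free.
   Least-squares via a bounded trust-region solver; flash₀ initialised
   at the tested intensity whose amplitude is nearest 0.5, τ at a
   quarter of the tested range; parameter tolerance 1e-10. Fits need
   ≥ 4 points and a relative-amplitude dynamic range ≥ 0.3; otherwise
   the fit is flagged and excluded from tuning curves rather than
   reported.
6. **Threshold.** The 10%-of-maximum intensity inverts analytically:
   threshold = flash₀ − τ·ln 9. It always precedes flash₀ and shifts
   one-for-one with it; the identity is verified against bisection to
   1e-9. Thresholds below the lowest tested intensity carry an
   `extrapolated` flag.
7. **Tuning curve.** Group mean threshold ± SE per stimulus wavelength;
   cells with no data (e.g. the 350 nm stimulus, tested only in a
   subset of animals) are simply absent.

A note on identifiability: because normalization divides by the maximum
*observed* amplitude, recovered parameters are biased by O(ε) when the
top tested intensity sits at Boltzmann value 1 − ε. Exact (1e-6)
round-trip recovery therefore presumes the tested range saturates the
response — which intensity-response protocols are designed to do — and
the round-trip tests use saturating truths accordingly.

## Statistics

- **PCA** of the four curve metrics on centered, unit-variance
  variables. Component signs are fixed (largest-magnitude loading
  positive) for reproducible score plots; per-group convex hulls of
  (PC1, PC2) scores are returned for plotting. Variance percentages sum
  to 100 by construction.
- **One-way ANOVA** (photographic scores across species): classical
  between/within decomposition, Tukey HSD adjusted p-values from the
  studentized-range distribution, and a compact-letter display (ties
  broken alphabetically) for boxplot annotation.
- **Two-way ANOVA** (threshold ~ group × wavelength): ordinary
  least-squares factorial fit with interaction, Type II sums of squares.
  Type II is reported because the original software's default is
  unknowable; on balanced designs it coincides with sequential SS (a
  tested invariant), so balanced synthetic checks are SS-type-invariant.
  Wavelength levels missing from any group (the 350 nm case) are
  dropped with a logged warning before fitting. Pairwise group
  contrasts are Welch t tests, Bonferroni-corrected; when the
  interaction is significant at α, simple-effects contrasts within each
  wavelength are added, Bonferroni-corrected over that family. α = 0.05
  by default.
- **Assumption checks**: Levene's test on absolute deviations from
  group means; normality per group via the KS statistic with estimated
  moments using the Lilliefors-corrected null by default (the naive KS
  p-value is exposed as an option since the original procedure is
  ambiguous, but it is badly conservative with estimated parameters).
  Constant groups are flagged and skipped.
- **Matched-filter report**: per group, the tested wavelength of
  minimum mean threshold, the wavelength of peak mean dorsal
  reflectance, and their absolute difference in nm. Deliberately
  descriptive — with six discrete stimulus wavelengths there is no
  meaningful significance test to attach.

## Synthetic data generator

The generator emulates the study's data shapes, not retinal physiology:

- **Spectra**: baseline + 0–2 Gaussian peaks + Gaussian noise, clipped
  at 0, on 300–700 nm. Default morph profiles place one dorsal band at
  642 nm (σ = 84 nm, i.e. FWHM ≈ 198 nm) and one at 560 nm (σ = 40 nm),
  matching the two aposematic morphs' reported band positions.
- **Marking tables**: per-surface fractions summing to ≤ 1, areas in
  mm², one bright marking plus dark background per frog by default.
- **ERG traces**: a-wave as a negative Gaussian bump (trough 30 ms
  after flash onset, σ 8 ms, amplitude 25% of the b-wave — cosmetic,
  since only the b-wave is analysed) plus b-wave as a positive Gaussian
  bump (peak 80 ms, σ 20 ms), jointly scaled so the trough-to-peak
  excursion equals max_bwave × Boltzmann(flash). 1 kHz sampling, 300 ms
  records, flash at 50 ms; 4 no-light flashes carrying only the DC
  offset; optional artifact traces with 10× pre-stimulus noise to
  exercise rejection. Intensity grid −5.0 to 0.0 log10 μmol·m⁻²·s⁻¹ in
  0.5 steps (neutral-density step sizes are not reported anywhere, so
  this is a declared default).
- **Cohorts**: the default design is two morphs of 11 animals (7F+4M
  and 6F+5M — the study's sample sizes), seven stimulus wavelengths
  350–650 nm, base τ = 0.4, per-wavelength base flash₀ between −2.2 and
  −2.9 with the base minimum at 600 nm, a between-animal flash₀ SD of
  0.15 log units, and a −0.5 log-unit effect-map shift for the second
  morph at 450 and 550 nm — the reported morph contrast. Per-flash
  variability is not reported in the source material; the amplitude
  noise default (SD 0.05 of the saturating amplitude) is a stated
  choice. Amplitude-table simulation floors amplitudes at 0, since a
  trough-to-peak measurement cannot be negative; this induces a small
  upward bias at the response floor, shared across groups.

What passing tests on these data do **not** show: robustness to real
trace pathologies (drift, oscillatory potentials, wavelength-dependent
waveform shape), photoreceptor-class mixtures, or calibrated-photography
color error — none of which the generator models.

## Problem sizes and numerical choices

Simulation-based checks use: 1000 parameter draws for the threshold
identity (tolerance 1e-9), 500 seeds for noisy recovery (median
|flash₀ error| < 0.15, median relative τ error < 20%), 2000 replicates
for type-I error calibration (acceptance band 0.040–0.060 at α = 0.05),
n = 10⁵ for the PCA correlation case (±1 percentage point), and 100
replicates of the 22-animal, 7-wavelength morph-contrast power
simulation (detection ≥ 80% required; observed ~100%). Solver
tolerances: 1e-10 on fit parameters; degenerate inputs (all-zero
curves, zero dynamic range, constant groups, empty masks) are flagged
or rejected with explicit messages rather than propagated as NaN.

## Known limitations

- No visual-pigment or cone-catch modelling: sensitivity is an
  operational ERG threshold, not an opsin absorbance prediction.
- The matched-filter comparison resolves sensitivity only to the tested
  stimulus set (50 nm spacing); reflectance peaks are continuous.
- Tukey HSD assumes balanced-ish groups (harmonic-mean correction via
  the standard implementation); heavily unbalanced designs should rely
  on the Bonferroni pairwise path.
- The ERG reader accepts uniform-sampling traces only.
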