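# Methods

This note documents the models and procedures implemented in `aquaphot`,
their assumptions, the defaults that matter, and the numerical choices made
where the method descriptions in the aquaphotomics literature leave the
design open.

## Data model and measurement design

A `SpectraSet` couples a strictly increasing wavelength grid (nm) to an
intensity matrix (one row per recorded spectrum) and a per-spectrum metadata
table (sample, replicate, consecutive scan index, group, concentration in
mM, temperature in °C, role).  Intensities are pseudo-absorbance
log10(1/T); `to_pseudo_absorbance` converts raw transmittance.  Acquisition
order defines matrix row order, but all grouping is metadata-driven, never
order-driven, so files may be re-sorted freely.  Any requested wavelength is
matched to the nearest grid point, ties to the lower wavelength.  Missing
concentration/temperature values propagate as missing, never as zero
(control water has no concentration).

`generate_measurement_plan` randomizes the (level, replicate) pairs with a
seeded generator and interleaves environmental water controls: one before
the first sample block and one after every `control_interval` samples.  For
the standard 10-level × 2-replicate design with controls every 5 that gives
5 control positions; at 3 consecutive scans per position the run records
60 sample + 15 control = 75 spectra, 6 per sample.  Controls may use their
own consecutive count (`control_consecutives`, default the same as samples)
since recorded totals alone do not pin down the per-control scan policy.

## Pretreatments

* **Savitzky–Golay** — local least-squares polynomial filtering via
  `scipy.signal.savgol_filter`.  Edge points are served by evaluating the
  polynomial fitted to the terminal window at the boundary positions
  (`mode="interp"`), i.e. asymmetric windows: output length equals input
  length, which keeps wavelength bookkeeping for aquagram axes near the
  1300/1600 nm edges trivial.  Derivatives are scaled by the grid step and
  therefore taken with respect to wavelength in nm.  Default for the worked
  example: window 21 points, 2nd-order polynomial.
* **SNV** — each spectrum to mean 0, sample (ddof = 1) standard deviation 1.
* **MSC** — each spectrum OLS-regressed on a reference (x ≈ a + b·r),
  corrected to (x − a)/b.  The default reference is the mean of the set
  being transformed, which makes the correction sample-set-dependent; an
  explicit stored reference is supported for cross-experiment comparability.
* **Detrend** — per-spectrum least-squares polynomial baseline (default
  degree 2) removed, computed in an orthonormalized basis of scaled
  wavelength for conditioning.
* **Resampling** — linear interpolation, extrapolation refused.

Recipes are ordered step lists, YAML-serializable; the runner applies steps
strictly in order, holds no hidden state, and warns if SNV and MSC are
combined (they are normally alternatives).  Test tolerances: 1e−10 absolute
for exact-algebra claims, 1e−8 for derivative claims — comfortable
double-precision headroom.

## Difference spectra

Three operators expose perturbation-activated water bands: subtracting the
averaged solvent reference; subtracting the solvent-library spectrum forming
the globally closest (sample, library) pair; and subtracting each sample's
first consecutive scan from its later scans.  "Closest" is scored by the
trapezoid area under the difference curve; the default integrates the
*absolute* difference, the only reading under which minimal area means
maximal similarity when the difference changes sign (a signed-area mode is
selectable).  The chosen library spectrum is subtracted from *all* sample
spectra, the minimal pair being recorded in the output metadata; ties go to
the lower library index.  The implementation is property-tested against an
independent brute-force search over all pairs.

## Chemometric models

* **PCA** — SVD of the mean-centered matrix; loadings orthonormal;
  deterministic sign convention (largest-magnitude loading element
  positive).  Reports default to the first six components.
* **PLS1 (NIPALS)** — weights w ∝ Xᵀy, X deflated only; regression vector
  b = W(PᵀW)⁻¹q.  Cross-validation is grouped leave-one-group-out: all
  spectra sharing the fold key (e.g. a concentration level) are held out
  together, which for the standard design yields 10 folds of 6 spectra.
  The reported latent-variable count is the smallest whose RMSECV lies
  within a factor 1.02 of the global minimum (parsimony rule; the
  literature reports LV counts without stating a selection rule).  The
  implementation is cross-checked in the tests against scikit-learn's PLS
  and against an explicit fold-by-fold oracle.
* **PLS-DA** — PLS1 on a 0/1 dummy response, class decision at 0.5,
  confusion counts reported; multi-class via one-vs-rest.
* **SIMCA** — per-class truncated PCA.  The published aquaphotomics
  applications name "interclass distance" and "discriminating power"
  without formulas, so the classical definitions are used and stated here
  explicitly: with s²(x→y) the mean squared residual of class-x spectra on
  class-y's model, D(a,b) = sqrt((s²(a→b) + s²(b→a)) / (s²(a→a) + s²(b→b)))
  (≈1 indistinguishable, >3 conventionally separated), and per-wavelength
  discriminating power sqrt(cross-fit residual variance / self-fit residual
  variance).
* **Band identification** — local extrema of both signs on any model vector
  (difference spectrum, loading, regression vector) via prominence-filtered
  peak search with a minimum separation in nm; positions are invariant to
  constant offsets.  The workflow collates bands across analyses: a
  wavelength is "activated" when bands within ±3 nm appear in ≥ k analyses
  (default k = 2), an explicit operationalization of the qualitative
  "consistently repeating" criterion; both knobs are configurable.

## Aquagrams

**Classic.**  A′λ = (Aλ − μλ)/σλ after MSC (default) or SNV of the full
examined set, averaged per group.  μλ and σλ are pooled over *all* spectra
of the examined set rather than per group: per-group standardization would
force every group mean to zero and no chart could show group contrast.  The
pooled choice implies the count-weighted mean of group values is exactly
zero at every axis — a tested identity.  Default axes are the centers of
the active WAMACS table.

**Bootstrap CIs.**  Within-group resampling with replacement, full
recomputation of the classic values per replicate, percentile
(α/2, 1 − α/2) limits; defaults B = 1000, α = 0.05.  The interval is widened
where necessary to bracket the full-data point estimate, so the bracket
property holds by construction.  Per-spectrum pretreatments (SNV) commute
with resampling and are applied once; mean-of-set MSC is recomputed inside
every replicate because its reference depends on the resample.  Results are
bit-reproducible under a fixed seed.  A 500-replicate simulation on a
two-group Gaussian-noise model (40 spectra per group, noise 0.01 AU, truth
evaluated on 10⁵ spectra per group) puts empirical coverage near 94 %; the
group size keeps the percentile bootstrap in its asymptotic regime.

**Temperature-based.**  Relative areas a(Ci) = AUC(Ci)/AUC(1300–1600) are
computed on baseline-corrected spectra, the baseline being the straight
line through the spectrum's values at the grid points nearest 1300 and
1600 nm; the ratio cancels multiplicative scatter and path-length
differences.  A pure-water reference library (≥ 5 distinct temperatures
required; 17 in the standard setting) is averaged per temperature level and
loess-calibrated per coordinate (degree 2, span 0.75, both configurable —
`statsmodels`' lowess is degree-1 only, so the local polynomial regression
is implemented in-package), evaluated on a lattice spanning exactly the
reference range at 0.01 °C steps.  Inversion picks the lattice temperature
whose calibrated area is closest to the observed one; among multiple roots
or ties the candidate nearest the nominal experiment temperature (default
28 °C) wins.  Areas outside the calibrated range raise an error naming the
group and coordinate, or clamp to the boundary with a warning when
requested.  CI propagation follows the average-spectrum route: the group
mean spectrum is bootstrapped, the pointwise percentile limit spectra are
mapped through the same area → temperature pipeline, and group-pair
significance is flagged as CI disjointness.

## Synthetic spectra

The simulator is a band-sum forward model: Gaussian component bands whose
amplitudes respond linearly to temperature and solute concentration, an
additive linear baseline, a per-spectrum lognormal scatter factor, additive
white noise, and a temperature-equivalent drift per consecutive scan
(illumination acting as a perturbation).  Band centers sit at positions
quoted for aqueous salt work (1342, 1364, 1412, 1440, 1452, 1462, 1498,
1512 nm); the temperature coefficients are positive for the free/weakly
bonded species near 1412 nm and negative for strongly bonded water near
1498–1512 nm, and the concentration coefficients are positive in 1342–1374
and 1440–1452 nm and negative in 1476–1512 nm — the qualitative signatures
the analyses are meant to recover.  Amplitudes, widths and coefficient
magnitudes are fixture parameters, not claims about real water; the model
makes no attempt at physically accurate band intensities, band shapes
(real water bands are not Gaussian), instrument line shapes, or detector
artifacts, so passing tests demonstrate the *algorithms*, not instrument
performance.  Defaults: grid 1300–1600 nm at 0.5 nm (601 points), noise
2e−4 AU, scatter 1 %, drift 0.05 °C-equivalent per scan — a well-averaged
transmission measurement.

Because band amplitudes are linear in T, every coordinate's relative area
is a rational-linear, hence strictly monotone, function of temperature, and
the calibration inversion is unique.  One conditioning caveat: C8
(1446–1452 nm) straddles the 1440 (+) and 1452 (−) temperature-coefficient
bands, whose contributions nearly cancel over its narrow window; its
area-vs-T slope is ~40× shallower than C5's, so the 0.1 °C recovery
guarantee presumes genuinely quiet averages (≤ 1e−6 AU additive noise on a
3-scan mean in the verification setting; at 1e−5 AU the worst-coordinate
error reaches ≈ 0.1 °C).  This mirrors the practical situation: coordinates
with weak temperature response carry wide temperature-equivalent error
bars.

## Problem sizes and verification scale

The verification suite exercises the standard 75-spectrum design on the
601-point first-overtone grid, a 17-level reference library, 200 random
instances for the closest-spectrum oracle, and 500 replicates × 500
bootstrap resamples for CI coverage — sizes chosen so the whole suite and
the acceptance script each complete in well under a minute on one core
while leaving every statistical check properly powered.

## Known limitations

* The WAMACS default bounds are a configuration shipped for convenience;
  only the structural constraints (12 ordered ranges, 6–20 nm wide, inside
  1300–1600 nm, with the C1–C3 / C7–C8 / C10–C12 regions as documented) are
  validated, and users with instrument-specific coordinate tables should
  supply their own CSV.
* Temperature-based aquagrams are defined only for the first overtone; the
  coordinate system does not transfer to other water absorption windows.
* The classic aquagram remains a relative construction: its values change
  with the set of samples examined.  Cross-experiment comparisons should
  use the temperature-based mode or an explicit MSC reference.
* PLS is single-response (PLS1); multi-response PLS2, nonlinear variants
  and variable-selection wrappers are out of scope.
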