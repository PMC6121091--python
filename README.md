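# aquaphot

Aquaphotomics chemometrics for near-infrared spectra of aqueous systems:
spectral preprocessing, difference-spectra operators, PCA / PLSR / SIMCA
modeling, and the three aquagram chart variants, together with a seeded
synthetic generator of first-overtone water spectra so every stage is
testable end-to-end without instrument data.

## Who this is for

Aquaphotomics reads the state of an aqueous or biological system from the
water bands of its NIR spectrum: a perturbation (solute concentration,
temperature, consecutive illumination) changes the population balance of
water molecular conformations, and the resulting *water absorbance spectral
pattern* (WASP) acts as a holistic marker.  The package targets
spectroscopists and chemometricians working in the first overtone of water
(1300–1600 nm), where twelve coordinate ranges (WAMACS, C1–C12) collect the
known water conformer bands.

## The core quantities

**Classic aquagram.**  For each displayed wavelength λ, after scatter
correction (MSC or SNV) of the examined set,

    A′λ = (Aλ − μλ) / σλ

with μλ, σλ the mean and standard deviation pooled over all spectra of the
examined set; A′λ is then averaged per sample group and displayed on radial
axes (one per water band).  A bootstrap variant resamples spectra within
groups to attach 95 % percentile confidence intervals.

**Temperature-based aquagram.**  The relative baseline-corrected area of
each WAMACS coordinate, a(Ci) = AUC(Ci) / AUC(1300–1600), is calibrated
against temperature on a pure-water reference library via local polynomial
regression (loess); an experimental group's areas are then inverted through
the calibration so its WASP is expressed in °C equivalents — absolute units
comparable across experiments.

**Chemometrics.**  PCA (SVD), PLS1 regression by NIPALS with grouped
leave-one-group-out cross-validation (RMSECV, R²cv), PLS-DA, SIMCA class
modeling with interclass distances and per-wavelength discriminating power,
and automatic band identification on any model vector.

## Worked example

Simulate the standard salt-series experiment — 10 KCl-like concentrations
(10–100 mM) × 2 replicates × 3 consecutive scans plus interleaved water
controls, 75 spectra in total — then preprocess, calibrate, and chart:

```python
import aquaphot as ap

plan = ap.generate_measurement_plan(n_levels=10, n_replicates=2,
                                    n_consecutives=3, control_interval=5,
                                    rng_seed=42)
model = ap.default_model()
sset = ap.simulate_dataset(model, plan,
                           {lvl: 10.0 * lvl for lvl in range(1, 11)},
                           t_nominal=28.0)
print("spectra:", sset.n_spectra)

pre = ap.msc(ap.savitzky_golay(sset, window=21, polyorder=2))
samples = sset.meta["role"] == "sample"
xs = ap.SpectraSet(pre.grid, pre.intensities[samples.to_numpy()],
                   pre.meta[samples], pre.unit)
y = xs.meta["concentration"].to_numpy(float)
cv = ap.plsr_crossvalidate(xs, y, fold_key="concentration", max_lv=10)
print(f"chosen LV: {cv.chosen_lv}  "
      f"RMSECV: {cv.rmsecv[cv.chosen_lv-1]:.3f} mM  "
      f"R2cv: {cv.r2cv[cv.chosen_lv-1]:.4f}")

aq = ap.classic_aquagram(sset, group_field="group", pretreatment="msc")
print(aq.to_frame().round(2).iloc[[0, 5, 10]])
```

prints

```
spectra: 75
chosen LV: 2  RMSECV: 0.289 mM  R2cv: 0.9999
         C1    C2    C3    C4    C5    C6    C7    C8    C9   C10   C11   C12
group
100mM  1.62  1.63  1.62  1.59  1.64  1.64  1.64  1.63  1.48 -1.63 -1.64 -1.63
50mM   0.17  0.15  0.18  0.22  0.17  0.20  0.19  0.19  0.00 -0.17 -0.18 -0.19
water -1.30 -1.30 -1.31 -1.28 -1.30 -1.30 -1.29 -1.30 -1.07  1.29  1.30  1.30
```

The cross-validated PLS model predicts concentration from the water bands
alone (the "water-mirror" effect: the solute absorbs no NIR light, but
restructures the water).  The aquagram rows show the salt's
structure-breaking signature: absorbance rises with concentration at the
free/weakly bonded coordinates (C1–C3, C7–C8) and falls at the strongly
hydrogen-bonded ones (C10–C12), with pure water mirroring the salt groups.

The same pipeline runs from the shell:

```
aquaphot design --levels 10 --replicates 2 --out plan.csv
aquaphot simulate --seed 42 --out sim
aquaphot aquagram --mode classic --in sim --out aquagram.csv
aquaphot run --config run.yml        # full workflow, CSV reports + run log
```

## Layout

- `src/aquaphot/dataset.py` — spectra + metadata container, CSV round-trip
- `src/aquaphot/design.py` — randomized measurement plans with controls
- `src/aquaphot/preprocess.py` — Savitzky–Golay, SNV, MSC, detrend, recipes
- `src/aquaphot/difference.py` — mean-reference / closest-spectrum /
  consecutive subtraction
- `src/aquaphot/chemometrics.py` — PCA, PLS1/NIPALS + grouped CV, PLS-DA,
  SIMCA, band finding
- `src/aquaphot/wamacs.py`, `aquagram.py` — coordinate table and the three
  aquagram variants
- `src/aquaphot/synthetic.py` — band-sum forward model of water spectra
- `src/aquaphot/workflow.py`, `cli.py` — end-to-end pipeline and CLI

See `docs/methods.md` for the model assumptions, parameter defaults and
numerical choices.
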