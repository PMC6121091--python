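"""Seeded simulator of first-overtone NIR water spectra.

A band-sum forward model: the pure-water first overtone is a sum of Gaussian
component bands whose amplitudes respond linearly to temperature (°C) and
solute concentration (mM), on top of an additive linear baseline, with a
per-spectrum multiplicative scatter factor, additive white noise, and a
temperature-equivalent drift per consecutive illumination.  The defaults
place the bands at positions quoted for aqueous salt work (1342, 1364, 1412,
1440, 1452, 1462, 1498, 1512 nm) with temperature coefficients positive for
the free/weakly bonded species near 1412-1415 nm and negative for strongly
hydrogen-bonded water near 1490-1512 nm, and concentration coefficients
positive in 1342-1374 and 1440-1452 nm and negative in 1476-1512 nm — the
qualitative structure the analyses assume.  It makes no claim to physically
accurate band intensities.

Spectrum amplitudes here are in pseudo-absorbance units (AU).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .dataset import SpectraSet, WavelengthGrid, make_meta
from .design import MeasurementPlan

__all__ = [
    "Band",
    "WaterSpectralModel",
    "default_model",
    "default_grid",
    "simulate_spectrum",
    "simulate_dataset",
    "simulate_reference_library",
]


@dataclass(frozen=True)
class Band:
    center: float      # nm
    sigma: float       # Gaussian width, nm
    amplitude: float   # base amplitude at 0 mM and the model's reference T, AU
    d_temperature: float  # AU per °C
    d_concentration: float  # AU per mM


@dataclass
class WaterSpectralModel:
    bands: list[Band]
    baseline_offset: float = 0.02          # AU
    baseline_slope: float = 5e-5           # AU per nm (relative to 1300 nm)
    scatter_sd: float = 0.0                # sd of the lognormal scatter factor
    noise_sd: float = 0.0                  # additive white noise, AU
    consecutive_drift: float = 0.0         # °C-equivalent per consecutive step
    reference_temperature: float = 28.0    # °C at which base amplitudes hold

    def __post_init__(self) -> None:
        if not self.bands:
            raise ValueError("model needs at least one band")
        for b in self.bands:
            if b.sigma <= 0:
                raise ValueError(f"band at {b.center} nm has non-positive width")
        if self.noise_sd < 0 or self.scatter_sd < 0:
            raise ValueError("noise/scatter standard deviations must be >= 0")


def default_grid() -> WavelengthGrid:
    """1300-1600 nm at 0.5 nm: the first-overtone working range (601 points)."""
    return WavelengthGrid.regular(1300.0, 1600.0, 0.5)


def default_model(noise_sd: float = 2e-4, scatter_sd: float = 0.01,
                  consecutive_drift: float = 0.05) -> WaterSpectralModel:
    """Default band set and perturbation coefficients.

    The noise floor (2e-4 AU) reflects a well-averaged transmission
    measurement; scatter_sd 0.01 gives ~1% multiplicative spread for the
    scatter corrections to work on; consecutive_drift 0.05 °C-equivalent per
    scan mimics the warming effect of consecutive illumination.
    """
    bands = [
        Band(1342.0, 8.0, 0.050, +4e-4, +2.0e-4),
        Band(1364.0, 8.0, 0.060, +3e-4, +2.0e-4),
        Band(1412.0, 14.0, 0.450, +4e-3, +3.0e-4),
        Band(1440.0, 12.0, 0.550, +1e-3, +3.0e-4),
        Band(1452.0, 12.0, 0.600, -1e-3, +2.0e-4),
        Band(1462.0, 10.0, 0.500, -1.5e-3, +1.0e-4),
        Band(1498.0, 14.0, 0.400, -4e-3, -3.0e-4),
        Band(1512.0, 10.0, 0.250, -2e-3, -2.0e-4),
    ]
    return WaterSpectralModel(
        bands=bands, noise_sd=noise_sd, scatter_sd=scatter_sd,
        consecutive_drift=consecutive_drift,
    )


_clip_warnings = 0


def simulate_spectrum(
    model: WaterSpectralModel,
    grid: WavelengthGrid,
    temperature: float,
    concentration: float,
    consecutive: int = 1,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """One simulated pseudo-absorbance spectrum.

    spectrum = scatter × [Σ_bands (base + dT·(T_eff − T_ref) + dC·c)·g(λ)
    + baseline] + noise, with T_eff = T + drift·(consecutive − 1).  Negative
    band amplitudes are clipped at zero with a warning.
    """
    global _clip_warnings
    lam = grid.values
    t_eff = temperature + model.consecutive_drift * (consecutive - 1)
    dT = t_eff - model.reference_temperature
    y = np.zeros_like(lam)
    for b in model.bands:
        amp = b.amplitude + b.d_temperature * dT + b.d_concentration * concentration
        if amp < 0:
            _clip_warnings += 1
            warnings.warn(
                f"negative amplitude at {b.center:g} nm clipped to 0",
                stacklevel=2,
            )
            amp = 0.0
        y += amp * np.exp(-0.5 * ((lam - b.center) / b.sigma) ** 2)
    y += model.baseline_offset + model.baseline_slope * (lam - lam[0])
    if model.scatter_sd > 0 or model.noise_sd > 0:
        if rng is None:
            raise ValueError("a seeded generator is required for noisy draws")
        if model.scatter_sd > 0:
            y = y * np.exp(rng.normal(0.0, model.scatter_sd))
        if model.noise_sd > 0:
            y = y + rng.normal(0.0, model.noise_sd, size=lam.size)
    return y


def simulate_dataset(
    model: WaterSpectralModel,
    plan: MeasurementPlan,
    level_to_concentration: dict[int, float],
    t_nominal: float,
    grid: WavelengthGrid | None = None,
    rng_seed: int | None = None,
) -> SpectraSet:
    """Simulate one spectrum per plan entry × consecutive scan.

    Controls take concentration 0 and role ``control``; sample levels map to
    concentrations (mM) through ``level_to_concentration``.  Group labels are
    the concentration for samples and ``"water"`` for controls.
    """
    grid = grid or default_grid()
    rng = np.random.default_rng(plan.rng_seed if rng_seed is None else rng_seed)
    records, rows = [], []
    order = 0
    for entry in plan.entries.itertuples():
        if entry.role == "control":
            conc, group = 0.0, "water"
            n_cons = plan.control_consecutives
        else:
            if entry.level not in level_to_concentration:
                raise ValueError(f"unmapped level {entry.level}")
            conc = float(level_to_concentration[entry.level])
            group = f"{conc:g}mM"
            n_cons = plan.n_consecutives
        for k in range(1, n_cons + 1):
            rows.append(
                simulate_spectrum(model, grid, t_nominal, conc, k, rng)
            )
            records.append(
                {
                    "sample_id": entry.sample_id,
                    "replicate": int(entry.replicate),
                    "consecutive": k,
                    "group": group,
                    "concentration": conc,
                    "temperature": t_nominal,
                    "role": entry.role,
                    "acquisition_order": order,
                }
            )
            order += 1
    return SpectraSet(grid, np.vstack(rows), make_meta(records), "absorbance")


def simulate_reference_library(
    model: WaterSpectralModel,
    temperatures,
    replicates: int = 1,
    grid: WavelengthGrid | None = None,
    rng_seed: int = 0,
) -> SpectraSet:
    """Pure-water spectra (c = 0, role ``reference``) on a temperature ladder."""
    temperatures = list(temperatures)
    if len(temperatures) < 2:
        raise ValueError("need at least 2 temperatures")
    grid = grid or default_grid()
    rng = np.random.default_rng(rng_seed)
    records, rows = [], []
    order = 0
    for t in temperatures:
        for r in range(1, replicates + 1):
            rows.append(simulate_spectrum(model, grid, float(t), 0.0, 1, rng))
            records.append(
                {
                    "sample_id": f"ref_{t:g}C",
                    "replicate": r,
                    "consecutive": 1,
                    "group": f"{t:g}C",
                    "concentration": 0.0,
                    "temperature": float(t),
                    "role": "reference",
                    "acquisition_order": order,
                }
            )
            order += 1
    return SpectraSet(grid, np.vstack(rows), make_meta(records), "absorbance")
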