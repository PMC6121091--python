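"""Spectral pretreatments: smoothing, derivatives, scatter and baseline
corrections, centering and resampling.

All operators take and return a :class:`~aquaphot.dataset.SpectraSet` and act
per spectrum unless noted.  Derivatives are with respect to wavelength in nm,
so a ``deriv=2`` Savitzky-Golay output has units absorbance·nm⁻².  An ordered
list of steps forms a :class:`PretreatmentRecipe`, serializable to YAML, and
the recipe runner applies the steps strictly in listed order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import yaml
from scipy.signal import savgol_filter

from .dataset import SpectraSet, WavelengthGrid

__all__ = [
    "savitzky_golay",
    "snv",
    "msc",
    "detrend",
    "mean_center",
    "resample_grid",
    "PretreatmentRecipe",
]


def savitzky_golay(
    sset: SpectraSet, window: int, polyorder: int, deriv: int = 0
) -> SpectraSet:
    """Savitzky-Golay local polynomial filter / derivative.

    Boundary points are handled by evaluating the polynomial fitted to the
    terminal window at the edge positions (asymmetric windows), so the output
    grid equals the input grid.  Derivatives are scaled by the grid step so
    they are taken with respect to wavelength in nm.
    """
    n = len(sset.grid)
    if window % 2 == 0:
        raise ValueError(f"window must be odd, got {window}")
    if window <= polyorder:
        raise ValueError(f"window ({window}) must exceed polyorder ({polyorder})")
    if window > n:
        raise ValueError(f"window ({window}) exceeds grid length ({n})")
    if deriv < 0 or deriv > polyorder:
        raise ValueError("deriv must satisfy 0 <= deriv <= polyorder")
    y = savgol_filter(
        sset.intensities, window, polyorder, deriv=deriv,
        delta=sset.grid.step, axis=1, mode="interp",
    )
    return sset.with_intensities(y)


def snv(sset: SpectraSet) -> SpectraSet:
    """Standard normal variate: each spectrum to mean 0, sample sd 1."""
    x = sset.intensities
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, ddof=1, keepdims=True)
    flat = np.flatnonzero(sd.ravel() == 0)
    if flat.size:
        raise ValueError(
            f"constant spectrum {sset.meta['spectrum_id'][flat[0]]!r}: "
            "SNV undefined"
        )
    return sset.with_intensities((x - mu) / sd)


def msc(
    sset: SpectraSet,
    reference: np.ndarray | None = None,
    return_coefficients: bool = False,
):
    """Multiplicative scatter correction.

    Each spectrum x is regressed on the reference r by ordinary least squares,
    x ≈ a + b·r, and corrected to (x − a)/b.  The default reference is the
    mean spectrum of the set being transformed; pass an explicit reference
    (e.g. a stored control-water mean) for cross-experiment comparability.
    """
    if sset.n_spectra < 1:
        raise ValueError("MSC needs at least one spectrum")
    x = sset.intensities
    r = x.mean(axis=0) if reference is None else np.asarray(reference, float)
    if r.shape != (len(sset.grid),):
        raise ValueError("reference length does not match the grid")
    rc = r - r.mean()
    denom = float(rc @ rc)
    if denom == 0:
        raise ValueError("MSC reference has zero variance")
    slopes = (x - x.mean(axis=1, keepdims=True)) @ rc / denom
    intercepts = x.mean(axis=1) - slopes * r.mean()
    if np.any(slopes == 0):
        raise ValueError("zero MSC slope: spectrum orthogonal to reference")
    out = sset.with_intensities((x - intercepts[:, None]) / slopes[:, None])
    if return_coefficients:
        return out, slopes, intercepts
    return out


def detrend(sset: SpectraSet, degree: int = 2) -> SpectraSet:
    """Subtract a per-spectrum least-squares polynomial baseline in λ."""
    n = len(sset.grid)
    if degree < 0 or degree >= n:
        raise ValueError(f"degree must satisfy 0 <= degree < {n}")
    # orthonormal polynomial basis in λ for numerical stability
    lam = sset.grid.values
    v = np.polynomial.polynomial.polyvander(
        (lam - lam.mean()) / (np.ptp(lam) / 2 or 1.0), degree
    )
    q, _ = np.linalg.qr(v)
    x = sset.intensities
    return sset.with_intensities(x - (x @ q) @ q.T)


def mean_center(sset: SpectraSet) -> SpectraSet:
    """Subtract the average spectrum of the set (column means become 0)."""
    if sset.n_spectra < 1:
        raise ValueError("cannot center an empty set")
    x = sset.intensities
    return sset.with_intensities(x - x.mean(axis=0, keepdims=True))


def resample_grid(sset: SpectraSet, new_grid: WavelengthGrid) -> SpectraSet:
    """Linear interpolation onto ``new_grid`` (no extrapolation)."""
    old = sset.grid.values
    new = new_grid.values
    if new[0] < old[0] or new[-1] > old[-1]:
        raise ValueError(
            f"resampling grid [{new[0]:g}, {new[-1]:g}] extends past the "
            f"data span [{old[0]:g}, {old[-1]:g}]"
        )
    y = np.vstack([np.interp(new, old, row) for row in sset.intensities]) \
        if sset.n_spectra else np.empty((0, len(new_grid)))
    return SpectraSet(new_grid, y, sset.meta.copy(), sset.unit)


# ---------------------------------------------------------------------------
# Recipes

_STEPS = {
    "savgol": savitzky_golay,
    "snv": snv,
    "msc": msc,
    "detrend": detrend,
    "mean_center": mean_center,
    "resample": resample_grid,
}


@dataclass
class PretreatmentRecipe:
    """Ordered list of named pretreatment steps with parameters."""

    steps: list[tuple[str, dict]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for name, _ in self.steps:
            if name not in _STEPS:
                raise ValueError(
                    f"unknown pretreatment step {name!r}; "
                    f"known: {sorted(_STEPS)}"
                )
        names = [n for n, _ in self.steps]
        if "snv" in names and "msc" in names:
            warnings.warn(
                "recipe applies both SNV and MSC; they are usually "
                "alternatives", stacklevel=2,
            )

    def apply(self, sset: SpectraSet) -> SpectraSet:
        out = sset
        for name, params in self.steps:
            params = dict(params)
            if name == "resample":
                params["new_grid"] = WavelengthGrid(
                    np.asarray(params.pop("grid"), float)
                )
            out = _STEPS[name](out, **params)
        return out

    def to_yaml(self) -> str:
        return yaml.safe_dump(
            [{"step": n, **p} for n, p in self.steps], sort_keys=False
        )

    @classmethod
    def from_yaml(cls, text: str) -> "PretreatmentRecipe":
        raw = yaml.safe_load(text) or []
        steps = []
        for item in raw:
            item = dict(item)
            steps.append((item.pop("step"), item))
        return cls(steps)
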