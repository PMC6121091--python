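"""Aquagrams: radar/linear charts of water absorbance spectral patterns.

Three variants are computed as data tables:

* **classic** — for each displayed wavelength λ the pretreated absorbance is
  standardized over the pooled examined set, A'λ = (Aλ − μλ)/σλ, and averaged
  per group.  A relative construction: values depend on the samples included.
* **classic with bootstrap CIs** — percentile confidence intervals from
  within-group resampling of the classic values.
* **temperature-based** — group changes expressed in °C equivalents: the
  relative baseline-corrected area of each WAMACS coordinate is matched
  against a loess calibration of area versus temperature built from a pure-
  water reference library, making aquagrams comparable across experiments.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._loess import loess
from .dataset import SpectraSet, WavelengthGrid, nearest_index
from .preprocess import msc as _msc, snv as _snv
from .wamacs import FIRST_OVERTONE, WAMACSTable

__all__ = [
    "AquagramResult",
    "TemperatureCalibration",
    "classic_aquagram",
    "aquagram_bootstrap_ci",
    "relative_wamacs_areas",
    "fit_temperature_calibration",
    "temperature_aquagram",
]


@dataclass
class AquagramResult:
    mode: str                      # classic | classic_ci | temperature | temperature_ci
    axes: list[str]                # axis labels (wavelengths or WAMACS labels)
    groups: list[str]
    values: np.ndarray             # [n_groups, n_axes]
    lo95: np.ndarray | None = None
    hi95: np.ndarray | None = None
    pretreatment: str | None = None
    seed: int | None = None
    significance: pd.DataFrame | None = None  # per group-pair per axis (CI modes)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.groups), len(self.axes)):
            raise ValueError("value array shape must be n_groups × n_axes")
        for b in (self.lo95, self.hi95):
            if b is not None and b.shape != self.values.shape:
                raise ValueError("CI bound shape must match values")
        if self.lo95 is not None and self.hi95 is not None:
            if not (
                (self.lo95 <= self.values + 1e-12).all()
                and (self.values <= self.hi95 + 1e-12).all()
            ):
                raise ValueError("CI bounds must bracket the point estimates")

    def to_frame(self) -> pd.DataFrame:
        """Wide table, one row per group; CI bounds as extra columns."""
        df = pd.DataFrame(self.values, index=pd.Index(self.groups, name="group"),
                          columns=self.axes)
        if self.lo95 is not None:
            for j, ax in enumerate(self.axes):
                df[f"{ax}_lo95"] = self.lo95[:, j]
                df[f"{ax}_hi95"] = self.hi95[:, j]
        return df

    def to_linear_frame(self) -> pd.DataFrame:
        """Linearized table with per-axis averages across groups appended."""
        df = self.to_frame()[self.axes]
        df.loc["average"] = df.mean(axis=0)
        return df


# ---------------------------------------------------------------------------
# classic aquagram

_PRETREATMENTS = {"msc", "snv", "none"}


def _pretreat_matrix(x: np.ndarray, pretreatment: str) -> np.ndarray:
    """Matrix-level pretreatment mirroring preprocess.msc / preprocess.snv."""
    if pretreatment == "none":
        return x
    if pretreatment == "snv":
        mu = x.mean(axis=1, keepdims=True)
        sd = x.std(axis=1, ddof=1, keepdims=True)
        if np.any(sd == 0):
            raise ValueError("constant spectrum: SNV undefined")
        return (x - mu) / sd
    if pretreatment == "msc":
        r = x.mean(axis=0)
        rc = r - r.mean()
        denom = float(rc @ rc)
        if denom == 0:
            raise ValueError("MSC reference has zero variance")
        slopes = (x - x.mean(axis=1, keepdims=True)) @ rc / denom
        intercepts = x.mean(axis=1) - slopes * r.mean()
        return (x - intercepts[:, None]) / slopes[:, None]
    raise ValueError(f"unknown pretreatment {pretreatment!r}")


def _classic_values(
    x: np.ndarray, axis_idx: np.ndarray, group_slices: list[np.ndarray],
    pretreatment: str,
) -> np.ndarray:
    """Pooled-standardized group means at the axis columns."""
    p = _pretreat_matrix(x, pretreatment)[:, axis_idx]
    mu = p.mean(axis=0)
    sd = p.std(axis=0, ddof=1)
    if np.any(sd == 0):
        j = int(np.flatnonzero(sd == 0)[0])
        raise ValueError(
            f"zero pooled standard deviation at axis index {j}: "
            "all spectra identical there"
        )
    z = (p - mu) / sd
    return np.vstack([z[idx].mean(axis=0) for idx in group_slices])


def _resolve_axes(
    sset: SpectraSet, axes, wamacs: WAMACSTable | None
):
    if axes is None:
        wamacs = wamacs if wamacs is not None else None
        if wamacs is None:
            from .wamacs import default_wamacs_table

            wamacs = default_wamacs_table()
        wavelengths = wamacs.centers
        labels = wamacs.labels
    else:
        wavelengths = [float(a) for a in axes]
        labels = [f"{w:g}" for w in wavelengths]
    lo, hi = sset.grid.values[0], sset.grid.values[-1]
    for w in wavelengths:
        if w < lo or w > hi:
            raise ValueError(f"axis {w:g} nm outside the grid span [{lo:g}, {hi:g}]")
    idx = np.array([nearest_index(sset.grid, w) for w in wavelengths])
    return idx, labels


def _group_indices(sset: SpectraSet, group_field: str):
    if group_field not in sset.meta.columns:
        raise ValueError(f"unknown group field {group_field!r}")
    labels = sset.meta[group_field].astype(str).to_numpy()
    groups = sorted(set(labels))
    return groups, [np.flatnonzero(labels == g) for g in groups]


def classic_aquagram(
    sset: SpectraSet,
    axes=None,
    group_field: str = "group",
    pretreatment: str = "msc",
    wamacs: WAMACSTable | None = None,
) -> AquagramResult:
    """Classic aquagram: pooled-standardized pretreated absorbance per group.

    ``axes`` is a list of display wavelengths in nm; by default the centers
    of the active WAMACS table are used.  The pretreatment (MSC by default,
    SNV selectable) is applied to the full examined set, then each axis is
    standardized with the mean and sample standard deviation pooled over all
    spectra, and standardized values are averaged within groups.
    """
    if pretreatment not in _PRETREATMENTS:
        raise ValueError(f"pretreatment must be one of {sorted(_PRETREATMENTS)}")
    if sset.n_spectra < 2:
        raise ValueError("classic aquagram needs at least 2 spectra")
    axis_idx, labels = _resolve_axes(sset, axes, wamacs)
    groups, slices = _group_indices(sset, group_field)
    values = _classic_values(sset.intensities, axis_idx, slices, pretreatment)
    return AquagramResult(
        mode="classic", axes=labels, groups=groups, values=values,
        pretreatment=pretreatment,
    )


def aquagram_bootstrap_ci(
    sset: SpectraSet,
    axes=None,
    group_field: str = "group",
    pretreatment: str = "msc",
    B: int = 1000,
    alpha: float = 0.05,
    rng_seed: int = 0,
    wamacs: WAMACSTable | None = None,
) -> AquagramResult:
    """Classic aquagram with percentile bootstrap confidence intervals.

    Spectra are resampled with replacement within each group and the classic
    values recomputed per replicate; the (alpha/2, 1−alpha/2) percentiles form
    the interval, widened if needed to bracket the full-data point estimate.
    Deterministic under a fixed ``rng_seed``.
    """
    if B < 100:
        raise ValueError("B must be >= 100")
    axis_idx, labels = _resolve_axes(sset, axes, wamacs)
    groups, slices = _group_indices(sset, group_field)
    for g, idx in zip(groups, slices):
        if idx.size < 2:
            raise ValueError(f"group {g!r} has a single spectrum; cannot bootstrap")
    x = sset.intensities
    point = _classic_values(x, axis_idx, slices, pretreatment)

    # per-spectrum pretreatments commute with resampling; apply them once
    per_spectrum = pretreatment in ("snv", "none")
    base = _pretreat_matrix(x, pretreatment) if per_spectrum else x
    inner = "none" if per_spectrum else pretreatment

    rng = np.random.default_rng(rng_seed)
    boot = np.empty((B, len(groups), len(labels)))
    # resampled rows are laid out group-block by group-block
    block_slices = []
    start = 0
    for idx in slices:
        block_slices.append(np.arange(start, start + idx.size))
        start += idx.size
    for b in range(B):
        rows = np.concatenate(
            [idx[rng.integers(0, idx.size, idx.size)] for idx in slices]
        )
        boot[b] = _classic_values(base[rows], axis_idx, block_slices, inner)
    lo = np.quantile(boot, alpha / 2, axis=0)
    hi = np.quantile(boot, 1 - alpha / 2, axis=0)
    lo = np.minimum(lo, point)
    hi = np.maximum(hi, point)
    sig = _significance_table(groups, labels, lo, hi)
    return AquagramResult(
        mode="classic_ci", axes=labels, groups=groups, values=point,
        lo95=lo, hi95=hi, pretreatment=pretreatment, seed=rng_seed,
        significance=sig,
    )


def _significance_table(groups, labels, lo, hi) -> pd.DataFrame:
    """Pairwise per-axis significance = CI disjointness."""
    rows = []
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            for k, ax in enumerate(labels):
                disjoint = hi[i, k] < lo[j, k] or hi[j, k] < lo[i, k]
                rows.append(
                    {"group_a": groups[i], "group_b": groups[j],
                     "axis": ax, "significant": bool(disjoint)}
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# temperature-based aquagram


def relative_wamacs_areas(
    spectrum, wamacs: WAMACSTable, grid: WavelengthGrid | None = None
) -> np.ndarray:
    """Relative baseline-corrected areas of the 12 WAMACS coordinates.

    The baseline is the straight line through the spectrum's values at the
    grid points nearest 1300 and 1600 nm; each coordinate's trapezoid area of
    (spectrum − baseline) is normalized by the total first-overtone area,
    cancelling scatter and path-length differences.
    """
    if isinstance(spectrum, SpectraSet):
        if spectrum.n_spectra != 1:
            raise ValueError("pass a single averaged spectrum")
        grid = spectrum.grid
        y = spectrum.intensities[0]
    else:
        if grid is None:
            raise ValueError("grid required with an array spectrum")
        y = np.asarray(spectrum, dtype=float)
    lam = grid.values
    lo_ov, hi_ov = FIRST_OVERTONE
    if lam[0] > lo_ov or lam[-1] < hi_ov:
        raise ValueError(
            f"grid [{lam[0]:g}, {lam[-1]:g}] does not span the first "
            f"overtone [{lo_ov:g}, {hi_ov:g}]"
        )
    i0, i1 = nearest_index(grid, lo_ov), nearest_index(grid, hi_ov)
    x0, x1 = lam[i0], lam[i1]
    baseline = y[i0] + (y[i1] - y[i0]) * (lam - x0) / (x1 - x0)
    corrected = y - baseline
    ov_mask = (lam >= lo_ov) & (lam <= hi_ov)
    total = float(np.trapezoid(corrected[ov_mask], lam[ov_mask]))
    # a numerically zero total (spectrum equal to its own baseline) is as
    # degenerate as a negative one
    if total <= 1e-12:
        raise ValueError("non-positive total first-overtone area")
    areas = np.empty(12)
    for k, (lo, hi) in enumerate(wamacs.intervals()):
        m = (lam >= lo) & (lam <= hi)
        areas[k] = np.trapezoid(corrected[m], lam[m]) / total
    return areas


@dataclass
class TemperatureCalibration:
    lattice: np.ndarray            # strictly increasing temperature lattice, °C
    curves: np.ndarray             # [12, n_lattice] calibrated relative areas
    labels: list[str]
    loess_span: float
    loess_degree: int
    reference_temperatures: np.ndarray
    reference_areas: np.ndarray    # [n_levels, 12] raw training points

    @property
    def t_range(self) -> tuple[float, float]:
        return float(self.lattice[0]), float(self.lattice[-1])

    def invert(
        self, coordinate: int, area: float, nominal_temperature: float,
        clamp: bool = False, context: str = "",
    ) -> float:
        """Temperature whose calibrated area is closest to ``area``.

        Ties / multiple roots resolve to the candidate nearest the nominal
        experiment temperature.  An area outside the calibrated curve range
        is an error unless ``clamp``, which warns and returns the boundary.
        """
        curve = self.curves[coordinate]
        lo, hi = curve.min(), curve.max()
        if area < lo or area > hi:
            label = self.labels[coordinate]
            msg = (
                f"observed relative area {area:.6g} at {label} outside the "
                f"calibrated range [{lo:.6g}, {hi:.6g}]"
                + (f" for {context}" if context else "")
            )
            if not clamp:
                raise ValueError(msg)
            warnings.warn(msg + "; clamped to the boundary", stacklevel=2)
            area = float(np.clip(area, lo, hi))
        d = np.abs(curve - area)
        candidates = np.flatnonzero(d <= d.min() + 1e-15)
        t = self.lattice[candidates]
        return float(t[np.argmin(np.abs(t - nominal_temperature))])


def fit_temperature_calibration(
    reference: SpectraSet,
    wamacs: WAMACSTable,
    loess_span: float = 0.75,
    lattice_step: float = 0.01,
    loess_degree: int = 2,
) -> TemperatureCalibration:
    """Loess calibration of relative WAMACS area versus water temperature.

    The reference spectra are averaged per temperature level (across
    replicates and consecutive scans), the relative areas computed, and a
    local polynomial regression per coordinate evaluated on a dense lattice
    spanning exactly the reference temperature range.
    """
    temps = reference.meta["temperature"].to_numpy(dtype=float)
    if np.isnan(temps).any():
        raise ValueError("all reference spectra need temperature metadata")
    levels = np.unique(temps)
    if levels.size < 5:
        raise ValueError(
            f"insufficient temperature levels: {levels.size} < 5"
        )
    areas = np.empty((levels.size, 12))
    for i, t in enumerate(levels):
        avg = reference.intensities[temps == t].mean(axis=0)
        areas[i] = relative_wamacs_areas(avg, wamacs, reference.grid)
    t_min, t_max = float(levels[0]), float(levels[-1])
    n_lat = int(round((t_max - t_min) / lattice_step)) + 1
    lattice = np.linspace(t_min, t_max, n_lat)
    curves = np.vstack(
        [
            loess(levels, areas[:, k], lattice, span=loess_span,
                  degree=loess_degree)
            for k in range(12)
        ]
    )
    return TemperatureCalibration(
        lattice=lattice, curves=curves, labels=wamacs.labels,
        loess_span=loess_span, loess_degree=loess_degree,
        reference_temperatures=levels, reference_areas=areas,
    )


def temperature_aquagram(
    experimental: SpectraSet,
    calibration: TemperatureCalibration,
    wamacs: WAMACSTable,
    group_field: str = "group",
    nominal_temperature: float = 28.0,
    with_ci: bool = False,
    B: int = 1000,
    alpha: float = 0.05,
    rng_seed: int = 0,
    clamp: bool = False,
) -> AquagramResult:
    """Temperature-based aquagram: group WASPs in °C-equivalent units.

    Each group's average spectrum is reduced to relative WAMACS areas and
    every coordinate's area inverted through the calibration to the matching
    pure-water temperature.  With ``with_ci``, the group-mean spectrum is
    bootstrapped, the pointwise percentile limit spectra mapped through the
    same area → temperature pipeline, and per group-pair significance flags
    (CI disjointness) reported.
    """
    groups, slices = _group_indices(experimental, group_field)
    rng = np.random.default_rng(rng_seed)
    values = np.empty((len(groups), 12))
    lo95 = np.empty_like(values) if with_ci else None
    hi95 = np.empty_like(values) if with_ci else None

    def invert_spectrum(y: np.ndarray, context: str) -> np.ndarray:
        a = relative_wamacs_areas(y, wamacs, experimental.grid)
        return np.array(
            [
                calibration.invert(k, a[k], nominal_temperature,
                                   clamp=clamp, context=context)
                for k in range(12)
            ]
        )

    for gi, (g, idx) in enumerate(zip(groups, slices)):
        mean_spec = experimental.intensities[idx].mean(axis=0)
        values[gi] = invert_spectrum(mean_spec, f"group {g!r}")
        if with_ci:
            if idx.size < 2:
                raise ValueError(
                    f"group {g!r} has a single spectrum; cannot bootstrap"
                )
            means = np.empty((B, len(experimental.grid)))
            for b in range(B):
                rows = idx[rng.integers(0, idx.size, idx.size)]
                means[b] = experimental.intensities[rows].mean(axis=0)
            lo_spec = np.quantile(means, alpha / 2, axis=0)
            hi_spec = np.quantile(means, 1 - alpha / 2, axis=0)
            t_a = invert_spectrum(lo_spec, f"group {g!r} (lower limit)")
            t_b = invert_spectrum(hi_spec, f"group {g!r} (upper limit)")
            lo95[gi] = np.minimum.reduce([t_a, t_b, values[gi]])
            hi95[gi] = np.maximum.reduce([t_a, t_b, values[gi]])

    sig = (
        _significance_table(groups, wamacs.labels, lo95, hi95)
        if with_ci else None
    )
    return AquagramResult(
        mode="temperature_ci" if with_ci else "temperature",
        axes=wamacs.labels, groups=groups, values=values,
        lo95=lo95, hi95=hi95, seed=rng_seed if with_ci else None,
        significance=sig,
    )
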