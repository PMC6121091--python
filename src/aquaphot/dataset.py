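"""Spectral data model and file round-tripping.

The universal currency of the pipeline is the :class:`SpectraSet`: a strictly
increasing wavelength grid (nm), an intensity matrix with one row per recorded
spectrum, and a per-spectrum metadata table.  Intensities are either raw
transmittance (a fraction) or pseudo-absorbance log10(1/T); every downstream
operator expects pseudo-absorbance.

On disk a SpectraSet is a pair of CSV files: the spectra file has the
wavelength grid as its header row and one numeric row per spectrum keyed by a
spectrum id; the metadata file carries one record per spectrum id
(sample_id, replicate, consecutive, group, concentration, temperature, role,
acquisition_order).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "WavelengthGrid",
    "SpectraSet",
    "META_COLUMNS",
    "read_spectra_csv",
    "write_spectra_csv",
    "to_pseudo_absorbance",
    "select_wavelength_range",
    "group_average",
    "nearest_index",
]

#: metadata columns every SpectraSet carries, in canonical order
META_COLUMNS = [
    "spectrum_id",
    "sample_id",
    "replicate",
    "consecutive",
    "group",
    "concentration",
    "temperature",
    "role",
    "acquisition_order",
]

_ROLES = {"sample", "control", "reference"}


@dataclass(frozen=True)
class WavelengthGrid:
    """Strictly increasing wavelength axis in nm."""

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1 or v.size < 2:
            raise ValueError("wavelength grid needs at least 2 points")
        if not np.all(np.isfinite(v)):
            raise ValueError("wavelength grid contains non-finite values")
        if not np.all(np.diff(v) > 0):
            raise ValueError("grid not increasing")
        object.__setattr__(self, "values", v)

    @property
    def step(self) -> float:
        """Nominal spacing in nm (median of successive differences)."""
        return float(np.median(np.diff(self.values)))

    def __len__(self) -> int:
        return self.values.size

    @classmethod
    def regular(cls, lo: float, hi: float, step: float) -> "WavelengthGrid":
        n = int(round((hi - lo) / step)) + 1
        return cls(lo + step * np.arange(n))


def nearest_index(grid: WavelengthGrid, wavelength: float) -> int:
    """Index of the grid point nearest ``wavelength``; ties go to the lower λ."""
    d = np.abs(grid.values - wavelength)
    m = d.min()
    # ties to the lower wavelength: first index achieving the minimum
    return int(np.flatnonzero(d <= m + 1e-12)[0])


@dataclass
class SpectraSet:
    grid: WavelengthGrid
    intensities: np.ndarray  # [n_spectra, n_wavelengths]
    meta: pd.DataFrame
    unit: str = "absorbance"  # "absorbance" (log 1/T) or "transmittance"

    def __post_init__(self) -> None:
        self.intensities = np.atleast_2d(np.asarray(self.intensities, dtype=float))
        if self.intensities.shape[0] == 0:
            self.intensities = self.intensities.reshape(0, len(self.grid))
        if self.intensities.shape[1] != len(self.grid):
            raise ValueError(
                f"matrix has {self.intensities.shape[1]} columns but grid has "
                f"{len(self.grid)} wavelengths"
            )
        if self.unit not in ("absorbance", "transmittance"):
            raise ValueError(f"unknown unit flag {self.unit!r}")
        self.meta = self.meta.reset_index(drop=True)
        if len(self.meta) != self.intensities.shape[0]:
            raise ValueError("metadata row count does not match spectrum count")
        for col in META_COLUMNS:
            if col not in self.meta.columns:
                raise ValueError(f"metadata missing column {col!r}")
        bad = set(self.meta["role"]) - _ROLES
        if bad:
            raise ValueError(f"unknown role values {sorted(bad)}")
        trip = self.meta[["sample_id", "replicate", "consecutive"]]
        if trip.duplicated().any():
            dup = trip[trip.duplicated()].iloc[0]
            raise ValueError(
                "duplicate (sample_id, replicate, consecutive) triple: "
                f"{tuple(dup)}"
            )

    @property
    def n_spectra(self) -> int:
        return self.intensities.shape[0]

    def copy(self) -> "SpectraSet":
        return SpectraSet(
            self.grid, self.intensities.copy(), self.meta.copy(), self.unit
        )

    def with_intensities(self, x: np.ndarray, unit: str | None = None) -> "SpectraSet":
        return SpectraSet(self.grid, x, self.meta.copy(), unit or self.unit)


def make_meta(records: Iterable[dict]) -> pd.DataFrame:
    """Build a canonical metadata frame, filling optional fields."""
    records = list(records)
    if not records:
        return pd.DataFrame(columns=META_COLUMNS)
    df = pd.DataFrame(records)
    defaults = {
        "group": "",
        "concentration": np.nan,
        "temperature": np.nan,
        "role": "sample",
    }
    for col, val in defaults.items():
        if col not in df.columns:
            df[col] = val
    if "spectrum_id" not in df.columns:
        df["spectrum_id"] = [
            f"{r.sample_id}_r{r.replicate}_c{r.consecutive}"
            for r in df.itertuples()
        ]
    if "acquisition_order" not in df.columns:
        df["acquisition_order"] = np.arange(len(df))
    return df[META_COLUMNS]


# ---------------------------------------------------------------------------
# CSV round-tripping


def write_spectra_csv(sset: SpectraSet, spectra_path, meta_path) -> None:
    """Write the spectra/metadata CSV pair at full float precision.

    Python's shortest round-trip ``repr`` is used for floats, so
    ``read_spectra_csv`` recovers bit-equal values.
    """
    spec = pd.DataFrame(
        sset.intensities,
        index=pd.Index(sset.meta["spectrum_id"], name="spectrum_id"),
        columns=[repr(float(w)) for w in sset.grid.values],
    )
    spec.to_csv(spectra_path)
    meta = sset.meta.copy()
    meta["unit"] = sset.unit
    meta.to_csv(meta_path, index=False)


def read_spectra_csv(spectra_path, meta_path) -> SpectraSet:
    """Read a spectra/metadata CSV pair written by :func:`write_spectra_csv`.

    Spectrum order follows the metadata ``acquisition_order`` column.
    """
    spec = pd.read_csv(spectra_path, index_col=0, float_precision="round_trip")
    try:
        wavelengths = np.array([float(c) for c in spec.columns])
    except ValueError as exc:
        raise ValueError(f"non-numeric wavelength header: {exc}") from None
    if wavelengths.size >= 2 and not np.all(np.diff(wavelengths) > 0):
        raise ValueError("grid not increasing")
    meta = pd.read_csv(meta_path, dtype={"sample_id": str, "group": str, "spectrum_id": str})
    meta["group"] = meta["group"].fillna("")
    unit = "absorbance"
    if "unit" in meta.columns:
        units = set(meta["unit"])
        if len(units) > 1:
            raise ValueError(f"inconsistent unit flags {sorted(units)}")
        if units:
            unit = units.pop()
        meta = meta.drop(columns="unit")
    if set(meta["spectrum_id"]) != set(spec.index.astype(str)):
        raise ValueError("spectrum ids of spectra and metadata files do not match")
    meta = meta.sort_values("acquisition_order", kind="stable").reset_index(drop=True)
    x = spec.loc[meta["spectrum_id"]].to_numpy(dtype=float)
    if np.isnan(x).any():
        raise ValueError("non-numeric or missing cell in spectra file")
    return SpectraSet(WavelengthGrid(wavelengths), x, meta[META_COLUMNS], unit)


# ---------------------------------------------------------------------------
# Unit conversion, slicing, grouping


def to_pseudo_absorbance(sset: SpectraSet) -> SpectraSet:
    """Convert transmittance to pseudo-absorbance A = log10(1/T)."""
    if sset.unit != "transmittance":
        raise ValueError("set is not in transmittance units")
    bad = np.argwhere(sset.intensities <= 0)
    if bad.size:
        i, j = bad[0]
        raise ValueError(
            f"non-positive transmittance in spectrum "
            f"{sset.meta['spectrum_id'][i]!r} at {sset.grid.values[j]:g} nm"
        )
    return sset.with_intensities(np.log10(1.0 / sset.intensities), unit="absorbance")


def select_wavelength_range(sset: SpectraSet, lo: float, hi: float) -> SpectraSet:
    """Restrict to grid points with lo <= λ <= hi (endpoints inclusive)."""
    if not lo < hi:
        raise ValueError("lo must be < hi")
    mask = (sset.grid.values >= lo) & (sset.grid.values <= hi)
    if not mask.any():
        raise ValueError(f"empty selection: [{lo}, {hi}] contains no grid point")
    return SpectraSet(
        WavelengthGrid(sset.grid.values[mask]),
        sset.intensities[:, mask],
        sset.meta.copy(),
        sset.unit,
    )


def group_average(sset: SpectraSet, keys: Sequence[str]) -> SpectraSet:
    """Average spectra over every distinct combination of metadata ``keys``.

    The result has one spectrum per combination, intensities the arithmetic
    mean, and an ``n_averaged`` count recorded in the group column-carrying
    metadata.  Non-key metadata fields keep the first value when unique within
    the group and are otherwise dropped to missing.
    """
    if sset.n_spectra == 0:
        raise ValueError("cannot average an empty set")
    for k in keys:
        if k not in sset.meta.columns:
            raise ValueError(f"unknown metadata field {k!r}")
    rows = []
    mats = []
    for order, (vals, idx) in enumerate(
        sset.meta.groupby(list(keys), sort=True, dropna=False).indices.items()
    ):
        if not isinstance(vals, tuple):
            vals = (vals,)
        sub = sset.meta.iloc[idx]
        rec = {}
        for col in META_COLUMNS:
            uniq = sub[col].drop_duplicates()
            rec[col] = uniq.iloc[0] if len(uniq) == 1 else np.nan
        rec.update(dict(zip(keys, vals)))
        rec["spectrum_id"] = "avg_" + "_".join(str(v) for v in vals)
        rec["acquisition_order"] = order
        for c in ("replicate", "consecutive"):
            if pd.isna(rec[c]):
                rec[c] = 0
        if pd.isna(rec["sample_id"]):
            # keep the (sample_id, replicate, consecutive) triple unique
            rec["sample_id"] = rec["spectrum_id"]
        rec["n_averaged"] = len(idx)
        rows.append(rec)
        mats.append(sset.intensities[idx].mean(axis=0))
    meta = pd.DataFrame(rows)
    meta = meta[META_COLUMNS + ["n_averaged"]]
    return SpectraSet(sset.grid, np.vstack(mats), meta, sset.unit)
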