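"""Difference-spectra operators for revealing activated water bands.

Three subtraction schemes: subtracting an averaged solvent reference,
subtracting the globally closest solvent-library spectrum (minimal area under
the difference curve), and subtracting the first consecutive scan of each
sample from its later consecutives (illumination perturbation).
"""

from __future__ import annotations

import numpy as np

from .dataset import SpectraSet, group_average

__all__ = [
    "subtract_mean_reference",
    "closest_spectrum_subtract",
    "consecutive_difference",
    "difference_area",
]


def _check_grids(a: SpectraSet, b: SpectraSet) -> None:
    if len(a.grid) != len(b.grid) or not np.array_equal(
        a.grid.values, b.grid.values
    ):
        raise ValueError("wavelength grids differ; resample first")


def subtract_mean_reference(sset: SpectraSet, reference: SpectraSet) -> SpectraSet:
    """Subtract the average of ``reference`` from every spectrum of ``sset``."""
    _check_grids(sset, reference)
    if reference.n_spectra == 0:
        raise ValueError("empty reference set")
    ref = reference.intensities.mean(axis=0)
    out = sset.with_intensities(sset.intensities - ref)
    out.meta["difference"] = "mean_reference"
    return out


def difference_area(
    diff: np.ndarray, wavelengths: np.ndarray, mode: str = "abs_area"
) -> float:
    """Area under a difference spectrum by the trapezoid rule.

    ``abs_area`` integrates |difference| (the default: "closest" then means
    "most similar" even when the difference changes sign); ``signed_area``
    integrates the raw difference.
    """
    if mode == "abs_area":
        return float(np.trapezoid(np.abs(diff), wavelengths))
    if mode == "signed_area":
        return float(np.trapezoid(diff, wavelengths))
    raise ValueError(f"unknown area mode {mode!r}")


def closest_spectrum_subtract(
    samples: SpectraSet,
    solvent_library: SpectraSet,
    mode: str = "abs_area",
    score_range: tuple[float, float] | None = None,
):
    """Subtract the solvent-library spectrum closest to any sample.

    All (sample, library) difference spectra are scored by the area under the
    difference curve over the working range; the library member of the
    globally minimal pair (ties to the lower library index) is subtracted
    from every sample spectrum.  Returns ``(differences, library_index,
    sample_index)``; the chosen pair is also recorded in the output metadata.
    """
    _check_grids(samples, solvent_library)
    if solvent_library.n_spectra == 0:
        raise ValueError("empty solvent library")
    lam = samples.grid.values
    if score_range is not None:
        lo, hi = score_range
        mask = (lam >= lo) & (lam <= hi)
        if not mask.any():
            raise ValueError("score range contains no grid point")
    else:
        mask = slice(None)
    best = (np.inf, -1, -1)
    for j in range(solvent_library.n_spectra):
        d = samples.intensities - solvent_library.intensities[j]
        for i in range(samples.n_spectra):
            score = difference_area(d[i][mask], lam[mask], mode)
            if score < best[0]:
                best = (score, j, i)
    _, j, i = best
    out = samples.with_intensities(
        samples.intensities - solvent_library.intensities[j]
    )
    out.meta["difference"] = "closest_spectrum"
    out.meta["closest_library_id"] = solvent_library.meta["spectrum_id"][j]
    out.meta["closest_sample_id"] = samples.meta["spectrum_id"][i]
    return out, j, i


def consecutive_difference(sset: SpectraSet) -> SpectraSet:
    """Subtract each sample's first consecutive scan from its later scans.

    For every (sample_id, replicate) group the consecutive-1 spectrum is the
    baseline; rows with consecutive k > 1 become (spectrum_k − spectrum_1) and
    the consecutive-1 rows are dropped, so the output has exactly
    n_spectra − n_groups rows.
    """
    meta = sset.meta
    keep = []
    x = sset.intensities.copy()
    for (sid, rep), idx in meta.groupby(
        ["sample_id", "replicate"], sort=False
    ).indices.items():
        cons = meta["consecutive"].iloc[idx].to_numpy()
        first = idx[cons == 1]
        if first.size != 1:
            raise ValueError(
                f"sample {sid!r} replicate {rep} lacks a consecutive-1 spectrum"
            )
        base = x[first[0]]
        for k in idx:
            if meta["consecutive"].iloc[k] != 1:
                x[k] = x[k] - base
                keep.append(k)
    keep = sorted(keep)
    out = SpectraSet(sset.grid, x[keep], meta.iloc[keep].copy(), sset.unit)
    out.meta["difference"] = "consecutive"
    return out
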