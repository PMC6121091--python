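"""Multivariate models for spectral data.

PCA (SVD on mean-centered spectra), PLS1 regression by NIPALS with grouped
leave-one-group-out cross-validation, PLS-DA on a 0/1 dummy response, SIMCA
class modeling with interclass distance and per-wavelength discriminating
power, and band (peak) identification on model vectors.

Model objects are plain result containers in the statsmodels spirit: they
carry the estimates and diagnostics and expose ``summary()`` / ``predict()``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .dataset import SpectraSet, WavelengthGrid

__all__ = [
    "PCAModel",
    "PLSRModel",
    "CrossValidationResult",
    "SIMCAClassModel",
    "pca_fit",
    "plsr_fit",
    "plsr_crossvalidate",
    "plsda_fit",
    "simca_fit",
    "simca_compare",
    "find_bands",
]


# ---------------------------------------------------------------------------
# PCA


@dataclass
class PCAModel:
    mean: np.ndarray
    loadings: np.ndarray          # [n_components, n_wavelengths], orthonormal
    scores: np.ndarray            # [n_spectra, n_components]
    explained_variance_pct: np.ndarray
    wavelengths: np.ndarray

    @property
    def n_components(self) -> int:
        return self.loadings.shape[0]

    def project(self, x: np.ndarray) -> np.ndarray:
        return (np.atleast_2d(x) - self.mean) @ self.loadings.T

    def reconstruct(self, scores: np.ndarray | None = None) -> np.ndarray:
        t = self.scores if scores is None else scores
        return self.mean + t @ self.loadings

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "component": np.arange(1, self.n_components + 1),
                "explained_variance_pct": self.explained_variance_pct,
                "cumulative_pct": np.cumsum(self.explained_variance_pct),
            }
        )


def pca_fit(sset: SpectraSet, n_components: int | None = None) -> PCAModel:
    """PCA by singular value decomposition of the mean-centered matrix.

    Sign convention: each loading's largest-magnitude element is positive,
    making the decomposition deterministic.
    """
    x = sset.intensities
    n, p = x.shape
    max_rank = min(n - 1, p)
    if n_components is None:
        n_components = max_rank
    if n_components > max_rank:
        raise ValueError(
            f"n_components ({n_components}) exceeds min(n-1, p) = {max_rank}"
        )
    mean = x.mean(axis=0)
    xc = x - mean
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    u, s, vt = u[:, :n_components], s[:n_components], vt[:n_components]
    # deterministic sign: largest-|loading| element positive
    for k in range(vt.shape[0]):
        j = np.argmax(np.abs(vt[k]))
        if vt[k, j] < 0:
            vt[k] *= -1
            u[:, k] *= -1
    total_var = float((xc**2).sum())
    ev_pct = (s**2) / total_var * 100.0 if total_var > 0 else np.zeros_like(s)
    return PCAModel(
        mean=mean,
        loadings=vt,
        scores=u * s,
        explained_variance_pct=ev_pct,
        wavelengths=sset.grid.values,
    )


# ---------------------------------------------------------------------------
# PLS1 (NIPALS)


@dataclass
class PLSRModel:
    n_lv: int
    x_mean: np.ndarray
    y_mean: float
    weights: np.ndarray            # W  [p, A]
    x_loadings: np.ndarray         # P  [p, A]
    y_loadings: np.ndarray         # q  [A]
    scores: np.ndarray             # T  [n, A]
    regression_vector: np.ndarray  # b  [p]
    r2_train: float
    wavelengths: np.ndarray
    rmsecv: np.ndarray | None = None   # per-LV, filled by cross-validation
    r2cv: np.ndarray | None = None
    chosen_lv: int | None = None

    def predict(self, x: np.ndarray) -> np.ndarray:
        return self.y_mean + (np.atleast_2d(x) - self.x_mean) @ self.regression_vector

    def summary(self) -> pd.DataFrame:
        rows = {"n_lv": [self.n_lv], "r2_train": [self.r2_train]}
        if self.rmsecv is not None:
            rows["rmsecv_at_chosen_lv"] = [self.rmsecv[self.chosen_lv - 1]]
            rows["r2cv_at_chosen_lv"] = [self.r2cv[self.chosen_lv - 1]]
            rows["chosen_lv"] = [self.chosen_lv]
        return pd.DataFrame(rows)


def _nipals_pls1(xc: np.ndarray, yc: np.ndarray, n_lv: int):
    """NIPALS PLS1 on centered data, deflating X only.

    Returns W, P, q and T; the regression vector is b = W (PᵀW)⁻¹ q.
    """
    n, p = xc.shape
    W = np.zeros((p, n_lv))
    P = np.zeros((p, n_lv))
    q = np.zeros(n_lv)
    T = np.zeros((n, n_lv))
    X = xc.copy()
    for a in range(n_lv):
        w = X.T @ yc
        nw = np.linalg.norm(w)
        if nw < 1e-14:
            # X residual carries no covariance with y: truncate
            W, P, q, T = W[:, :a], P[:, :a], q[:a], T[:, :a]
            break
        w /= nw
        t = X @ w
        tt = float(t @ t)
        if tt < 1e-28:
            W, P, q, T = W[:, :a], P[:, :a], q[:a], T[:, :a]
            break
        p_a = X.T @ t / tt
        q_a = float(yc @ t) / tt
        W[:, a], P[:, a], q[a], T[:, a] = w, p_a, q_a, t
        X = X - np.outer(t, p_a)
    return W, P, q, T


def _regression_vector(W: np.ndarray, P: np.ndarray, q: np.ndarray) -> np.ndarray:
    if W.shape[1] == 0:
        return np.zeros(W.shape[0])
    return W @ np.linalg.solve(P.T @ W, q)


def plsr_fit(sset: SpectraSet, y: np.ndarray, n_lv: int) -> PLSRModel:
    """Fit PLS1 by NIPALS (X deflated only) with ``n_lv`` latent variables."""
    x = sset.intensities
    y = np.asarray(y, dtype=float)
    if y.shape != (x.shape[0],):
        raise ValueError("y length must equal the spectrum count")
    if np.ptp(y) == 0:
        raise ValueError("constant response: PLS regression undefined")
    if n_lv < 1:
        raise ValueError("n_lv must be >= 1")
    rank = min(x.shape[0] - 1, x.shape[1])
    if n_lv > rank:
        warnings.warn(
            f"n_lv ({n_lv}) exceeds the data rank bound ({rank}); capped",
            stacklevel=2,
        )
        n_lv = rank
    x_mean = x.mean(axis=0)
    y_mean = float(y.mean())
    W, P, q, T = _nipals_pls1(x - x_mean, y - y_mean, n_lv)
    b = _regression_vector(W, P, q)
    yhat = y_mean + (x - x_mean) @ b
    ss_res = float(((y - yhat) ** 2).sum())
    ss_tot = float(((y - y_mean) ** 2).sum())
    return PLSRModel(
        n_lv=W.shape[1],
        x_mean=x_mean,
        y_mean=y_mean,
        weights=W,
        x_loadings=P,
        y_loadings=q,
        scores=T,
        regression_vector=b,
        r2_train=1.0 - ss_res / ss_tot,
        wavelengths=sset.grid.values,
    )


@dataclass
class CrossValidationResult:
    rmsecv: np.ndarray      # per LV count 1..max_lv
    r2cv: np.ndarray
    chosen_lv: int
    fold_labels: np.ndarray  # fold assignment per spectrum (audit log)
    predictions: np.ndarray  # [n, max_lv] cross-validated predictions

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "n_lv": np.arange(1, len(self.rmsecv) + 1),
                "rmsecv": self.rmsecv,
                "r2cv": self.r2cv,
            }
        )


def plsr_crossvalidate(
    sset: SpectraSet,
    y: np.ndarray,
    fold_key: str,
    max_lv: int,
    lv_tolerance: float = 1.02,
) -> CrossValidationResult:
    """Grouped leave-one-group-out cross-validation for PLS1.

    All spectra sharing a ``fold_key`` metadata value (e.g. a concentration
    level) are held out together.  ``chosen_lv`` is the smallest LV count
    whose RMSECV is within ``lv_tolerance`` of the global minimum (parsimony
    rule).
    """
    x = sset.intensities
    y = np.asarray(y, dtype=float)
    if fold_key not in sset.meta.columns:
        raise ValueError(f"unknown metadata field {fold_key!r}")
    labels = sset.meta[fold_key].to_numpy()
    uniq = pd.unique(labels)
    if len(uniq) < 2:
        raise ValueError("fold_key must partition the spectra into >= 2 groups")
    n = x.shape[0]
    preds = np.full((n, max_lv), np.nan)
    for val in uniq:
        test = labels == val
        if test.all():
            raise ValueError("a fold contains all spectra")
        train = ~test
        xt, yt = x[train], y[train]
        x_mean = xt.mean(axis=0)
        y_mean = float(yt.mean())
        a_max = min(max_lv, min(xt.shape[0] - 1, xt.shape[1]))
        W, P, q, _ = _nipals_pls1(xt - x_mean, yt - y_mean, a_max)
        for a in range(1, max_lv + 1):
            k = min(a, W.shape[1])
            b = _regression_vector(W[:, :k], P[:, :k], q[:k])
            preds[test, a - 1] = y_mean + (x[test] - x_mean) @ b
    resid = preds - y[:, None]
    rmsecv = np.sqrt((resid**2).mean(axis=0))
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2cv = 1.0 - (resid**2).sum(axis=0) / ss_tot
    chosen = int(np.argmax(rmsecv <= lv_tolerance * rmsecv.min())) + 1
    return CrossValidationResult(
        rmsecv=rmsecv,
        r2cv=r2cv,
        chosen_lv=chosen,
        fold_labels=labels,
        predictions=preds,
    )


def plsda_fit(sset: SpectraSet, class_labels, n_lv: int):
    """PLS-DA: PLS1 on a 0/1 dummy response for a two-class problem.

    Returns ``(model, confusion)`` where class 1 is predicted when the dummy
    prediction exceeds 0.5.  ``confusion`` is a 2×2 table indexed
    [true, predicted] over classes sorted lexicographically.
    """
    labels = np.asarray(class_labels)
    classes = np.unique(labels)
    if classes.size != 2:
        raise ValueError(
            f"PLS-DA needs exactly 2 classes, got {classes.size} "
            "(use one-vs-rest for multi-class)"
        )
    dummy = (labels == classes[1]).astype(float)
    model = plsr_fit(sset, dummy, n_lv)
    pred = (model.predict(sset.intensities) > 0.5).astype(int)
    confusion = np.zeros((2, 2), dtype=int)
    for t, p in zip(dummy.astype(int), pred):
        confusion[t, p] += 1
    return model, confusion


# ---------------------------------------------------------------------------
# SIMCA


@dataclass
class SIMCAClassModel:
    label: str
    pca: PCAModel
    k: int
    residual_sd: float  # self-fit residual standard deviation

    def residual_matrix(self, x: np.ndarray) -> np.ndarray:
        xc = np.atleast_2d(x) - self.pca.mean
        return xc - (xc @ self.pca.loadings.T) @ self.pca.loadings


def simca_fit(
    sset: SpectraSet, class_field: str, k: int
) -> list[SIMCAClassModel]:
    """Fit a truncated PCA model per class (soft independent class modeling)."""
    if class_field not in sset.meta.columns:
        raise ValueError(f"unknown metadata field {class_field!r}")
    labels = sset.meta[class_field].to_numpy()
    classes = pd.unique(labels)
    if len(classes) < 2:
        raise ValueError("SIMCA needs at least 2 classes")
    models = []
    for c in sorted(classes.astype(str)):
        idx = np.flatnonzero(labels.astype(str) == c)
        if idx.size < k + 2:
            raise ValueError(
                f"class {c!r} has {idx.size} spectra; needs >= k + 2 = {k + 2}"
            )
        sub = SpectraSet(
            sset.grid, sset.intensities[idx], sset.meta.iloc[idx], sset.unit
        )
        pca = pca_fit(sub, n_components=k)
        resid = pca.reconstruct() - sub.intensities
        models.append(
            SIMCAClassModel(
                label=c, pca=pca, k=k,
                residual_sd=float(np.sqrt((resid**2).mean())),
            )
        )
    return models


def simca_compare(models: list[SIMCAClassModel], sset: SpectraSet, class_field: str):
    """Interclass distances and per-wavelength discriminating power.

    D(a,b) = sqrt((s²_{a→b} + s²_{b→a}) / (s²_{a→a} + s²_{b→b})) with
    s²_{x→y} the mean squared residual of class-x spectra on class-y's model;
    ~1 means indistinguishable classes, > 3 conventionally well separated.
    Discriminating power per wavelength is sqrt(cross-fit residual variance /
    self-fit residual variance) pooled over ordered class pairs.
    """
    labels = sset.meta[class_field].to_numpy().astype(str)
    by_class = {m.label: np.flatnonzero(labels == m.label) for m in models}
    nm = len(models)
    p = len(sset.grid)
    # s2[x, y, λ]: residual variance of class-x spectra on class-y's model
    s2 = np.zeros((nm, nm, p))
    for i, mx in enumerate(models):
        xi = sset.intensities[by_class[mx.label]]
        for j, my in enumerate(models):
            s2[i, j] = (my.residual_matrix(xi) ** 2).mean(axis=0)
    dist = np.zeros((nm, nm))
    for i in range(nm):
        for j in range(i + 1, nm):
            d = np.sqrt(
                (s2[i, j].mean() + s2[j, i].mean())
                / (s2[i, i].mean() + s2[j, j].mean())
            )
            dist[i, j] = dist[j, i] = d
    cross = sum(s2[i, j] for i in range(nm) for j in range(nm) if i != j)
    self_ = sum(s2[i, i] for i in range(nm))
    disc_power = np.sqrt(cross / np.where(self_ > 0, self_, np.nan))
    return dist, disc_power


# ---------------------------------------------------------------------------
# Band identification


def find_bands(
    vector: np.ndarray,
    grid: WavelengthGrid,
    min_prominence: float = 0.0,
    min_separation_nm: float = 0.0,
) -> pd.DataFrame:
    """Local extrema of both signs on a model vector (loading, regression
    vector, difference spectrum...).

    Returns a frame of (wavelength, sign, magnitude) sorted by |magnitude|
    descending.  Positions are invariant to adding a constant offset.
    """
    v = np.asarray(vector, dtype=float)
    if v.shape != (len(grid),):
        raise ValueError("vector length must equal the grid length")
    distance = max(1, int(np.ceil(min_separation_nm / grid.step)))
    rows = []
    for sign, w in ((1, v), (-1, -v)):
        peaks, props = find_peaks(w, prominence=min_prominence or None,
                                  distance=distance)
        for p_idx in peaks:
            rows.append(
                {
                    "wavelength": grid.values[p_idx],
                    "sign": sign,
                    "magnitude": abs(v[p_idx]),
                }
            )
    out = pd.DataFrame(rows, columns=["wavelength", "sign", "magnitude"])
    return out.sort_values(
        "magnitude", ascending=False, kind="stable"
    ).reset_index(drop=True)
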