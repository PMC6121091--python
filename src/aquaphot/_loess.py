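"""Local polynomial regression (loess) with tricube weights.

Used for the temperature-calibration curves: a handful of reference
temperature levels, fitted with a degree-2 local polynomial and evaluated on
a dense lattice.  Exact on global polynomials of degree <= the local degree.
"""

from __future__ import annotations

import numpy as np

__all__ = ["loess"]


def loess(
    x: np.ndarray,
    y: np.ndarray,
    x_eval: np.ndarray,
    span: float = 0.75,
    degree: int = 2,
) -> np.ndarray:
    """Evaluate a loess fit of y(x) at ``x_eval``.

    ``span`` is the fraction of points in each local window (at least
    degree + 1 points are always used); weights are tricube in the scaled
    distance to the evaluation point.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    x_eval = np.asarray(x_eval, dtype=float)
    n = x.size
    if n != y.size:
        raise ValueError("x and y lengths differ")
    if not 0 < span <= 1:
        raise ValueError("span must be in (0, 1]")
    k = max(int(np.ceil(span * n)), degree + 1)
    if k > n:
        raise ValueError(f"need at least {degree + 1} points, got {n}")
    out = np.empty_like(x_eval)
    scale = np.ptp(x) or 1.0
    for i, x0 in enumerate(x_eval):
        d = np.abs(x - x0)
        idx = np.argsort(d, kind="stable")[:k]
        h = d[idx].max()
        if h == 0:
            # all window points coincide with x0
            out[i] = y[idx].mean()
            continue
        w = (1 - np.clip(d[idx] / h, 0, 1) ** 3) ** 3
        w = np.maximum(w, 1e-9)  # keep the design full rank at window edges
        t = (x[idx] - x0) / scale
        v = np.vander(t, degree + 1, increasing=True)
        wv = v * w[:, None]
        beta, *_ = np.linalg.lstsq(wv.T @ v, wv.T @ y[idx], rcond=None)
        out[i] = beta[0]
    return out
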