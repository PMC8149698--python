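"""Two-dimensional locally weighted regression over plate coordinates.

Classic loess: for every prediction point, take the nearest ``span`` fraction
of fit points in (row, col) Euclidean distance, weight them with the tricube
kernel, and fit a weighted linear (degree 1) or quadratic (degree 2)
polynomial. All prediction points are solved in one batched normal-equations
pass, which is fast at plate scale (a few hundred wells).
"""

from __future__ import annotations

import numpy as np

__all__ = ["loess2d"]


def _design(rows: np.ndarray, cols: np.ndarray, degree: int) -> np.ndarray:
    terms = [np.ones_like(rows, dtype=float), rows, cols]
    if degree == 2:
        terms += [rows * cols, rows**2, cols**2]
    return np.column_stack(terms)


def loess2d(
    fit_rows: np.ndarray,
    fit_cols: np.ndarray,
    fit_values: np.ndarray,
    pred_rows: np.ndarray,
    pred_cols: np.ndarray,
    span: float = 0.5,
    degree: int = 1,
    robust_iters: int = 1,
) -> np.ndarray:
    """Predict a loess surface at (pred_rows, pred_cols).

    Parameters
    ----------
    fit_rows, fit_cols, fit_values:
        Coordinates and responses of the wells the surface is fitted on.
    pred_rows, pred_cols:
        Coordinates at which the surface is evaluated (may include wells not
        used for fitting, e.g. control wells).
    span:
        Fraction of fit points in each local neighbourhood, in (0, 1].
    degree:
        Local polynomial degree, 1 or 2.
    robust_iters:
        Number of bisquare robustifying reweights, so isolated outliers (e.g.
        strong hits) do not drag the surface toward themselves. 0 disables.
    """
    if not 0.0 < span <= 1.0:
        raise ValueError("span must lie in (0, 1]")
    if degree not in (1, 2):
        raise ValueError("degree must be 1 or 2")
    fit_rows = np.asarray(fit_rows, dtype=float)
    fit_cols = np.asarray(fit_cols, dtype=float)
    y = np.asarray(fit_values, dtype=float)
    pred_rows = np.asarray(pred_rows, dtype=float)
    pred_cols = np.asarray(pred_cols, dtype=float)
    n_fit = len(y)
    q = max(int(np.ceil(span * n_fit)), _design(fit_rows, fit_cols, degree).shape[1] + 1)
    q = min(q, n_fit)

    X = _design(fit_rows, fit_cols, degree)

    def kernel(rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
        d = np.hypot(rows[:, None] - fit_rows[None, :], cols[:, None] - fit_cols[None, :])
        # local bandwidth = distance to the q-th nearest fit point
        h = np.maximum(np.partition(d, q - 1, axis=1)[:, q - 1], 1e-12)
        w = np.clip(1.0 - (d / h[:, None]) ** 3, 0.0, None) ** 3
        # points exactly at the bandwidth edge get zero weight; ensure the
        # local system stays well-posed by flooring the q nearest weights
        order = np.argsort(d, axis=1)[:, :q]
        np.put_along_axis(
            w, order, np.maximum(np.take_along_axis(w, order, axis=1), 1e-9), axis=1
        )
        return w

    def solve(w: np.ndarray, Xp: np.ndarray) -> np.ndarray:
        # batched weighted least squares via normal equations
        XtWX = np.einsum("if,mi,ig->mfg", X, w, X)
        XtWy = np.einsum("if,mi,i->mf", X, w, y)
        XtWX += 1e-10 * np.eye(X.shape[1])[None, :, :]
        beta = np.linalg.solve(XtWX, XtWy[..., None])[..., 0]
        return np.einsum("mf,mf->m", Xp, beta)

    w_pred = kernel(pred_rows, pred_cols)
    delta = np.ones(n_fit)
    if robust_iters > 0:
        w_fit = kernel(fit_rows, fit_cols)
        for _ in range(robust_iters):
            resid = y - solve(w_fit * delta[None, :], X)
            s = np.median(np.abs(resid))
            if s <= 1e-12:  # (near-)exact fit; robust weights undefined
                break
            delta = np.clip(1.0 - (resid / (6.0 * s)) ** 2, 0.0, None) ** 2
    return solve(w_pred * delta[None, :], _design(pred_rows, pred_cols, degree))
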