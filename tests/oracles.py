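"""Independent brute-force oracles used to cross-check the implementation.

These deliberately avoid the package's own code paths: normal equations via
pseudoinverse, closed-form ridge solves, textbook Pearson correlation,
explicit leave-one-out loops and the hat-matrix identity.
"""

from __future__ import annotations

import numpy as np


def pinv_ols(X: np.ndarray, y: np.ndarray, intercept: bool = True):
    """Least squares by explicit pseudoinverse of the design matrix."""
    X = np.asarray(X, float)
    if intercept:
        design = np.column_stack([np.ones(len(X)), X])
    else:
        design = X
    coef = np.linalg.pinv(design) @ np.asarray(y, float)
    resid = y - design @ coef
    return coef, float(resid @ resid)


def ridge_closed_form(Xs: np.ndarray, yc: np.ndarray, lam: float) -> np.ndarray:
    """(X'X + lam I)^-1 X'y via explicit matrix inverse."""
    p = Xs.shape[1]
    return np.linalg.inv(Xs.T @ Xs + lam * np.eye(p)) @ (Xs.T @ yc)


def pearson_r2(a, b) -> float:
    """Squared Pearson correlation from the textbook sum formula."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    n = a.size
    num = n * (a * b).sum() - a.sum() * b.sum()
    den = np.sqrt(n * (a**2).sum() - a.sum() ** 2) * np.sqrt(
        n * (b**2).sum() - b.sum() ** 2
    )
    return float((num / den) ** 2)


def explicit_loo_rmse(Xs: np.ndarray, yc: np.ndarray, fit_fn) -> float:
    """Leave-one-out RMSE by literally refitting on each n-1 subset.

    ``fit_fn(X, y) -> coefficients`` fits on centered/standardized data.
    """
    n = Xs.shape[0]
    resid = np.empty(n)
    for i in range(n):
        mask = np.arange(n) != i
        b = fit_fn(Xs[mask], yc[mask])
        resid[i] = yc[i] - Xs[i] @ b
    return float(np.sqrt((resid**2).mean()))


def hat_matrix_loo_residuals(Xs: np.ndarray, yc: np.ndarray) -> np.ndarray:
    """OLS LOO residuals via the identity e_i / (1 - h_ii) on a fixed design."""
    H = Xs @ np.linalg.pinv(Xs.T @ Xs) @ Xs.T
    e = yc - H @ yc
    return e / (1.0 - np.diag(H))


def soft_threshold_oracle(z: np.ndarray, gamma: float) -> np.ndarray:
    return np.sign(z) * np.maximum(np.abs(z) - gamma, 0.0)
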