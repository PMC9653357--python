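"""Reduction of the motor battery to lateralized component scores.

A stroke cohort's motor battery (range-of-motion, strength, dexterity and
functional scales for both body sides) is reduced with a principal component
analysis followed by an oblique (promax) rotation, yielding two correlated
components interpreted as overall motor ability of the left and right side
of the body.  Factor scores are signed so that higher raw performance maps
to a higher score; impairment is a negative score.

The varimax and promax rotations are implemented here directly (they are
short, fully deterministic algorithms) and are cross-checked in the test
suite against R's ``stats::promax``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .synthetic import MotorBattery, SIDES, TIMEPOINTS


class DegenerateVarianceError(ValueError):
    """A battery column is constant and cannot be standardized."""


# ---------------------------------------------------------------------------
# rotations
# ---------------------------------------------------------------------------


def varimax(loadings: np.ndarray, tol: float = 1e-10, max_iter: int = 1000):
    """Orthogonal varimax rotation with Kaiser row normalization.

    Kaiser's pairwise-Jacobi scheme: every factor pair is rotated in turn by
    its closed-form optimal angle until no pair moves.  (The closed form
    makes the degenerate equal-eigenvalue case, where gradient-based
    rotations stall, converge as well.)  Returns (rotated loadings, rotation
    matrix T); rotated = loadings_normalized @ T, un-normalized back to the
    original communalities.
    """
    A = np.asarray(loadings, dtype=float)
    p, k = A.shape
    if k < 2:
        return A.copy(), np.eye(k)
    h = np.sqrt((A**2).sum(axis=1))
    h[h == 0] = 1.0
    L = A / h[:, None]
    T = np.eye(k)
    for _ in range(max_iter):
        largest = 0.0
        for i in range(k - 1):
            for j in range(i + 1, k):
                x, y = L[:, i], L[:, j]
                u = x * x - y * y
                v = 2.0 * x * y
                a, b = u.sum(), v.sum()
                c = (u * u - v * v).sum()
                d = 2.0 * (u * v).sum()
                num = d - 2.0 * a * b / p
                den = c - (a * a - b * b) / p
                theta = 0.25 * np.arctan2(num, den)
                if abs(theta) < 1e-12:
                    continue
                largest = max(largest, abs(theta))
                co, si = np.cos(theta), np.sin(theta)
                L[:, i], L[:, j] = co * x + si * y, -si * x + co * y
                T[:, [i, j]] = T[:, [i, j]] @ np.array([[co, -si], [si, co]])
        if largest < tol:
            break
    return L * h[:, None], T


def promax(loadings: np.ndarray, power: int = 4):
    """Oblique promax rotation (varimax first, then a power-``power`` target).

    Returns (pattern matrix, factor correlation matrix Phi, total rotation).
    The fitted subspace is unchanged: pattern @ Phi @ pattern.T equals the
    unrotated loadings' outer product exactly.
    """
    L, T_v = varimax(loadings)
    # sign-preserving power target sharpens the simple structure
    Q = L * np.abs(L) ** (power - 1)
    U, *_ = np.linalg.lstsq(L, Q, rcond=None)
    d = np.diag(np.linalg.inv(U.T @ U))
    U = U * np.sqrt(d)[None, :]
    pattern = L @ U
    rot = T_v @ U
    inv_rot = np.linalg.inv(rot)
    phi = inv_rot @ inv_rot.T
    return pattern, phi, rot


# ---------------------------------------------------------------------------
# domain type
# ---------------------------------------------------------------------------


@dataclass
class MotorOutcome:
    """Lateralized motor component scores per patient, side and timepoint."""

    scores: np.ndarray  # n_patients x 2 sides x 3 timepoints
    loadings: dict = field(default_factory=dict)  # timepoint -> n_tests x 2 pattern
    variance_explained: dict = field(default_factory=dict)  # timepoint -> fraction
    factor_correlation: dict = field(default_factory=dict)  # timepoint -> scalar
    patient_ids: list[str] = field(default_factory=list)
    test_names: list[str] = field(default_factory=list)

    def score_vector(self, side: str, timepoint: str) -> np.ndarray:
        return self.scores[:, SIDES.index(side), TIMEPOINTS.index(timepoint)]

    def to_csv(self, path) -> None:
        rows = []
        for i, pid in enumerate(self.patient_ids):
            for s, side in enumerate(SIDES):
                for t, tp in enumerate(TIMEPOINTS):
                    rows.append(
                        {"patient_id": pid, "side": side, "timepoint": tp,
                         "score": self.scores[i, s, t]}
                    )
        pd.DataFrame(rows).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "MotorOutcome":
        df = pd.read_csv(path)
        pids = list(dict.fromkeys(df["patient_id"].astype(str)))
        scores = np.zeros((len(pids), len(SIDES), len(TIMEPOINTS)))
        idx = {p: i for i, p in enumerate(pids)}
        for _, row in df.iterrows():
            scores[idx[str(row["patient_id"])],
                   SIDES.index(row["side"]),
                   TIMEPOINTS.index(row["timepoint"])] = row["score"]
        return cls(scores=scores, patient_ids=pids)


@dataclass
class ObliquePCAResult:
    """Single-matrix oblique PCA: scores, pattern loadings, fit summaries."""

    scores: np.ndarray  # n_patients x n_components (column 0 = left, 1 = right)
    loadings: np.ndarray  # n_tests x n_components pattern matrix
    variance_explained: float  # from the unrotated components
    factor_correlation: float
    test_names: list[str]


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------


def _standardize_columns(X: np.ndarray, names: list[str]) -> np.ndarray:
    sd = X.std(axis=0, ddof=1)
    constant = np.where(sd == 0)[0]
    if constant.size:
        bad = ", ".join(names[j] for j in constant)
        raise DegenerateVarianceError(f"constant battery column(s): {bad}")
    return (X - X.mean(axis=0)) / sd


def fit_oblique_pca(
    battery_matrix: np.ndarray,
    test_names: list[str] | None = None,
    n_components: int = 2,
    anchor_test: str = "grip_kg",
) -> ObliquePCAResult:
    """PCA of the standardized battery followed by promax rotation.

    Factor scores use the regression (Thurstone) method on the standardized
    data.  When ``test_names`` carry ``l_`` / ``r_`` prefixes, factors are
    assigned to body sides by their structure loadings and ordered
    (left, right); each factor's sign is anchored so the side's
    ``anchor_test`` loads positively (higher performance -> higher score).
    ``variance_explained`` is the unrotated top-``n_components`` eigenvalue
    share of the correlation matrix.
    """
    X = np.asarray(battery_matrix, dtype=float)
    n, m = X.shape
    if test_names is None:
        test_names = [f"test_{j}" for j in range(m)]
    if n < 10:
        raise ValueError(f"need at least 10 patients, got {n}")
    if m < 3:
        raise ValueError(f"need at least 3 tests, got {m}")
    Z = _standardize_columns(X, list(test_names))
    R = (Z.T @ Z) / (n - 1)
    eigvals, eigvecs = np.linalg.eigh(R)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    top = np.clip(eigvals[:n_components], 0.0, None)
    variance_explained = float(top.sum() / m)
    A = eigvecs[:, :n_components] * np.sqrt(top)[None, :]

    pattern, phi, _ = promax(A)
    structure = pattern @ phi

    # regression-method factor scores on the standardized data
    weights = np.linalg.solve(R, structure)
    scores = Z @ weights

    # assign factors to sides via structure loadings, then anchor the sign
    sided = [name[:2] in ("l_", "r_") for name in test_names]
    if n_components == 2 and all(sided):
        left_idx = [j for j, name in enumerate(test_names) if name.startswith("l_")]
        right_idx = [j for j, name in enumerate(test_names) if name.startswith("r_")]
        left_ss = (structure[left_idx] ** 2).sum(axis=0)
        # factor with the larger left-side structure load is the left factor
        lf = int(np.argmax(left_ss - (structure[right_idx] ** 2).sum(axis=0)))
        perm = [lf, 1 - lf]
        pattern, structure = pattern[:, perm], structure[:, perm]
        scores = scores[:, perm]
        phi = phi[np.ix_(perm, perm)]
        for col, prefix in enumerate(("l_", "r_")):
            anchor = f"{prefix}{anchor_test}"
            j = test_names.index(anchor) if anchor in test_names else (
                left_idx[0] if col == 0 else right_idx[0]
            )
            if structure[j, col] < 0:
                pattern[:, col] *= -1
                structure[:, col] *= -1
                scores[:, col] *= -1
                phi[col, 1 - col] *= -1
                phi[1 - col, col] *= -1
    else:
        for col in range(n_components):
            j = int(np.argmax(np.abs(structure[:, col])))
            if structure[j, col] < 0:
                pattern[:, col] *= -1
                structure[:, col] *= -1
                scores[:, col] *= -1
                phi[col, :] *= -1
                phi[:, col] *= -1
                np.fill_diagonal(phi, 1.0)

    factor_corr = float(phi[0, 1]) if n_components >= 2 else 0.0
    return ObliquePCAResult(
        scores=scores,
        loadings=pattern,
        variance_explained=variance_explained,
        factor_correlation=factor_corr,
        test_names=list(test_names),
    )


def fit_motor_outcome(battery: MotorBattery, pooled: bool = False) -> MotorOutcome:
    """Oblique PCA of the battery into left/right scores, per timepoint.

    Each timepoint is reduced independently by default; with ``pooled`` a
    single PCA is fitted on the stacked timepoints and scored per timepoint.
    """
    results: dict[str, ObliquePCAResult] = {}
    if pooled:
        mats, pids_ref = [], None
        for tp in TIMEPOINTS:
            M, pids, names = battery.matrix(tp)
            mats.append(M)
            pids_ref = pids
        stacked = np.vstack(mats)
        pooled_fit = fit_oblique_pca(stacked, names)
        n = len(pids_ref)
        for t, tp in enumerate(TIMEPOINTS):
            res = ObliquePCAResult(
                scores=pooled_fit.scores[t * n : (t + 1) * n],
                loadings=pooled_fit.loadings,
                variance_explained=pooled_fit.variance_explained,
                factor_correlation=pooled_fit.factor_correlation,
                test_names=pooled_fit.test_names,
            )
            results[tp] = res
        pids = pids_ref
    else:
        for tp in TIMEPOINTS:
            M, pids, names = battery.matrix(tp)
            results[tp] = fit_oblique_pca(M, names)

    n = len(pids)
    scores = np.zeros((n, len(SIDES), len(TIMEPOINTS)))
    loadings, varexp, fcorr = {}, {}, {}
    for t, tp in enumerate(TIMEPOINTS):
        scores[:, :, t] = results[tp].scores
        loadings[tp] = results[tp].loadings
        varexp[tp] = results[tp].variance_explained
        fcorr[tp] = results[tp].factor_correlation
    return MotorOutcome(
        scores=scores,
        loadings=loadings,
        variance_explained=varexp,
        factor_correlation=fcorr,
        patient_ids=pids,
        test_names=results[TIMEPOINTS[0]].test_names,
    )


def impairment_proportion(outcome: MotorOutcome, timepoint: str) -> dict[str, float]:
    """Fraction of patients with a motor score strictly below zero, per side."""
    if timepoint not in TIMEPOINTS:
        raise ValueError(f"unknown timepoint {timepoint!r}; expected one of {TIMEPOINTS}")
    t = TIMEPOINTS.index(timepoint)
    return {
        side: float((outcome.scores[:, s, t] < 0).mean())
        for s, side in enumerate(SIDES)
    }
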