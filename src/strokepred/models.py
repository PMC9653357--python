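"""The six predictive model families for component-score regression.

Motor outcomes (one latent score per side and timepoint) are predicted from
46 disconnectome component scores with six linear families:

* backward / forward *hierarchical* regression (bHLR / fHLR): predictors are
  dropped or added strictly in component-index order, each step judged by a
  nested-model F-test;
* backward / forward *stepwise* regression: predictors are removed/added by
  coefficient p-value, with a cap on the number of predictors as the tuned
  hyperparameter;
* lasso (L1 penalty, coordinate descent with soft-thresholding) and ridge
  (L2 penalty, closed form), whose penalties are the tuned hyperparameters.

All families operate on z-scored predictors and a centered response, using
training-fold statistics only, so penalties are comparable across components
and selection is invariant to affine rescaling of the raw predictors.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from ._utils import Standardizer, as_2d_float

FAMILIES = ("bHLR", "fHLR", "stepwise_backward", "stepwise_forward", "lasso", "ridge")

#: Relative threshold below which a residual sum of squares counts as zero.
_RSS_EPS = 1e-12


class EmptyDataError(ValueError):
    pass


class ConvergenceError(RuntimeError):
    """Coordinate descent failed to converge; carries the last iterate."""

    def __init__(self, msg: str, coefficients: np.ndarray):
        super().__init__(msg)
        self.coefficients = coefficients


class DegenerateComparisonError(ValueError):
    """Nested F-test between models with identical predictor counts."""


@dataclass
class ModelFit:
    """A fitted linear model on the standardized training scale.

    ``coefficients`` has one entry per original predictor column (zeros for
    unselected predictors) on the z-scored scale; ``intercept`` is the
    training mean of the response.  ``scaler`` stores the training-fold
    standardization so prediction applies exactly the training transform.
    """

    family: str
    coefficients: np.ndarray
    intercept: float
    selected: list[int]
    scaler: Standardizer
    hyperparameter: float | int | None = None
    rss: float | None = None
    df_resid: int | None = None
    n_train: int | None = None

    def __post_init__(self):
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if not np.all(np.isfinite(self.coefficients)):
            raise ValueError("non-finite coefficients")

    def to_json(self, path=None) -> str:
        d = {
            "family": self.family,
            "coefficients": self.coefficients.tolist(),
            "intercept": self.intercept,
            "selected": list(map(int, self.selected)),
            "hyperparameter": self.hyperparameter,
            "scaling": self.scaler.to_dict(),
            "rss": self.rss,
            "df_resid": self.df_resid,
            "n_train": self.n_train,
        }
        s = json.dumps(d, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(s)
        return s

    @classmethod
    def from_json(cls, source) -> "ModelFit":
        if isinstance(source, str) and source.lstrip().startswith("{"):
            d = json.loads(source)
        else:
            with open(source) as fh:
                d = json.load(fh)
        return cls(
            family=d["family"],
            coefficients=np.asarray(d["coefficients"]),
            intercept=d["intercept"],
            selected=d["selected"],
            scaler=Standardizer.from_dict(d["scaling"]),
            hyperparameter=d["hyperparameter"],
            rss=d["rss"],
            df_resid=d["df_resid"],
            n_train=d["n_train"],
        )


@dataclass
class FTestResult:
    f_stat: float
    df_numerator: int
    df_denominator: int
    p_value: float


# ---------------------------------------------------------------------------
# core least squares on pre-standardized data
# ---------------------------------------------------------------------------


def _ols_core(Xs: np.ndarray, yc: np.ndarray) -> tuple[np.ndarray, float, int]:
    """Least squares of centered y on standardized X (intercept absorbed).

    Returns (coefficients, RSS, residual df counting the absorbed intercept).
    Rank-deficient designs fall back to the minimum-norm solution with a
    warning.
    """
    n, p = Xs.shape
    if n == 0:
        raise EmptyDataError("no training rows")
    if p == 0:
        return np.zeros(0), float(yc @ yc), n - 1
    coef, _, rank, _ = np.linalg.lstsq(Xs, yc, rcond=None)
    if rank < p:
        warnings.warn(
            f"rank-deficient design (rank {rank} < {p}); minimum-norm solution",
            stacklevel=2,
        )
    resid = yc - Xs @ coef
    rss = float(resid @ resid)
    df = n - rank - 1
    return coef, rss, df


def _prepare(X, y):
    X = as_2d_float(X, "X")
    y = np.asarray(y, dtype=float).ravel()
    if X.shape[0] != y.size:
        raise ValueError("X and y have different numbers of rows")
    if X.shape[0] == 0:
        raise EmptyDataError("zero rows")
    scaler = Standardizer.fit(X)
    return scaler.transform(X), y - y.mean(), float(y.mean()), scaler


def fit_ols(X, y, selected: list[int] | None = None, family: str = "ols") -> ModelFit:
    """Ordinary least squares on standardized predictors (subset optional)."""
    Xs, yc, ymean, scaler = _prepare(X, y)
    p = Xs.shape[1]
    sel = list(range(p)) if selected is None else sorted(selected)
    coef_sub, rss, df = _ols_core(Xs[:, sel], yc)
    coefficients = np.zeros(p)
    coefficients[sel] = coef_sub
    return ModelFit(
        family=family,
        coefficients=coefficients,
        intercept=ymean,
        selected=sel,
        scaler=scaler,
        rss=rss,
        df_resid=df,
        n_train=Xs.shape[0],
    )


def predict(fit: ModelFit, X_new) -> np.ndarray:
    """Apply the stored training standardization, then the linear predictor."""
    X_new = as_2d_float(X_new, "X_new")
    if X_new.shape[1] != fit.coefficients.size:
        raise ValueError(
            f"X_new has {X_new.shape[1]} columns, model expects {fit.coefficients.size}"
        )
    return fit.intercept + fit.scaler.transform(X_new) @ fit.coefficients


# ---------------------------------------------------------------------------
# nested-model F-test
# ---------------------------------------------------------------------------


def _f_from_rss(
    rss_reduced: float, rss_full: float, delta_p: int, df_full: int, scale: float
) -> FTestResult:
    if delta_p == 0:
        raise DegenerateComparisonError("models have identical predictor counts")
    eps = _RSS_EPS * max(scale, 1.0)
    if rss_full <= eps:
        # saturated full model: any RSS drop is decisive, none is null
        if rss_reduced <= eps:
            return FTestResult(0.0, delta_p, max(df_full, 1), 1.0)
        return FTestResult(np.inf, delta_p, max(df_full, 1), 0.0)
    f = max(rss_reduced - rss_full, 0.0) / delta_p / (rss_full / df_full)
    p = float(stats.f.sf(f, delta_p, df_full))
    return FTestResult(float(f), delta_p, df_full, p)


def f_test_nested(fit_full: ModelFit, fit_reduced: ModelFit) -> FTestResult:
    """F-test comparing nested OLS fits on the same data.

    F = ((RSS_r - RSS_f) / dp) / (RSS_f / df_f), p from the F distribution.
    """
    if not set(fit_reduced.selected) <= set(fit_full.selected):
        raise ValueError("reduced predictor set is not nested in the full set")
    if fit_full.n_train != fit_reduced.n_train:
        raise ValueError("fits are not on the same data")
    dp = len(fit_full.selected) - len(fit_reduced.selected)
    scale = max(fit_reduced.rss, fit_full.rss)
    return _f_from_rss(fit_reduced.rss, fit_full.rss, dp, fit_full.df_resid, scale)


# ---------------------------------------------------------------------------
# hierarchical (index-ordered) selection
# ---------------------------------------------------------------------------


def hierarchical_select(X, y, direction: str, alpha: float = 0.05) -> ModelFit:
    """Hierarchical predictor elimination/addition in fixed index order.

    Backward: starting from the full model, predictors are visited from the
    last index to the first; each is dropped unless the nested F-test of the
    current model against the model without it is significant at ``alpha``.
    Forward: starting empty, predictors are visited from the first index and
    each is retained only if adding it significantly improves the fit.
    Passes are repeated until a full pass changes nothing (a single forward
    pass can miss a weak predictor whose effect is masked by stronger ones
    not yet in the model).
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if direction not in ("backward", "forward"):
        raise ValueError("direction must be 'backward' or 'forward'")
    Xs, yc, ymean, scaler = _prepare(X, y)
    n, p = Xs.shape

    def rss_df(sel: list[int]) -> tuple[float, int]:
        _, rss, df = _ols_core(Xs[:, sel], yc)
        return rss, df

    tss = float(yc @ yc)
    if direction == "backward":
        selected = list(range(p))
        for _ in range(p):
            changed = False
            rss_cur, df_cur = rss_df(selected)
            for j in sorted(selected, reverse=True):
                trial = [i for i in selected if i != j]
                rss_trial, _ = rss_df(trial)
                test = _f_from_rss(rss_trial, rss_cur, 1, df_cur, max(tss, rss_trial))
                if test.p_value > alpha:  # j does not help: drop it
                    selected = trial
                    changed = True
                    rss_cur, df_cur = rss_df(selected)
            if not changed:
                break
    else:
        selected: list[int] = []
        for _ in range(p):
            changed = False
            rss_cur, _ = rss_df(selected)
            for j in range(p):
                if j in selected:
                    continue
                trial = sorted(selected + [j])
                rss_trial, df_trial = rss_df(trial)
                test = _f_from_rss(rss_cur, rss_trial, 1, df_trial, max(tss, rss_cur))
                if test.p_value <= alpha:
                    selected = trial
                    changed = True
                    rss_cur = rss_trial
            if not changed:
                break

    coef_sub, rss, df = _ols_core(Xs[:, selected], yc)
    coefficients = np.zeros(p)
    coefficients[selected] = coef_sub
    return ModelFit(
        family="bHLR" if direction == "backward" else "fHLR",
        coefficients=coefficients,
        intercept=ymean,
        selected=selected,
        scaler=scaler,
        rss=rss,
        df_resid=df,
        n_train=n,
    )


# ---------------------------------------------------------------------------
# stepwise (p-value ordered) selection
# ---------------------------------------------------------------------------


def _coef_pvalues(Xs: np.ndarray, yc: np.ndarray, sel: list[int]) -> np.ndarray:
    """Two-sided t-test p-values of each selected coefficient.

    A numerically perfect fit makes every nonzero coefficient maximally
    significant and every (numerically) zero coefficient maximally
    insignificant.
    """
    Xsub = Xs[:, sel]
    n, k = Xsub.shape
    coef, rss, df = _ols_core(Xsub, yc)
    tss = float(yc @ yc)
    if rss <= _RSS_EPS * max(tss, 1.0) or df <= 0:
        return np.where(np.abs(coef) > 1e-8, 0.0, 1.0)
    sigma2 = rss / df
    xtx_inv = np.linalg.pinv(Xsub.T @ Xsub)
    se = np.sqrt(np.clip(sigma2 * np.diag(xtx_inv), 0.0, None))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, coef / se, np.inf * np.sign(coef))
    return 2.0 * stats.t.sf(np.abs(t), df)


def stepwise_select(
    X, y, direction: str, alpha: float = 0.05, max_predictors: int | None = None
) -> ModelFit:
    """Stepwise selection by coefficient p-value with a size cap.

    Backward: start from the full model and repeatedly remove the predictor
    with the largest p-value until every remaining p-value is <= ``alpha``
    and at most ``max_predictors`` remain.  Forward: repeatedly add the
    candidate with the smallest p-value (in the model including it) while
    that p-value is <= ``alpha``, stopping at ``max_predictors``.  Ties are
    broken in favour of the lower predictor index.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    Xs, yc, ymean, scaler = _prepare(X, y)
    n, p = Xs.shape
    if max_predictors is None:
        max_predictors = p
    if not 1 <= max_predictors <= p:
        raise ValueError("need 1 <= max_predictors <= n_predictors")

    if direction == "backward":
        selected = list(range(p))
        while selected:
            pvals = _coef_pvalues(Xs, yc, selected)
            if len(selected) <= max_predictors and pvals.max() <= alpha:
                break
            # drop the least significant; on ties keep the lower index
            worst = max(range(len(selected)), key=lambda i: (pvals[i], selected[i]))
            selected.pop(worst)
    elif direction == "forward":
        selected = []
        while len(selected) < max_predictors:
            candidates = [j for j in range(p) if j not in selected]
            if not candidates:
                break
            best_j, best_p = None, None
            for j in candidates:
                trial = sorted(selected + [j])
                pvals = _coef_pvalues(Xs, yc, trial)
                pj = pvals[trial.index(j)]
                if best_p is None or pj < best_p:  # strict: ties keep lower index
                    best_j, best_p = j, pj
            if best_p is None or best_p > alpha:
                break
            selected = sorted(selected + [best_j])
    else:
        raise ValueError("direction must be 'backward' or 'forward'")

    coef_sub, rss, df = _ols_core(Xs[:, selected], yc)
    coefficients = np.zeros(p)
    coefficients[selected] = coef_sub
    return ModelFit(
        family=f"stepwise_{direction}",
        coefficients=coefficients,
        intercept=ymean,
        selected=sorted(selected),
        scaler=scaler,
        hyperparameter=int(max_predictors),
        rss=rss,
        df_resid=df,
        n_train=n,
    )


# ---------------------------------------------------------------------------
# penalized families
# ---------------------------------------------------------------------------


def ridge_path_solver(Xs: np.ndarray, yc: np.ndarray):
    """Return a solver lambda2 -> coefficients via one eigendecomposition.

    Solves (Xs'Xs + lambda2 I) b = Xs'y for many penalties cheaply; used by
    both :func:`fit_ridge` and the leave-one-out tuner.
    """
    G = Xs.T @ Xs
    c = Xs.T @ yc
    evals, evecs = np.linalg.eigh(G)
    vc = evecs.T @ c

    def solve(lambda2: float) -> np.ndarray:
        return evecs @ (vc / (np.clip(evals, 0.0, None) + lambda2)) if lambda2 > 0 \
            else np.linalg.lstsq(Xs, yc, rcond=None)[0]

    return solve


def fit_ridge(X, y, lambda2: float) -> ModelFit:
    """Ridge regression: b = (Xs'Xs + lambda2 I)^-1 Xs'y on z-scored predictors.

    The response is centered and the intercept (training mean of y) is not
    penalized.  The L2 penalty shrinks but never zeroes coefficients, so
    ``selected`` is always the full predictor set.
    """
    if lambda2 < 0:
        raise ValueError("lambda2 must be >= 0")
    Xs, yc, ymean, scaler = _prepare(X, y)
    p = Xs.shape[1]
    if lambda2 == 0:
        coef, _, _, _ = np.linalg.lstsq(Xs, yc, rcond=None)
    else:
        coef = np.linalg.solve(Xs.T @ Xs + lambda2 * np.eye(p), Xs.T @ yc)
    resid = yc - Xs @ coef
    return ModelFit(
        family="ridge",
        coefficients=coef,
        intercept=ymean,
        selected=list(range(p)),
        scaler=scaler,
        hyperparameter=float(lambda2),
        rss=float(resid @ resid),
        df_resid=None,
        n_train=Xs.shape[0],
    )


def soft_threshold(z: float, gamma: float) -> float:
    """Soft-thresholding operator S(z, gamma) = sign(z) max(|z| - gamma, 0)."""
    return np.sign(z) * max(abs(z) - gamma, 0.0)


def lasso_lambda_max(X, y) -> float:
    """Smallest L1 penalty that zeroes every coefficient: max|Xs'yc| / n."""
    Xs, yc, _, _ = _prepare(X, y)
    return float(np.max(np.abs(Xs.T @ yc)) / Xs.shape[0])


def _cd_kernel(Xs, yc, col_nrm, b, lambda1, tol, max_iter):
    """Cyclic coordinate-descent sweeps; returns iterations used or -1."""
    n, p = Xs.shape
    r = yc - Xs @ b
    for it in range(max_iter):
        delta = 0.0
        for j in range(p):
            if col_nrm[j] == 0.0:
                continue
            bj_old = b[j]
            rho = (Xs[:, j] @ r) / n + col_nrm[j] * bj_old
            a = abs(rho) - lambda1
            bj_new = (np.sign(rho) * a / col_nrm[j]) if a > 0.0 else 0.0
            if bj_new != bj_old:
                r += Xs[:, j] * (bj_old - bj_new)
                b[j] = bj_new
                d = abs(bj_new - bj_old)
                if d > delta:
                    delta = d
        if delta < tol:
            return it + 1
    return -1


try:  # the jitted kernel cuts coordinate-descent cost by ~two orders
    from numba import njit

    _cd_kernel = njit(cache=True)(_cd_kernel)
except ImportError:  # pragma: no cover - numba is an optional accelerator
    pass


def _kkt_violation_raw(Xs, yc, b, lambda1) -> float:
    n = Xs.shape[0]
    g = Xs.T @ (yc - Xs @ b) / n
    active = b != 0
    v_a = np.abs(g[active] - lambda1 * np.sign(b[active]))
    v_i = np.clip(np.abs(g[~active]) - lambda1, 0.0, None)
    parts = np.concatenate([v_a, v_i])
    return float(parts.max()) if parts.size else 0.0


def _lasso_cd(
    Xs: np.ndarray,
    yc: np.ndarray,
    lambda1: float,
    tol: float,
    max_iter: int,
    coef0: np.ndarray | None = None,
) -> np.ndarray:
    """Cyclic coordinate descent for (1/2n)||yc - Xs b||^2 + lambda1 ||b||_1.

    Between chunks of sweeps an active-set Newton step is attempted: the KKT
    stationarity system is solved directly for the current sign pattern and
    accepted only if the signs verify and no inactive gradient exceeds the
    penalty.  The accelerated exit is exact (machine-precision subgradient
    conditions); plain coordinate descent remains the fallback, so ill-
    conditioned near-interpolation problems (p close to n at tiny penalties)
    terminate quickly instead of crawling at the coordinate-descent rate.
    """
    n, p = Xs.shape
    Xs = np.ascontiguousarray(Xs)
    yc = np.ascontiguousarray(yc)
    col_nrm = np.ascontiguousarray((Xs**2).sum(axis=0) / n)
    b = np.zeros(p) if coef0 is None else coef0.copy()
    G = None
    c = None
    used = 0
    chunk = 50
    while used < max_iter:
        if np.any(b):  # try the exact active-set solve from the warm iterate
            if G is None:
                G = Xs.T @ Xs / n
                c = Xs.T @ yc / n
            cand = _active_set_polish(G, c, b, lambda1, tol, n)
            if cand is not None and _kkt_violation_raw(Xs, yc, cand, lambda1) <= max(
                tol, 1e-9
            ):
                return cand
        status = _cd_kernel(
            Xs, yc, col_nrm, b, float(lambda1), float(tol),
            int(min(chunk, max_iter - used)),
        )
        if status >= 0:
            return b
        used += chunk
    raise ConvergenceError(
        f"lasso did not converge in {max_iter} iterations (lambda1={lambda1})", b
    )


def _active_set_polish(G, c, b, lambda1, tol, n, max_pass=40):
    """Exact active-set solve of the lasso KKT system from a warm iterate.

    Iterates: solve stationarity on the working set for its sign pattern,
    drop coordinates whose sign flips, admit the worst inactive violator;
    terminates when the full subgradient conditions hold.  Returns None if
    the working set cycles (caller falls back to coordinate descent).
    """
    p = c.size
    active = [int(j) for j in np.flatnonzero(b)]
    signs = {j: np.sign(b[j]) for j in active}
    if not active:
        return None
    for _ in range(max_pass):
        A = sorted(active)
        if len(A) >= n:
            return None  # interpolating working set: leave it to descent
        sA = np.array([signs[j] for j in A])
        try:
            bA = np.linalg.solve(G[np.ix_(A, A)], c[A] - lambda1 * sA)
        except np.linalg.LinAlgError:
            return None
        flipped = [j for j, v in zip(A, bA) if np.sign(v) != signs[j]]
        if flipped:
            for j in flipped:
                active.remove(j)
                signs.pop(j)
            if not active:
                return None
            continue
        cand = np.zeros(p)
        cand[A] = bA
        g = c - G @ cand
        inactive = np.setdiff1d(np.arange(p), A)
        if inactive.size:
            viol = np.abs(g[inactive]) - lambda1
            worst = int(np.argmax(viol))
            if viol[worst] > min(tol, 1e-9):
                j = int(inactive[worst])
                active.append(j)
                signs[j] = np.sign(g[j])
                continue
        return cand
    return None


def fit_lasso(X, y, lambda1: float, tol: float = 1e-7, max_iter: int = 10_000) -> ModelFit:
    """Lasso via cyclic coordinate descent with soft-thresholding.

    Objective (1/2n)||yc - Xs b||^2 + lambda1 ||b||_1 on z-scored predictors
    and centered response; coefficients outside the active set are exactly
    zero and the converged solution satisfies the subgradient (KKT)
    optimality conditions to tolerance.
    """
    if lambda1 < 0:
        raise ValueError("lambda1 must be >= 0")
    Xs, yc, ymean, scaler = _prepare(X, y)
    coef = _lasso_cd(Xs, yc, lambda1, tol, max_iter)
    # snap numerical dust to exact zero so the active set is unambiguous
    big = np.abs(coef).max() if coef.size else 0.0
    coef[np.abs(coef) <= 1e-12 * max(big, 1.0)] = 0.0
    selected = [int(j) for j in np.flatnonzero(coef)]
    resid = yc - Xs @ coef
    return ModelFit(
        family="lasso",
        coefficients=coef,
        intercept=ymean,
        selected=selected,
        scaler=scaler,
        hyperparameter=float(lambda1),
        rss=float(resid @ resid),
        df_resid=None,
        n_train=Xs.shape[0],
    )


def lasso_kkt_violation(X, y, fit: ModelFit) -> float:
    """Maximum violation of the lasso subgradient optimality conditions.

    For active coefficients the gradient must equal lambda1 * sign(b_j); for
    inactive ones it must not exceed lambda1 in magnitude.  Returns the
    largest deviation (0 for an exact optimum).
    """
    Xs = fit.scaler.transform(as_2d_float(X, "X"))
    yc = np.asarray(y, dtype=float).ravel() - fit.intercept
    n = Xs.shape[0]
    g = Xs.T @ (yc - Xs @ fit.coefficients) / n
    lam = fit.hyperparameter
    active = fit.coefficients != 0
    v_active = np.abs(g[active] - lam * np.sign(fit.coefficients[active]))
    v_inactive = np.clip(np.abs(g[~active]) - lam, 0.0, None)
    parts = np.concatenate([v_active, v_inactive])
    return float(parts.max()) if parts.size else 0.0
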