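"""Evaluation protocol: repeated splits, LOOCV tuning, mode-of-R² summaries.

The protocol mirrors a longitudinal prediction study design: for each model
family, body side and timepoint the cohort is split into training and test
sets (80/20 for tuned families, 78/22 for the hierarchical ones), any
hyperparameter is tuned by leave-one-out cross-validation on the training
set (smallest RMSE wins), the tuned model is refitted on the full training
set, and out-of-sample accuracy is the squared Pearson correlation between
predictions and observations on the test set.  The split is repeated many
times with consecutive seeds and the distribution of test R² is summarised
by its mode (Gaussian KDE, Silverman bandwidth).

Predictor importance for ridge models is the mean absolute standardized
coefficient across repetitions; overlap of the ridge top-k with the lasso
active set quantifies cross-family consistency.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from . import models
from .models import ModelFit, FAMILIES

HLR_FAMILIES = ("bHLR", "fHLR")


class FoldError(RuntimeError):
    """A cross-validation fold failed to fit."""


@dataclass
class SplitSpec:
    """A deterministic random train/test partition."""

    n_total: int
    train_fraction: float
    seed: int
    train_indices: np.ndarray
    test_indices: np.ndarray


@dataclass
class EvalConfig:
    """Protocol settings shared across families.

    ``ridge_grid`` spans 1e-4..1e4 (60 log-spaced penalties) and the lasso
    grid spans four decades below the training-set lambda_max; the stepwise
    grid is every predictor-count cap 1..p.  ``r2_definition`` selects the
    primary accuracy definition; both are always recorded.
    """

    base_seed: int = 0
    alpha: float = 0.05
    train_fraction_default: float = 0.80
    train_fraction_hlr: float = 0.78
    ridge_grid: np.ndarray = field(
        default_factory=lambda: 10.0 ** np.linspace(-4, 4, 60)
    )
    lasso_grid_decades: tuple[float, float] = (-4.0, 0.0)
    lasso_grid_size: int = 60
    lasso_tol: float = 1e-7
    lasso_max_iter: int = 10_000
    r2_definition: str = "squared_correlation"  # or "one_minus_sse"
    mode_method: str = "kde"
    mode_grid_points: int = 512

    def train_fraction(self, family: str) -> float:
        return self.train_fraction_hlr if family in HLR_FAMILIES else self.train_fraction_default


@dataclass
class EvalResult:
    """Repeated-split evaluation of one family x side x timepoint cell."""

    family: str
    side: str
    timepoint: str
    r2_values: np.ndarray  # primary definition, one per repetition (nan = degenerate)
    r2_mode: float
    chosen_hyperparameters: list
    coef_abs_mean: np.ndarray  # mean |standardized coefficient| per component
    selection_frequency: np.ndarray  # fraction of repetitions each predictor selected
    r2_values_alt: np.ndarray  # the other R² definition, for reference
    n_missing: int = 0


# ---------------------------------------------------------------------------
# splits and accuracy
# ---------------------------------------------------------------------------


def split_data(n_total: int, train_fraction: float, seed: int) -> SplitSpec:
    """Uniform random partition without replacement; |train| = round(f * n).

    Rounding (not flooring) the training size reproduces the canonical
    62-patient splits: 80% -> 50 train / 12 test and 78% -> 48 / 14.
    """
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must be in (0, 1)")
    if n_total < 5:
        raise ValueError("need n_total >= 5")
    n_train = int(np.floor(train_fraction * n_total + 0.5))
    if n_train == 0 or n_train == n_total:
        raise ValueError(f"degenerate split: {n_train}/{n_total - n_train}")
    perm = np.random.default_rng(seed).permutation(n_total)
    return SplitSpec(
        n_total=n_total,
        train_fraction=train_fraction,
        seed=seed,
        train_indices=np.sort(perm[:n_train]),
        test_indices=np.sort(perm[n_train:]),
    )


def r_squared(predictions, observations) -> float:
    """Squared Pearson correlation between predictions and observations.

    Affine-invariant by construction.  Constant predictions (for which the
    correlation is undefined) are scored 0 with a warning; constant
    observations violate the precondition and raise.
    """
    pred = np.asarray(predictions, dtype=float).ravel()
    obs = np.asarray(observations, dtype=float).ravel()
    if pred.size != obs.size or pred.size < 3:
        raise ValueError("need at least 3 prediction/observation pairs")
    if np.std(obs) == 0:
        raise ValueError("observations are constant; R² undefined")
    if np.std(pred) == 0:
        warnings.warn("constant predictions; R² defined as 0", stacklevel=2)
        return 0.0
    r = np.corrcoef(pred, obs)[0, 1]
    return float(r**2)


def r_squared_sse(predictions, observations) -> float:
    """1 - SSE/SST accuracy (can be negative out of sample)."""
    pred = np.asarray(predictions, dtype=float).ravel()
    obs = np.asarray(observations, dtype=float).ravel()
    sst = float(((obs - obs.mean()) ** 2).sum())
    if sst == 0:
        raise ValueError("observations are constant; R² undefined")
    return 1.0 - float(((obs - pred) ** 2).sum()) / sst


# ---------------------------------------------------------------------------
# LOOCV tuning
# ---------------------------------------------------------------------------


def _loo_ridge(Xs, yc, grid):
    """Exact leave-one-out ridge residuals for every penalty in the grid.

    Each fold removes one row from the Gram matrix (a rank-one downdate) and
    solves for all penalties through one eigendecomposition per fold, which
    is algebraically identical to refitting on the n-1 remaining rows.
    """
    n, p = Xs.shape
    G = Xs.T @ Xs
    c = Xs.T @ yc
    resid = np.empty((len(grid), n))
    grid = np.asarray(grid, dtype=float)
    for i in range(n):
        x = Xs[i]
        G_i = G - np.outer(x, x)
        c_i = c - x * yc[i]
        if np.all(grid > 0):
            evals, evecs = np.linalg.eigh(G_i)
            evals = np.clip(evals, 0.0, None)
            vc = evecs.T @ c_i
            vx = evecs.T @ x
            for g, lam in enumerate(grid):
                resid[g, i] = yc[i] - vx @ (vc / (evals + lam))
        else:  # unpenalized entries: plain per-fold least squares
            mask = np.arange(n) != i
            for g, lam in enumerate(grid):
                if lam > 0:
                    b = np.linalg.solve(G_i + lam * np.eye(p), c_i)
                else:
                    b, *_ = np.linalg.lstsq(Xs[mask], yc[mask], rcond=None)
                resid[g, i] = yc[i] - x @ b
    return resid


def _loo_lasso(Xs, yc, grid, tol, max_iter):
    """Leave-one-out lasso residuals, warm-started along the descending path."""
    n, p = Xs.shape
    order = np.argsort(np.asarray(grid))[::-1]  # fit large penalties first
    resid = np.empty((len(grid), n))
    for i in range(n):
        mask = np.arange(n) != i
        Xf, yf = Xs[mask], yc[mask]
        b = np.zeros(p)
        for g in order:
            b = models._lasso_cd(Xf, yf, float(grid[g]), tol, max_iter, coef0=b)
            resid[g, i] = yc[i] - Xs[i] @ b
    return resid


def _forward_path(Xs, yc, alpha):
    """Greedy forward addition order by candidate p-value (cap-independent)."""
    n, p = Xs.shape
    path, selected = [], []
    while len(selected) < p:
        best_j, best_p = None, None
        for j in range(p):
            if j in selected:
                continue
            trial = sorted(selected + [j])
            pv = models._coef_pvalues(Xs, yc, trial)
            pj = pv[trial.index(j)]
            if best_p is None or pj < best_p:
                best_j, best_p = j, pj
        if best_p is None or best_p > alpha:
            break
        selected = sorted(selected + [best_j])
        path.append(best_j)
    return path


def _backward_path(Xs, yc, alpha):
    """Full drop sequence by largest p-value; returns states and their
    'all-significant' flags, indexed by model size."""
    p = Xs.shape[1]
    selected = list(range(p))
    states = {p: list(selected)}
    ok = {0: True}
    while selected:
        pvals = models._coef_pvalues(Xs, yc, selected)
        ok[len(selected)] = bool(pvals.max() <= alpha)
        worst = max(range(len(selected)), key=lambda i: (pvals[i], selected[i]))
        selected = [s for k, s in enumerate(selected) if k != worst]
        states[len(selected)] = list(selected)
    return states, ok


def _loo_stepwise(Xs, yc, grid, direction, alpha):
    """Leave-one-out stepwise residuals for every predictor-count cap.

    The greedy selection path does not depend on the cap, so it is computed
    once per fold and truncated, which reproduces ``stepwise_select`` exactly.
    """
    n, p = Xs.shape
    grid = [int(k) for k in grid]
    resid = np.empty((len(grid), n))
    for i in range(n):
        mask = np.arange(n) != i
        Xf, yf = Xs[mask], yc[mask]
        if direction == "forward":
            path = _forward_path(Xf, yf, alpha)
            subsets = {k: sorted(path[: min(k, len(path))]) for k in grid}
        else:
            states, ok = _backward_path(Xf, yf, alpha)
            subsets = {}
            for k in grid:
                m = min(k, p)
                while m > 0 and not ok.get(m, False):
                    m -= 1
                subsets[k] = states[m]
        cache = {}
        for g, k in enumerate(grid):
            key = tuple(subsets[k])
            if key not in cache:
                if key:
                    b, *_ = np.linalg.lstsq(Xf[:, list(key)], yf, rcond=None)
                else:
                    b = np.zeros(0)
                cache[key] = b
            b = cache[key]
            resid[g, i] = yc[i] - (Xs[i, list(key)] @ b if key else 0.0)
    return resid


def loocv_tune(X_train, y_train, family: str, hyper_grid, config: EvalConfig | None = None):
    """Tune one hyperparameter by leave-one-out RMSE on the training set.

    The training design is standardized once (training statistics) and each
    patient is held out in turn against models fitted on the remainder.
    Returns ``(best_value, rmse_per_grid_value)``; RMSE ties go to the
    smaller model (larger penalty, or smaller predictor cap).
    """
    config = config or EvalConfig()
    grid = np.asarray(list(hyper_grid))
    if grid.size == 0:
        raise ValueError("hyper_grid is empty")
    Xs, yc, ymean, scaler = models._prepare(X_train, y_train)
    n = Xs.shape[0]
    if n < 5:
        raise ValueError("need at least 5 training rows for LOOCV")
    try:
        if family == "ridge":
            resid = _loo_ridge(Xs, yc, grid.astype(float))
        elif family == "lasso":
            resid = _loo_lasso(Xs, yc, grid.astype(float), config.lasso_tol, config.lasso_max_iter)
        elif family in ("stepwise_backward", "stepwise_forward"):
            resid = _loo_stepwise(Xs, yc, grid, family.split("_")[1], config.alpha)
        else:
            raise ValueError(f"family {family!r} has no tunable hyperparameter")
    except models.ConvergenceError as exc:
        raise FoldError(f"LOOCV fold failed to converge: {exc}") from exc
    rmse = np.sqrt((resid**2).mean(axis=1))
    best = rmse.min()
    tie = np.flatnonzero(rmse == best)
    if family in ("stepwise_backward", "stepwise_forward"):
        idx = tie[np.argmin(grid[tie])]
        return int(grid[idx]), rmse
    idx = tie[np.argmax(grid[tie])]
    return float(grid[idx]), rmse


# ---------------------------------------------------------------------------
# mode, importance, overlap
# ---------------------------------------------------------------------------


def distribution_mode(values, method: str = "kde", grid_points: int = 512) -> float:
    """Mode of a continuous sample.

    Gaussian KDE with Silverman bandwidth evaluated on ``grid_points``
    equally spaced points over [min, max] (argmax), or a histogram-based
    alternative.  An (effectively) constant sample returns its value.
    """
    vals = np.asarray(values, dtype=float)
    vals = vals[np.isfinite(vals)]
    if vals.size < 10:
        raise ValueError("need at least 10 finite values for a mode estimate")
    if np.ptp(vals) == 0:
        return float(vals[0])
    if method == "kde":
        try:
            kde = stats.gaussian_kde(vals, bw_method="silverman")
        except np.linalg.LinAlgError:
            return float(np.median(vals))
        grid = np.linspace(vals.min(), vals.max(), grid_points)
        return float(grid[np.argmax(kde(grid))])
    if method == "histogram":
        counts, edges = np.histogram(vals, bins=min(grid_points, 64))
        j = int(np.argmax(counts))
        return float((edges[j] + edges[j + 1]) / 2)
    raise ValueError(f"unknown mode method {method!r}")


def rank_importance(result, k: int = 3, component_ids: list[str] | None = None):
    """Top-k components by mean absolute standardized coefficient.

    ``result`` may be an :class:`EvalResult`, a sequence of fitted models,
    or a precomputed vector of mean |coefficient| values.  Returns a list of
    (component id, importance) pairs, largest first.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if isinstance(result, EvalResult):
        imp = result.coef_abs_mean
    elif isinstance(result, np.ndarray):
        imp = result
    else:
        fits = list(result)
        imp = np.mean([np.abs(f.coefficients) for f in fits], axis=0)
    p = imp.size
    if k > p:
        raise ValueError(f"k={k} exceeds {p} components")
    ids = component_ids or [f"C{j + 1}" for j in range(p)]
    order = np.argsort(imp)[::-1][:k]
    return [(ids[j], float(imp[j])) for j in order]


def component_overlap(ridge_top_k, lasso_selected) -> int:
    """Number of components shared between the ridge top-k and lasso active set."""
    return len(set(ridge_top_k) & set(lasso_selected))


# ---------------------------------------------------------------------------
# repeated evaluation
# ---------------------------------------------------------------------------


def _fit_family(X_tr, y_tr, family: str, config: EvalConfig) -> ModelFit:
    if family == "bHLR":
        return models.hierarchical_select(X_tr, y_tr, "backward", config.alpha)
    if family == "fHLR":
        return models.hierarchical_select(X_tr, y_tr, "forward", config.alpha)
    if family == "ridge":
        best, _ = loocv_tune(X_tr, y_tr, "ridge", config.ridge_grid, config)
        return models.fit_ridge(X_tr, y_tr, best)
    if family == "lasso":
        lam_max = models.lasso_lambda_max(X_tr, y_tr)
        lo, hi = config.lasso_grid_decades
        grid = lam_max * 10.0 ** np.linspace(lo, hi, config.lasso_grid_size)
        best, _ = loocv_tune(X_tr, y_tr, "lasso", grid, config)
        return models.fit_lasso(X_tr, y_tr, best, config.lasso_tol, config.lasso_max_iter)
    if family in ("stepwise_backward", "stepwise_forward"):
        p = np.asarray(X_tr).shape[1]
        grid = np.arange(1, p + 1)
        direction = family.split("_")[1]
        best, _ = loocv_tune(X_tr, y_tr, family, grid, config)
        return models.stepwise_select(X_tr, y_tr, direction, config.alpha, best)
    raise ValueError(f"unknown family {family!r}; expected one of {FAMILIES}")


def _resolve_xy(scores, outcome, side, timepoint):
    from .disconnectome import ComponentScores
    from .behavior import MotorOutcome

    if isinstance(scores, ComponentScores):
        X = scores.betas
    else:
        X = np.asarray(scores, dtype=float)
    if isinstance(outcome, MotorOutcome):
        y = outcome.score_vector(side, timepoint)
    else:
        y = np.asarray(outcome, dtype=float).ravel()
    if X.shape[0] != y.size:
        raise ValueError("scores and outcome cover different numbers of patients")
    return X, y


def repeated_evaluation(
    scores,
    outcome,
    family: str,
    side: str = "left",
    timepoint: str = "2w",
    n_repeats: int = 1000,
    config: EvalConfig | None = None,
) -> EvalResult:
    """Repeat the split / tune / refit / test cycle and summarise test R².

    Repetition ``r`` uses split seed ``config.base_seed + r``.  Repetitions
    whose test outcomes are constant are recorded as missing (NaN), not
    dropped.  An empty selected model predicts the training mean and scores
    R² = 0 by the constant-prediction rule.  The mode of the R² distribution
    is KDE-based for >= 10 repetitions and the median otherwise.
    """
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    config = config or EvalConfig()
    X, y = _resolve_xy(scores, outcome, side, timepoint)
    n, p = X.shape
    frac = config.train_fraction(family)

    r2_primary = np.empty(n_repeats)
    r2_alt = np.empty(n_repeats)
    hypers: list = []
    coef_abs = np.zeros(p)
    sel_freq = np.zeros(p)
    n_missing = 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for r in range(n_repeats):
            split = split_data(n, frac, config.base_seed + r)
            X_tr, y_tr = X[split.train_indices], y[split.train_indices]
            X_te, y_te = X[split.test_indices], y[split.test_indices]
            fit = _fit_family(X_tr, y_tr, family, config)
            hypers.append(fit.hyperparameter)
            coef_abs += np.abs(fit.coefficients)
            sel_freq += (fit.coefficients != 0) | np.isin(np.arange(p), fit.selected)
            preds = models.predict(fit, X_te)
            if np.std(y_te) == 0:
                r2_primary[r] = np.nan
                r2_alt[r] = np.nan
                n_missing += 1
                continue
            corr_r2 = 0.0 if np.std(preds) == 0 else r_squared(preds, y_te)
            sse_r2 = r_squared_sse(preds, y_te)
            if config.r2_definition == "one_minus_sse":
                r2_primary[r], r2_alt[r] = sse_r2, corr_r2
            else:
                r2_primary[r], r2_alt[r] = corr_r2, sse_r2
    finite = r2_primary[np.isfinite(r2_primary)]
    if finite.size >= 10:
        mode = distribution_mode(finite, config.mode_method, config.mode_grid_points)
    else:
        mode = float(np.median(finite)) if finite.size else float("nan")
    return EvalResult(
        family=family,
        side=side,
        timepoint=timepoint,
        r2_values=r2_primary,
        r2_mode=mode,
        chosen_hyperparameters=hypers,
        coef_abs_mean=coef_abs / n_repeats,
        selection_frequency=sel_freq / n_repeats,
        r2_values_alt=r2_alt,
        n_missing=n_missing,
    )
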