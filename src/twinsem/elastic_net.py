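"""Elastic-net regression by cyclic coordinate descent, with k-fold CV.

The objective, for response y, predictors X, penalty weight ``lam`` and
mixing parameter ``alpha`` (``alpha = 1`` is the LASSO, ``alpha = 0`` ridge):

    sum_i (y_i - b0 - x_i' beta)^2
        + lam * sum_j [ (1 - alpha)/2 * beta_j^2 + alpha * |beta_j| ]

Residual sums of squares are not divided by n, so for a single standardized
predictor with x'x = n the LASSO solution is the soft-threshold of the OLS
coefficient at lam * alpha / (2 n).  Coordinate updates use the covariance
(Gram) form, which makes full (alpha, lambda) paths cheap for p up to a few
hundred.

Cross-validation folds are stratified by family so that relatives never
straddle the train/test split; per alpha the rule reports lambda_min (the
smallest mean CV-MSE) and lambda_1se (the largest lambda within one
standard error of it), and the alpha whose [lambda_min, lambda_1se] window
has the smallest MSE range is preferred.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ENConfig",
    "ENPath",
    "en_objective",
    "fit_en",
    "fit_en_path",
    "cross_validate",
    "select_mediators",
    "kkt_violation",
]


@dataclass
class ENConfig:
    """Grid and convergence settings for the cross-validated elastic net."""

    alpha_grid: np.ndarray = field(default_factory=lambda: np.round(np.arange(0.0, 1.0001, 0.05), 2))
    k_folds: int = 10
    n_lambda: int = 100
    lambda_decades: float = 3.0
    lambda_path: np.ndarray | None = None
    tol: float = 1e-10
    max_sweeps: int = 100_000
    seed: int = 0

    def __post_init__(self) -> None:
        self.alpha_grid = np.asarray(self.alpha_grid, dtype=float)
        if np.any((self.alpha_grid < 0) | (self.alpha_grid > 1)):
            raise ValueError("alpha values must lie in [0, 1]")
        if self.k_folds < 2:
            raise ValueError("k_folds must be >= 2")
        if self.lambda_path is not None:
            lp = np.asarray(self.lambda_path, dtype=float)
            if np.any(lp <= 0) or np.any(np.diff(lp) >= 0):
                raise ValueError("lambda_path must be positive and strictly decreasing")
            self.lambda_path = lp


def en_objective(
    beta: np.ndarray, intercept: float, X: np.ndarray, y: np.ndarray, lam: float, alpha: float
) -> float:
    """Penalized residual sum of squares (the quantity coordinate descent
    minimizes)."""
    if lam < 0:
        raise ValueError("lam must be >= 0")
    beta = np.asarray(beta, dtype=float)
    resid = y - intercept - X @ beta
    rss = float(resid @ resid)
    pen = lam * float(np.sum((1.0 - alpha) / 2.0 * beta**2 + alpha * np.abs(beta)))
    return rss + pen


def _soft(z: float, t: float) -> float:
    if z > t:
        return z - t
    if z < -t:
        return z + t
    return 0.0


def _cd_solve(
    xtx: np.ndarray,
    xty: np.ndarray,
    lam: float,
    alpha: float,
    beta0: np.ndarray,
    tol: float,
    max_sweeps: int,
) -> np.ndarray:
    """Cyclic coordinate descent in the Gram form; warm-started at beta0."""
    p = len(xty)
    beta = beta0.copy()
    denom = np.diag(xtx) + lam * (1.0 - alpha) / 2.0
    thresh = lam * alpha / 2.0
    grad = xty - xtx @ beta  # maintained gradient of RSS/2 wrt beta... (see below)
    for sweep in range(max_sweeps):
        max_delta = 0.0
        for j in range(p):
            rho = grad[j] + xtx[j, j] * beta[j]
            new = _soft(rho, thresh) / denom[j]
            d = new - beta[j]
            if d != 0.0:
                grad -= xtx[:, j] * d
                beta[j] = new
                max_delta = max(max_delta, abs(d))
        if max_delta < tol:
            return beta
    raise RuntimeError(
        f"coordinate descent did not converge in {max_sweeps} sweeps "
        f"(lam={lam:.4g}, alpha={alpha:.3g}, last max update {max_delta:.3g})"
    )


def _lambda_max(xty: np.ndarray, alpha: float) -> float:
    # smallest lam with all coefficients zero; for near-ridge alphas use the
    # glmnet convention of computing it at a small positive alpha
    a = max(alpha, 1e-3)
    return 2.0 * float(np.max(np.abs(xty))) / a


def _auto_lambda(xty: np.ndarray, alpha: float, n_lambda: int, decades: float) -> np.ndarray:
    lmax = _lambda_max(xty, alpha)
    if lmax <= 0:
        lmax = 1.0
    return np.geomspace(lmax, lmax * 10.0 ** (-decades), n_lambda)


def fit_en(
    X: np.ndarray,
    y: np.ndarray,
    lam: float,
    alpha: float,
    beta0: np.ndarray | None = None,
    tol: float = 1e-10,
    max_sweeps: int = 100_000,
) -> tuple[np.ndarray, float]:
    """Single (lam, alpha) fit; returns (beta, intercept)."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.shape[0] != len(y) or X.shape[0] < 2:
        raise ValueError("X and y must agree on n >= 2")
    xm = X.mean(axis=0)
    ym = float(y.mean())
    Xc = X - xm
    yc = y - ym
    xtx = Xc.T @ Xc
    xty = Xc.T @ yc
    b0 = np.zeros(X.shape[1]) if beta0 is None else np.asarray(beta0, dtype=float).copy()
    beta = _cd_solve(xtx, xty, lam, alpha, b0, tol, max_sweeps)
    intercept = ym - float(xm @ beta)
    return beta, intercept


def fit_en_path(
    X: np.ndarray,
    y: np.ndarray,
    alpha: float,
    lambdas: np.ndarray | None = None,
    config: ENConfig | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Coefficient path over a decreasing lambda sequence with warm starts.

    Returns ``(lambdas, betas, intercepts)`` with ``betas`` shaped
    (n_lambda, p).
    """
    config = config or ENConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    xm = X.mean(axis=0)
    ym = float(y.mean())
    Xc = X - xm
    yc = y - ym
    xtx = Xc.T @ Xc
    xty = Xc.T @ yc
    if lambdas is None:
        lambdas = (
            config.lambda_path
            if config.lambda_path is not None
            else _auto_lambda(xty, alpha, config.n_lambda, config.lambda_decades)
        )
    lambdas = np.asarray(lambdas, dtype=float)
    p = X.shape[1]
    betas = np.empty((len(lambdas), p))
    intercepts = np.empty(len(lambdas))
    beta = np.zeros(p)
    for i, lam in enumerate(lambdas):
        beta = _cd_solve(xtx, xty, lam, alpha, beta, config.tol, config.max_sweeps)
        betas[i] = beta
        intercepts[i] = ym - float(xm @ beta)
    return lambdas, betas, intercepts


def kkt_violation(
    X: np.ndarray, y: np.ndarray, beta: np.ndarray, intercept: float, lam: float, alpha: float
) -> float:
    """Largest violation of the subgradient stationarity conditions.

    At a minimizer, for each j: 2 x_j'(y - b0 - X beta) - lam (1-alpha)
    beta_j lies in lam * alpha * [sign(beta_j)] (the interval [-1, 1]
    scaled, when beta_j = 0).
    """
    resid = y - intercept - X @ beta
    g = 2.0 * X.T @ resid - lam * (1.0 - alpha) * beta
    viol = np.where(
        beta != 0.0,
        np.abs(g - lam * alpha * np.sign(beta)),
        np.maximum(np.abs(g) - lam * alpha, 0.0),
    )
    return float(np.max(viol)) if len(viol) else 0.0


@dataclass
class ENPath:
    """Cross-validated elastic-net surface over (alpha, lambda).

    ``coefficients[i]`` holds the full-data path for ``alpha_grid[i]``;
    ``cv_mse``/``cv_mse_se`` the CV error surface; ``lambda_min`` and
    ``lambda_1se`` the per-alpha rule choices; ``best_alpha`` the alpha
    whose [lambda_min, lambda_1se] window spans the smallest MSE range.
    """

    alpha_grid: np.ndarray
    lambdas: list[np.ndarray]
    coefficients: list[np.ndarray]
    intercepts: list[np.ndarray]
    cv_mse: list[np.ndarray]
    cv_mse_se: list[np.ndarray]
    lambda_min: np.ndarray
    lambda_1se: np.ndarray
    predictor_names: list[str]
    best_alpha: float

    def alpha_index(self, alpha: float | None = None) -> int:
        a = self.best_alpha if alpha is None else alpha
        return int(np.argmin(np.abs(self.alpha_grid - a)))

    def to_frame(self):
        import pandas as pd

        rows = []
        for i, a in enumerate(self.alpha_grid):
            for k, lam in enumerate(self.lambdas[i]):
                for j, name in enumerate(self.predictor_names):
                    coef = self.coefficients[i][k, j]
                    if coef != 0.0:
                        rows.append(
                            {"alpha": a, "lambda": lam, "predictor": name, "coefficient": coef}
                        )
        return pd.DataFrame(rows, columns=["alpha", "lambda", "predictor", "coefficient"])

    def summary_dict(self) -> dict:
        i = self.alpha_index()
        return {
            "best_alpha": float(self.best_alpha),
            "lambda_min": float(self.lambda_min[i]),
            "lambda_1se": float(self.lambda_1se[i]),
        }


def _family_folds(
    n: int, k: int, groups: np.ndarray | None, rng: np.random.Generator
) -> np.ndarray:
    """Fold assignment per row; whole families are kept in one fold."""
    if groups is None:
        groups = np.arange(n)
    groups = np.asarray(groups)
    uniq = np.unique(groups)
    perm = rng.permutation(len(uniq))
    fold_of_group = dict(zip(uniq[perm], np.arange(len(uniq)) % k))
    return np.asarray([fold_of_group[g] for g in groups])


def cross_validate(
    X: np.ndarray,
    y: np.ndarray,
    config: ENConfig | None = None,
    groups: np.ndarray | None = None,
    predictor_names: list[str] | None = None,
) -> ENPath:
    """k-fold CV over the alpha grid with an automatic lambda path per alpha."""
    config = config or ENConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if config.k_folds > n:
        raise ValueError("k_folds exceeds the number of observations")
    rng = np.random.default_rng(config.seed)
    folds = _family_folds(n, config.k_folds, groups, rng)
    names = predictor_names or [f"x{j}" for j in range(p)]

    lambdas_out, coefs_out, icpt_out, mse_out, se_out = [], [], [], [], []
    lam_min = np.empty(len(config.alpha_grid))
    lam_1se = np.empty(len(config.alpha_grid))
    for i, alpha in enumerate(config.alpha_grid):
        lams, betas, icpts = fit_en_path(X, y, alpha, config=config)
        fold_mse = np.full((config.k_folds, len(lams)), np.nan)
        for f in range(config.k_folds):
            tr = folds != f
            te = ~tr
            if te.sum() == 0:
                continue
            if np.var(y[tr]) == 0:
                warnings.warn(f"fold {f}: constant training response; fold skipped")
                continue
            _, b_tr, i_tr = fit_en_path(X[tr], y[tr], alpha, lambdas=lams, config=config)
            pred = X[te] @ b_tr.T + i_tr[None, :]
            fold_mse[f] = np.mean((y[te][:, None] - pred) ** 2, axis=0)
        valid = ~np.isnan(fold_mse).all(axis=1)
        mse = np.nanmean(fold_mse[valid], axis=0)
        se = np.nanstd(fold_mse[valid], axis=0, ddof=1) / np.sqrt(valid.sum())
        k_min = int(np.argmin(mse))
        lam_min[i] = lams[k_min]
        within = mse <= mse[k_min] + se[k_min]
        lam_1se[i] = float(np.max(lams[within]))
        lambdas_out.append(lams)
        coefs_out.append(betas)
        icpt_out.append(icpts)
        mse_out.append(mse)
        se_out.append(se)

    # alpha whose [lambda_min, lambda_1se] window has the smallest MSE range
    ranges = np.empty(len(config.alpha_grid))
    mins = np.empty(len(config.alpha_grid))
    for i in range(len(config.alpha_grid)):
        lams, mse = lambdas_out[i], mse_out[i]
        win = (lams >= lam_min[i] - 1e-12) & (lams <= lam_1se[i] + 1e-12)
        ranges[i] = float(mse[win].max() - mse[win].min())
        mins[i] = float(mse.min())
    best = np.lexsort((mins, np.round(ranges, 12)))[0]
    return ENPath(
        alpha_grid=config.alpha_grid,
        lambdas=lambdas_out,
        coefficients=coefs_out,
        intercepts=icpt_out,
        cv_mse=mse_out,
        cv_mse_se=se_out,
        lambda_min=lam_min,
        lambda_1se=lam_1se,
        predictor_names=names,
        best_alpha=float(config.alpha_grid[best]),
    )


def select_mediators(
    path: ENPath,
    max_mse_increase: float | None = None,
    alpha: float | None = None,
    exclude: tuple[str, ...] = (),
) -> list[str]:
    """Predictors with nonzero coefficients in the CV-chosen lambda window,
    ranked by |coefficient| at lambda_min.

    ``max_mse_increase`` (in CV standard errors) caps the window's upper
    lambda; 0 restricts selection to lambda_min, the default (None) uses the
    1-SE rule upper end.
    """
    i = path.alpha_index(alpha)
    lams = path.lambdas[i]
    mse = path.cv_mse[i]
    se = path.cv_mse_se[i]
    k_min = int(np.argmin(mse))
    if max_mse_increase is None:
        upper = path.lambda_1se[i]
    elif max_mse_increase <= 0:
        upper = path.lambda_min[i]
    else:
        within = mse <= mse[k_min] + max_mse_increase * se[k_min]
        upper = float(np.max(lams[within]))
    window = (lams >= path.lambda_min[i] - 1e-12) & (lams <= upper + 1e-12)
    betas = path.coefficients[i]
    nonzero_any = np.any(betas[window] != 0.0, axis=0)
    rank_mag = np.abs(betas[k_min])
    chosen = [
        (path.predictor_names[j], rank_mag[j])
        for j in range(betas.shape[1])
        if nonzero_any[j] and path.predictor_names[j] not in exclude
    ]
    chosen.sort(key=lambda t: -t[1])
    return [name for name, _ in chosen]
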