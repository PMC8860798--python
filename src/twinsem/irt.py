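"""Full-information item factor analysis for binary trauma/symptom items.

A single latent trait theta ~ N(0, 1) drives all items through the
two-parameter logistic (2PL) curve

    P(y_ij = 1 | theta_i) = logistic(disc_j * (theta_i - diff_j)),

where ``diff_j`` (the item difficulty) is the trait location at which the
endorsement probability is exactly one half and ``disc_j`` > 0 is the
discrimination.  Marginal maximum likelihood is obtained with a
Bock-Aitkin EM algorithm over a fixed Gauss-Hermite quadrature grid
(49 points by default).  Discriminations convert to standardized factor
loadings through the logistic scaling constant D = 1.702:

    loading = (disc/D) / sqrt(1 + (disc/D)^2).

The variance explained by the factor is reported as the mean squared
standardized loading.  Sum-score level variables condense the raw item
counts into the ordinal exposure (0-2) and symptom (1-4) scales used by
the downstream SEM; the symptom level is defined only for persons
endorsing at least one exposure item.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

__all__ = [
    "ItemFactorModel",
    "ItemFactorResults",
    "SumScoreRule",
    "build_sum_score_levels",
    "difficulty_location",
    "loading_to_discrimination",
    "discrimination_to_loading",
    "variance_explained",
    "item_response_curve",
]

LOGISTIC_D = 1.702


def loading_to_discrimination(loading: np.ndarray, scale: float = LOGISTIC_D) -> np.ndarray:
    """Standardized loading -> 2PL discrimination (inverse of the
    ``discrimination_to_loading`` map; round-trips to machine precision)."""
    lam = np.asarray(loading, dtype=float)
    if np.any(np.abs(lam) >= 1):
        raise ValueError("standardized loadings must lie in (-1, 1)")
    return scale * lam / np.sqrt(1.0 - lam**2)


def discrimination_to_loading(disc: np.ndarray, scale: float = LOGISTIC_D) -> np.ndarray:
    a = np.asarray(disc, dtype=float) / scale
    return a / np.sqrt(1.0 + a**2)


def item_response_curve(theta: np.ndarray, disc: float, diff: float) -> np.ndarray:
    """2PL endorsement probability; rises asymptotically to one."""
    if disc <= 0:
        raise ValueError("discrimination must be > 0")
    return expit(disc * (np.asarray(theta, dtype=float) - diff))


def difficulty_location(disc: float, diff: float) -> float:
    """Trait value where the endorsement probability is exactly 0.5."""
    if disc <= 0:
        raise ValueError("discrimination must be > 0")
    return float(diff)


def variance_explained(loadings: np.ndarray) -> float:
    """Proportion of item variance carried by the factor: mean squared
    standardized loading."""
    lam = np.asarray(loadings, dtype=float)
    return float(np.mean(lam**2))


def _gh_nodes(n: int) -> tuple[np.ndarray, np.ndarray]:
    """Gauss-Hermite nodes/weights rescaled for a standard-normal prior."""
    x, w = np.polynomial.hermite.hermgauss(n)
    return np.sqrt(2.0) * x, w / np.sqrt(np.pi)


class ItemFactorModel:
    """Single-factor full-information model for a binary item matrix.

    Parameters
    ----------
    items : (n_persons, n_items) array or DataFrame with entries in
        {0, 1, NaN}.
    n_quadrature : number of Gauss-Hermite points.
    """

    def __init__(self, items, n_quadrature: int = 49, scale: float = LOGISTIC_D):
        if isinstance(items, pd.DataFrame):
            self.item_names = list(items.columns)
            y = items.to_numpy(dtype=float)
        else:
            y = np.asarray(items, dtype=float)
            self.item_names = [f"item_{j + 1:02d}" for j in range(y.shape[1])]
        if y.ndim != 2 or y.shape[1] < 2:
            raise ValueError("need a 2-D matrix with at least two items")
        bad = ~(np.isnan(y) | (y == 0) | (y == 1))
        if bad.any():
            raise ValueError("item entries must be 0, 1 or missing")
        obs = ~np.isnan(y)
        self.excluded: list[str] = []
        keep = []
        for j in range(y.shape[1]):
            col = y[obs[:, j], j]
            if len(col) == 0 or col.min() == col.max():
                self.excluded.append(self.item_names[j])
            else:
                keep.append(j)
        if self.excluded:
            warnings.warn(
                f"constant/empty items excluded from the factor model: {self.excluded}"
            )
        if len(keep) < 2:
            raise ValueError("fewer than two non-degenerate items")
        self._keep = keep
        self.item_names = [self.item_names[j] for j in keep]
        self.y = y[:, keep]
        self.obs = obs[:, keep]
        self.scale = scale
        self.nodes, self.weights = _gh_nodes(n_quadrature)

    # -- likelihood pieces --------------------------------------------------

    def _loglik_by_node(self, disc: np.ndarray, diff: np.ndarray) -> np.ndarray:
        """log P(response vector | theta_q), persons x nodes."""
        z = disc[None, :] * (self.nodes[:, None] - diff[None, :])  # nodes x items
        logp = -np.logaddexp(0.0, -z)
        logq = -np.logaddexp(0.0, z)
        y = np.nan_to_num(self.y)
        # persons x nodes: sum over observed items of y log p + (1-y) log q
        return (y * self.obs) @ logp.T + ((1.0 - y) * self.obs) @ logq.T

    def marginal_loglik(self, disc: np.ndarray, diff: np.ndarray) -> float:
        ll = self._loglik_by_node(np.asarray(disc, float), np.asarray(diff, float))
        ll = ll + np.log(self.weights)[None, :]
        m = ll.max(axis=1, keepdims=True)
        return float(np.sum(m.ravel() + np.log(np.sum(np.exp(ll - m), axis=1))))

    # -- EM -----------------------------------------------------------------

    def fit(
        self,
        max_iter: int = 3000,
        tol: float = 1e-5,
        start: tuple[np.ndarray, np.ndarray] | None = None,
    ) -> "ItemFactorResults":
        """Bock-Aitkin EM to marginal-ML estimates.

        Raises on non-convergence, carrying the last iterate in the
        exception arguments.
        """
        n_items = self.y.shape[1]
        if start is not None:
            disc, diff = (np.asarray(v, dtype=float).copy() for v in start)
        else:
            prop = np.nansum(self.y, axis=0) / self.obs.sum(axis=0)
            disc = np.full(n_items, 1.5)
            from scipy.stats import norm

            diff = np.clip(norm.ppf(1.0 - prop) * 1.2, -4.0, 6.0)
        history = []
        prev = -np.inf
        for it in range(max_iter):
            # E-step: posterior weights over quadrature nodes
            ll = self._loglik_by_node(disc, diff) + np.log(self.weights)[None, :]
            m = ll.max(axis=1, keepdims=True)
            post = np.exp(ll - m)
            norm_c = post.sum(axis=1, keepdims=True)
            post /= norm_c
            marg = float(np.sum(m.ravel() + np.log(norm_c.ravel())))
            history.append(marg)
            if marg + 1e-9 < prev:
                raise RuntimeError(
                    f"EM marginal log-likelihood decreased at iteration {it}"
                )
            converged = marg - prev < tol and it > 0
            prev = marg
            if converged:
                break
            # expected counts per node
            y = np.nan_to_num(self.y)
            r = post.T @ (y * self.obs)  # nodes x items: expected endorsements
            n_q = post.T @ self.obs  # nodes x items: expected trials
            # M-step: per-item weighted logistic Newton in (slope, intercept)
            # with step-halving on the expected complete-data log-likelihood,
            # which guarantees EM's monotone ascent
            for j in range(n_items):
                a, d = disc[j], -disc[j] * diff[j]

                def q_val(a_, d_):
                    eta = a_ * self.nodes + d_
                    return float(
                        r[:, j] @ (-np.logaddexp(0.0, -eta))
                        + (n_q[:, j] - r[:, j]) @ (-np.logaddexp(0.0, eta))
                    )

                q_cur = q_val(a, d)
                for _ in range(25):
                    eta = a * self.nodes + d
                    p = expit(eta)
                    w = n_q[:, j] * p * (1.0 - p)
                    g = r[:, j] - n_q[:, j] * p
                    g1 = float(g @ self.nodes)
                    g2 = float(g.sum())
                    h11 = float(w @ self.nodes**2)
                    h12 = float(w @ self.nodes)
                    h22 = float(w.sum())
                    det = h11 * h22 - h12**2
                    if det <= 1e-12:
                        break
                    da = (h22 * g1 - h12 * g2) / det
                    dd = (h11 * g2 - h12 * g1) / det
                    step = 1.0
                    if max(abs(da), abs(dd)) > 2.0:
                        step = 2.0 / max(abs(da), abs(dd))
                    accepted = False
                    for _half in range(20):
                        a_new = min(max(a + step * da, 1e-3), 50.0)
                        d_new = d + step * dd
                        q_new = q_val(a_new, d_new)
                        if q_new >= q_cur - 1e-12:
                            a, d, q_cur = a_new, d_new, q_new
                            accepted = True
                            break
                        step *= 0.5
                    if not accepted or max(abs(da), abs(dd)) < 1e-9:
                        break
                disc[j], diff[j] = a, -d / a
        else:
            raise RuntimeError(
                "EM did not converge", {"disc": disc, "diff": diff, "loglik": history}
            )
        return ItemFactorResults(
            model=self,
            discrimination=disc,
            difficulty=diff,
            loglik=history[-1],
            loglik_history=np.asarray(history),
            n_iter=len(history),
        )


@dataclass
class ItemFactorResults:
    """Marginal-ML item parameters and fit statistics."""

    model: ItemFactorModel
    discrimination: np.ndarray
    difficulty: np.ndarray
    loglik: float
    loglik_history: np.ndarray
    n_iter: int

    @property
    def loadings(self) -> np.ndarray:
        return discrimination_to_loading(self.discrimination, self.model.scale)

    @property
    def variance_explained(self) -> float:
        return variance_explained(self.loadings)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "item": self.model.item_names,
                "loading": self.loadings,
                "discrimination": self.discrimination,
                "difficulty": self.difficulty,
            }
        )

    def summary(self) -> str:
        df = self.to_frame()
        lines = [
            "Single-factor 2PL item model (marginal ML, Gauss-Hermite EM)",
            f"  items: {len(self.model.item_names)}  excluded: {self.model.excluded}",
            f"  log-likelihood: {self.loglik:.3f}  iterations: {self.n_iter}",
            f"  variance explained (mean squared loading): {self.variance_explained:.3f}",
            "",
            df.to_string(index=False, float_format=lambda v: f"{v:.3f}"),
        ]
        return "\n".join(lines)

    def plot_icc(self, ax=None):  # pragma: no cover - convenience plotting
        """Item characteristic curves over the trait scale."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        theta = np.linspace(-4, 6, 300)
        for a, b, name in zip(self.discrimination, self.difficulty, self.model.item_names):
            ax.plot(theta, item_response_curve(theta, a, b), label=name, lw=1)
        ax.set_xlabel("theta (SD units)")
        ax.set_ylabel("P(endorse)")
        return ax


# ---------------------------------------------------------------------------
# ordinal sum-score levels


@dataclass
class SumScoreRule:
    """Binning of raw item counts into ordinal levels.

    ``te_cuts=[1, 2]`` maps counts {0}->0, {1}->1, {>=2}->2;
    ``ptsd_cuts=[2, 3, 4]`` maps counts {<=1}->1, {2}->2, {3}->3, {>=4}->4.
    """

    te_cuts: list[int] = field(default_factory=lambda: [1, 2])
    ptsd_cuts: list[int] = field(default_factory=lambda: [2, 3, 4])


def _bin_counts(counts: np.ndarray, cuts: list[int], base: int) -> np.ndarray:
    levels = np.full(len(counts), float(base))
    for cut in cuts:
        levels = np.where(np.isnan(counts), np.nan, levels + (counts >= cut))
    return levels


def build_sum_score_levels(
    te_items: pd.DataFrame,
    ptsd_items: pd.DataFrame,
    rule: SumScoreRule | None = None,
) -> pd.DataFrame:
    """Raw counts and ordinal levels for the exposure and symptom scales.

    Counts run over non-missing items; a person with every item missing gets
    a missing level, and the symptom level is missing whenever the exposure
    count is zero (symptoms presuppose at least one reported event).
    """
    rule = rule or SumScoreRule()
    te = te_items.to_numpy(dtype=float)
    ptsd = ptsd_items.to_numpy(dtype=float)
    te_obs = ~np.isnan(te)
    ptsd_obs = ~np.isnan(ptsd)
    te_count = np.where(te_obs.any(axis=1), np.nansum(te, axis=1), np.nan)
    ptsd_count = np.where(ptsd_obs.any(axis=1), np.nansum(ptsd, axis=1), np.nan)
    te_level = _bin_counts(te_count, rule.te_cuts, base=0)
    ptsd_level = _bin_counts(ptsd_count, rule.ptsd_cuts, base=1)
    ptsd_level = np.where(np.isnan(te_count) | (te_count == 0), np.nan, ptsd_level)
    return pd.DataFrame(
        {
            "te_count": te_count,
            "ptsd_count": ptsd_count,
            "te_level": te_level,
            "ptsdsx_level": ptsd_level,
        },
        index=te_items.index,
    )
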