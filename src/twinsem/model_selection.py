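"""Model comparison (likelihood-ratio tests, AIC) and the eigenvalue-based
effective number of independent tests.

AIC follows the degrees-of-freedom convention ``AIC = -2lnL - 2*df`` with
``df`` counted as observed data points minus estimated parameters, so a
*larger* df (fewer parameters) lowers AIC at equal likelihood.  The
effective number of tests uses the Li & Ji (2005) eigenvalue construction,
which maps a p x p correlation matrix onto a value in [1, p].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "ComparisonRow",
    "aic_from_df",
    "likelihood_ratio_test",
    "effective_tests",
    "adjusted_alpha",
    "select_model",
    "comparison_table",
]


@dataclass
class ComparisonRow:
    """One line of a model-comparison table."""

    base: str
    comparison: str | None
    ep: int
    minus2ll: float
    df: int
    aic: float
    diff_ll: float | None = None
    diff_df: int | None = None
    p: float | None = None

    def __post_init__(self) -> None:
        if self.p is not None and not (0.0 <= self.p <= 1.0):
            raise ValueError(f"p must be in [0, 1], got {self.p}")


def aic_from_df(minus2ll: float, df: int) -> float:
    """AIC under the observed-statistics df convention: -2lnL - 2*df."""
    if df < 0:
        raise ValueError(f"df must be >= 0, got {df}")
    return minus2ll - 2.0 * df


def likelihood_ratio_test(base, nested, base_name: str = "base",
                          nested_name: str = "nested", tol: float = 1e-6) -> ComparisonRow:
    """Chi-square LRT of a nested model against the base (fuller) model.

    ``base`` and ``nested`` expose ``minus2ll``, ``ep`` and ``df`` (any fit
    result object does).  Raises if the nested fit beats the base by more
    than ``tol`` — a sign of non-nesting or a failed base fit.
    """
    diff_ll = nested.minus2ll - base.minus2ll
    diff_df = base.ep - nested.ep
    if diff_ll < -tol:
        raise ValueError(
            f"nested model fits better than base by {-diff_ll:.4g}; "
            "models are not nested or the base fit failed"
        )
    diff_ll = max(diff_ll, 0.0)
    if diff_df <= 0:
        raise ValueError("nested model must free fewer parameters than the base")
    p = float(stats.chi2.sf(diff_ll, diff_df))
    return ComparisonRow(
        base=base_name,
        comparison=nested_name,
        ep=nested.ep,
        minus2ll=nested.minus2ll,
        df=nested.df,
        aic=aic_from_df(nested.minus2ll, nested.df),
        diff_ll=diff_ll,
        diff_df=diff_df,
        p=p,
    )


def effective_tests(corr: np.ndarray, tol: float = 1e-8) -> float:
    """Effective number of independent tests from a correlation matrix.

    Li-Ji construction over the eigenvalues lambda_i:
    ``Meff = sum_i [ I(lambda_i >= 1) + (lambda_i - floor(lambda_i)) ]``.
    Equals p for the identity matrix and 1 under perfect correlation.
    """
    corr = np.asarray(corr, dtype=float)
    if corr.ndim != 2 or corr.shape[0] != corr.shape[1]:
        raise ValueError("correlation matrix must be square")
    if not np.allclose(corr, corr.T, atol=1e-10):
        raise ValueError("correlation matrix must be symmetric")
    eig = np.linalg.eigvalsh(corr)
    if eig.min() < -tol:
        raise ValueError(f"correlation matrix has eigenvalue {eig.min():.3g} < 0")
    eig = np.clip(eig, 0.0, None)
    # the floor is discontinuous at integers; snap eigenvalues that are
    # integer up to numerical precision before splitting them
    eig = np.round(eig, 10)
    return float(np.sum((eig >= 1.0).astype(float) + (eig - np.floor(eig))))


def adjusted_alpha(alpha: float, corr: np.ndarray) -> float:
    """Per-test significance level alpha / Meff for correlated outcomes."""
    return alpha / effective_tests(corr)


def select_model(rows: list[ComparisonRow], alpha_level: float = 0.05) -> str:
    """Choose among compared models: of those not significantly worse than
    the best-fitting one, take the smallest AIC (ties -> fewest ep).

    ``rows`` must contain one row without a ``comparison`` (the base model's
    own statistics) plus one row per nested comparison.
    """
    if not rows:
        raise ValueError("no comparison rows supplied")
    candidates = []
    for row in rows:
        name = row.comparison if row.comparison is not None else row.base
        acceptable = row.p is None or row.p > alpha_level
        if acceptable:
            candidates.append((row.aic, row.ep, name))
    if not candidates:
        raise ValueError("no acceptable model: every nested fit is significantly worse")
    candidates.sort()
    return candidates[0][2]


def comparison_table(rows: list[ComparisonRow]):
    """Rows as a DataFrame in the conventional comparison layout."""
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "base": r.base,
                "comparison": r.comparison,
                "ep": r.ep,
                "minus2LL": r.minus2ll,
                "df": r.df,
                "AIC": r.aic,
                "diffLL": r.diff_ll,
                "diffdf": r.diff_df,
                "p": r.p,
            }
            for r in rows
        ]
    )
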