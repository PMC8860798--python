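"""Masking, conditional missingness, residualization and standardization.

The fixed pipeline order is: conditional symptom-score missingness -> MRI
quality-control mask -> covariate residualization + standardization ->
outlier mask.  Rows are never dropped — masking only introduces cell-level
missingness — and every action is appended to a machine-readable
provenance log.

Conventions adopted where the source rules are ambiguous: "surpassing
±4 SD" is a strict inequality, and the SD used for the outlier rule is
that of the residualized column before masking.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "AnalysisTable",
    "PreprocessConfig",
    "apply_qc_mask",
    "residualize_standardize",
    "mask_outliers",
    "conditional_ptsdsx_missing",
    "rank_inverse_normal",
    "run_preprocess",
]

QC_THRESHOLD = 600.0
OUTLIER_SD = 4.0
SKEW_WARN = 2.0
KURT_WARN = 7.0


@dataclass
class PreprocessConfig:
    qc_threshold: float = QC_THRESHOLD
    outlier_sd: float = OUTLIER_SD
    score_covariates: tuple[str, ...] = ("age", "sex", "ancestry")
    roi_extra_covariates: tuple[str, ...] = ("scanner",)
    subcortical_total: str = "total_subcortical_volume"
    cortical_total: str = "total_cortical_volume"
    normalize_scores: bool = False  # optional rank-based inverse-normal transform


@dataclass
class AnalysisTable:
    """Processed table plus the audit trail of masking actions."""

    data: pd.DataFrame
    provenance: list[dict] = field(default_factory=list)

    def log(self, action: str, **info) -> None:
        self.provenance.append({"action": action, **info})

    def warnings(self) -> list[dict]:
        return [p for p in self.provenance if p.get("level") == "warning"]


def conditional_ptsdsx_missing(
    table: AnalysisTable, te_count_col: str = "te_count", targets: tuple[str, ...] = ("ptsdsx_level",)
) -> AnalysisTable:
    """Symptom variables are undefined for persons reporting zero events:
    set them missing where the exposure count is 0 (other data retained)."""
    df = table.data
    zero = df[te_count_col].to_numpy(dtype=float) == 0
    for col in targets:
        if col in df.columns:
            n_masked = int((zero & df[col].notna()).sum())
            df.loc[zero, col] = np.nan
            table.log("conditional_ptsdsx_missing", column=col, n_masked=n_masked)
    return table


def apply_qc_mask(
    table: AnalysisTable,
    roi_cols: list[str],
    qc_col: str = "qc_score",
    threshold: float = QC_THRESHOLD,
) -> AnalysisTable:
    """Set every ROI cell missing for subjects with qc_score strictly below
    the threshold; non-imaging measures of those subjects are retained."""
    df = table.data
    fail = df[qc_col].to_numpy(dtype=float) < threshold
    for col in roi_cols:
        df.loc[fail, col] = np.nan
    table.log("qc_mask", threshold=threshold, n_subjects_masked=int(fail.sum()),
              n_columns=len(roi_cols))
    return table


def _design_matrix(covariates: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    parts = [pd.Series(1.0, index=covariates.index, name="intercept")]
    for col in covariates.columns:
        s = covariates[col]
        if s.dtype == object or isinstance(s.dtype, pd.CategoricalDtype):
            dummies = pd.get_dummies(s, prefix=col, drop_first=True, dtype=float)
            parts.append(dummies)
        else:
            parts.append(s.astype(float))
    X = pd.concat(parts, axis=1)
    return X.to_numpy(dtype=float), list(X.columns)


def residualize_standardize(y: pd.Series, covariates: pd.DataFrame) -> pd.Series:
    """OLS residuals of y on the covariate design, scaled to unit SD.

    The regression is fitted on rows where y and all covariates are
    observed; residuals are produced for every row with complete
    covariates, so missing y propagates.  A rank-deficient design raises an
    error naming the aliased column.
    """
    X, names = _design_matrix(covariates)
    yv = y.to_numpy(dtype=float)
    cov_ok = np.all(np.isfinite(X), axis=1)
    fit_rows = cov_ok & np.isfinite(yv)
    if fit_rows.sum() <= X.shape[1]:
        raise ValueError("too few complete cases to fit the covariate regression")
    Xf = X[fit_rows]
    # detect aliased columns via the QR diagonal
    _, r = np.linalg.qr(Xf)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(Xf.shape) * np.finfo(float).eps * 100
    if np.any(diag < tol):
        bad = [names[j] for j in np.flatnonzero(diag < tol)]
        raise ValueError(f"rank-deficient covariate design; aliased column(s): {bad}")
    beta, *_ = np.linalg.lstsq(Xf, yv[fit_rows], rcond=None)
    resid = np.full(len(yv), np.nan)
    rows = cov_ok & np.isfinite(yv)
    resid[rows] = yv[rows] - X[rows] @ beta
    sd = np.nanstd(resid, ddof=0)
    if not sd > 0:
        raise ValueError("residuals have zero variance; cannot standardize")
    resid = (resid - np.nanmean(resid)) / sd
    return pd.Series(resid, index=y.index, name=y.name)


def mask_outliers(column: pd.Series, limit: float = OUTLIER_SD) -> pd.Series:
    """Datapoints strictly surpassing ±limit SD become missing.

    The column is taken as already standardized (the pipeline applies this
    immediately after residualization), so its values are the z scores; not
    recomputing the SD here keeps a second application from masking further
    points.
    """
    z = column.to_numpy(dtype=float)
    out = np.abs(z) > limit
    res = column.copy()
    res[out] = np.nan
    return res


def rank_inverse_normal(column: pd.Series, offset: float = 3.0 / 8.0) -> pd.Series:
    """Blom-type rank-based inverse-normal transform (sensitivity option)."""
    v = column.to_numpy(dtype=float)
    out = np.full(len(v), np.nan)
    obs = np.isfinite(v)
    n = obs.sum()
    ranks = stats.rankdata(v[obs])
    out[obs] = stats.norm.ppf((ranks - offset) / (n - 2 * offset + 1))
    return pd.Series(out, index=column.index, name=column.name)


def _moment_checks(table: AnalysisTable, cols: list[str]) -> None:
    for col in cols:
        v = table.data[col].dropna().to_numpy()
        if len(v) < 8:
            continue
        sk = float(stats.skew(v))
        ku = float(stats.kurtosis(v))
        entry = {"column": col, "skewness": sk, "kurtosis": ku}
        if abs(sk) > SKEW_WARN or abs(ku) > KURT_WARN:
            entry["level"] = "warning"
        table.log("moments", **entry)


def run_preprocess(
    cohort: pd.DataFrame,
    score_cols: tuple[str, str] = ("te_level", "ptsdsx_level"),
    te_count_col: str = "te_count",
    config: PreprocessConfig | None = None,
) -> AnalysisTable:
    """Full preprocessing chain on a cohort table carrying sum-score levels.

    Produces standardized quasi-continuous ``te_score``/``ptsdsx_score``
    columns and standardized ``roi_*`` residual columns.  Idempotent up to
    numerical tolerance when re-applied to its own output.
    """
    config = config or PreprocessConfig()
    df = cohort.copy()
    table = AnalysisTable(data=df)
    roi_cols = [c for c in df.columns if c.startswith("roi_")]

    conditional_ptsdsx_missing(table, te_count_col=te_count_col, targets=(score_cols[1],))
    if "qc_score" in df.columns and roi_cols:
        apply_qc_mask(table, roi_cols, threshold=config.qc_threshold)

    score_covs = [c for c in config.score_covariates if c in df.columns]
    te_raw, ptsd_raw = score_cols
    df["te_score"] = residualize_standardize(df[te_raw], df[score_covs])
    df["ptsdsx_score"] = residualize_standardize(df[ptsd_raw], df[score_covs])
    table.log("residualize_standardize", columns=["te_score", "ptsdsx_score"],
              covariates=score_covs)

    roi_covs = score_covs + [c for c in config.roi_extra_covariates if c in df.columns]
    for col in roi_cols:
        covs = list(roi_covs)
        # total-volume adjustment: subcortical ROIs use the subcortical
        # total, cortical ROIs the cortical total (name-prefix convention)
        total = (
            config.cortical_total
            if col.startswith("roi_cortical") or col.startswith("roi_c_")
            else config.subcortical_total
        )
        if total in df.columns:
            covs.append(total)
        df[col] = residualize_standardize(df[col], df[covs])
    if roi_cols:
        table.log("residualize_standardize", columns=roi_cols, covariates=roi_covs)

    for col in ["te_score", "ptsdsx_score", *roi_cols]:
        before = int(df[col].notna().sum())
        df[col] = mask_outliers(df[col], limit=config.outlier_sd)
        masked = before - int(df[col].notna().sum())
        if masked:
            table.log("outlier_mask", column=col, limit=config.outlier_sd, n_masked=masked)

    if config.normalize_scores:
        df["te_score"] = rank_inverse_normal(df["te_score"])
        df["ptsdsx_score"] = rank_inverse_normal(df["ptsdsx_score"])
        table.log("rank_inverse_normal", columns=["te_score", "ptsdsx_score"])

    _moment_checks(table, ["te_score", "ptsdsx_score"])
    table.data = df
    return table
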