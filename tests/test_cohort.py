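"""Generator: pedigree/site sharing, 2PL items, determinism, MC oracle."""

import numpy as np
import pandas as pd
import pytest

from twinsem import (
    CohortSpec,
    TruthRecord,
    generate_cohort,
    generate_item_responses,
    inject_missingness_and_outliers,
    monte_carlo_implied_cov,
)
from twinsem.cohort import CohortTable, calibrate_zero_rate, default_te_item_params
from twinsem.components import VarianceComponents as VC


def _univariate_truth(va, vc, ve, vs):
    return TruthRecord(
        components={"te": VC(va, vc, ve, vs) if ve > 0 else VC(va, vc, 1e-9, vs),
                    "ptsdsx": VC(0.3, 0.3, 0.4, 0.0)},
        c=0.0,
    )


def _pair_corr(df, col, relation):
    sub = df[df.relation == relation].sort_values("family_id", kind="mergesort")
    arr = sub[col].to_numpy().reshape(-1, 2)
    return np.corrcoef(arr[:, 0], arr[:, 1])[0, 1], np.cov(arr[:, 0], arr[:, 1])[0, 1]


def test_mz_cross_twin_correlation_is_one_in_all_genetic_case():
    truth = _univariate_truth(1.0, 0.0, 0.0, 0.0)
    spec = CohortSpec(n_mz_pairs=1000, n_dz_pairs=0, n_sib_pairs=0, n_singletons=0,
                      generate_items=False, seed=1)
    table, _ = generate_cohort(spec, truth)
    r, _ = _pair_corr(table.data, "te_score_true", "MZ")
    assert r > 0.999


def test_dz_cross_twin_covariance_matches_half_va_plus_vc():
    # closed form: cov(DZ twins) = 0.5*VA + VC = 0.55
    truth = _univariate_truth(0.5, 0.3, 0.2, 0.0)
    spec = CohortSpec(n_mz_pairs=0, n_dz_pairs=5000, n_sib_pairs=0, n_singletons=0,
                      generate_items=False, seed=2)
    table, _ = generate_cohort(spec, truth)
    _, cov = _pair_corr(table.data, "te_score_true", "DZ")
    # 3 Monte-Carlo SEs for a covariance of bivariate normals
    se = np.sqrt((1.0 + 0.55**2) / 5000)
    assert abs(cov - 0.55) < 3 * se


def test_mz_minus_dz_cross_covariance_approximates_half_va():
    truth = _univariate_truth(0.6, 0.2, 0.2, 0.0)
    spec = CohortSpec(n_mz_pairs=4000, n_dz_pairs=4000, n_sib_pairs=0, n_singletons=0,
                      generate_items=False, seed=3)
    table, _ = generate_cohort(spec, truth)
    _, cov_mz = _pair_corr(table.data, "te_score_true", "MZ")
    _, cov_dz = _pair_corr(table.data, "te_score_true", "DZ")
    se = np.sqrt(2 * (1.0 + 0.8**2) / 4000)
    assert abs((cov_mz - cov_dz) - 0.3) < 3 * se


def test_null_paths_give_null_exposure_outcome_correlation():
    truth = TruthRecord(
        components={"te": VC(0.3, 0.3, 0.4, 0.0), "m": VC(0.3, 0.3, 0.4, 0.0),
                    "ptsdsx": VC(0.3, 0.3, 0.4, 0.0)},
        a={"m": 0.0}, b={"m": 0.0}, c=0.0,
    )
    spec = CohortSpec(n_mz_pairs=0, n_dz_pairs=0, n_sib_pairs=0, n_singletons=20000,
                      generate_items=False, seed=4)
    table, _ = generate_cohort(spec, truth)
    r = np.corrcoef(table.data.te_score_true, table.data.ptsdsx_score_true)[0, 1]
    assert abs(r) < 3.5 / np.sqrt(20000)


def test_standardized_phenotypes_have_unit_variance(mediation_truth):
    spec = CohortSpec(n_mz_pairs=1000, n_dz_pairs=1000, n_sib_pairs=0, n_singletons=3000,
                      generate_items=False, seed=5)
    table, _ = generate_cohort(spec, mediation_truth)
    for col in ("te_score_true", "roi_wm", "ptsdsx_score_true"):
        assert abs(table.data[col].var() - 1.0) < 0.07


def test_same_seed_reproduces_table_bit_identically(mediation_truth):
    spec = CohortSpec(n_mz_pairs=50, n_dz_pairs=50, n_sib_pairs=20, n_singletons=100, seed=9)
    t1, _ = generate_cohort(spec, mediation_truth)
    t2, _ = generate_cohort(spec, mediation_truth)
    pd.testing.assert_frame_equal(t1.data, t2.data)


def test_twins_share_family_and_site(small_cohort):
    _, table, _ = small_cohort
    df = table.data
    twins = df[df.relation.isin(["MZ", "DZ"])]
    for _, fam in twins.groupby("family_id"):
        assert len(fam) == 2
        assert fam.site_id.nunique() == 1
        assert fam.relation.nunique() == 1


def test_invalid_spec_names_offending_field():
    with pytest.raises(ValueError, match="n_mz_pairs"):
        CohortSpec(n_mz_pairs=-1)
    with pytest.raises(ValueError, match="qc_fail_rate"):
        CohortSpec(qc_fail_rate=1.5)
    with pytest.raises(ValueError, match="at least one family"):
        CohortSpec(n_mz_pairs=0, n_dz_pairs=0, n_sib_pairs=0, n_singletons=0)


# -- items ------------------------------------------------------------------


def test_endorsement_is_half_at_theta_equal_difficulty():
    rng = np.random.default_rng(0)
    params = np.array([[1.3, 1.7]])
    theta = np.full(200000, 1.7)
    items = generate_item_responses(theta, params, rng)
    assert abs(items.mean() - 0.5) < 0.005


def test_high_discrimination_below_difficulty_gives_no_endorsement():
    rng = np.random.default_rng(0)
    params = np.array([[60.0, 1.0]])
    items = generate_item_responses(np.full(5000, 0.5), params, rng)
    assert items.mean() < 1e-3


def test_nonpositive_discrimination_rejected():
    with pytest.raises(ValueError):
        generate_item_responses(np.zeros(5), np.array([[0.0, 1.0]]), np.random.default_rng(0))


def test_zero_te_calibration_hits_target_rate(small_cohort):
    # spec sets the observed zero-exposure fraction near 62%
    _, table, truth = small_cohort
    te_cols = [c for c in table.data.columns if c.startswith("te_item_")]
    zero_frac = (table.data[te_cols].sum(axis=1) == 0).mean()
    assert abs(zero_frac - 0.6195) < 0.03
    # most difficulties remain extreme after calibration
    assert (truth.te_item_params[:, 1] >= 2.0).sum() >= 13


def test_calibrate_zero_rate_is_exact_in_expectation():
    rng = np.random.default_rng(1)
    theta = rng.standard_normal(50000)
    shifted = calibrate_zero_rate(theta, default_te_item_params(), 0.6195)
    p = 1.0 / (1.0 + np.exp(-shifted[:, 0] * (theta[:, None] - shifted[:, 1])))
    assert abs(np.prod(1 - p, axis=1).mean() - 0.6195) < 1e-4


# -- missingness / outliers --------------------------------------------------


def test_qc_injection_matches_rate(small_cohort):
    spec, table, _ = small_cohort
    out = inject_missingness_and_outliers(table, spec)
    frac = (out.data.qc_score < 600).mean()
    n = len(out.data)
    assert abs(frac - spec.qc_fail_rate) < 3 * np.sqrt(0.068 * 0.932 / n)


def test_zero_rates_leave_table_clean(small_cohort):
    spec, table, _ = small_cohort
    import dataclasses

    clean_spec = dataclasses.replace(spec, qc_fail_rate=0.0, outlier_rate=0.0)
    out = inject_missingness_and_outliers(table, clean_spec)
    assert (out.data.qc_score >= 600).all()
    roi = [c for c in table.data.columns if c.startswith("roi_")]
    pd.testing.assert_frame_equal(out.data[roi], table.data[roi])


def test_outliers_exceed_four_sd(small_cohort):
    spec, table, _ = small_cohort
    import dataclasses

    spiked = dataclasses.replace(spec, outlier_rate=0.05)
    out = inject_missingness_and_outliers(table, spiked)
    col = out.data["roi_wm"]
    z = (col - table.data["roi_wm"].mean()) / table.data["roi_wm"].std(ddof=0)
    assert (np.abs(z) > 4).sum() > 0


# -- round trip ---------------------------------------------------------------


def test_table_roundtrip_preserves_truth(tmp_path, small_cohort):
    _, table, truth = small_cohort
    path = tmp_path / "cohort.tsv"
    table.write(path)
    back = CohortTable.read(path)
    assert back.seed == table.seed
    assert back.truth.c == truth.c
    assert back.truth.components["te"].var_a == truth.components["te"].var_a
    pd.testing.assert_frame_equal(
        back.data, table.data, check_exact=False, rtol=1e-12
    )


# -- Monte-Carlo oracle --------------------------------------------------------


def test_mc_cov_univariate_closed_forms():
    truth = _univariate_truth(0.5, 0.3, 0.2, 0.0)
    mc = monte_carlo_implied_cov(truth, "MZ", n_replicates=200000, seed=0)
    assert abs(mc[0, 2] - 0.8) < 0.01  # VA + VC
    truth_s = TruthRecord(
        components={"te": VC(0.3, 0.3, 0.3, 0.1), "ptsdsx": VC(0.3, 0.3, 0.4, 0.0)}, c=0.0
    )
    mc2 = monte_carlo_implied_cov(truth_s, "UNRELATED_SAME_SITE", n_replicates=200000, seed=1)
    assert abs(mc2[0, 2] - 0.1) < 0.01  # VS only
    truth_e = _univariate_truth(0.0, 0.0, 1.0, 0.0)
    mc3 = monte_carlo_implied_cov(truth_e, "MZ", n_replicates=100000, seed=2)
    assert abs(mc3[0, 2]) < 0.015


def test_mc_cov_rejects_bad_inputs():
    truth = _univariate_truth(0.5, 0.3, 0.2, 0.0)
    with pytest.raises(ValueError, match="pair_type"):
        monte_carlo_implied_cov(truth, "COUSIN", n_replicates=2000)
    with pytest.raises(ValueError, match="n_replicates"):
        monte_carlo_implied_cov(truth, "MZ", n_replicates=10)
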