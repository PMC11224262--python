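import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from semcoh.stats import (
    CoherenceModel,
    posthoc_power_two_group,
    studentized_range_crit,
    studentized_range_sf,
    tukey_adjusted_p,
    two_sample_t,
)

from conftest import random_design


# ---------------------------------------------------------------------------
# two-sample t-test


def test_identical_samples_null_result():
    r = two_sample_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
    assert r.t == pytest.approx(0.0)
    assert r.p == pytest.approx(1.0)
    assert r.d == pytest.approx(0.0)


def test_unit_shift_gives_unit_cohens_d():
    r = two_sample_t([1.0, 2.0, 3.0], [2.0, 3.0, 4.0])
    assert abs(r.d) == pytest.approx(1.0)  # pooled SD is exactly 1
    assert r.mean_diff == pytest.approx(-1.0)
    assert np.sign(r.d) == np.sign(r.mean_diff)


def test_welch_matches_formula_and_scipy_oracle():
    rng = np.random.default_rng(1)
    for _ in range(30):
        x = rng.normal(0, 1, int(rng.integers(5, 40)))
        y = rng.normal(0.3, 2, int(rng.integers(5, 40)))
        r = two_sample_t(x, y)
        # brute-force Welch formulas
        a, b = x.var(ddof=1) / len(x), y.var(ddof=1) / len(y)
        t_o = (x.mean() - y.mean()) / np.sqrt(a + b)
        df_o = (a + b) ** 2 / (a**2 / (len(x) - 1) + b**2 / (len(y) - 1))
        assert r.t == pytest.approx(t_o, abs=1e-10)
        assert r.df == pytest.approx(df_o, abs=1e-10)
        ref = sps.ttest_ind(x, y, equal_var=False)
        assert r.t == pytest.approx(ref.statistic, abs=1e-10)
        assert r.p == pytest.approx(ref.pvalue, abs=1e-10)


def test_pooled_variant_matches_scipy():
    rng = np.random.default_rng(2)
    x, y = rng.normal(size=12), rng.normal(size=20)
    r = two_sample_t(x, y, equal_var=True)
    ref = sps.ttest_ind(x, y, equal_var=True)
    assert r.t == pytest.approx(ref.statistic, abs=1e-12)
    assert r.p == pytest.approx(ref.pvalue, abs=1e-12)
    assert r.df == len(x) + len(y) - 2


def test_zero_variance_both_samples_rejected():
    with pytest.raises(ValueError):
        two_sample_t([1.0, 1.0], [2.0, 2.0])


def test_ci_contains_point_estimate():
    rng = np.random.default_rng(3)
    r = two_sample_t(rng.normal(size=30), rng.normal(1, 1, 25))
    assert r.ci_low <= r.mean_diff <= r.ci_high
    assert r.d_ci_low <= r.d <= r.d_ci_high


# ---------------------------------------------------------------------------
# studentized range


@pytest.mark.parametrize("q,k,df", [(3.5, 3, 10), (3.0, 5, 30), (4.2, 4, 2494),
                                    (2.0, 3, 5), (5.5, 10, 60), (1.0, 7, 15)])
def test_studentized_range_matches_scipy(q, k, df):
    assert studentized_range_sf(q, k, df) == pytest.approx(
        sps.studentized_range.sf(q, k, df), abs=1e-6
    )


def test_studentized_range_infinite_df_limit():
    # large df converges to the normal-range distribution
    assert studentized_range_sf(3.3, 4, np.inf) == pytest.approx(
        studentized_range_sf(3.3, 4, 1e6), abs=1e-4
    )


def test_critical_value_against_monte_carlo_max_range():
    # q_crit(alpha=.05, k=3, large df) vs brute-force range of 3 normals
    rng = np.random.default_rng(5)
    z = rng.standard_normal((10**6, 3))
    ranges = z.max(axis=1) - z.min(axis=1)
    mc = np.quantile(ranges, 0.95)
    assert studentized_range_crit(0.05, 3, 1e9) == pytest.approx(mc, abs=0.01)


def test_tukey_k2_reduces_to_unadjusted_t():
    for t, df in [(1.3, 11), (2.7, 200), (0.4, 2494)]:
        assert tukey_adjusted_p(t, 2, df) == pytest.approx(
            2 * sps.t.sf(abs(t), df), abs=1e-14
        )


def test_tukey_adjustment_never_below_unadjusted_for_k3():
    for t in (0.5, 1.5, 2.2, 3.0):
        for k in (3, 5, 8):
            assert tukey_adjusted_p(t, k, 100) >= 2 * sps.t.sf(t, 100) - 1e-12


def test_studentized_range_input_validation():
    with pytest.raises(ValueError):
        studentized_range_sf(3.0, 1, 10)
    assert studentized_range_sf(-1.0, 3, 10) == 1.0


# ---------------------------------------------------------------------------
# OLS model


def _oracle_fit(X, y):
    """Normal-equations oracle: pinv-based coefficients and covariance."""
    xtx_inv = np.linalg.inv(X.T @ X)
    beta = xtx_inv @ X.T @ y
    resid = y - X @ beta
    df = X.shape[0] - X.shape[1]
    sigma2 = resid @ resid / df
    return beta, sigma2 * xtx_inv, sigma2, df


def test_exact_linear_response_recovered():
    rng = np.random.default_rng(6)
    df, cov_names = random_design(rng, n=80, k=2)
    df["coherence"] = 3.0 + 2.5 * df["x0"]  # exactly linear, no noise
    res = CoherenceModel.from_dataframe(df, covariates=cov_names).fit()
    assert res.params["x0"] == pytest.approx(2.5, abs=1e-10)
    assert res.rsquared_adj == pytest.approx(1.0, abs=1e-10)


def test_intercept_only_model_recovers_sample_mean():
    y = np.array([1.0, 2.0, 4.0, 9.0])
    m = CoherenceModel(y=y, groups=["g"] * 4, covariates=np.empty((4, 0)),
                       covariate_names=[])
    res = m.fit()
    assert res.params["Intercept"] == pytest.approx(y.mean(), abs=1e-12)


def test_fit_matches_normal_equations_oracle():
    rng = np.random.default_rng(7)
    df, cov_names = random_design(rng, n=200, k=3)
    model = CoherenceModel.from_dataframe(df, covariates=cov_names)
    res = model.fit()
    beta_o, cov_o, sigma2_o, df_o = _oracle_fit(model.X, model.y)
    np.testing.assert_allclose(res.params.to_numpy(), beta_o, atol=1e-9)
    np.testing.assert_allclose(res.cov_params.to_numpy(), cov_o, atol=1e-9)
    assert res.sigma2 == pytest.approx(sigma2_o, abs=1e-12)
    assert res.df_resid == df_o


def test_fit_matches_statsmodels():
    import statsmodels.api as sm

    rng = np.random.default_rng(8)
    df, cov_names = random_design(rng, n=150, k=4)
    model = CoherenceModel.from_dataframe(df, covariates=cov_names)
    res = model.fit()
    ref = sm.OLS(model.y, model.X).fit()
    np.testing.assert_allclose(res.params.to_numpy(), ref.params, atol=1e-10)
    np.testing.assert_allclose(res.bse.to_numpy(), ref.bse, atol=1e-10)
    np.testing.assert_allclose(res.pvalues.to_numpy(), ref.pvalues, atol=1e-10)
    assert res.rsquared_adj == pytest.approx(ref.rsquared_adj, abs=1e-12)


def test_adjusted_r2_not_above_r2():
    rng = np.random.default_rng(9)
    df, cov_names = random_design(rng)
    res = CoherenceModel.from_dataframe(df, covariates=cov_names).fit()
    assert res.rsquared_adj <= res.rsquared


def test_partial_eta_sq_identity_and_range():
    rng = np.random.default_rng(10)
    df, cov_names = random_design(rng)
    res = CoherenceModel.from_dataframe(df, covariates=cov_names).fit()
    eta = res.partial_eta_sq
    assert ((eta >= 0) & (eta <= 1)).all()
    t2 = res.tvalues**2
    np.testing.assert_allclose(eta, t2 / (t2 + res.df_resid), atol=1e-14)


def test_rank_deficiency_names_offending_column():
    rng = np.random.default_rng(11)
    df, cov_names = random_design(rng, n=100, k=2)
    df["x1"] = df["x0"]  # perfectly collinear
    with pytest.raises(ValueError, match="x1"):
        CoherenceModel.from_dataframe(df, covariates=cov_names).fit()


def test_reference_group_choice_changes_coding_not_fit():
    rng = np.random.default_rng(12)
    df, cov_names = random_design(rng, n=120, k=3)
    r1 = CoherenceModel.from_dataframe(df, covariates=cov_names, reference_group="g0").fit()
    r2 = CoherenceModel.from_dataframe(df, covariates=cov_names, reference_group="g2").fit()
    assert r1.rsquared == pytest.approx(r2.rsquared, abs=1e-12)
    pd.testing.assert_frame_equal(r1.emmeans(), r2.emmeans(), atol=1e-10)


# ---------------------------------------------------------------------------
# estimated marginal means + Tukey contrasts


def test_emms_reduce_to_cell_means_without_covariates():
    y = np.array([1.0, 2.0, 3.0, 5.0, 6.0, 7.0])
    groups = ["a", "a", "a", "b", "b", "b"]
    res = CoherenceModel(y, groups, np.empty((6, 0)), []).fit()
    em = res.emmeans().set_index("group")["emmean"]
    assert em["a"] == pytest.approx(2.0, abs=1e-12)
    assert em["b"] == pytest.approx(6.0, abs=1e-12)


def test_emms_invariant_to_covariate_location_shift():
    rng = np.random.default_rng(13)
    df, cov_names = random_design(rng, n=150, k=3)
    res1 = CoherenceModel.from_dataframe(df, covariates=cov_names).fit()
    shifted = df.copy()
    shifted[cov_names] = shifted[cov_names] + 17.5
    res2 = CoherenceModel.from_dataframe(shifted, covariates=cov_names).fit()
    pd.testing.assert_frame_equal(res1.emmeans(), res2.emmeans(), atol=1e-8)


def test_emm_and_contrast_match_quadratic_form_oracle():
    rng = np.random.default_rng(14)
    for _ in range(20):
        df, cov_names = random_design(rng)
        model = CoherenceModel.from_dataframe(df, covariates=cov_names)
        res = model.fit()
        beta_o, cov_o, _, _ = _oracle_fit(model.X, model.y)
        gm = model.covariates.mean(axis=0)
        levels = model.levels
        em = res.emmeans().set_index("group")

        def xrow(g):
            x = np.zeros(model.X.shape[1])
            x[0] = 1.0
            if g != levels[0]:
                x[1 + levels[1:].index(g)] = 1.0
            x[len(levels):] = gm
            return x

        for g in levels:
            x = xrow(g)
            assert em.loc[g, "emmean"] == pytest.approx(x @ beta_o, abs=1e-10)
            assert em.loc[g, "se"] == pytest.approx(np.sqrt(x @ cov_o @ x), abs=1e-10)
        for _, row in res.pairwise().iterrows():
            c = xrow(row["group1"]) - xrow(row["group2"])
            assert row["estimate"] == pytest.approx(c @ beta_o, abs=1e-10)
            assert row["se"] == pytest.approx(np.sqrt(c @ cov_o @ c), abs=1e-10)


def test_emm_differences_antisymmetric():
    rng = np.random.default_rng(15)
    df, cov_names = random_design(rng, n=90, k=3)
    res = CoherenceModel.from_dataframe(df, covariates=cov_names).fit()
    pw = res.pairwise().set_index(["group1", "group2"])
    em = res.emmeans().set_index("group")["emmean"]
    for (g1, g2), row in pw.iterrows():
        assert row["estimate"] == pytest.approx(em[g1] - em[g2], abs=1e-10)


def test_equal_groups_give_zero_contrast_unit_p():
    y = np.tile([1.0, 2.0, 3.0, 4.0], 2)
    groups = ["a"] * 4 + ["b"] * 4
    res = CoherenceModel(y, groups, np.empty((8, 0)), []).fit()
    row = res.pairwise().iloc[0]
    assert row["estimate"] == pytest.approx(0.0, abs=1e-12)
    assert row["cohens_d"] == pytest.approx(0.0, abs=1e-12)
    assert row["p_tukey"] == pytest.approx(1.0, abs=1e-12)


def test_unknown_group_emm_rejected():
    res = CoherenceModel(np.arange(6.0), ["a", "a", "a", "b", "b", "b"],
                         np.empty((6, 0)), []).fit()
    with pytest.raises(ValueError):
        res._emm_row("zzz")


def test_summary_renders_key_quantities():
    rng = np.random.default_rng(16)
    df, cov_names = random_design(rng, n=80, k=2)
    res = CoherenceModel.from_dataframe(df, covariates=cov_names).fit()
    text = res.summary()
    assert "adj. R^2" in text
    assert "Tukey-adjusted pairwise contrasts" in text
    assert "Estimated marginal means" in text


# ---------------------------------------------------------------------------
# power


def test_power_at_zero_effect_equals_alpha():
    assert posthoc_power_two_group(0.0, 50, 50, 0.05) == pytest.approx(0.05, abs=1e-9)


def test_power_monotone_in_effect_and_n():
    p1 = posthoc_power_two_group(0.2, 50, 50)
    p2 = posthoc_power_two_group(0.5, 50, 50)
    p3 = posthoc_power_two_group(0.2, 500, 500)
    assert p1 < p2 and p1 < p3


def test_power_matches_simulation_oracle_small_n():
    # simulate the pooled two-sample t-test directly at n=20 per group
    rng = np.random.default_rng(17)
    n, d, alpha, B = 20, 0.8, 0.05, 20_000
    x = rng.normal(d, 1, (B, n))
    y = rng.normal(0, 1, (B, n))
    sp = np.sqrt(((n - 1) * x.var(axis=1, ddof=1) + (n - 1) * y.var(axis=1, ddof=1)) / (2 * n - 2))
    t = (x.mean(axis=1) - y.mean(axis=1)) / (sp * np.sqrt(2 / n))
    crit = sps.t.ppf(1 - alpha / 2, 2 * n - 2)
    sim = np.mean(np.abs(t) > crit)
    assert posthoc_power_two_group(d, n, n, alpha) == pytest.approx(sim, abs=0.01)


def test_power_input_validation():
    with pytest.raises(ValueError):
        posthoc_power_two_group(0.3, 1, 50)
    with pytest.raises(ValueError):
        posthoc_power_two_group(0.3, 10, 10, alpha=0.0)
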