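"""Kinship, REML mixed model, type III Wald tests, r2, LS means."""

import numpy as np
import pandas as pd
import pytest

from repeatarch import (
    LinearMixedModel,
    build_model_spec,
    fit_lmm,
    kinship_centered,
    ls_means,
    partial_r2,
    r2_nakagawa,
    wald_type3,
)
from repeatarch.lmm import ModelSpec, build_design


# ---------------------------------------------------------------------------
# kinship


def test_kinship_identical_rows_give_identical_entries(rng):
    G = rng.integers(0, 3, size=(6, 50)).astype(float)
    G[3] = G[0]
    K = kinship_centered(G)
    np.testing.assert_allclose(K[0], K[3])
    np.testing.assert_allclose(K[:, 0], K[:, 3])


def test_kinship_monomorphic_loci_give_zero_matrix():
    G = np.ones((5, 20)) * 2.0
    np.testing.assert_allclose(kinship_centered(G), 0.0)


def test_kinship_matches_double_loop_oracle(rng):
    G = rng.integers(0, 3, size=(20, 100)).astype(float)
    K = kinship_centered(G)
    W = G - G.mean(axis=0)
    expected = np.empty((20, 20))
    for i in range(20):
        for j in range(20):
            expected[i, j] = np.dot(W[i], W[j]) / 100
    np.testing.assert_allclose(K, expected, atol=1e-10)


def test_kinship_centers_loci_not_individuals(rng):
    # only column (locus) centering: row means of W are generally nonzero
    G = rng.integers(0, 3, size=(10, 60)).astype(float)
    W = G - G.mean(axis=0)
    assert np.abs(W.mean(axis=1)).max() > 1e-6


def test_kinship_mean_imputes_missing(rng):
    G = rng.integers(0, 3, size=(8, 30)).astype(float)
    G2 = G.copy()
    G2[0, 0] = np.nan
    K = kinship_centered(G2)
    assert np.isfinite(K).all()
    with pytest.raises(ValueError):
        kinship_centered(np.empty((5, 0)))


# ---------------------------------------------------------------------------
# model specs and design matrices


def test_preset_term_lists():
    ab = build_model_spec("abundance", response="Ty3")
    assert ab.terms == (
        "longitude", "latitude", "sex", "habitat", "sex:habitat", "ancestry"
    )
    joint = build_model_spec("joint")
    assert joint.terms == ("genome_size_z", "atp_copy_number_z", "pgv_ft_z")
    assert joint.response == "flowering_time"


def test_interaction_without_main_effect_rejected():
    with pytest.raises(ValueError, match="lacks main effect"):
        ModelSpec(response="y", terms=("sex", "sex:habitat"))


def test_sum_to_zero_coding_columns():
    df = pd.DataFrame({"y": [1.0, 2, 3, 4], "sex": ["M", "F", "M", "F"]})
    d = build_design(df, ModelSpec(response="y", terms=("sex",)))
    np.testing.assert_allclose(d.X[:, 1], [-1, 1, -1, 1])  # F=+1, M=-1


# ---------------------------------------------------------------------------
# REML fit


def simulate_lmm(rng, n=150, lam=1.0, sigma_e2=1.0, beta=(1.0, 0.5), K=None):
    X = np.column_stack([np.ones(n), rng.normal(size=n)])
    if K is None:
        G = rng.binomial(2, rng.uniform(0.1, 0.9, 300), size=(n, 300)).astype(float)
        K = kinship_centered(G)
    L = np.linalg.cholesky(K + 1e-8 * np.eye(n))
    u = np.sqrt(lam * sigma_e2) * (L @ rng.standard_normal(n))
    y = X @ np.asarray(beta) + u + np.sqrt(sigma_e2) * rng.standard_normal(n)
    return X, y, K


def test_identity_kinship_reproduces_ols(rng):
    n = 120
    X = np.column_stack([np.ones(n), rng.normal(size=(n, 2))])
    y = X @ [1.0, 0.5, -0.3] + rng.normal(size=n)
    m = LinearMixedModel().fit(X, y, K=np.eye(n))
    ols = np.linalg.lstsq(X, y, rcond=None)[0]
    np.testing.assert_allclose(m.coef_, ols, atol=1e-6)


def test_zero_genetic_variance_hits_lower_boundary(rng):
    n = 150
    X, y, K = simulate_lmm(rng, n=n, lam=0.0)
    m = LinearMixedModel().fit(X, y, K=K)
    share = m.sigma_g2_ * m.K_diag_mean_ / (
        m.sigma_g2_ * m.K_diag_mean_ + m.sigma_e2_
    )
    assert share < 0.1  # estimated genetic variance stays near zero
    # marginal ~ conditional R2 when sigma_g2 ~ 0
    spec = ModelSpec(response="y", terms=("x",))
    df = pd.DataFrame({"y": y, "x": X[:, 1]})
    fit = fit_lmm(df, spec, K=K)
    marg, cond = r2_nakagawa(fit)
    assert cond - marg < 0.05


def test_lambda_recovery_median_in_band(rng):
    lams = []
    X0, y0, K = simulate_lmm(rng, n=200, lam=1.0)
    for _ in range(20):
        X, y, _ = simulate_lmm(rng, n=200, lam=1.0, K=K)
        lams.append(LinearMixedModel().fit(X, y, K=K).lambda_)
    assert 0.5 <= np.median(lams) <= 2.0  # acceptance runs the tighter study


def test_gls_matches_direct_normal_equations(rng):
    X, y, K = simulate_lmm(rng, n=100, lam=0.8)
    m = LinearMixedModel().fit(X, y, K=K)
    V = m.sigma_g2_ * K + m.sigma_e2_ * np.eye(len(y))
    Vi = np.linalg.inv(V)
    beta = np.linalg.solve(X.T @ Vi @ X, X.T @ Vi @ y)
    np.testing.assert_allclose(m.coef_, beta, rtol=1e-8, atol=1e-10)


def test_reml_optimum_stable_under_grid_refinement(rng):
    X, y, K = simulate_lmm(rng, n=120, lam=1.0)
    lam_coarse = LinearMixedModel(grid_points=100).fit(X, y, K=K).lambda_
    lam_fine = LinearMixedModel(grid_points=400).fit(X, y, K=K).lambda_
    assert abs(np.log10(lam_coarse) - np.log10(lam_fine)) < 1e-4


def test_singular_design_rejected(rng):
    n = 50
    x = rng.normal(size=n)
    X = np.column_stack([np.ones(n), x, 2 * x])
    with pytest.raises(ValueError, match="aliased"):
        LinearMixedModel().fit(X, rng.normal(size=n), K=np.eye(n))


def test_invalid_kinship_rejected(rng):
    n = 30
    X = np.column_stack([np.ones(n), rng.normal(size=n)])
    y = rng.normal(size=n)
    K = rng.normal(size=(n, n))
    with pytest.raises(ValueError, match="symmetric"):
        LinearMixedModel().fit(X, y, K=K)
    K = -np.eye(n)
    with pytest.raises(ValueError, match="PSD"):
        LinearMixedModel().fit(X, y, K=K)


# ---------------------------------------------------------------------------
# Wald tests / partial r2 / ls means


def covariate_frame(rng, n=200):
    return pd.DataFrame(
        {
            "sex": rng.choice(["M", "F"], n),
            "habitat": rng.choice(["Ag", "Nat"], n),
            "x": rng.normal(size=n),
        }
    )


def test_wald_single_df_identity(rng):
    df = covariate_frame(rng)
    df["y"] = 1.0 + 0.4 * df["x"] + rng.normal(size=len(df))
    fit = fit_lmm(df, ModelSpec(response="y", terms=("x",)), K=np.eye(len(df)))
    chi2, dfree, p = wald_type3(fit, "x")
    sl = fit.design.blocks["x"]
    beta, se = fit.model.coef_[sl][0], fit.model.se_[sl][0]
    assert dfree == 1
    assert chi2 == pytest.approx((beta / se) ** 2)


def test_type3_invariant_to_level_order(rng):
    df = covariate_frame(rng)
    df["y"] = (
        1.0
        + np.where(df["sex"] == "M", -1.0, 1.0)
        + np.where(df["habitat"] == "Ag", 0.5, -0.5)
        + rng.normal(size=len(df))
    )
    spec = ModelSpec(response="y", terms=("sex", "habitat", "sex:habitat"))
    fit1 = fit_lmm(df, spec, K=np.eye(len(df)))
    relab = df.assign(sex=df["sex"].map({"M": "aM", "F": "zF"}))
    fit2 = fit_lmm(relab, spec, K=np.eye(len(df)))
    for term in spec.terms:
        c1, _, p1 = wald_type3(fit1, term)
        c2, _, p2 = wald_type3(fit2, term)
        assert c1 == pytest.approx(c2, rel=1e-8)


def test_type3_matches_anova_on_balanced_design(rng):
    # balanced 2x2 with many replicates: type III F ~ sequential F ~ chi2/df
    import statsmodels.api as sm
    from statsmodels.formula.api import ols

    reps = 100
    df = pd.DataFrame(
        {
            "sex": np.repeat(["M", "F"], 2 * reps),
            "habitat": np.tile(np.repeat(["Ag", "Nat"], reps), 2),
        }
    )
    df["y"] = (
        1.0
        + np.where(df["sex"] == "M", -2.0, 2.0)
        + np.where(df["habitat"] == "Ag", 1.0, -1.0)
        + rng.normal(size=len(df))
    )
    spec = ModelSpec(response="y", terms=("sex", "habitat", "sex:habitat"))
    fit = fit_lmm(df, spec, K=np.eye(len(df)))
    anova = sm.stats.anova_lm(
        ols("y ~ C(sex, Sum) * C(habitat, Sum)", data=df).fit(), typ=1
    )
    for term, alab in [("sex", "C(sex, Sum)"), ("habitat", "C(habitat, Sum)")]:
        chi2, dfree, _ = wald_type3(fit, term)
        assert chi2 / dfree == pytest.approx(anova.loc[alab, "F"], rel=0.02)


def test_partial_r2_equals_squared_correlation_for_simple_regression(rng):
    n = 300
    x = rng.normal(size=n)
    y = 0.5 * x + rng.normal(size=n)
    df = pd.DataFrame({"y": y, "x": x})
    fit = fit_lmm(df, ModelSpec(response="y", terms=("x",)), K=np.eye(n))
    r2 = np.corrcoef(x, y)[0, 1] ** 2
    assert partial_r2(fit, "x") == pytest.approx(r2, abs=0.01)


def test_partial_r2_limits(rng):
    n = 200
    x = rng.normal(size=n)
    # noise -> 0: the only predictor approaches partial r2 of 1
    df = pd.DataFrame({"y": 2 * x + 1e-8 * rng.normal(size=n), "x": x})
    fit = fit_lmm(df, ModelSpec(response="y", terms=("x",)), K=np.eye(n))
    assert partial_r2(fit, "x") > 0.999
    # true-zero effect stays near zero
    df0 = pd.DataFrame({"y": rng.normal(size=500), "x": rng.normal(size=500)})
    fit0 = fit_lmm(df0, ModelSpec(response="y", terms=("x",)), K=np.eye(500))
    assert partial_r2(fit0, "x") < 0.02


def test_nakagawa_intercept_only_marginal_zero(rng):
    n = 100
    df = pd.DataFrame({"y": rng.normal(size=n), "one": np.ones(n)})
    fit = fit_lmm(df, ModelSpec(response="y", terms=()), K=np.eye(n))
    marg, cond = r2_nakagawa(fit)
    assert marg == pytest.approx(0.0, abs=1e-12)
    assert cond <= 1.0


def test_ls_means_balanced_equal_group_means(rng):
    df = pd.DataFrame(
        {
            "sex": np.repeat(["M", "F"], 40),
            "y": np.concatenate([rng.normal(2, 1, 40), rng.normal(5, 1, 40)]),
        }
    )
    fit = fit_lmm(df, ModelSpec(response="y", terms=("sex",)), K=np.eye(80))
    lsm = ls_means(fit, "sex")
    for level in ("M", "F"):
        assert lsm.loc[level, "estimate"] == pytest.approx(
            df[df["sex"] == level]["y"].mean(), abs=1e-8
        )


def test_ls_means_balanced_2x2_are_cell_mean_averages(rng):
    reps = 30
    df = pd.DataFrame(
        {
            "sex": np.repeat(["M", "F"], 2 * reps),
            "habitat": np.tile(np.repeat(["Ag", "Nat"], reps), 2),
        }
    )
    df["y"] = rng.normal(size=len(df)) + np.where(df["sex"] == "M", 1.0, -1.0)
    spec = ModelSpec(response="y", terms=("sex", "habitat", "sex:habitat"))
    fit = fit_lmm(df, spec, K=np.eye(len(df)))
    lsm = ls_means(fit, "sex")
    for level in ("M", "F"):
        cells = df[df["sex"] == level].groupby("habitat")["y"].mean()
        assert lsm.loc[level, "estimate"] == pytest.approx(cells.mean(), abs=1e-8)


def test_ls_means_covariate_adjusted(rng):
    n = 120
    df = covariate_frame(rng, n)
    df["y"] = 2.0 + 1.5 * df["x"] + np.where(df["sex"] == "M", -1, 1) + rng.normal(
        size=n
    )
    fit = fit_lmm(df, ModelSpec(response="y", terms=("sex", "x")), K=np.eye(n))
    lsm = ls_means(fit, "sex")
    sl_x = fit.design.blocks["x"]
    sl_s = fit.design.blocks["sex"]
    b0 = fit.model.coef_[0]
    manual_m = b0 + fit.model.coef_[sl_s][0] * (-1) + fit.model.coef_[sl_x][0] * df[
        "x"
    ].mean()
    assert lsm.loc["M", "estimate"] == pytest.approx(manual_m, abs=1e-10)
    with pytest.raises(ValueError):
        ls_means(fit, "x")


def test_listwise_missing_drop(rng):
    df = covariate_frame(rng, 60)
    df["y"] = rng.normal(size=60)
    df.loc[df.index[:5], "y"] = np.nan
    fit = fit_lmm(df, ModelSpec(response="y", terms=("x",)), K=np.eye(60))
    assert fit.n_dropped == 5
    assert fit.model.n_ == 55
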