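"""Kinship-aware linear mixed models.

The model is ``y = X b + u + e`` with ``u ~ N(0, sg2 K)`` for a
centered-genotype relatedness matrix K and ``e ~ N(0, se2 I)``.  Variance
components are estimated by REML profiled over the ratio
``lambda = sg2/se2``: K is eigendecomposed once, the data rotated, and the
one-dimensional profile likelihood maximized over log10(lambda) on a grid
followed by bounded refinement.  Fixed effects come from GLS at the
optimum; terms are tested with type III Wald chi-square statistics under
sum-to-zero factor coding, with semi-partial r2, Nakagawa-style
marginal/conditional R2 and least-squares means on top.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from sklearn.base import BaseEstimator

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Kinship


def kinship_centered(genotypes) -> pd.DataFrame | np.ndarray:
    """Relatedness from the centered genotype matrix: K = W W' / p.

    Each locus (column) is centered by its sample mean; missing dosages are
    mean-imputed (zero after centering).  Rows (individuals) are *not*
    centered, matching the centered-genotype algorithm of standard GWAS
    tools.
    """
    is_df = isinstance(genotypes, pd.DataFrame)
    G = np.asarray(genotypes, dtype=float)
    if G.ndim != 2 or G.shape[1] == 0:
        raise ValueError("genotype matrix must be 2-D with at least one locus")
    col_mean = np.nanmean(G, axis=0)
    col_mean = np.where(np.isnan(col_mean), 0.0, col_mean)  # all-missing locus
    W = G - col_mean
    W[np.isnan(W)] = 0.0
    K = W @ W.T / G.shape[1]
    K = (K + K.T) / 2.0
    if is_df:
        return pd.DataFrame(K, index=genotypes.index, columns=genotypes.index)
    return K


# ---------------------------------------------------------------------------
# Model specification and design matrices


@dataclass(frozen=True)
class ModelSpec:
    """A fixed-effect structure: response plus main-effect/interaction terms.

    Interaction terms use ':' (``sex:habitat``); every interaction's
    components must appear as main effects.  Presets mirror the three
    analysis models: per-class repeat abundance on geography/sex/habitat/
    ancestry (``abundance``), a phenotype on genome size plus those terms
    (``phenotype``), and a phenotype on the three z-scaled genetic
    predictors (``joint``).
    """

    response: str
    terms: tuple
    preset: str = "custom"

    def __post_init__(self):
        mains = {t for t in self.terms if ":" not in t}
        for t in self.terms:
            if ":" in t:
                for comp in t.split(":"):
                    if comp not in mains:
                        raise ValueError(
                            f"interaction {t!r} lacks main effect {comp!r}"
                        )

    @property
    def variables(self) -> tuple:
        seen = []
        for t in self.terms:
            for comp in t.split(":"):
                if comp not in seen:
                    seen.append(comp)
        return tuple(seen)


ABUNDANCE_TERMS = ("longitude", "latitude", "sex", "habitat", "sex:habitat", "ancestry")
JOINT_TERMS = ("genome_size_z", "atp_copy_number_z", "pgv_ft_z")


def build_model_spec(preset: str, response: str | None = None, terms=None) -> ModelSpec:
    """Construct one of the preset model specifications.

    ``abundance``: response (a repeat-class abundance) on longitude,
    latitude, sex*habitat and ancestry; ``phenotype`` adds genome size and
    defaults to flowering time; ``joint``: flowering time on z(genome
    size) + z(ATP-locus CN) + z(PGV).
    ``Sex*Env`` expands to both main effects plus the interaction.
    """
    if preset == "abundance":
        if response is None:
            raise ValueError("abundance preset needs a response (a repeat-class abundance)")
        return ModelSpec(response=response, terms=ABUNDANCE_TERMS, preset="abundance")
    if preset == "phenotype":
        return ModelSpec(
            response=response or "flowering_time",
            terms=("genome_size_mb",) + ABUNDANCE_TERMS,
            preset="phenotype",
        )
    if preset == "joint":
        return ModelSpec(
            response=response or "flowering_time", terms=JOINT_TERMS, preset="joint"
        )
    if preset == "custom":
        if response is None or terms is None:
            raise ValueError("custom spec needs response and terms")
        return ModelSpec(response=response, terms=tuple(terms), preset="custom")
    raise ValueError(f"unknown preset {preset!r}")


@dataclass
class DesignInfo:
    """A realized design matrix with per-term column blocks."""

    X: np.ndarray
    column_names: list
    blocks: dict  # term -> slice into X's columns
    factor_levels: dict  # variable -> tuple of levels (factors only)
    continuous_means: dict  # variable -> sample mean (continuous only)


def _is_factor(series: pd.Series) -> bool:
    return (
        series.dtype == object
        or isinstance(series.dtype, pd.CategoricalDtype)
        or series.dtype == bool
    )


def _code_factor(values: pd.Series, levels) -> np.ndarray:
    """Sum-to-zero (deviation) coding: k-1 columns, last level coded -1."""
    k = len(levels)
    idx = pd.Categorical(values, categories=levels).codes
    if (idx < 0).any():
        bad = sorted(set(values) - set(levels))
        raise ValueError(f"unknown factor level(s): {bad}")
    Z = np.zeros((len(values), k - 1))
    for i in range(k - 1):
        Z[idx == i, i] = 1.0
    Z[idx == k - 1, :] = -1.0
    return Z


def build_design(data: pd.DataFrame, spec: ModelSpec) -> DesignInfo:
    """Encode the fixed-effect design with sum-to-zero factor contrasts."""
    factor_levels: dict = {}
    continuous_means: dict = {}
    var_cols: dict = {}  # variable -> (ndarray columns, names)
    for v in spec.variables:
        if v not in data.columns:
            raise ValueError(f"model variable {v!r} not in data")
        s = data[v]
        if _is_factor(s):
            levels = tuple(sorted(pd.unique(s.astype(str))))
            if len(levels) < 2:
                raise ValueError(f"factor {v!r} has a single level")
            factor_levels[v] = levels
            Z = _code_factor(s.astype(str), levels)
            var_cols[v] = (Z, [f"{v}[S.{lv}]" for lv in levels[:-1]])
        else:
            x = s.to_numpy(float)
            continuous_means[v] = float(np.mean(x))
            var_cols[v] = (x[:, None], [v])
    cols = [np.ones((len(data), 1))]
    names = ["Intercept"]
    blocks: dict = {}
    pos = 1
    for t in spec.terms:
        comps = t.split(":")
        Z, nm = var_cols[comps[0]]
        for comp in comps[1:]:
            Z2, nm2 = var_cols[comp]
            Z = np.einsum("ni,nj->nij", Z, Z2).reshape(len(data), -1)
            nm = [f"{a}:{b}" for a in nm for b in nm2]
        cols.append(Z)
        names.extend(nm)
        blocks[t] = slice(pos, pos + Z.shape[1])
        pos += Z.shape[1]
    X = np.hstack(cols)
    return DesignInfo(
        X=X,
        column_names=names,
        blocks=blocks,
        factor_levels=factor_levels,
        continuous_means=continuous_means,
    )


# ---------------------------------------------------------------------------
# The estimator


class LinearMixedModel(BaseEstimator):
    """Single-kernel linear mixed model fitted by profiled REML.

    Parameters
    ----------
    log10_lambda_bounds : (float, float)
        Search range for log10(sg2/se2).
    grid_points : int
        Coarse grid size before bounded refinement.
    refine_tol : float
        Absolute tolerance of the refinement in log10(lambda).
    psd_tol : float
        Negative-eigenvalue tolerance (relative) accepted for K.

    Attributes (after ``fit``)
    --------------------------
    coef_, cov_coef_, se_ : GLS fixed effects at the REML optimum.
    sigma_g2_, sigma_e2_, lambda_ : variance components and their ratio.
    loglik_reml_ : profiled restricted log-likelihood at the optimum.
    boundary_ : True when lambda_ hit the search boundary.
    fitted_marginal_, fitted_conditional_ : X b and X b + BLUP(u).
    """

    def __init__(
        self,
        log10_lambda_bounds=(-5.0, 5.0),
        grid_points: int = 100,
        refine_tol: float = 1e-6,
        psd_tol: float = 1e-8,
    ):
        self.log10_lambda_bounds = log10_lambda_bounds
        self.grid_points = grid_points
        self.refine_tol = refine_tol
        self.psd_tol = psd_tol

    def fit(self, X, y, K=None):
        X = np.asarray(X, float)
        y = np.asarray(y, float).ravel()
        n, p = X.shape
        if len(y) != n:
            raise ValueError("X and y have different numbers of rows")
        if not (np.isfinite(X).all() and np.isfinite(y).all()):
            raise ValueError("non-finite values in X or y")
        # rank check with named aliased columns
        _, R = np.linalg.qr(X)
        diag = np.abs(np.diag(R))
        tol = diag.max() * max(n, p) * np.finfo(float).eps
        aliased = np.where(diag < tol)[0]
        if aliased.size:
            raise ValueError(f"singular design: aliased column indices {aliased.tolist()}")
        if n <= p + 1:
            raise ValueError(f"need n > rank(X)+1 (n={n}, rank={p})")
        if K is None:
            K = np.zeros((n, n))
        K = np.asarray(K, float)
        if K.shape != (n, n):
            raise ValueError("K not conformable with y")
        if np.max(np.abs(K - K.T)) > 1e-10 * max(1.0, np.abs(K).max()):
            raise ValueError("K is not symmetric")
        d, U = np.linalg.eigh((K + K.T) / 2.0)
        scale = max(1.0, d.max()) if d.size else 1.0
        if d.min() < -self.psd_tol * scale:
            raise ValueError(f"K is not PSD (min eigenvalue {d.min():.3g})")
        d = np.clip(d, 0.0, None)

        yt = U.T @ y
        Xt = U.T @ X

        def neg_reml(log10_lam):
            return -_profiled_reml(10.0**log10_lam, d, Xt, yt)

        lo, hi = self.log10_lambda_bounds
        grid = np.linspace(lo, hi, self.grid_points)
        vals = np.array([neg_reml(g) for g in grid])
        i = int(np.argmin(vals))
        a = grid[max(i - 1, 0)]
        b = grid[min(i + 1, len(grid) - 1)]
        if i in (0, len(grid) - 1):
            best_log10 = grid[i]
        else:
            res = optimize.minimize_scalar(
                neg_reml,
                bounds=(a, b),
                method="bounded",
                options={"xatol": self.refine_tol},
            )
            best_log10 = float(res.x)
            if neg_reml(best_log10) > vals[i]:
                best_log10 = grid[i]
        lam = 10.0**best_log10
        self.boundary_ = bool(
            best_log10 <= lo + 1e-9 or best_log10 >= hi - 1e-9
        )
        ll, beta, cov_beta, sigma_e2, w = _profiled_reml(
            lam, d, Xt, yt, full=True
        )
        self.lambda_ = lam
        self.loglik_reml_ = ll
        self.coef_ = beta
        self.cov_coef_ = cov_beta
        self.se_ = np.sqrt(np.diag(cov_beta))
        self.sigma_e2_ = sigma_e2
        self.sigma_g2_ = lam * sigma_e2
        self.n_ = n
        self.rank_ = p
        self.eig_d_ = d
        self.K_diag_mean_ = float(np.mean(np.diag(K)))
        self.fitted_marginal_ = X @ beta
        resid_t = yt - Xt @ beta
        u_t = lam * d * w * resid_t  # BLUP in rotated coordinates
        self.fitted_conditional_ = self.fitted_marginal_ + U @ u_t
        self.X_ = X
        self.y_ = y
        return self

    def predict(self, X):
        return np.asarray(X, float) @ self.coef_


def _profiled_reml(lam, d, Xt, yt, full=False):
    """Profiled restricted log-likelihood at variance ratio ``lam``."""
    n, p = Xt.shape
    w = 1.0 / (lam * d + 1.0)
    XtW = Xt * w[:, None]
    A = XtW.T @ Xt
    b = XtW.T @ yt
    beta = np.linalg.solve(A, b)
    resid = yt - Xt @ beta
    rss = float(resid @ (w * resid))
    sigma_e2 = rss / (n - p)
    sign, logdet_A = np.linalg.slogdet(A)
    ll = -0.5 * (
        (n - p) * np.log(2.0 * np.pi * sigma_e2)
        + (n - p)
        + np.sum(np.log(lam * d + 1.0))
        + logdet_A
    )
    if not full:
        return ll
    cov_beta = sigma_e2 * np.linalg.inv(A)
    return ll, beta, cov_beta, sigma_e2, w


# ---------------------------------------------------------------------------
# High-level fitting on data frames


@dataclass
class LMMFit:
    """A fitted mixed model plus the design metadata needed for inference."""

    model: LinearMixedModel
    spec: ModelSpec
    design: DesignInfo
    data: pd.DataFrame
    individual_ids: list
    n_dropped: int = 0

    @property
    def y(self):
        return self.model.y_

    @property
    def X(self):
        return self.model.X_

    def term_table(self) -> pd.DataFrame:
        rows = []
        for t in self.spec.terms:
            chi2, df, p = wald_type3(self, t)
            rows.append((t, chi2, df, p, partial_r2(self, t)))
        return pd.DataFrame(
            rows, columns=["term", "chi2", "df", "p", "partial_r2"]
        ).set_index("term")


def fit_lmm(
    data: pd.DataFrame,
    spec: ModelSpec,
    K: pd.DataFrame | np.ndarray | None = None,
    **model_kwargs,
) -> LMMFit:
    """Fit a preset/custom model on a covariate+phenotype table.

    Rows with missing response or covariates are dropped listwise (count
    logged); K is aligned to the retained individuals when it carries ids.
    """
    cols = [spec.response, *spec.variables]
    missing = [c for c in cols if c not in data.columns]
    if missing:
        raise ValueError(f"data lacks column(s) {missing}")
    sub = data[cols].copy()
    keep = sub.notna().all(axis=1)
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("fit_lmm: dropped %d rows with missing values", n_dropped)
    sub = sub[keep]
    ids = list(data.index[keep])
    if K is not None:
        if isinstance(K, pd.DataFrame):
            K = K.loc[ids, ids].to_numpy(float)
        else:
            K = np.asarray(K, float)[np.ix_(keep.to_numpy(), keep.to_numpy())]
    design = build_design(sub, spec)
    model = LinearMixedModel(**model_kwargs)
    model.fit(design.X, sub[spec.response].to_numpy(float), K=K)
    return LMMFit(
        model=model,
        spec=spec,
        design=design,
        data=sub,
        individual_ids=ids,
        n_dropped=n_dropped,
    )


def wald_type3(fit: LMMFit, term: str):
    """Type III Wald test of one term's coefficient block.

    chi2 = b' Cov(b)^-1 b over the block, df = block size.  Sum-to-zero
    coding makes the result invariant to factor level order.
    """
    if term not in fit.design.blocks:
        raise ValueError(f"term {term!r} not in model")
    sl = fit.design.blocks[term]
    b = fit.model.coef_[sl]
    C = fit.model.cov_coef_[sl, sl]
    try:
        chi2 = float(b @ np.linalg.solve(C, b))
    except np.linalg.LinAlgError as err:
        raise ValueError(f"term {term!r} is aliased: {err}") from err
    df = b.size
    return chi2, df, float(stats.chi2.sf(chi2, df))


def partial_r2(fit: LMMFit, term: str) -> float:
    """Semi-partial r2 of one term: (df*F)/(df*F + df_resid).

    F = chi2/df and df_resid = n - rank(X); an approximate-df variant of
    the standard semi-partial R2 for mixed models.
    """
    chi2, df, _ = wald_type3(fit, term)
    df_resid = fit.model.n_ - fit.model.rank_
    if df_resid <= 0:
        raise ValueError("zero residual degrees of freedom")
    f = chi2 / df
    return float(df * f / (df * f + df_resid))


def r2_nakagawa(fit: LMMFit):
    """(marginal, conditional) R2: fixed effects vs fixed + kinship."""
    m = fit.model
    var_fixed = float(np.var(m.fitted_marginal_, ddof=1))
    var_g = m.sigma_g2_ * m.K_diag_mean_
    denom = var_fixed + var_g + m.sigma_e2_
    if denom <= 0:
        raise ValueError("degenerate zero-variance fit")
    return var_fixed / denom, (var_fixed + var_g) / denom


def ls_means(fit: LMMFit, factors) -> pd.DataFrame:
    """Least-squares (marginal) means of a factor or factor pair.

    Predictions at the grand mean of continuous covariates, averaged with
    equal weight over the levels of every other factor.
    """
    if isinstance(factors, str):
        factors = (factors,)
    for f in factors:
        if f not in fit.design.factor_levels:
            raise ValueError(f"{f!r} is not a factor in this model")
    other = [v for v in fit.design.factor_levels if v not in factors]
    rows = []
    for combo in itertools.product(*(fit.design.factor_levels[f] for f in factors)):
        grid = []
        for fill in itertools.product(
            *(fit.design.factor_levels[v] for v in other)
        ):
            rec = dict(zip(factors, combo)) | dict(zip(other, fill))
            rec |= fit.design.continuous_means
            grid.append(rec)
        Xg = _encode_rows(pd.DataFrame(grid), fit)
        x = Xg.mean(axis=0)
        est = float(x @ fit.model.coef_)
        se = float(np.sqrt(x @ fit.model.cov_coef_ @ x))
        rows.append((*combo, est, se))
    return pd.DataFrame(
        rows, columns=[*factors, "estimate", "se"]
    ).set_index(list(factors))


def _encode_rows(df: pd.DataFrame, fit: LMMFit) -> np.ndarray:
    """Encode new rows with the fitted design's coding."""
    var_cols = {}
    for v in fit.spec.variables:
        if v in fit.design.factor_levels:
            var_cols[v] = _code_factor(
                df[v].astype(str), fit.design.factor_levels[v]
            )
        else:
            var_cols[v] = df[v].to_numpy(float)[:, None]
    cols = [np.ones((len(df), 1))]
    for t in fit.spec.terms:
        comps = t.split(":")
        Z = var_cols[comps[0]]
        for comp in comps[1:]:
            Z2 = var_cols[comp]
            Z = np.einsum("ni,nj->nij", Z, Z2).reshape(len(df), -1)
        cols.append(Z)
    return np.hstack(cols)
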