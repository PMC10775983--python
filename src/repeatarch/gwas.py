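"""Genome-wide association and polygenic values.

Associations are run per feature (SNP dosage or gene/repeat copy number)
against a quantitative trait by GLS under the variance structure
``sg2 K + se2 I`` estimated once under the null model (the standard
single-null-fit approximate mixed-model GWA); an unstructured mode drops
the kinship control entirely.  Benjamini-Hochberg q-values and Bonferroni
flags are attached; effects at FDR-selected loci feed the polygenic value
``PGV = 2 * sum_l alpha_l * p_l`` with genotypes coded 0 / 0.5 / 1, and
its shifted-log10 + z-scale transform.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .lmm import LinearMixedModel

logger = logging.getLogger(__name__)


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, in the input order.

    q_(i) = min over k >= i of (m * p_(k) / k), capped at 1.
    """
    p = np.asarray(p_values, float)
    if p.ndim != 1:
        raise ValueError("p_values must be 1-D")
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def bonferroni(p_values, alpha: float = 0.10) -> np.ndarray:
    """Boolean flags for p <= alpha / m (family-wise control)."""
    if not (0 < alpha <= 1):
        raise ValueError("alpha must be in (0, 1]")
    p = np.asarray(p_values, float)
    if p.size < 1:
        raise ValueError("need at least one p-value")
    return p <= alpha / p.size


def gwa_lmm(
    y,
    features: pd.DataFrame,
    K=None,
    covariates: np.ndarray | None = None,
    fdr_alpha: float = 0.10,
    bonferroni_alpha: float = 0.10,
    refit_variance: bool = False,
) -> pd.DataFrame:
    """Per-feature association scan with optional kinship control.

    ``features`` is individuals x loci (SNP dosages or copy numbers).
    With K, the null model ``y ~ covariates + u + e`` is fitted once by
    REML; each feature is then tested by GLS under the fixed estimated
    variance structure (set ``refit_variance=True`` to re-profile lambda
    per feature).  Monomorphic features are skipped with a logged count
    and returned with NaN statistics.

    Returns a frame indexed by locus with effect (alpha), se, p, q and a
    Bonferroni flag.
    """
    y = np.asarray(y, float).ravel()
    n = y.size
    if features.shape[0] != n:
        raise ValueError(
            f"features has {features.shape[0]} rows but y has {n} values"
        )
    if np.sum(np.isfinite(y)) < 30:
        raise ValueError("need a finite trait for >= 30 individuals")
    G = features.to_numpy(float)
    X0 = (
        np.ones((n, 1))
        if covariates is None
        else np.column_stack([np.ones(n), np.asarray(covariates, float)])
    )
    keep = np.nanstd(G, axis=0) > 0
    n_skip = int((~keep).sum())
    if n_skip:
        logger.info("gwa_lmm: skipped %d monomorphic/zero-variance features", n_skip)

    if K is not None:
        K = np.asarray(K, float)
        if K.shape != (n, n):
            raise ValueError("K not conformable with y")
        null = LinearMixedModel().fit(X0, y, K=K)
        d, U = np.linalg.eigh((K + K.T) / 2.0)
        d = np.clip(d, 0.0, None)
        w = 1.0 / (null.sigma_g2_ * d + null.sigma_e2_)
        yt = U.T @ y
        X0t = U.T @ X0
        Gt = U.T @ G[:, keep]
    else:
        # unstructured mode: fixed residual scale from the covariate-only fit,
        # mirroring the single-null-fit convention of the kinship mode (and
        # coinciding with it exactly when K is the zero matrix)
        beta0, *_ = np.linalg.lstsq(X0, y, rcond=None)
        r0 = y - X0 @ beta0
        sigma0 = float(r0 @ r0) / (n - X0.shape[1])
        w = np.full(n, 1.0 / sigma0)
        yt, X0t, Gt = y, X0, G[:, keep]
        null = None

    if refit_variance and K is not None:
        eff = np.full(Gt.shape[1], np.nan)
        se = np.full(Gt.shape[1], np.nan)
        for j in range(Gt.shape[1]):
            m = LinearMixedModel().fit(
                np.column_stack([X0, G[:, keep][:, j]]), y, K=K
            )
            eff[j] = m.coef_[-1]
            se[j] = m.se_[-1]
    else:
        eff, se = _gls_scan(yt, X0t, Gt, w)

    z = eff / se
    p = 2.0 * stats.norm.sf(np.abs(z))
    out = pd.DataFrame(
        {
            "effect": np.nan,
            "se": np.nan,
            "p": np.nan,
            "q": np.nan,
            "bonferroni_significant": False,
        },
        index=features.columns,
    )
    out.loc[features.columns[keep], "effect"] = eff
    out.loc[features.columns[keep], "se"] = se
    out.loc[features.columns[keep], "p"] = p
    out.loc[features.columns[keep], "q"] = bh_fdr(p)
    out.loc[features.columns[keep], "bonferroni_significant"] = bonferroni(
        p, bonferroni_alpha
    )
    out.attrs["n_skipped_monomorphic"] = n_skip
    out.attrs["fdr_alpha"] = fdr_alpha
    if null is not None:
        out.attrs["null_lambda"] = null.lambda_
        out.attrs["null_sigma_g2"] = null.sigma_g2_
        out.attrs["null_sigma_e2"] = null.sigma_e2_
    return out


def _gls_scan(yt, X0t, Gt, w):
    """Vectorized per-locus GLS under a fixed (null-estimated) variance.

    The weights absorb the variance scale, so the Wald SE of the slope is
    1/sqrt(g' W g) after residualizing both trait and locus on X0.
    """
    WX0 = X0t * w[:, None]
    A0 = X0t.T @ WX0
    yr = yt - X0t @ np.linalg.solve(A0, WX0.T @ yt)
    Gr = Gt - X0t @ np.linalg.solve(A0, WX0.T @ Gt)
    gWg = np.einsum("ij,ij->j", Gr, Gr * w[:, None])
    gWy = (Gr * w[:, None]).T @ yr
    eff = gWy / gWg
    se = np.sqrt(1.0 / gWg)
    return eff, se


class MixedModelGWAS(BaseEstimator):
    """Estimator wrapper around :func:`gwa_lmm`.

    ``fit(G, y, K=...)`` stores the scan in ``results_``;
    ``selected_loci(q_threshold)`` returns the FDR-passing locus ids.
    """

    def __init__(
        self,
        use_kinship: bool = True,
        fdr_alpha: float = 0.10,
        bonferroni_alpha: float = 0.10,
        refit_variance: bool = False,
    ):
        self.use_kinship = use_kinship
        self.fdr_alpha = fdr_alpha
        self.bonferroni_alpha = bonferroni_alpha
        self.refit_variance = refit_variance

    def fit(self, G, y, K=None):
        self.results_ = gwa_lmm(
            y,
            G,
            K=K if self.use_kinship else None,
            fdr_alpha=self.fdr_alpha,
            bonferroni_alpha=self.bonferroni_alpha,
            refit_variance=self.refit_variance,
        )
        return self

    def selected_loci(self, q_threshold: float | None = None) -> list:
        q = self.results_["q"]
        thr = self.fdr_alpha if q_threshold is None else q_threshold
        return list(self.results_.index[q < thr])


def polygenic_value(
    effects: pd.Series, genotypes: pd.DataFrame, loci=None
) -> pd.Series:
    """PGV(ind) = 2 * sum over selected loci of alpha_l * p_l(ind).

    ``genotypes`` hold dosages in [0, 2]; the genotype coding p = dosage/2
    (0 for homozygous reference, 0.5 heterozygote, 1 homozygous alternate).
    """
    if loci is None:
        loci = list(effects.index)
    loci = list(loci)
    missing = [l for l in loci if l not in genotypes.columns]
    if missing:
        raise ValueError(f"selected locus missing from genotypes: {missing[:5]}")
    missing_eff = [l for l in loci if l not in effects.index]
    if missing_eff:
        raise ValueError(f"selected locus missing an effect: {missing_eff[:5]}")
    P = genotypes[loci].to_numpy(float) / 2.0
    alpha = effects.loc[loci].to_numpy(float)
    return pd.Series(2.0 * (P @ alpha), index=genotypes.index, name="pgv")


@dataclass
class PGVTable:
    """Raw polygenic values plus the shifted-log10 and z-scaled versions."""

    raw: pd.Series
    shifted_log: pd.Series
    z: pd.Series
    shift: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"pgv_raw": self.raw, "pgv_log": self.shifted_log, "pgv_z": self.z}
        )


def transform_pgv(raw: pd.Series, eps_fraction: float = 0.05) -> PGVTable:
    """Shift positive (if needed), log10, then z-scale (mean 0, sd 1, n-1).

    When the minimum is <= 0 every value is shifted by |min| plus
    ``eps_fraction`` of the value range so the minimum is strictly
    positive before the log.  The default keeps the log span within about
     1.3 decades: a vanishing epsilon would park the minimum individual
    many decades below the rest, a single point of extreme leverage in
    any downstream regression.
    """
    raw = pd.Series(raw, dtype=float)
    if raw.nunique() < 2:
        raise ValueError("constant polygenic values cannot be z-scaled")
    mn, mx = float(raw.min()), float(raw.max())
    shift = 0.0
    if mn <= 0:
        shift = abs(mn) + eps_fraction * (mx - mn)
    logged = np.log10(raw + shift)
    z = (logged - logged.mean()) / logged.std(ddof=1)
    return PGVTable(raw=raw, shifted_log=logged, z=z, shift=shift)


# ---------------------------------------------------------------------------
# I/O


def read_dosage_tsv(path) -> pd.DataFrame:
    """Individuals x loci dosage matrix from TSV (first column = id)."""
    return pd.read_csv(path, sep="\t", index_col=0)


def read_vcf_dosages(path) -> pd.DataFrame:
    """Dosage matrix (0/1/2 from GT) from a VCF via cyvcf2."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    loci, rows = [], []
    for var in vcf:
        loci.append(var.ID if var.ID else f"{var.CHROM}:{var.POS}")
        gts = np.asarray(var.gt_types, dtype=float)  # 0=hom-ref,1=het,2=unknown,3=hom-alt
        dos = np.select(
            [gts == 0, gts == 1, gts == 3], [0.0, 1.0, 2.0], default=np.nan
        )
        rows.append(dos)
    return pd.DataFrame(
        np.asarray(rows).T, index=pd.Index(samples, name="individual_id"), columns=loci
    )


def read_effects_tsv(path) -> pd.DataFrame:
    """Effects table (locus, alpha/effect, se, p)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df
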