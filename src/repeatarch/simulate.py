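"""Synthetic cohort generator with planted effects.

Emulates a resequenced dioecious weed cohort: ~186 individuals from paired
agricultural/natural populations spanning 38-41 degrees latitude, two
admixing varietal ancestries whose mixture follows the latitudinal
gradient, a ~594 Mb genome whose size varies through repeat content
(16 repeat classes, rDNA most dispersed), 20-35x sequencing coverage with
gamma-Poisson (overdispersed) region depths, a large-effect gene
copy-number locus in the ATP-synthesis pathway, ~97 polygenic flowering
loci, and sex/habitat/geography effects on flowering time and growth rate.

Every stage records its ground truth (`SimTruth`) so each pipeline stage
can be checked for parameter recovery, and the phenotype is stored as the
exact sum of its recorded components.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .depth import DepthSummary
from .intervals import DEFAULT_TAXONOMY, INTERVAL_COLUMNS, REPEAT_CLASSES
from .lmm import kinship_centered

# Class-level defaults.  Mean haploid bp abundances put the four largest
# classes at their observed medians (Ty3 86.8 Mb, Copia 59.0, Helitron
# 50.1, unknown-LTR 49.3) with realistic fills elsewhere; CVs make rDNA
# the most variable classes.
DEFAULT_CLASS_ABUNDANCE_MB = {
    "Ty3": 86.8,
    "Copia": 59.0,
    "Helitron": 50.1,
    "LTR_unknown": 49.3,
    "LINE": 8.0,
    "TIR_Tc1Mariner": 3.0,
    "TIR_PiFHarbinger": 2.0,
    "TIR_hAT": 4.0,
    "TIR_Mutator": 5.0,
    "TIR_CACTA": 4.0,
    "rDNA_5S": 2.0,
    "rDNA_18S": 3.0,
    "rDNA_28S": 4.0,
    "simple_repeat": 10.0,
    "low_complexity": 5.0,
    "unknown_repeat": 30.0,
}

DEFAULT_CLASS_CV_PCT = {
    "Ty3": 10.0,
    "Copia": 10.0,
    "Helitron": 12.0,
    "LTR_unknown": 12.0,
    "LINE": 15.0,
    "TIR_Tc1Mariner": 15.0,
    "TIR_PiFHarbinger": 15.0,
    "TIR_hAT": 15.0,
    "TIR_Mutator": 15.0,
    "TIR_CACTA": 15.0,
    "rDNA_5S": 35.0,
    "rDNA_18S": 40.0,
    "rDNA_28S": 30.0,
    "simple_repeat": 15.0,
    "low_complexity": 12.0,
    "unknown_repeat": 20.0,
}

DEFAULT_ELEMENT_LENGTH_BP = {
    "Ty3": 6000,
    "Copia": 5000,
    "Helitron": 5000,
    "LTR_unknown": 4000,
    "LINE": 3000,
    "TIR_Tc1Mariner": 1500,
    "TIR_PiFHarbinger": 1200,
    "TIR_hAT": 2000,
    "TIR_Mutator": 2500,
    "TIR_CACTA": 3000,
    "rDNA_5S": 500,
    "rDNA_18S": 1800,
    "rDNA_28S": 3400,
    "simple_repeat": 300,
    "low_complexity": 400,
    "unknown_repeat": 1000,
}

# bp-per-degree latitudinal clines for a few classes (negative = declines
# northward), emulating the observed decline of repeat content with latitude
DEFAULT_CLINES_BP_PER_DEGREE = {
    "Ty3": -2.0e6,
    "LTR_unknown": -1.5e6,
    "rDNA_28S": -0.8e6,
    "unknown_repeat": 0.5e6,
}


@dataclass
class SimConfig:
    """All knobs of the synthetic cohort; defaults are the study conditions."""

    seed: int = 0
    n_individuals: int = 186
    n_chromosomes: int = 16
    single_copy_bp: int = 269_000_000
    n_genes: int = 2000
    gene_length_mean_bp: float = 3000.0
    gene_length_sigma: float = 0.4  # lognormal sigma of gene lengths
    elements_per_class: int = 250
    class_abundance_mb: dict = field(
        default_factory=lambda: dict(DEFAULT_CLASS_ABUNDANCE_MB)
    )
    class_cv_pct: dict = field(default_factory=lambda: dict(DEFAULT_CLASS_CV_PCT))
    element_length_bp: dict = field(
        default_factory=lambda: dict(DEFAULT_ELEMENT_LENGTH_BP)
    )
    element_length_sigma: float = 0.5
    cline_bp_per_degree: dict = field(
        default_factory=lambda: dict(DEFAULT_CLINES_BP_PER_DEGREE)
    )
    shared_load_cv: float = 0.05  # per-individual repeat-load multiplier CV

    # population structure
    n_populations: int = 17
    latitude_range: tuple = (38.0, 41.0)
    longitude_range: tuple = (-96.0, -84.0)
    n_snps: int = 1000
    fst: float = 0.15  # allele-frequency divergence of the two varieties
    ancestral_maf_range: tuple = (0.05, 0.95)
    ancestry_lat_slope: float = -1.5  # logit ancestry per degree latitude
    ancestry_noise_sd: float = 0.5

    # sequencing depth
    depth_range: tuple = (20.0, 35.0)
    depth_overdispersion: float = 0.01  # excess CV^2 beyond Poisson per region
    read_length_bp: int = 150
    zero_noise: bool = False

    # flowering-time architecture (days)
    beta_gs_days_per_mb: float = 0.08  # +0.8 days per 10 Mb
    sex_effect_days: float = -8.7  # males earlier
    habitat_effect_days: float = 2.0  # natural habitat later
    sex_habitat_effect_days: float = 2.5
    lat_effect_days_per_degree: float = -1.5
    long_effect_days_per_degree: float = -0.2
    ancestry_effect_days: float = -3.0
    flowering_intercept_days: float = 60.0
    sigma_g2: float = 4.0
    sigma_e2: float = 4.0
    n_polygenic: int = 97
    polygenic_decay: float = 0.25  # geometric decay of per-locus variance shares
    pgv_target_share: float = 0.35  # PGV share of flowering-time variance
    atp_target_share: float = 0.20  # ATP-locus share of flowering-time variance
    alpha: dict | None = None  # explicit per-locus effects (overrides calibration)
    beta_atp_days_per_copy: float | None = None  # overrides calibration
    atp_cn_base: int = 2
    atp_cn_gamma_shape: float = 2.0
    atp_cn_gamma_scale: float = 1.75
    atp_lat_slope_copies_per_degree: float = -0.5  # CN declines northward
    atp_ancestry_loading_copies: float = 3.0  # CN higher with var. rudis ancestry

    # growth rate (height gain per day)
    beta_gs_growth_per_mb: float = -0.004
    growth_intercept: float = 4.5
    growth_sigma_g2: float = 0.05
    growth_sigma_e2: float = 0.15

    # recombination landscape (per 100 kb window, unitless 4Ner)
    recomb_log_mean: float = -3.0
    recomb_log_sd: float = 1.0

    def __post_init__(self):
        for name in ("sigma_g2", "sigma_e2", "growth_sigma_g2", "growth_sigma_e2"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if min(self.depth_range) <= 0:
            raise ValueError("depth range must be positive")
        if any(v < 0 for v in self.class_cv_pct.values()):
            raise ValueError("class CVs must be >= 0")
        if self.depth_overdispersion < 0:
            raise ValueError("depth_overdispersion must be >= 0")

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("depth_range", "latitude_range", "longitude_range",
                    "ancestral_maf_range"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(_jsonable(dataclasses.asdict(self)), fh, sort_keys=False)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


@dataclass
class SimTruth:
    """Ground truth recorded by the generator."""

    genome_size_bp: pd.Series
    element_rho: pd.DataFrame  # individuals x repeat elements (haploid ratio)
    gene_rho: pd.DataFrame  # individuals x genes
    atp_gene_id: str
    atp_diploid_cn: pd.Series
    ancestry: pd.Series
    kinship: pd.DataFrame
    polygenic_loci: list = field(default_factory=list)
    alpha: pd.Series | None = None
    beta_atp: float = np.nan
    beta_gs: float = np.nan
    flowering_components: pd.DataFrame | None = None
    growth_components: pd.DataFrame | None = None


@dataclass
class SimBundle:
    """Everything the pipeline consumes, in memory."""

    config: SimConfig
    annotation: pd.DataFrame
    chrom_sizes: dict
    covariates: pd.DataFrame
    genotypes: pd.DataFrame
    snp_positions: pd.DataFrame
    kinship: pd.DataFrame
    feature_depths: pd.DataFrame
    depth_summaries: list
    phenotypes: pd.DataFrame
    recombination: pd.DataFrame
    truth: SimTruth


def _lognormal_multiplier(rng, cv, size):
    """Mean-1 lognormal draws with coefficient of variation ``cv``."""
    if cv <= 0:
        return np.ones(size)
    s2 = np.log1p(cv**2)
    return rng.lognormal(mean=-s2 / 2.0, sigma=np.sqrt(s2), size=size)


# ---------------------------------------------------------------------------
# Stage 1: annotation


def simulate_annotation(config: SimConfig, rng=None):
    """Place genes and repeat elements on the reference chromosomes.

    Elements of a class never overlap each other (cross-class overlaps may
    occur and are left to priority resolution).  Deterministic given seed.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    ref_repeat_bp = sum(
        config.elements_per_class * config.element_length_bp[c]
        for c in REPEAT_CLASSES
    )
    ref_len = config.single_copy_bp + ref_repeat_bp
    chrom_len = int(np.ceil(ref_len / config.n_chromosomes))
    chrom_sizes = {f"chr{i + 1:02d}": chrom_len for i in range(config.n_chromosomes)}
    requested_bp = (
        config.n_genes * config.gene_length_mean_bp + 1.5 * ref_repeat_bp
    )
    if requested_bp > 0.5 * ref_len:
        raise ValueError("genome too small to place the requested features")
    chroms = list(chrom_sizes)

    rows = []

    def _place(n, mean_len, sigma, feature_class, prefix):
        lengths = np.maximum(
            30, rng.lognormal(np.log(mean_len) - sigma**2 / 2, sigma, n)
        ).astype(np.int64)
        chrom_idx = rng.integers(0, len(chroms), n)
        placed_by_chrom = {c: [] for c in chroms}
        kept = 0
        for i in np.argsort(chrom_idx, kind="stable"):
            c = chroms[chrom_idx[i]]
            L = int(lengths[i])
            start = int(rng.integers(0, chrom_len - L))
            # reject class-internal overlap with already placed elements
            ok = all(start + L <= s or start >= e for s, e in placed_by_chrom[c])
            if not ok:
                continue
            placed_by_chrom[c].append((start, start + L))
            kept += 1
            rows.append((c, start, start + L, feature_class, f"{prefix}{kept:05d}"))

    _place(config.n_genes, config.gene_length_mean_bp, config.gene_length_sigma,
           "gene", "gene")
    for cls in REPEAT_CLASSES:
        _place(
            config.elements_per_class,
            config.element_length_bp[cls],
            config.element_length_sigma,
            cls,
            f"{cls}_",
        )
    ann = pd.DataFrame(rows, columns=INTERVAL_COLUMNS)
    ann = ann.sort_values(["chrom", "start"]).reset_index(drop=True)
    return ann, DEFAULT_TAXONOMY, chrom_sizes


def simulate_recombination(config: SimConfig, chrom_sizes, rng,
                           window_bp: int = 100_000) -> pd.DataFrame:
    """Lognormal per-window population-scaled recombination rates (4Ner)."""
    rows = []
    for chrom, size in chrom_sizes.items():
        n_win = int(np.ceil(size / window_bp))
        vals = rng.lognormal(config.recomb_log_mean, config.recomb_log_sd, n_win)
        for w in range(n_win):
            rows.append(
                (chrom, w * window_bp, min((w + 1) * window_bp, size), vals[w])
            )
    return pd.DataFrame(
        rows, columns=["chrom", "window_start", "window_end", "recomb_4Ner"]
    )


# ---------------------------------------------------------------------------
# Stage 2: population structure and genotypes


def simulate_population(config: SimConfig, rng=None):
    """Two admixing varietal ancestries along a latitudinal gradient.

    Returns (genotypes, snp_positions, covariates, kinship).  Admixture is
    a logistic function of latitude plus noise; genotypes are binomial
    draws from the admixed allele frequencies; habitats are paired within
    populations; sexes 1:1.
    """
    rng = np.random.default_rng(config.seed + 1) if rng is None else rng
    n = config.n_individuals
    npop = config.n_populations
    lat = rng.uniform(*config.latitude_range, npop)
    lon = rng.uniform(*config.longitude_range, npop)
    pop_idx = np.arange(n) % npop
    habitat = np.where(np.arange(n) % (2 * npop) < npop, "Ag", "Nat")
    ind_lat = lat[pop_idx] + rng.normal(0.0, 0.02, n)  # paired sites <25 km apart
    ind_lon = lon[pop_idx] + rng.normal(0.0, 0.02, n)
    sex = np.array(["M", "F"])[rng.permutation(np.arange(n) % 2)]
    lat_mid = np.mean(config.latitude_range)
    logit = config.ancestry_lat_slope * (ind_lat - lat_mid) + rng.normal(
        0.0, config.ancestry_noise_sd, n
    )
    ancestry = 1.0 / (1.0 + np.exp(-logit))  # var. rudis proportion

    p0 = rng.uniform(*config.ancestral_maf_range, config.n_snps)
    if config.fst > 0:
        a = p0 * (1.0 - config.fst) / config.fst
        b = (1.0 - p0) * (1.0 - config.fst) / config.fst
        p1 = rng.beta(a, b)
        p2 = rng.beta(a, b)
    else:
        p1 = p2 = p0
    freq = ancestry[:, None] * p1[None, :] + (1.0 - ancestry[:, None]) * p2[None, :]
    dosage = rng.binomial(2, freq).astype(float)

    ids = [f"ind{i + 1:04d}" for i in range(n)]
    loci = [f"snp{j + 1:06d}" for j in range(config.n_snps)]
    genotypes = pd.DataFrame(dosage, index=pd.Index(ids, name="individual_id"),
                             columns=loci)
    chrom_names = [f"chr{i + 1:02d}" for i in range(config.n_chromosomes)]
    snp_positions = pd.DataFrame(
        {
            "locus": loci,
            "chrom": [chrom_names[c] for c in rng.integers(
                0, config.n_chromosomes, config.n_snps)],
            "pos": rng.integers(1, config.single_copy_bp // config.n_chromosomes,
                                config.n_snps),
        }
    ).set_index("locus")
    covariates = pd.DataFrame(
        {
            "sex": sex,
            "habitat": habitat,
            "latitude": ind_lat,
            "longitude": ind_lon,
            "ancestry": ancestry,
            "population": [f"pop{p + 1:02d}" for p in pop_idx],
        },
        index=genotypes.index,
    )
    kinship = kinship_centered(genotypes)
    return genotypes, snp_positions, covariates, kinship


# ---------------------------------------------------------------------------
# Stage 3: copy numbers and genome sizes


def simulate_copy_number(
    config: SimConfig, annotation: pd.DataFrame, covariates: pd.DataFrame, rng=None
) -> SimTruth:
    """Per-individual per-element copy numbers and true genome sizes.

    rho(ind, element) = class baseline x shared individual load x per-class
    lognormal multiplier x latitudinal cline factor.  Gene copy number is 1
    except at the planted ATP-pathway locus (diploid 2-14).
    """
    rng = np.random.default_rng(config.seed + 2) if rng is None else rng
    ids = covariates.index
    n = len(ids)
    rep = annotation[annotation["feature_class"].isin(REPEAT_CLASSES)]
    genes = annotation[annotation["feature_class"] == "gene"]
    lat_mid = np.mean(config.latitude_range)
    lat_dev = covariates["latitude"].to_numpy() - lat_mid

    shared = _lognormal_multiplier(rng, config.shared_load_cv, n)
    rho = np.zeros((n, len(rep)))
    col_of = {fid: j for j, fid in enumerate(rep["feature_id"])}
    floored = 0
    for cls, grp in rep.groupby("feature_class"):
        lens = (grp["end"] - grp["start"]).to_numpy(float)
        target_bp = config.class_abundance_mb[cls] * 1e6
        baseline = target_bp / lens.sum()  # equal rho across class elements
        cv = config.class_cv_pct.get(cls, 0.0) / 100.0
        mult = shared * _lognormal_multiplier(rng, cv, n)
        slope = config.cline_bp_per_degree.get(cls, 0.0)
        cline = 1.0 + slope * lat_dev / target_bp
        neg = cline < 0
        if neg.any():
            floored += int(neg.sum())
            cline = np.maximum(cline, 0.0)
        ind_factor = baseline * mult * cline
        cols = [col_of[f] for f in grp["feature_id"]]
        rho[:, cols] = ind_factor[:, None]
    if floored:
        import warnings

        warnings.warn(
            f"{floored} individual/class cline factors went negative; floored at 0",
            stacklevel=2,
        )
    element_rho = pd.DataFrame(rho, index=ids, columns=rep["feature_id"].to_numpy())

    # gene copy numbers: single copy except the planted ATP-pathway CNV
    gene_ids = genes["feature_id"].to_numpy()
    atp_gene_id = gene_ids[len(gene_ids) // 2]
    # the ATP-pathway CNV is clinal: copy number declines northward and rises
    # with var. rudis ancestry, so it is partially structured like the SNPs
    anc = covariates["ancestry"].to_numpy()
    atp_latent = (
        rng.gamma(config.atp_cn_gamma_shape, config.atp_cn_gamma_scale, n)
        + config.atp_lat_slope_copies_per_degree * lat_dev
        + config.atp_ancestry_loading_copies * (anc - anc.mean())
    )
    atp_dip = config.atp_cn_base + np.round(np.maximum(atp_latent, 0.0))
    gene_rho = pd.DataFrame(1.0, index=ids, columns=gene_ids)
    gene_rho[atp_gene_id] = atp_dip / 2.0

    rep_lens = (rep["end"] - rep["start"]).to_numpy(float)
    gene_lens = pd.Series(
        (genes["end"] - genes["start"]).to_numpy(float), index=gene_ids
    )
    genome_size = (
        config.single_copy_bp
        + element_rho.to_numpy() @ rep_lens
        + (gene_rho - 1.0).to_numpy() @ gene_lens.to_numpy()
    )
    return SimTruth(
        genome_size_bp=pd.Series(genome_size, index=ids, name="genome_size_bp"),
        element_rho=element_rho,
        gene_rho=gene_rho,
        atp_gene_id=atp_gene_id,
        atp_diploid_cn=pd.Series(atp_dip, index=ids, name="atp_diploid_cn"),
        ancestry=covariates["ancestry"],
        kinship=pd.DataFrame(),  # filled by simulate_all
    )


# ---------------------------------------------------------------------------
# Stage 4: sequencing coverage


def simulate_coverage(
    config: SimConfig, truth: SimTruth, annotation: pd.DataFrame, rng=None
):
    """Per-feature mean depths and per-individual depth summaries.

    Region read counts are gamma-Poisson: mean = base_depth * rho *
    length / read_length, variance = mean + overdispersion * mean^2.  The
    genome-wide summed depth is the noisy feature depth total plus the
    single-copy background, so it stays consistent with the true genome
    size and base depth.
    """
    rng = np.random.default_rng(config.seed + 3) if rng is None else rng
    ids = truth.element_rho.index
    n = len(ids)
    base = rng.uniform(*config.depth_range, n)

    rho = pd.concat([truth.gene_rho, truth.element_rho], axis=1)
    ann = annotation.set_index("feature_id")
    lens = (ann["end"] - ann["start"]).astype(float).reindex(rho.columns)
    mu_depth = base[:, None] * rho.to_numpy()
    if config.zero_noise:
        depths = mu_depth
    else:
        mu_reads = mu_depth * lens.to_numpy()[None, :] / config.read_length_bp
        phi = config.depth_overdispersion
        if phi > 0:
            lam = rng.gamma(1.0 / phi, mu_reads * phi)
        else:
            lam = mu_reads
        reads = rng.poisson(lam)
        depths = reads * config.read_length_bp / lens.to_numpy()[None, :]
    feature_depths = pd.DataFrame(depths, index=ids, columns=rho.columns)

    gene_cols = list(truth.gene_rho.columns)
    gene_len_total = float(lens[gene_cols].sum())
    background_bp = config.single_copy_bp - gene_len_total
    summaries = []
    feat_bp_sum = depths @ lens.to_numpy()
    for i, ind in enumerate(ids):
        total = base[i] * background_bp + feat_bp_sum[i]
        summaries.append(
            DepthSummary(
                individual_id=ind,
                total_depth_sum=float(total),
                per_gene_mean_depth=feature_depths.loc[ind, gene_cols],
            )
        )
    return feature_depths, summaries


# ---------------------------------------------------------------------------
# Stage 5: phenotypes


def simulate_phenotypes(
    config: SimConfig,
    truth: SimTruth,
    genotypes: pd.DataFrame,
    covariates: pd.DataFrame,
    K: pd.DataFrame,
    rng=None,
):
    """Flowering time and growth rate as exact sums of recorded components.

    The ATP-locus and polygenic effect scales are calibrated so those
    components hold their configured shares (default 20% and 35%) of the
    realized phenotypic variance; explicit ``alpha`` /
    ``beta_atp_days_per_copy`` bypass the calibration.
    """
    rng = np.random.default_rng(config.seed + 4) if rng is None else rng
    ids = covariates.index
    n = len(ids)
    lat_mid = np.mean(config.latitude_range)
    lon_mid = np.mean(config.longitude_range)

    gs_mb = truth.genome_size_bp.to_numpy() / 1e6
    comp = {
        "intercept": np.full(n, config.flowering_intercept_days),
        "genome_size": config.beta_gs_days_per_mb * (gs_mb - gs_mb.mean()),
        "sex": np.where(covariates["sex"] == "M", config.sex_effect_days, 0.0),
        "habitat": np.where(
            covariates["habitat"] == "Nat", config.habitat_effect_days, 0.0
        ),
        "sex_habitat": np.where(
            (covariates["sex"] == "M") & (covariates["habitat"] == "Nat"),
            config.sex_habitat_effect_days,
            0.0,
        ),
        "latitude": config.lat_effect_days_per_degree
        * (covariates["latitude"].to_numpy() - lat_mid),
        "longitude": config.long_effect_days_per_degree
        * (covariates["longitude"].to_numpy() - lon_mid),
        "ancestry": config.ancestry_effect_days
        * (covariates["ancestry"].to_numpy() - covariates["ancestry"].mean()),
    }
    Kmat = K.loc[ids, ids].to_numpy(float)
    L = np.linalg.cholesky(Kmat + 1e-8 * np.eye(n))
    comp["kinship_u"] = np.sqrt(config.sigma_g2) * (L @ rng.standard_normal(n))
    comp["residual"] = np.sqrt(config.sigma_e2) * rng.standard_normal(n)

    # polygenic architecture: geometric-decay variance shares over L loci
    # causal loci are common and weakly ancestry-aligned: a mixed-model GWA
    # can only ever recover effects not confounded with genome-wide structure,
    # so the planted architecture lives on the detectable loci
    dosage = genotypes.to_numpy(float)
    freqs = dosage.mean(axis=0) / 2.0
    anc_dev = covariates["ancestry"].to_numpy() - covariates["ancestry"].mean()
    with np.errstate(invalid="ignore"):
        anc_corr = np.abs(
            (dosage - dosage.mean(axis=0)).T @ anc_dev
            / (dosage.std(axis=0) * anc_dev.std() * len(anc_dev))
        )
    common = (freqs >= 0.1) & (freqs <= 0.9)
    cutoff = np.nanmedian(anc_corr[common])
    eligible = np.where(common & (anc_corr <= cutoff))[0]
    if eligible.size < config.n_polygenic:
        raise ValueError("not enough common SNPs for the polygenic architecture")
    loci_idx = np.sort(rng.choice(eligible, config.n_polygenic, replace=False))
    loci = [genotypes.columns[j] for j in loci_idx]
    decay = config.polygenic_decay
    w = decay ** np.arange(config.n_polygenic)
    w /= w.sum()
    var_dos = dosage[:, loci_idx].var(axis=0, ddof=1)
    signs = rng.choice([-1.0, 1.0], config.n_polygenic)
    alpha_unit = signs * np.sqrt(w / np.maximum(var_dos, 1e-12))
    pgv_unit = dosage[:, loci_idx] @ alpha_unit  # = 2 * sum alpha * p

    atp_cn = truth.atp_diploid_cn.to_numpy(float)
    atp_unit = atp_cn - atp_cn.mean()

    other = sum(v for k, v in comp.items() if k != "intercept")
    v_other = float(np.var(other, ddof=1))
    a_share, b_share = config.atp_target_share, config.pgv_target_share
    rest = 1.0 - a_share - b_share
    if config.beta_atp_days_per_copy is not None:
        beta_atp = config.beta_atp_days_per_copy
    else:
        beta_atp = np.sqrt(
            a_share / rest * v_other / max(np.var(atp_unit, ddof=1), 1e-12)
        )
    if config.alpha is not None:
        alpha = pd.Series(config.alpha, dtype=float)
        loci = list(alpha.index)
        pgv = genotypes[loci].to_numpy(float) @ alpha.to_numpy()
    else:
        scale = np.sqrt(
            b_share / rest * v_other / max(np.var(pgv_unit, ddof=1), 1e-12)
        )
        alpha = pd.Series(alpha_unit * scale, index=loci, name="alpha")
        pgv = pgv_unit * scale
    comp["atp_locus"] = beta_atp * atp_unit
    comp["polygenic"] = pgv - pgv.mean()

    flowering_components = pd.DataFrame(comp, index=ids)
    flowering = flowering_components.sum(axis=1)

    gcomp = {
        "intercept": np.full(n, config.growth_intercept),
        "genome_size": config.beta_gs_growth_per_mb * (gs_mb - gs_mb.mean()),
        "kinship_u": np.sqrt(config.growth_sigma_g2)
        * (L @ rng.standard_normal(n)),
        "residual": np.sqrt(config.growth_sigma_e2) * rng.standard_normal(n),
    }
    growth_components = pd.DataFrame(gcomp, index=ids)
    growth = growth_components.sum(axis=1)

    phenotypes = pd.DataFrame(
        {"flowering_time": flowering, "growth_rate": growth}, index=ids
    )
    truth.polygenic_loci = list(loci)
    truth.alpha = alpha
    truth.beta_atp = float(beta_atp)
    truth.beta_gs = config.beta_gs_days_per_mb
    truth.flowering_components = flowering_components
    truth.growth_components = growth_components
    return phenotypes, truth


# ---------------------------------------------------------------------------
# Orchestration and writers


def simulate_all(config: SimConfig) -> SimBundle:
    """Run every stage in dependency order under one master seed."""
    annotation, taxonomy, chrom_sizes = simulate_annotation(config)
    recomb = simulate_recombination(
        config, chrom_sizes, np.random.default_rng(config.seed + 5)
    )
    genotypes, snp_positions, covariates, kinship = simulate_population(config)
    truth = simulate_copy_number(config, annotation, covariates)
    truth.kinship = kinship
    feature_depths, summaries = simulate_coverage(config, truth, annotation)
    phenotypes, truth = simulate_phenotypes(
        config, truth, genotypes, covariates, kinship
    )
    return SimBundle(
        config=config,
        annotation=annotation,
        chrom_sizes=chrom_sizes,
        covariates=covariates,
        genotypes=genotypes,
        snp_positions=snp_positions,
        kinship=kinship,
        feature_depths=feature_depths,
        depth_summaries=summaries,
        phenotypes=phenotypes,
        recombination=recomb,
        truth=truth,
    )


def write_vcf(genotypes: pd.DataFrame, snp_positions: pd.DataFrame, path) -> None:
    """Minimal diploid VCF (GT only) from a 0/1/2 dosage matrix."""
    gt_code = {0: "0/0", 1: "0/1", 2: "1/1"}
    samples = list(genotypes.index)
    pos_sorted = snp_positions.sort_values(["chrom", "pos"])
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom in pos_sorted["chrom"].unique():
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(samples)
            + "\n"
        )
        for locus, row in pos_sorted.iterrows():
            gts = "\t".join(
                gt_code[int(round(genotypes.at[s, locus]))] for s in samples
            )
            fh.write(
                f"{row['chrom']}\t{int(row['pos'])}\t{locus}\tA\tT\t.\tPASS\t.\tGT\t{gts}\n"
            )


def write_bundle(bundle: SimBundle, out_dir) -> None:
    """Persist the bundle as plain standard-format files."""
    from .depth import write_depth_bed
    from .intervals import write_gff3

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle.config.to_yaml(out / "sim_config.yaml")
    write_gff3(bundle.annotation, out / "annotation.gff3")
    bundle.covariates.to_csv(out / "covariates.tsv", sep="\t")
    bundle.phenotypes.to_csv(out / "phenotypes.tsv", sep="\t")
    bundle.kinship.to_csv(out / "kinship.tsv", sep="\t")
    bundle.recombination.to_csv(out / "recombination.tsv", sep="\t", index=False)
    write_vcf(bundle.genotypes, bundle.snp_positions, out / "genotypes.vcf")
    depth_dir = out / "depths"
    depth_dir.mkdir(exist_ok=True)
    totals = {}
    for s in bundle.depth_summaries:
        write_depth_bed(
            bundle.annotation,
            bundle.feature_depths.loc[s.individual_id],
            depth_dir / f"{s.individual_id}.bed",
        )
        totals[s.individual_id] = s.total_depth_sum
    with open(out / "total_depth_sums.json", "w") as fh:
        json.dump(totals, fh, indent=1)
    truth = bundle.truth
    truth.genome_size_bp.to_csv(out / "truth_genome_size.tsv", sep="\t")
    truth.flowering_components.to_csv(out / "truth_flowering_components.tsv", sep="\t")
    scalars = {
        "atp_gene_id": truth.atp_gene_id,
        "beta_atp": truth.beta_atp,
        "beta_gs": truth.beta_gs,
        "polygenic_loci": truth.polygenic_loci,
        "alpha": {k: float(v) for k, v in truth.alpha.items()},
    }
    with open(out / "truth.json", "w") as fh:
        json.dump(_jsonable(scalars), fh, indent=1)
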