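"""End-to-end orchestration: simulate/ingest -> quantify -> models -> report.

Stages run in dependency order; every stage's output is a plain pandas
object persisted as TSV/JSON so stages are independently inspectable.
Rerunning with the same config and seed reproduces the report exactly
(the REML optimizer is deterministic).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .depth import (
    abundance_dispersion,
    class_abundance,
    copy_number,
    genome_size_range_pct,
    genome_size_table,
)
from .gwas import MixedModelGWAS, polygenic_value, transform_pgv
from .intervals import (
    DEFAULT_TAXONOMY,
    REPEAT_CLASSES,
    density_regression,
    resolve_overlaps,
    window_density,
)
from .lmm import build_model_spec, fit_lmm, r2_nakagawa
from .simulate import SimBundle, SimConfig, simulate_all

logger = logging.getLogger(__name__)

STAGES = ("simulate", "quantify", "windows", "abundance", "phenotype", "gwa", "pgv", "joint")

_DEPENDENCIES = {
    "quantify": ("simulate",),
    "windows": ("simulate",),
    "abundance": ("quantify",),
    "phenotype": ("quantify",),
    "gwa": ("simulate", "quantify"),
    "pgv": ("gwa",),
    "joint": ("quantify", "gwa", "pgv"),
}


class DependencyError(RuntimeError):
    """A stage was requested whose inputs were toggled off."""


class StageError(RuntimeError):
    """A stage failed; the failing stage is named in the message."""


@dataclass
class RunConfig:
    """Pipeline run configuration."""

    sim: SimConfig = field(default_factory=SimConfig)
    out_dir: str | None = None
    seed: int | None = None  # overrides sim.seed when given
    fdr_alpha: float = 0.10
    bonferroni_alpha: float = 0.10
    window_bp: int = 100_000
    min_fragment_bp: int = 21
    cn_gwa_kinship: bool = True
    snp_gwa_kinship: bool = True
    stages: tuple = STAGES

    def __post_init__(self):
        for thr in (self.fdr_alpha, self.bonferroni_alpha):
            if not (0 < thr <= 1):
                raise ValueError("thresholds must lie in (0, 1]")
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stage(s): {sorted(unknown)}")
        if self.seed is not None:
            self.sim = dataclasses.replace(self.sim, seed=self.seed)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "sim" in raw:
            raw["sim"] = SimConfig(**raw["sim"])
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        return cls(**raw)

    def config_hash(self) -> str:
        payload = yaml.safe_dump(
            {
                "sim": _plain(dataclasses.asdict(self.sim)),
                "run": {
                    k: _plain(v)
                    for k, v in dataclasses.asdict(self).items()
                    if k != "sim"
                },
            },
            sort_keys=True,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _plain(obj):
    if isinstance(obj, dict):
        return {str(k): _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj


@dataclass
class ReportBundle:
    """Structured results of one pipeline run."""

    genome_size: pd.DataFrame | None = None
    abundance: pd.DataFrame | None = None
    abundance_stats: pd.DataFrame | None = None
    window_regressions: pd.DataFrame | None = None
    abundance_model_terms: pd.DataFrame | None = None
    phenotype_model_terms: pd.DataFrame | None = None
    gwa_snp: pd.DataFrame | None = None
    gwa_cn: pd.DataFrame | None = None
    gwa_summary: dict = field(default_factory=dict)
    pgv: pd.DataFrame | None = None
    joint_model_terms: pd.DataFrame | None = None
    joint_model_r2: dict = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)

    def to_json_dict(self) -> dict:
        def frame(df):
            if df is None:
                return None
            return json.loads(df.to_json(orient="split", double_precision=15))

        return {
            "genome_size": frame(self.genome_size),
            "abundance_stats": frame(self.abundance_stats),
            "window_regressions": frame(self.window_regressions),
            "abundance_model_terms": frame(self.abundance_model_terms),
            "phenotype_model_terms": frame(self.phenotype_model_terms),
            "gwa_summary": _plain(self.gwa_summary),
            "pgv": frame(self.pgv),
            "joint_model_terms": frame(self.joint_model_terms),
            "joint_model_r2": _plain(self.joint_model_r2),
            "provenance": _plain(self.provenance),
        }


def run_pipeline(config: RunConfig, bundle: SimBundle | None = None) -> ReportBundle:
    """Execute the enabled stages in dependency order.

    A pre-built :class:`SimBundle` (e.g. loaded from files) may be passed
    to skip simulation.  Stage failures raise :class:`StageError` naming
    the stage; partial outputs written so far are retained.
    """
    enabled = set(config.stages)
    if bundle is not None:
        enabled.add("simulate")
    for stage in sorted(enabled, key=STAGES.index):
        for dep in _DEPENDENCIES.get(stage, ()):
            if dep not in enabled:
                raise DependencyError(
                    f"stage {stage!r} requires {dep!r}, which is toggled off"
                )
    report = ReportBundle()
    out = Path(config.out_dir) if config.out_dir else None
    if out:
        out.mkdir(parents=True, exist_ok=True)
    state: dict = {}

    def _run(stage, fn):
        if stage not in enabled:
            logger.info("stage %s skipped", stage)
            return
        t0 = time.perf_counter()
        try:
            fn()
        except (DependencyError,):
            raise
        except Exception as err:
            raise StageError(f"stage {stage!r} failed: {err}") from err
        logger.info("stage %s done in %.2fs", stage, time.perf_counter() - t0)

    def do_simulate():
        state["bundle"] = bundle if bundle is not None else simulate_all(config.sim)

    def do_quantify():
        b = state["bundle"]
        repeats = b.annotation[b.annotation["feature_class"].isin(REPEAT_CLASSES)]
        resolved = resolve_overlaps(
            repeats, DEFAULT_TAXONOMY, min_fragment_bp=config.min_fragment_bp
        )
        state["resolved"] = resolved
        cn = copy_number(b.feature_depths, b.depth_summaries)
        state["cn"] = cn
        gs = genome_size_table(b.depth_summaries)
        abund = class_abundance(cn, resolved, DEFAULT_TAXONOMY, by="class")
        report.genome_size = gs
        report.abundance = abund
        report.abundance_stats = abundance_dispersion(abund)
        if out:
            gs.to_csv(out / "genome_size.tsv", sep="\t")
            abund.to_csv(out / "abundance.tsv", sep="\t")
            report.abundance_stats.to_csv(out / "abundance_stats.tsv", sep="\t")

    def do_windows():
        b = state["bundle"]
        resolved = state["resolved"]
        with_genes = pd.concat(
            [resolved, b.annotation[b.annotation["feature_class"] == "gene"]]
        )
        wt = window_density(
            with_genes, window_bp=config.window_bp, chrom_sizes=b.chrom_sizes
        )
        wt = wt.rename(columns={"gene": "cds_density"})
        if "cds_density" not in wt.columns:
            wt["cds_density"] = 0.0
        wt = wt.merge(
            b.recombination, on=["chrom", "window_start", "window_end"], how="left"
        )
        # superfamily densities: sum of member-class densities
        rows = []
        for sf in sorted({DEFAULT_TAXONOMY.superfamily_of(c) for c in REPEAT_CLASSES}):
            members = [
                c
                for c in REPEAT_CLASSES
                if DEFAULT_TAXONOMY.superfamily_of(c) == sf and c in wt.columns
            ]
            if not members:
                continue
            wt[sf + "__density"] = wt[members].sum(axis=1)
            fit = density_regression(wt, sf + "__density")
            rows.append(
                {
                    "superfamily": sf,
                    "slope_cds": fit.slope_cds,
                    "se_cds": fit.se_cds,
                    "p_cds": fit.p_cds,
                    "slope_recomb": fit.slope_recomb,
                    "se_recomb": fit.se_recomb,
                    "p_recomb": fit.p_recomb,
                    "r_squared": fit.r_squared,
                    "degenerate": fit.degenerate,
                }
            )
        report.window_regressions = pd.DataFrame(rows).set_index("superfamily")
        state["windows"] = wt
        if out:
            report.window_regressions.to_csv(out / "window_regressions.tsv", sep="\t")

    def do_abundance_models():
        b = state["bundle"]
        data = b.covariates.join(report.abundance)
        rows = []
        for cls in report.abundance.columns:
            spec = build_model_spec("abundance", response=cls)
            fit = fit_lmm(data, spec, K=b.kinship)
            tt = fit.term_table()
            tt.insert(0, "repeat_class", cls)
            rows.append(tt.reset_index())
        report.abundance_model_terms = pd.concat(rows, ignore_index=True)
        if out:
            report.abundance_model_terms.to_csv(out / "abundance_model_terms.tsv", sep="\t", index=False)

    def do_phenotype_models():
        b = state["bundle"]
        data = b.covariates.join(b.phenotypes)
        data["genome_size_mb"] = report.genome_size["genome_size_mb"]
        rows = []
        for trait in ("flowering_time", "growth_rate"):
            spec = build_model_spec("phenotype", response=trait)
            fit = fit_lmm(data, spec, K=b.kinship)
            tt = fit.term_table()
            tt.insert(0, "trait", trait)
            marg, cond = r2_nakagawa(fit)
            tt["marginal_r2"] = marg
            tt["conditional_r2"] = cond
            rows.append(tt.reset_index())
            state[f"phenotype_model_{trait}"] = fit
        report.phenotype_model_terms = pd.concat(rows, ignore_index=True)
        if out:
            report.phenotype_model_terms.to_csv(out / "phenotype_model_terms.tsv", sep="\t", index=False)

    def do_gwa():
        b = state["bundle"]
        y = b.phenotypes["flowering_time"]
        K = b.kinship.to_numpy(float)
        snp_scan = MixedModelGWAS(
            use_kinship=config.snp_gwa_kinship,
            fdr_alpha=config.fdr_alpha,
            bonferroni_alpha=config.bonferroni_alpha,
        ).fit(b.genotypes, y, K=K)
        state["snp_scan"] = snp_scan
        report.gwa_snp = snp_scan.results_
        gene_cols = list(b.truth.gene_rho.columns) if b.truth else [
            c for c in state["cn"].rho.columns if c.startswith("gene")
        ]
        gene_cn = state["cn"].diploid[gene_cols]
        cn_scan = MixedModelGWAS(
            use_kinship=config.cn_gwa_kinship,
            fdr_alpha=config.fdr_alpha,
            bonferroni_alpha=config.bonferroni_alpha,
        ).fit(gene_cn, y, K=K)
        state["cn_scan"] = cn_scan
        report.gwa_cn = cn_scan.results_
        top_gene = cn_scan.results_["p"].idxmin()
        state["top_cn_gene"] = top_gene
        report.gwa_summary = {
            "n_snps_tested": int(snp_scan.results_["p"].notna().sum()),
            "n_snps_fdr": int((snp_scan.results_["q"] < config.fdr_alpha).sum()),
            "n_snps_bonferroni": int(
                snp_scan.results_["bonferroni_significant"].sum()
            ),
            "n_genes_tested": int(cn_scan.results_["p"].notna().sum()),
            "n_genes_fdr": int((cn_scan.results_["q"] < config.fdr_alpha).sum()),
            "n_genes_bonferroni": int(
                cn_scan.results_["bonferroni_significant"].sum()
            ),
            "top_cn_gene": top_gene,
            "top_cn_gene_p": float(cn_scan.results_.loc[top_gene, "p"]),
        }
        if out:
            snp_scan.results_.to_csv(out / "gwa_snp.tsv", sep="\t")
            cn_scan.results_.to_csv(out / "gwa_cn.tsv", sep="\t")

    def do_pgv():
        b = state["bundle"]
        scan = state["snp_scan"]
        loci = scan.selected_loci(config.fdr_alpha)
        report.gwa_summary["n_pgv_loci"] = len(loci)
        if len(loci) == 0:
            raise StageError(
                "stage 'pgv' failed: no loci pass the FDR threshold; "
                "polygenic value undefined"
            )
        raw = polygenic_value(scan.results_["effect"], b.genotypes, loci)
        table = transform_pgv(raw)
        state["pgv"] = table
        report.pgv = table.to_frame()
        if out:
            report.pgv.to_csv(out / "pgv.tsv", sep="\t")

    def do_joint_model():
        b = state["bundle"]

        def z(x):
            x = np.asarray(x, float)
            return (x - x.mean()) / x.std(ddof=1)

        data = b.covariates.join(b.phenotypes)
        data["genome_size_z"] = z(report.genome_size["genome_size_mb"])
        data["atp_copy_number_z"] = z(
            state["cn"].diploid[state["top_cn_gene"]]
        )
        data["pgv_ft_z"] = state["pgv"].z
        spec = build_model_spec("joint")
        fit = fit_lmm(data, spec, K=b.kinship)
        report.joint_model_terms = fit.term_table()
        marg, cond = r2_nakagawa(fit)
        report.joint_model_r2 = {"marginal": marg, "conditional": cond}
        if out:
            report.joint_model_terms.to_csv(out / "joint_model_terms.tsv", sep="\t")

    _run("simulate", do_simulate)
    _run("quantify", do_quantify)
    _run("windows", do_windows)
    _run("abundance", do_abundance_models)
    _run("phenotype", do_phenotype_models)
    _run("gwa", do_gwa)
    _run("pgv", do_pgv)
    _run("joint", do_joint_model)

    report.provenance = {
        "config_hash": config.config_hash(),
        "seed": config.sim.seed,
        "version": __version__,
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "stages": sorted(enabled, key=STAGES.index),
    }
    if report.genome_size is not None:
        report.provenance["genome_size_range_pct"] = genome_size_range_pct(
            report.genome_size["genome_size_mb"]
        )
    if out:
        write_report(report, out)
    return report


def write_report(report: ReportBundle, out_dir) -> None:
    """Write report.json plus a human-readable summary."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "report.json", "w") as fh:
        json.dump(report.to_json_dict(), fh, indent=1, default=_json_default)
    lines = ["# pipeline summary", ""]
    if report.genome_size is not None:
        gs = report.genome_size["genome_size_mb"]
        lines += [
            f"genome size (Mb): min {gs.min():.1f}, max {gs.max():.1f}, "
            f"mean {gs.mean():.1f} "
            f"(largest exceeds smallest by {genome_size_range_pct(gs):.1f}%)",
        ]
    if report.gwa_summary:
        s = report.gwa_summary
        lines += [
            f"SNP GWA: {s['n_snps_fdr']}/{s['n_snps_tested']} pass FDR, "
            f"{s['n_snps_bonferroni']} pass Bonferroni",
            f"gene CN GWA: top gene {s['top_cn_gene']} (p={s['top_cn_gene_p']:.3g})",
        ]
    if report.joint_model_terms is not None:
        lines.append("")
        lines.append("flowering time ~ genetic predictors (chi2, p, partial r2):")
        for term, row in report.joint_model_terms.iterrows():
            lines.append(
                f"  {term}: chi2={row['chi2']:.1f}, p={row['p']:.3g}, "
                f"partial_r2={row['partial_r2']:.3f}"
            )
        lines.append(
            f"  marginal R2={report.joint_model_r2['marginal']:.3f}, "
            f"conditional R2={report.joint_model_r2['conditional']:.3f}"
        )
    (out / "summary.txt").write_text("\n".join(lines) + "\n")


def _json_default(obj):
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")
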