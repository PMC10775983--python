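"""Read-depth quantification: genome size, copy number, repeat abundance.

The input contract is per-region mean-depth tables (one per individual, as
emitted by region-depth summarizers run on BAMs) plus each individual's
genome-wide summed depth.  Genome size is the summed per-base depth scaled
by the median coverage of genic regions (genes being, on average, single
copy); region copy number is the region's mean depth scaled by the same
median, doubled for the diploid scale.  Class bp abundances are
copy-number-weighted element lengths summed within classes, superfamilies
or orders, on the haploid scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .intervals import (
    DEFAULT_TAXONOMY,
    REPEAT_CLASSES,
    RepeatTaxonomy,
    _open_text,
    validate_intervals,
)


@dataclass
class DepthSummary:
    """Per-individual depth summary.

    total_depth_sum is the cumulative per-base depth over all reference
    positions (read-bases); per_gene_mean_depth maps gene_id -> mean depth.
    """

    individual_id: str
    total_depth_sum: float
    per_gene_mean_depth: pd.Series
    median_genic_coverage: float = field(init=False)

    def __post_init__(self):
        if self.total_depth_sum < 0:
            raise ValueError(f"{self.individual_id}: negative total_depth_sum")
        self.median_genic_coverage = median_genic_coverage(self.per_gene_mean_depth)


@dataclass
class CopyNumberMatrix:
    """Individuals x features copy-number estimates.

    ``rho`` is the haploid-relative depth ratio (single-copy features have
    rho ~ 1); ``diploid`` is 2*rho, the diploid copy number.
    """

    rho: pd.DataFrame

    @property
    def diploid(self) -> pd.DataFrame:
        return 2.0 * self.rho


def median_genic_coverage(per_gene_mean_depth: pd.Series) -> float:
    """Median over genes of per-gene mean depth."""
    depths = pd.Series(per_gene_mean_depth).dropna()
    if len(depths) == 0:
        raise ValueError("no genes with finite depth")
    return float(np.median(depths.to_numpy(float)))


def estimate_genome_size(summary: DepthSummary) -> float:
    """Haploid genome size in bp: total summed depth / median genic coverage."""
    med = summary.median_genic_coverage
    if med <= 0:
        raise ValueError(
            f"{summary.individual_id}: median genic coverage is {med}; "
            "cannot scale summed depth to genome size"
        )
    return summary.total_depth_sum / med


def genome_size_table(summaries) -> pd.DataFrame:
    """Genome sizes for a collection of DepthSummary, in bp and Mb."""
    rows = [
        (s.individual_id, estimate_genome_size(s)) for s in _as_summary_list(summaries)
    ]
    df = pd.DataFrame(rows, columns=["individual_id", "genome_size_bp"])
    df["genome_size_mb"] = df["genome_size_bp"] / 1e6
    return df.set_index("individual_id")


def genome_size_range_pct(sizes) -> float:
    """Percent by which the largest genome size exceeds the smallest."""
    arr = np.asarray(sizes, float)
    if arr.size < 2:
        raise ValueError("need at least two genome sizes")
    return 100.0 * (arr.max() - arr.min()) / arr.min()


def _as_summary_list(summaries):
    if isinstance(summaries, dict):
        return list(summaries.values())
    return list(summaries)


def copy_number(depths: pd.DataFrame, summaries) -> CopyNumberMatrix:
    """Scale per-feature mean depth by each individual's median genic coverage.

    ``depths`` is individuals (rows) x features (columns) mean depth.
    """
    by_id = {s.individual_id: s for s in _as_summary_list(summaries)}
    missing = [i for i in depths.index if i not in by_id]
    if missing:
        raise ValueError(f"no DepthSummary for individual(s): {missing[:5]}")
    med = pd.Series(
        {i: by_id[i].median_genic_coverage for i in depths.index}, dtype=float
    )
    if (med <= 0).any():
        bad = med[med <= 0].index.tolist()
        raise ValueError(f"non-positive median genic coverage for: {bad[:5]}")
    rho = depths.div(med, axis=0)
    return CopyNumberMatrix(rho=rho)


def class_abundance(
    cn: CopyNumberMatrix,
    annotation: pd.DataFrame,
    taxonomy: RepeatTaxonomy = DEFAULT_TAXONOMY,
    by: str = "class",
) -> pd.DataFrame:
    """Per-individual bp abundance of each repeat class/superfamily/order.

    abundance(ind, class) = sum over elements of the class of
    rho_element(ind) * element_length, i.e. the haploid-genome bp total.
    """
    ann = validate_intervals(annotation)
    ann = ann[ann["feature_class"].isin(REPEAT_CLASSES)]
    missing = set(ann["feature_id"]) - set(cn.rho.columns)
    if missing:
        raise ValueError(
            f"annotated element(s) missing from copy-number matrix: "
            f"{sorted(missing)[:5]}"
        )
    groups = ann["feature_class"].map(lambda c: taxonomy.group(c, by))
    all_groups = sorted({taxonomy.group(c, by) for c in REPEAT_CLASSES})
    out = pd.DataFrame(0.0, index=cn.rho.index, columns=all_groups)
    for g, idx in groups.groupby(groups).groups.items():
        sub = ann.loc[idx]
        w = (sub["end"] - sub["start"]).to_numpy(float)
        out[g] = cn.rho[sub["feature_id"].to_numpy()].to_numpy() @ w
    return out


def abundance_dispersion(table: pd.DataFrame) -> pd.DataFrame:
    """Across-individual variance (n-1) and CV (%) of each class abundance.

    CV = 100 * sd / mean; classes with zero mean get CV = NaN and
    ``cv_defined = False``.
    """
    if len(table) < 2:
        raise ValueError("need >= 2 individuals for dispersion statistics")
    mean = table.mean(axis=0)
    sd = table.std(axis=0, ddof=1)
    var = sd**2
    cv = 100.0 * sd / mean.where(mean != 0)
    return pd.DataFrame(
        {
            "mean_bp": mean,
            "variance_bp2": var,
            "cv_pct": cv,
            "cv_defined": mean != 0,
        }
    )


# ---------------------------------------------------------------------------
# I/O


def read_depth_bed(path) -> pd.Series:
    """Read one individual's per-region mean-depth BED.

    Columns: chrom, start, end, feature_id, mean_depth (the dialect of
    common region-depth summarizers).  Gzip transparent.  Returns a Series
    feature_id -> mean depth.
    """
    ids, vals = [], []
    with _open_text(path) as fh:
        for k, line in enumerate(fh):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 5:
                raise ValueError(f"{path}: line {k + 1} has fewer than 5 columns")
            ids.append(parts[3])
            vals.append(float(parts[4]))
    return pd.Series(vals, index=pd.Index(ids, name="feature_id"), name="mean_depth")


def write_depth_bed(annotation: pd.DataFrame, depths: pd.Series, path) -> None:
    ann = validate_intervals(annotation)
    with _open_text(path, "wt") as fh:
        for row in ann.itertuples(index=False):
            fh.write(
                f"{row.chrom}\t{row.start}\t{row.end}\t{row.feature_id}\t"
                f"{depths[row.feature_id]:.6g}\n"
            )
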