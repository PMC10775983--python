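"""Genomic-interval algebra for repeat annotations.

Feature sets are plain pandas DataFrames with the columns
``chrom, start, end, feature_class, feature_id`` and 0-based half-open
coordinates.  GFF3 input (1-based inclusive) is converted at the I/O
boundary.  The central operation is priority resolution of overlapping
repeat annotations (rDNA > known TE > simple/low-complexity > unknown),
followed by window densities, gene distances and the density-on-
CDS/recombination regression.
"""

from __future__ import annotations

import gzip
from bisect import bisect_left, bisect_right
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd
import statsmodels.api as sm

INTERVAL_COLUMNS = ["chrom", "start", "end", "feature_class", "feature_id"]

#: Closed vocabulary of feature classes.
FEATURE_CLASSES = (
    "gene",
    "CDS",
    "rDNA_5S",
    "rDNA_18S",
    "rDNA_28S",
    "Ty3",
    "Copia",
    "LTR_unknown",
    "LINE",
    "Helitron",
    "TIR_Tc1Mariner",
    "TIR_PiFHarbinger",
    "TIR_hAT",
    "TIR_Mutator",
    "TIR_CACTA",
    "simple_repeat",
    "low_complexity",
    "unknown_repeat",
)

#: The 16 repeat classes quantified per individual (everything but gene/CDS).
REPEAT_CLASSES = tuple(c for c in FEATURE_CLASSES if c not in ("gene", "CDS"))


class GenomicInterval(NamedTuple):
    chrom: str
    start: int
    end: int
    feature_class: str
    feature_id: str

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class RepeatTaxonomy:
    """Maps repeat classes to (order, superfamily) and resolution priority.

    Lower ``priority_rank`` wins when annotations overlap.
    """

    classification: dict = field(default_factory=lambda: dict(_DEFAULT_CLASSIFICATION))
    priority_rank: dict = field(default_factory=lambda: dict(_DEFAULT_PRIORITY))

    def __post_init__(self):
        missing = set(self.classification) - set(self.priority_rank)
        if missing:
            raise ValueError(f"classes without a priority rank: {sorted(missing)}")

    @property
    def classes(self) -> tuple:
        return tuple(self.classification)

    def order_of(self, feature_class: str) -> str:
        return self.classification[feature_class][0]

    def superfamily_of(self, feature_class: str) -> str:
        return self.classification[feature_class][1]

    def group(self, feature_class: str, by: str) -> str:
        if by == "class":
            return feature_class
        if by == "order":
            return self.order_of(feature_class)
        if by == "superfamily":
            return self.superfamily_of(feature_class)
        raise ValueError(f"unknown grouping {by!r} (use class/order/superfamily)")


_DEFAULT_CLASSIFICATION = {
    # class: (order, superfamily)
    "rDNA_5S": ("rDNA", "5S"),
    "rDNA_18S": ("rDNA", "18S"),
    "rDNA_28S": ("rDNA", "28S"),
    "Ty3": ("LTR", "Ty3"),
    "Copia": ("LTR", "Copia"),
    "LTR_unknown": ("LTR", "unknown_LTR"),
    "LINE": ("LINE", "LINE"),
    "Helitron": ("Helitron", "Helitron"),
    "TIR_Tc1Mariner": ("TIR", "Tc1_Mariner"),
    "TIR_PiFHarbinger": ("TIR", "PIF_Harbinger"),
    "TIR_hAT": ("TIR", "hAT"),
    "TIR_Mutator": ("TIR", "Mutator"),
    "TIR_CACTA": ("TIR", "CACTA"),
    "simple_repeat": ("simple", "simple_repeat"),
    "low_complexity": ("simple", "low_complexity"),
    "unknown_repeat": ("unknown", "unknown_repeat"),
}

# rDNA > known TE > simple repeats and low complexity > unknown repeats
_DEFAULT_PRIORITY = {
    "rDNA_5S": 0,
    "rDNA_18S": 0,
    "rDNA_28S": 0,
    "Ty3": 1,
    "Copia": 1,
    "LTR_unknown": 1,
    "LINE": 1,
    "Helitron": 1,
    "TIR_Tc1Mariner": 1,
    "TIR_PiFHarbinger": 1,
    "TIR_hAT": 1,
    "TIR_Mutator": 1,
    "TIR_CACTA": 1,
    "simple_repeat": 2,
    "low_complexity": 2,
    "unknown_repeat": 3,
}

DEFAULT_TAXONOMY = RepeatTaxonomy()


def validate_intervals(intervals: pd.DataFrame, allowed_classes=None) -> pd.DataFrame:
    """Check coordinates and the closed feature-class vocabulary.

    Returns the frame with canonical column order and integer coordinates.
    """
    missing = [c for c in INTERVAL_COLUMNS if c not in intervals.columns]
    if missing:
        raise ValueError(f"interval table missing columns: {missing}")
    out = intervals.loc[:, INTERVAL_COLUMNS].copy()
    out["start"] = out["start"].astype(np.int64)
    out["end"] = out["end"].astype(np.int64)
    bad = out["start"] >= out["end"]
    if bad.any():
        row = out[bad].iloc[0]
        raise ValueError(
            f"invalid interval (start >= end): {row.feature_id} "
            f"{row.chrom}:{row.start}-{row.end}"
        )
    if (out["start"] < 0).any():
        raise ValueError("negative start coordinate")
    allowed = set(allowed_classes if allowed_classes is not None else FEATURE_CLASSES)
    unknown = set(out["feature_class"]) - allowed
    if unknown:
        raise ValueError(f"unknown feature_class label(s): {sorted(unknown)}")
    return out


def resolve_overlaps(
    intervals: pd.DataFrame,
    taxonomy: RepeatTaxonomy = DEFAULT_TAXONOMY,
    min_fragment_bp: int = 21,
) -> pd.DataFrame:
    """Resolve overlapping repeat annotations by class priority.

    Each base is assigned to the highest-priority covering feature
    (rDNA > known TE > simple/low-complexity > unknown).  Ties within a
    priority level go to the longer feature, then the smaller start, then
    the lexicographically smaller feature_id.  Fragments shorter than
    ``min_fragment_bp`` (default: anything left with <= 20 bp) are dropped
    as likely false positives.

    Output intervals are pairwise disjoint and sorted by (chrom, start).
    """
    iv = validate_intervals(intervals, allowed_classes=taxonomy.classes)
    if min_fragment_bp < 1:
        raise ValueError("min_fragment_bp must be >= 1")
    rank = taxonomy.priority_rank
    iv = iv.assign(
        _rank=iv["feature_class"].map(rank),
        _len=iv["end"] - iv["start"],
    )
    out_rows = []
    for chrom, grp in iv.groupby("chrom", sort=True):
        grp = grp.sort_values(
            ["_rank", "_len", "start", "feature_id"],
            ascending=[True, False, True, True],
            kind="mergesort",
        )
        # occupied: sorted disjoint list of (start, end) already claimed
        occ_start: list[int] = []
        occ_end: list[int] = []
        for row in grp.itertuples(index=False):
            frags = _subtract_occupied(row.start, row.end, occ_start, occ_end)
            for s, e in frags:
                _insert_occupied(s, e, occ_start, occ_end)
                out_rows.append((chrom, s, e, row.feature_class, row.feature_id))
    out = pd.DataFrame(out_rows, columns=INTERVAL_COLUMNS)
    out = out[(out["end"] - out["start"]) >= min_fragment_bp]
    return out.sort_values(["chrom", "start", "end"]).reset_index(drop=True)


def _subtract_occupied(start, end, occ_start, occ_end):
    """Fragments of [start, end) not covered by the occupied list."""
    frags = []
    i = bisect_right(occ_end, start)  # first occupied block that may overlap
    cur = start
    while cur < end and i < len(occ_start):
        s, e = occ_start[i], occ_end[i]
        if s >= end:
            break
        if s > cur:
            frags.append((cur, min(s, end)))
        cur = max(cur, e)
        i += 1
    if cur < end:
        frags.append((cur, end))
    return frags


def _insert_occupied(start, end, occ_start, occ_end):
    """Insert a disjoint block, coalescing with abutting neighbours."""
    i = bisect_left(occ_start, start)
    # merge with predecessor if it abuts
    if i > 0 and occ_end[i - 1] == start:
        start = occ_start[i - 1]
        del occ_start[i - 1], occ_end[i - 1]
        i -= 1
    if i < len(occ_start) and occ_start[i] == end:
        end = occ_end[i]
        del occ_start[i], occ_end[i]
    occ_start.insert(i, start)
    occ_end.insert(i, end)


def window_density(
    intervals: pd.DataFrame,
    window_bp: int = 100_000,
    chrom_sizes: dict | None = None,
    classes=None,
) -> pd.DataFrame:
    """Per-window fraction of unique bp occupied by each feature class.

    ``intervals`` must be disjoint (run :func:`resolve_overlaps` first;
    genes/CDS may be included for CDS density).  Windows tile each
    chromosome from 0; a trailing short window is kept, normalized by its
    true width, and flagged with ``short_window=True``.
    """
    if window_bp <= 0:
        raise ValueError("window_bp must be positive")
    iv = validate_intervals(intervals)
    if classes is None:
        classes = sorted(iv["feature_class"].unique())
    if chrom_sizes is None:
        chrom_sizes = iv.groupby("chrom")["end"].max().to_dict()
    rows = []
    index = {}
    for chrom, size in chrom_sizes.items():
        n_win = int(np.ceil(size / window_bp))
        for w in range(n_win):
            ws = w * window_bp
            we = min(ws + window_bp, size)
            index[(chrom, ws)] = len(rows)
            rows.append(
                {
                    "chrom": chrom,
                    "window_start": ws,
                    "window_end": we,
                    "short_window": (we - ws) < window_bp,
                    **{c: 0.0 for c in classes},
                }
            )
    cls_set = set(classes)
    for row in iv.itertuples(index=False):
        if row.feature_class not in cls_set:
            continue
        size = chrom_sizes.get(row.chrom)
        if size is None:
            continue
        w0 = row.start // window_bp
        w1 = (min(row.end, size) - 1) // window_bp
        for w in range(w0, w1 + 1):
            ws = w * window_bp
            we = min(ws + window_bp, size)
            ov = min(row.end, we) - max(row.start, ws)
            if ov > 0:
                rows[index[(row.chrom, ws)]][row.feature_class] += ov
    out = pd.DataFrame(rows)
    width = (out["window_end"] - out["window_start"]).astype(float)
    for c in classes:
        out[c] = out[c] / width
    return out


def distance_to_nearest_gene(
    repeats: pd.DataFrame, genes: pd.DataFrame
) -> pd.Series:
    """Distance (bp) from each repeat to its nearest gene.

    Dialect of the standard closest-feature tool: overlapping -> 0,
    book-ended -> 1, otherwise gap + 1.  Repeats on chromosomes without any
    gene get NaN (flagged missing).
    """
    rep = validate_intervals(repeats)
    gen = validate_intervals(genes)
    if len(gen) == 0:
        raise ValueError("empty gene set")
    by_chrom = {}
    for chrom, grp in gen.groupby("chrom"):
        grp_sorted = grp.sort_values("start")
        g_start = grp_sorted["start"].to_numpy()
        g_end = grp_sorted["end"].to_numpy()
        # running max of ends over genes sorted by start: overlap queries
        run_max_end = np.maximum.accumulate(g_end)
        ends_sorted = np.sort(g_end)
        by_chrom[chrom] = (g_start, run_max_end, ends_sorted)
    dists = np.full(len(rep), np.nan)
    for i, row in enumerate(rep.itertuples(index=False)):
        hit = by_chrom.get(row.chrom)
        if hit is None:
            continue  # gene-free chromosome: flagged missing
        g_start, run_max_end, ends_sorted = hit
        k = np.searchsorted(g_start, row.end, side="left")
        if k > 0 and run_max_end[k - 1] > row.start:
            dists[i] = 0.0  # overlap
            continue
        best = np.inf
        if k < len(g_start):  # nearest gene to the right (abutting -> gap 0 -> 1)
            best = g_start[k] - row.end + 1
        j = np.searchsorted(ends_sorted, row.start, side="right")
        if j > 0:  # nearest gene end to the left
            best = min(best, row.start - ends_sorted[j - 1] + 1)
        dists[i] = best
    return pd.Series(dists, index=rep.index, name="distance_to_gene")


@dataclass
class DensityRegression:
    """OLS fit of a repeat class's window density on CDS density and 4Ner."""

    focal_class: str
    n_windows: int
    degenerate: bool
    intercept: float = np.nan
    slope_cds: float = np.nan
    slope_recomb: float = np.nan
    se_cds: float = np.nan
    se_recomb: float = np.nan
    f_cds: float = np.nan
    f_recomb: float = np.nan
    p_cds: float = np.nan
    p_recomb: float = np.nan
    r_squared: float = np.nan


def density_regression(
    windows: pd.DataFrame, focal_class: str, cds_col: str = "cds_density",
    recomb_col: str = "recomb_4Ner",
) -> DensityRegression:
    """Multiple regression of per-window class density on CDS density and
    population-scaled recombination rate, with per-term (drop-one) F tests.

    Degenerate inputs (constant response, collinear predictors, <4 usable
    windows) yield a flagged result without p-values.
    """
    cols = [focal_class, cds_col, recomb_col]
    for c in cols:
        if c not in windows.columns:
            raise ValueError(f"window table lacks column {c!r}")
    data = windows[cols].replace([np.inf, -np.inf], np.nan).dropna()
    n = len(data)
    y = data[focal_class].to_numpy(float)
    X = sm.add_constant(data[[cds_col, recomb_col]].to_numpy(float))
    if n < 4 or np.var(y) == 0 or np.linalg.matrix_rank(X) < X.shape[1]:
        return DensityRegression(focal_class=focal_class, n_windows=n, degenerate=True)
    fit = sm.OLS(y, X).fit()
    # continuous single-df terms: type III (drop-one) F equals t^2
    t = fit.tvalues
    return DensityRegression(
        focal_class=focal_class,
        n_windows=n,
        degenerate=False,
        intercept=fit.params[0],
        slope_cds=fit.params[1],
        slope_recomb=fit.params[2],
        se_cds=fit.bse[1],
        se_recomb=fit.bse[2],
        f_cds=t[1] ** 2,
        f_recomb=t[2] ** 2,
        p_cds=fit.pvalues[1],
        p_recomb=fit.pvalues[2],
        r_squared=fit.rsquared,
    )


# ---------------------------------------------------------------------------
# I/O


def _open_text(path, mode="rt"):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def read_bed(path) -> pd.DataFrame:
    """Read a BED (3+1: class in column 4, optional id in column 5)."""
    rows = []
    with _open_text(path) as fh:
        for k, line in enumerate(fh):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 4:
                raise ValueError(f"{path}: line {k + 1} has fewer than 4 columns")
            feature_id = parts[4] if len(parts) > 4 else f"feat{k}"
            rows.append((parts[0], int(parts[1]), int(parts[2]), parts[3], feature_id))
    return pd.DataFrame(rows, columns=INTERVAL_COLUMNS)


def write_bed(intervals: pd.DataFrame, path) -> None:
    iv = validate_intervals(intervals)
    with _open_text(path, "wt") as fh:
        for row in iv.itertuples(index=False):
            fh.write(
                f"{row.chrom}\t{row.start}\t{row.end}\t{row.feature_class}\t{row.feature_id}\n"
            )


def read_gff3(path, class_attribute: str = "repeat_class") -> pd.DataFrame:
    """Read features from GFF3, converting to 0-based half-open coordinates.

    The feature class is taken from the ``repeat_class`` attribute when
    present, otherwise from the GFF3 type column; the id from ``ID``.
    """
    rows = []
    with _open_text(path) as fh:
        for k, line in enumerate(fh):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 9:
                raise ValueError(f"{path}: line {k + 1} is not GFF3")
            attrs = dict(
                kv.split("=", 1) for kv in parts[8].split(";") if "=" in kv
            )
            fclass = attrs.get(class_attribute, parts[2])
            fid = attrs.get("ID", f"feat{k}")
            rows.append((parts[0], int(parts[3]) - 1, int(parts[4]), fclass, fid))
    return pd.DataFrame(rows, columns=INTERVAL_COLUMNS)


def write_gff3(intervals: pd.DataFrame, path, source: str = "repeatarch") -> None:
    iv = validate_intervals(intervals)
    with _open_text(path, "wt") as fh:
        fh.write("##gff-version 3\n")
        for row in iv.itertuples(index=False):
            ftype = "gene" if row.feature_class in ("gene", "CDS") else "repeat_region"
            fh.write(
                f"{row.chrom}\t{source}\t{ftype}\t{row.start + 1}\t{row.end}\t.\t.\t.\t"
                f"ID={row.feature_id};repeat_class={row.feature_class}\n"
            )


def read_recombination_tsv(path) -> pd.DataFrame:
    """Read per-window population recombination rates (chrom, start, end, 4Ner)."""
    df = pd.read_csv(path, sep="\t")
    df.columns = ["chrom", "window_start", "window_end", "recomb_4Ner"][: len(df.columns)]
    return df
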