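"""Interval algebra: priority resolution, densities, gene distances."""

import numpy as np
import pandas as pd
import pytest

from repeatarch import (
    DEFAULT_TAXONOMY,
    density_regression,
    distance_to_nearest_gene,
    resolve_overlaps,
    window_density,
)
from repeatarch.intervals import read_bed, read_gff3, write_bed, write_gff3

from conftest import random_intervals


def iv(*rows):
    return pd.DataFrame(
        rows, columns=["chrom", "start", "end", "feature_class", "feature_id"]
    )


# ---------------------------------------------------------------------------
# brute-force oracles


def paint_oracle(intervals, taxonomy=DEFAULT_TAXONOMY, min_fragment_bp=21):
    """Per-base painting: each base goes to the best covering feature."""
    out_rows = []
    for chrom, grp in intervals.groupby("chrom"):
        L = int(grp["end"].max())
        best = np.full(L, -1, dtype=int)
        keys = []
        for pos_idx, row in enumerate(grp.itertuples(index=False)):
            keys.append(
                (
                    taxonomy.priority_rank[row.feature_class],
                    -(row.end - row.start),
                    row.start,
                    row.feature_id,
                )
            )
        order = sorted(range(len(keys)), key=lambda i: keys[i])
        rows = list(grp.itertuples(index=False))
        for i in order:
            row = rows[i]
            seg = best[row.start : row.end]  # view into the paint array
            seg[seg == -1] = i
        # assemble runs
        run_start = None
        cur = -1
        for pos in range(L + 1):
            v = best[pos] if pos < L else -1
            if v != cur:
                if cur != -1:
                    row = rows[cur]
                    out_rows.append(
                        (chrom, run_start, pos, row.feature_class, row.feature_id)
                    )
                run_start = pos
                cur = v
    out = iv(*out_rows)
    out = out[(out["end"] - out["start"]) >= min_fragment_bp]
    return out.sort_values(["chrom", "start"]).reset_index(drop=True)


def density_oracle(intervals, window_bp, chrom_sizes):
    rows = []
    for chrom, size in chrom_sizes.items():
        sub = intervals[intervals["chrom"] == chrom]
        for ws in range(0, size, window_bp):
            we = min(ws + window_bp, size)
            counts = {}
            for row in sub.itertuples(index=False):
                for pos in range(row.start, row.end):
                    if ws <= pos < we:
                        counts[row.feature_class] = counts.get(row.feature_class, 0) + 1
            rows.append((chrom, ws, we, {k: v / (we - ws) for k, v in counts.items()}))
    return rows


def distance_oracle(repeats, genes):
    out = []
    for r in repeats.itertuples(index=False):
        cands = genes[genes["chrom"] == r.chrom]
        if len(cands) == 0:
            out.append(np.nan)
            continue
        best = np.inf
        for g in cands.itertuples(index=False):
            if g.start < r.end and g.end > r.start:
                best = 0
            else:
                gap = max(g.start - r.end, r.start - g.end)
                best = min(best, gap + 1)
        out.append(best)
    return np.array(out, dtype=float)


# ---------------------------------------------------------------------------
# resolve_overlaps


def test_priority_forces_rdna_over_te():
    res = resolve_overlaps(
        iv(("c1", 100, 200, "rDNA_5S", "r1"), ("c1", 150, 300, "Ty3", "t1"))
    )
    assert res.values.tolist() == [
        ["c1", 100, 200, "rDNA_5S", "r1"],
        ["c1", 200, 300, "Ty3", "t1"],
    ]


def test_short_trimmed_fragment_removed():
    # TE trimmed down to exactly 20 bp ([280, 300)) is dropped ...
    res = resolve_overlaps(
        iv(("c1", 100, 280, "rDNA_5S", "r1"), ("c1", 100, 300, "Ty3", "t1"))
    )
    assert res["feature_id"].tolist() == ["r1"]
    # ... while a 21 bp fragment survives
    res21 = resolve_overlaps(
        iv(("c1", 100, 279, "rDNA_5S", "r1"), ("c1", 100, 300, "Ty3", "t1"))
    )
    assert res21["feature_id"].tolist() == ["r1", "t1"]
    assert res21.set_index("feature_id").loc["t1", "start"] == 279


def test_equal_priority_tie_goes_to_longer_feature():
    res = resolve_overlaps(
        iv(("c1", 100, 400, "Ty3", "long"), ("c1", 50, 300, "Copia", "short"))
    )
    # Ty3 is longer: keeps [100,400); Copia keeps [50,100)
    by_id = res.set_index("feature_id")
    assert (by_id.loc["long", "start"], by_id.loc["long", "end"]) == (100, 400)
    assert (by_id.loc["short", "start"], by_id.loc["short", "end"]) == (50, 100)


def test_resolve_rejects_bad_inputs():
    with pytest.raises(ValueError, match="unknown feature_class"):
        resolve_overlaps(iv(("c1", 0, 10, "martian", "x")))
    with pytest.raises(ValueError, match="start >= end"):
        resolve_overlaps(iv(("c1", 10, 10, "Ty3", "x")))


@pytest.mark.parametrize("seed", range(5))
def test_resolve_matches_perbase_painting_oracle(seed):
    rng = np.random.default_rng(seed)
    fixture = random_intervals(rng, 200)
    got = resolve_overlaps(fixture)
    expected = paint_oracle(fixture)
    pd.testing.assert_frame_equal(got, expected)


def test_resolve_is_idempotent(rng):
    fixture = random_intervals(rng, 150)
    once = resolve_overlaps(fixture)
    twice = resolve_overlaps(once)
    pd.testing.assert_frame_equal(once, twice)


def test_resolution_conserves_covered_bases(rng):
    # output bp <= unique covered bp; equal when no fragment is short
    fixture = random_intervals(rng, 100)
    res = resolve_overlaps(fixture, min_fragment_bp=1)
    covered = np.zeros(60_000, bool)
    for row in fixture.itertuples(index=False):
        covered[row.start : row.end] = True
    assert (res["end"] - res["start"]).sum() == covered.sum()
    res21 = resolve_overlaps(fixture, min_fragment_bp=21)
    assert (res21["end"] - res21["start"]).sum() <= covered.sum()


# ---------------------------------------------------------------------------
# window_density


def test_full_and_empty_windows():
    ann = iv(("c1", 0, 1000, "Ty3", "t1"))
    wt = window_density(ann, window_bp=1000, chrom_sizes={"c1": 3000})
    assert wt.loc[0, "Ty3"] == 1.0
    assert wt.loc[1, "Ty3"] == 0.0 and wt.loc[2, "Ty3"] == 0.0


def test_trailing_short_window_normalized_and_flagged():
    ann = iv(("c1", 1000, 1250, "Ty3", "t1"))
    wt = window_density(ann, window_bp=1000, chrom_sizes={"c1": 1500})
    last = wt.iloc[-1]
    assert last["short_window"] and last["window_end"] == 1500
    assert last["Ty3"] == pytest.approx(250 / 500)


def test_window_density_rejects_nonpositive_width():
    with pytest.raises(ValueError):
        window_density(iv(("c1", 0, 10, "Ty3", "t")), window_bp=0)


def test_window_density_matches_perbase_count_oracle(rng):
    fixture = resolve_overlaps(random_intervals(rng, 80, chrom_len=20_000))
    sizes = {"chrA": 20_000}
    wt = window_density(fixture, window_bp=3000, chrom_sizes=sizes)
    for chrom, ws, we, dens in density_oracle(fixture, 3000, sizes):
        row = wt[(wt["chrom"] == chrom) & (wt["window_start"] == ws)].iloc[0]
        for cls, d in dens.items():
            assert row[cls] == pytest.approx(d, abs=1e-12)


def test_window_row_sums_of_disjoint_classes_bounded(rng):
    fixture = resolve_overlaps(random_intervals(rng, 300, chrom_len=30_000))
    wt = window_density(fixture, window_bp=5000, chrom_sizes={"chrA": 30_000})
    cls_cols = [c for c in wt.columns
                if c not in ("chrom", "window_start", "window_end", "short_window")]
    assert (wt[cls_cols].sum(axis=1) <= 1 + 1e-9).all()


# ---------------------------------------------------------------------------
# distance_to_nearest_gene


@pytest.mark.parametrize(
    "repeat,gene,expected",
    [
        ((100, 200), (150, 400), 0.0),  # overlap
        ((100, 200), (200, 300), 1.0),  # book-ended
        ((100, 200), (250, 300), 51.0),  # gap of 50 -> 51
        ((300, 400), (100, 200), 101.0),  # gene left of repeat
    ],
)
def test_gene_distance_dialect(repeat, gene, expected):
    reps = iv(("c1", *repeat, "Ty3", "t1"))
    genes = iv(("c1", *gene, "gene", "g1"))
    assert distance_to_nearest_gene(reps, genes).iloc[0] == expected


def test_gene_distance_missing_on_genefree_chromosome():
    reps = iv(("c2", 0, 100, "Ty3", "t1"))
    genes = iv(("c1", 0, 100, "gene", "g1"))
    assert np.isnan(distance_to_nearest_gene(reps, genes).iloc[0])
    with pytest.raises(ValueError, match="empty gene set"):
        distance_to_nearest_gene(reps, genes.iloc[:0])


def test_gene_distance_matches_allpairs_oracle(rng):
    reps = random_intervals(rng, 120, chroms=("chrA", "chrB"))
    genes = random_intervals(rng, 40, classes=["gene"], chroms=("chrA", "chrB"))
    got = distance_to_nearest_gene(reps, genes).to_numpy()
    expected = distance_oracle(reps, genes)
    np.testing.assert_allclose(got, expected)


# ---------------------------------------------------------------------------
# density regression


def _windows_frame(rng, n=300):
    cds = rng.uniform(0, 0.4, n)
    rec = rng.lognormal(-3, 1, n)
    return pd.DataFrame({"cds_density": cds, "recomb_4Ner": rec})


def test_density_regression_recovers_planted_slope(rng):
    wt = _windows_frame(rng)
    wt["Ty3"] = 0.5 - 0.3 * wt["cds_density"] + rng.normal(0, 0.01, len(wt))
    fit = density_regression(wt, "Ty3")
    assert not fit.degenerate
    assert abs(fit.slope_cds - (-0.3)) < 3 * fit.se_cds
    assert fit.p_cds < 1e-6


def test_orthogonal_predictors_match_simple_regressions(rng):
    # with exactly orthogonalized predictors, multiple-regression slopes
    # equal the two simple-regression slopes
    wt = _windows_frame(rng)
    x1 = wt["cds_density"] - wt["cds_density"].mean()
    x2 = wt["recomb_4Ner"] - wt["recomb_4Ner"].mean()
    x2 = x2 - (x2 @ x1) / (x1 @ x1) * x1
    wt["cds_density"], wt["recomb_4Ner"] = x1, x2
    wt["Ty3"] = 0.2 + 0.5 * x1 - 0.1 * x2 + rng.normal(0, 0.02, len(wt))
    fit = density_regression(wt, "Ty3")
    simple1 = (wt["Ty3"] @ x1) / (x1 @ x1)
    simple2 = (wt["Ty3"] @ x2) / (x2 @ x2)
    assert fit.slope_cds == pytest.approx(simple1, rel=1e-9)
    assert fit.slope_recomb == pytest.approx(simple2, rel=1e-9)


def test_density_regression_matches_normal_equations(rng):
    wt = _windows_frame(rng, n=120)
    wt["LINE"] = 0.1 + 0.2 * wt["cds_density"] + rng.normal(0, 0.05, len(wt))
    fit = density_regression(wt, "LINE")
    X = np.column_stack(
        [np.ones(len(wt)), wt["cds_density"], wt["recomb_4Ner"]]
    )
    beta = np.linalg.solve(X.T @ X, X.T @ wt["LINE"].to_numpy())
    assert np.allclose([fit.intercept, fit.slope_cds, fit.slope_recomb], beta,
                       rtol=1e-8)


def test_constant_response_flagged_degenerate(rng):
    wt = _windows_frame(rng, n=50)
    wt["Copia"] = 0.25
    fit = density_regression(wt, "Copia")
    assert fit.degenerate and np.isnan(fit.p_cds)


# ---------------------------------------------------------------------------
# I/O round-trips


def test_bed_and_gff3_round_trip(tmp_path, rng):
    fixture = resolve_overlaps(random_intervals(rng, 50))
    write_bed(fixture, tmp_path / "a.bed")
    pd.testing.assert_frame_equal(read_bed(tmp_path / "a.bed"), fixture)
    write_gff3(fixture, tmp_path / "a.gff3")
    back = read_gff3(tmp_path / "a.gff3")
    pd.testing.assert_frame_equal(back, fixture)
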