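"""Thresholds, inflation factor, DMRs, overlaps, annotation, exports."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from longewas import simcohort
from longewas.errors import DataError, ValidationError
from longewas.inference import (
    InflationReport,
    annotate_nearest_gene,
    bed_to_intervals,
    bonferroni_threshold,
    combine_region,
    find_dmrs,
    flag_significance,
    format_threshold,
    genomic_lambda,
    manhattan_data,
    overlap_sets,
    regional_slice,
)
from longewas.lmm import ewas_lmm


def _table(ps, chrom=None, pos=None, estimates=None):
    n = len(ps)
    return pd.DataFrame(
        {
            "cpg_id": [f"cg{i:05d}" for i in range(n)],
            "chrom": chrom if chrom is not None else ["1"] * n,
            "pos": pos if pos is not None else np.arange(1, n + 1) * 1000,
            "exposure": "auc",
            "model": "lmm",
            "estimate": estimates if estimates is not None else np.ones(n),
            "se": np.ones(n),
            "z": np.ones(n),
            "p": ps,
            "n_obs": 100,
            "n_subjects": 100,
            "status": "ok",
        }
    )


@pytest.mark.parametrize(
    "alpha,n,expected",
    [(0.05, 1, 0.05), (0.05, 5, 0.01), (0.05, 719_360, 6.950622775800713e-08)],
)
def test_bonferroni_threshold(alpha, n, expected):
    assert bonferroni_threshold(alpha, n) == pytest.approx(expected, rel=1e-12)


def test_threshold_formatting_truncates_mantissa():
    assert format_threshold(bonferroni_threshold(0.05, 719_360)) == "6.9e-08"
    assert format_threshold(0.05) == "5.0e-02"


def test_bonferroni_rejects_invalid_inputs():
    with pytest.raises(ValidationError):
        bonferroni_threshold(1.5, 10)
    with pytest.raises(ValidationError):
        bonferroni_threshold(0.05, 0)


def test_flag_significance_tiers():
    table = _table([5e-9, 5e-6, 0.2])
    flagged, counts = flag_significance(table, n_tests=719_360)
    assert list(flagged["tier"]) == ["genome-wide", "suggestive", "none"]
    assert counts["genome-wide"] == 1 and counts["suggestive"] == 1


def test_suggestive_boundary_is_inclusive():
    flagged, _ = flag_significance(_table([1e-5]), n_tests=719_360)
    assert flagged["tier"].iloc[0] == "suggestive"


def test_null_table_has_no_genome_wide_hits(rng):
    """1000 uniform p at the epigenome-wide threshold: hit probability ~7e-5."""
    flagged, counts = flag_significance(_table(rng.uniform(size=1000)), n_tests=719_360)
    assert counts["genome-wide"] == 0


def test_tier_counts_shrink_as_thresholds_tighten(rng):
    table = _table(rng.uniform(size=500) ** 3)
    loose = flag_significance(table, suggestive=1e-2)[1]
    tight = flag_significance(table, suggestive=1e-4)[1]
    assert tight["suggestive"] <= loose["suggestive"]


def test_lambda_is_one_on_uniform_quantiles():
    n = 2001
    p = (np.arange(1, n + 1) - 0.5) / n
    assert genomic_lambda(p).lam == pytest.approx(1.0, abs=1e-3)


def test_lambda_two_on_doubled_chi_square():
    n = 2001
    p0 = (np.arange(1, n + 1) - 0.5) / n
    p = stats.chi2.sf(2 * stats.chi2.isf(p0, 1), 1)
    assert genomic_lambda(p).lam == pytest.approx(2.0, abs=1e-3)


def test_lambda_invariant_to_row_order(rng):
    p = rng.uniform(size=500)
    assert genomic_lambda(p).lam == genomic_lambda(p[::-1]).lam


def test_lambda_requires_enough_tests():
    with pytest.raises(ValidationError):
        genomic_lambda(np.array([0.5] * 9))


# ---------------------------------------------------------------------------
# DMRs
# ---------------------------------------------------------------------------


def test_combine_region_identity_correlation_closed_form():
    k, b, s = 4, 0.3, 0.1
    combined, se, z, p, ridge = combine_region(
        np.full(k, b), np.full(k, s), np.eye(k)
    )
    assert combined == pytest.approx(b, abs=1e-12)
    assert z == pytest.approx(np.sqrt(k) * b / s, abs=1e-10)
    assert not ridge


def test_combine_region_singular_correlation_ridged():
    combined, se, z, p, ridge = combine_region(
        np.array([0.2, 0.2]), np.array([0.1, 0.1]), np.ones((2, 2))
    )
    assert ridge
    assert np.isfinite(z)


def test_single_cpg_region_equals_wald_test():
    residuals, samples, ann, _ = simcohort.simulate_region_study(
        n_null=40, region_size=1, region_effect=0.05, seed=13
    )
    table = ewas_lmm(residuals, samples, "auc", annotation=ann)
    stacked = pd.concat([residuals["birth"], residuals["5y"]], axis=1)
    dmrs = find_dmrs(table, stacked)
    assert len(dmrs) >= 1
    for _, region in dmrs[dmrs["n_cpgs"] == 1].iterrows():
        row = table.loc[table["cpg_id"] == region["cpg_ids"]].iloc[0]
        assert region["estimate"] == row["estimate"]
        assert region["se"] == row["se"]
        assert region["p"] == row["p"]


def test_planted_correlated_region_recovered_exactly():
    residuals, samples, ann, truth = simcohort.simulate_region_study(
        n_null=200, region_size=3, region_effect=0.03, region_rho=0.7, seed=29
    )
    table = ewas_lmm(residuals, samples, "auc", annotation=ann)
    stacked = pd.concat([residuals["birth"], residuals["5y"]], axis=1)
    dmrs = find_dmrs(table, stacked)
    top = dmrs.iloc[0]
    planted = truth[truth != 0].index
    assert top["cpg_ids"] == ",".join(planted)
    assert top["n_cpgs"] == 3
    assert top["start"] == int(ann.loc[planted, "pos"].min())
    assert top["end"] == int(ann.loc[planted, "pos"].max())
    assert top["p_adjusted"] < 0.05


def test_adjusted_p_is_bonferroni_over_candidates():
    residuals, samples, ann, _ = simcohort.simulate_region_study(
        n_null=100, region_size=1, region_effect=0.05, seed=17
    )
    table = ewas_lmm(residuals, samples, "auc", annotation=ann)
    stacked = pd.concat([residuals["birth"], residuals["5y"]], axis=1)
    dmrs = find_dmrs(table, stacked)
    n = len(dmrs)
    np.testing.assert_allclose(
        dmrs["p_adjusted"], np.minimum(1.0, dmrs["p"] * n), rtol=1e-12
    )
    assert (dmrs["p_adjusted"] >= dmrs["p"]).all()


def test_gap_and_sign_break_candidate_runs():
    ps = [1e-4, 1e-4, 1e-4, 1e-4]
    pos = [1000, 1300, 5000, 5200]           # gap 3700 splits runs
    est = [0.5, 0.5, 0.5, -0.5]              # sign flip splits again
    table = _table(ps, pos=pos, estimates=est)
    residuals = pd.DataFrame(
        np.random.default_rng(0).standard_normal((4, 30)), index=table["cpg_id"]
    )
    dmrs = find_dmrs(table, residuals, maxgap=500)
    sizes = sorted(dmrs["n_cpgs"])
    assert sizes == [1, 1, 2]


# ---------------------------------------------------------------------------
# overlaps
# ---------------------------------------------------------------------------


def test_overlap_toy_sets():
    universe_p = {"A": [1e-6, 1e-6, 0.5], "B": [0.5, 1e-6, 0.5], "C": [0.5, 0.5, 0.5]}
    tables = {name: _table(ps) for name, ps in universe_p.items()}
    rep = overlap_sets(tables)
    assert rep.sets["A"] == {"cg00000", "cg00001"}
    assert rep.intersections[("A", "B")] == {"cg00001"}
    assert rep.intersections[("A", "C")] == set()
    counts = {k: len(v) for k, v in rep.intersections.items() if len(k) == 1}
    assert counts == {("A",): 2, ("B",): 1, ("C",): 0}


def test_overlap_identical_tables():
    t = _table([1e-6, 0.5])
    rep = overlap_sets({"x": t, "y": t.copy()})
    assert rep.intersections[("x", "y")] == rep.sets["x"]


def test_overlap_rejects_mismatched_universe():
    a = _table([0.5, 0.5])
    b = _table([0.5, 0.5, 0.5])
    with pytest.raises(DataError, match="universe"):
        overlap_sets({"a": a, "b": b})


# ---------------------------------------------------------------------------
# gene annotation
# ---------------------------------------------------------------------------


GENES = pd.DataFrame(
    {"chrom": ["1", "1"], "start": [100, 300], "end": [200, 400], "name": ["G1", "G2"]}
)


def test_annotation_containment_and_tie_rule():
    table = _table([0.5, 0.5], pos=[150, 250])
    out = annotate_nearest_gene(table, GENES)
    assert list(out["gene"]) == ["G1", "G1"]       # 250 ties 50/50 -> smaller start
    assert list(out["gene_distance"]) == [0, 50]


def test_annotation_missing_chromosome_is_empty():
    table = _table([0.5], chrom=["7"], pos=[150])
    out = annotate_nearest_gene(table, GENES)
    assert out["gene"].iloc[0] == ""
    assert np.isnan(out["gene_distance"].iloc[0])


def test_annotation_matches_bruteforce_oracle(rng):
    genes = pd.DataFrame(
        {
            "chrom": rng.choice(["1", "2"], 40),
            "start": (s := rng.integers(1, 100_000, 40)),
            "end": s + rng.integers(10, 5000, 40),
            "name": [f"G{i}" for i in range(40)],
        }
    )
    table = _table(
        [0.5] * 60, chrom=list(rng.choice(["1", "2"], 60)),
        pos=list(rng.integers(1, 110_000, 60)),
    )
    out = annotate_nearest_gene(table, genes)
    for _, row in out.iterrows():
        best, best_d = "", np.inf
        for _, g in genes[genes["chrom"] == row["chrom"]].iterrows():
            d = max(0, g["start"] - row["pos"], row["pos"] - g["end"])
            if d < best_d or (d == best_d and g["start"] < best_start):
                best, best_d, best_start = g["name"], d, g["start"]
        assert row["gene"] == best
        assert row["gene_distance"] == best_d


def test_bed_conversion_shifts_start_only():
    bed = pd.DataFrame({"chrom": ["1"], "start": [99], "end": [200], "name": ["G"]})
    out = bed_to_intervals(bed)
    assert out["start"].iloc[0] == 100 and out["end"].iloc[0] == 200


# ---------------------------------------------------------------------------
# exports
# ---------------------------------------------------------------------------


def test_manhattan_thresholds_metadata():
    data, meta = manhattan_data(_table([1e-9, 1.0]), n_tests=719_360)
    assert meta["genome_wide_neglog10"] == pytest.approx(7.161, abs=1e-3)
    assert meta["suggestive_neglog10"] == pytest.approx(5.0)
    assert data.loc[data["cpg_id"] == "cg00001", "neglog10_p"].iloc[0] == 0.0


def test_regional_slice_window_contract():
    pos = [1_000, 20_000, 60_000, 200_000]
    table = _table([0.5] * 4, pos=pos)
    sl = regional_slice(table, "cg00001", window=50_000)
    assert set(sl["pos"]) == {1_000, 20_000, 60_000}
    with pytest.raises(ValidationError, match="anchor"):
        regional_slice(table, "nonexistent")


def test_export_plots_writes_data_files(tmp_path):
    from longewas.inference import export_plots

    table = _table([1e-6, 0.2, 0.9])
    inflation = genomic_lambda(np.linspace(0.01, 0.99, 50))
    written = export_plots(table, tmp_path, inflation, regional_anchors=("cg00000",))
    for key in ("manhattan", "thresholds", "qq", "regional_cg00000"):
        assert written[key].exists()
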