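"""Preprocessing: transforms, probe filters, batch adjustment, deconvolution,
residualization."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from longewas import simcohort
from longewas.errors import ValidationError
from longewas.preprocess import (
    CellComposition,
    MethylationStudy,
    beta_to_m,
    combat_matrix,
    estimate_cell_composition,
    filter_probes,
    m_to_beta,
    residualize,
)


@pytest.mark.parametrize(
    "beta,m",
    [
        (0.5, 0.0),
        (0.8, 2.0),
        (0.25, -np.log2(3)),
        (0.013, -6.247),  # a near-unmethylated promoter CpG
    ],
)
def test_beta_to_m_values(beta, m):
    assert beta_to_m(beta) == pytest.approx(m, abs=1e-3)


def test_beta_to_m_rejects_out_of_range():
    with pytest.raises(ValidationError):
        beta_to_m(1.2)
    with pytest.raises(ValidationError):
        beta_to_m(-0.1)


def test_beta_boundaries_are_clipped_to_finite_m():
    m = beta_to_m(np.array([0.0, 1.0]))
    assert np.isfinite(m).all()
    assert m[0] == pytest.approx(np.log2(1e-6 / (1 - 1e-6)))


@given(st.floats(1e-5, 1 - 1e-5))
@settings(max_examples=80, derandomize=True)
def test_transform_round_trip(beta):
    assert m_to_beta(beta_to_m(beta)) == pytest.approx(beta, abs=1e-12)
    assert beta_to_m(m_to_beta(beta_to_m(beta))) == pytest.approx(
        beta_to_m(beta), rel=1e-11, abs=1e-12
    )


def _toy_study(n_samples=50):
    """Ten CpGs: 2 sex-chromosome, 1 'rs' id, 1 zero-variance, 1 failing
    detection in 6% of samples; 5 clean."""
    rng = np.random.default_rng(0)
    ids = [f"cg{i:05d}" for i in range(9)] + ["rs00001"]
    beta = pd.DataFrame(
        rng.uniform(0.2, 0.8, (10, n_samples)),
        index=ids,
        columns=[f"smp{j}" for j in range(n_samples)],
    )
    beta.iloc[5] = 0.42  # constant row
    ann = pd.DataFrame(
        {
            "chrom": ["1"] * 10,
            "pos": np.arange(1, 11) * 1000,
            "is_sex_chrom": [False] * 10,
            "is_snp_maf05": [False] * 10,
            "is_cross_reactive": [False] * 10,
            "is_noncpg": [False] * 10,
        },
        index=pd.Index(ids, name="cpg_id"),
    )
    ann.loc[ids[0], "is_sex_chrom"] = True
    ann.loc[ids[1], "is_sex_chrom"] = True
    det = pd.DataFrame(0.001, index=ids, columns=beta.columns)
    n_fail = int(round(0.06 * n_samples))
    det.iloc[7, :n_fail] = 0.5
    meta = pd.DataFrame(
        {"subject_id": beta.columns, "timepoint": "birth", "batch": "b1", "age": 39.0},
        index=beta.columns,
    )
    return MethylationStudy(beta=beta, sample_metadata=meta, cpg_annotation=ann, detection_p=det)


def test_filter_probes_counts_by_rule():
    filtered, report = filter_probes(_toy_study())
    counts = report.set_index("rule")["n_removed"]
    assert counts["non_cpg"] == 1
    assert counts["sex_chromosome"] == 2
    assert counts["zero_variance"] == 1
    assert counts["detection_failure"] == 1
    assert counts["retained"] == 5
    assert len(filtered.beta) == 5


def test_filter_probes_identity_when_nothing_flagged():
    study = _toy_study()
    study.cpg_annotation.loc[:, ["is_sex_chrom"]] = False
    clean = MethylationStudy(
        beta=study.beta.iloc[:5],
        sample_metadata=study.sample_metadata,
        cpg_annotation=study.cpg_annotation.iloc[:5],
    )
    filtered, report = filter_probes(clean)
    assert filtered.beta.equals(clean.beta)


def test_probe_failing_two_rules_counted_once_under_first():
    study = _toy_study()
    # make a sex-chromosome probe also SNP-flagged: still attributed to sex rule?
    # the first rule in the documented order is non_cpg, then sex; flag the 'rs'
    # probe as sex-chromosome too and check it stays under non_cpg
    study.cpg_annotation.loc["rs00001", "is_sex_chrom"] = True
    _, report = filter_probes(study)
    counts = report.set_index("rule")["n_removed"]
    assert counts["non_cpg"] == 1
    assert counts["sex_chromosome"] == 2


def test_filter_probes_idempotent(small_sim):
    once, _ = filter_probes(small_sim.study)
    twice, report = filter_probes(once)
    assert once.beta.equals(twice.beta)
    assert report.set_index("rule")["n_removed"].drop("retained").sum() == 0


# ---------------------------------------------------------------------------
# batch adjustment
# ---------------------------------------------------------------------------


def test_combat_single_batch_is_identity(rng):
    m = rng.standard_normal((40, 30))
    adjusted, model = combat_matrix(m, np.array(["b1"] * 30), None)
    np.testing.assert_allclose(adjusted, m, atol=1e-12)


def test_combat_requires_two_samples_per_batch(rng):
    m = rng.standard_normal((10, 5))
    with pytest.raises(ValidationError, match="batch"):
        combat_matrix(m, np.array(["a", "a", "a", "a", "b"]), None)


def test_combat_rejects_collinear_protected(rng):
    m = rng.standard_normal((10, 20))
    batch = np.array(["a"] * 10 + ["b"] * 10)
    protected = np.column_stack([np.ones(20), np.ones(20)])
    with pytest.raises(ValidationError, match="rank"):
        combat_matrix(m, batch, protected, ["c1", "c2"])


def _batch_fixture(rng, shift_sd=0.5, n_probes=400, n_samples=200, effect=0.0):
    batch = np.array(["a"] * (n_samples // 2) + ["b"] * (n_samples // 2))
    exposure = rng.standard_normal(n_samples)
    shifts = rng.normal(0, shift_sd, (n_probes, 2))
    m = (
        rng.normal(0, 0.2, (n_probes, n_samples))
        + shifts[:, (batch == "b").astype(int)]
        + effect * exposure[None, :]
    )
    return m, batch, exposure


def test_combat_removes_planted_location_shifts(rng):
    m, batch, exposure = _batch_fixture(rng)
    adjusted, _ = combat_matrix(m, batch, exposure[:, None], ["exposure"])

    def batch_gap(mat):
        return np.abs(
            mat[:, batch == "a"].mean(axis=1) - mat[:, batch == "b"].mean(axis=1)
        ).mean()

    assert batch_gap(adjusted) < 0.1 * batch_gap(m)


def test_combat_preserves_protected_exposure_slope(rng):
    m, batch, exposure = _batch_fixture(rng, shift_sd=0.0, effect=0.05)
    adjusted, _ = combat_matrix(m, batch, exposure[:, None], ["exposure"])
    x = np.column_stack([np.ones_like(exposure), exposure])
    before = np.linalg.lstsq(x, m.T, rcond=None)[0][1]
    after = np.linalg.lstsq(x, adjusted.T, rcond=None)[0][1]
    assert np.abs(after - before).max() < 1e-2


# ---------------------------------------------------------------------------
# cell-composition estimation
# ---------------------------------------------------------------------------


def _panels(seed=3, n_cpgs=300):
    return simcohort.simulate_reference_panels(
        simcohort.SimulationConfig(n_cpgs=n_cpgs, n_causal=0, seed=seed)
    )


def test_deconvolution_recovers_exact_mixture():
    panels = _panels()
    p_true = np.array([0.3, 0.2, 0.1, 0.1, 0.1, 0.1, 0.1])
    f = panels.cord.loc[:, panels.cord_discriminating]
    y = pd.DataFrame((f.to_numpy().T @ p_true)[:, None], index=f.columns, columns=["s1"])
    comp = estimate_cell_composition(y, panels.cord, panels.cord_discriminating)
    np.testing.assert_allclose(comp.proportions.to_numpy()[0], p_true, atol=1e-6)


def test_deconvolution_recovers_pure_cell_type():
    panels = _panels()
    f = panels.cord.loc[:, panels.cord_discriminating]
    y = pd.DataFrame(f.iloc[2].to_numpy()[:, None], index=f.columns, columns=["s1"])
    comp = estimate_cell_composition(y, panels.cord, panels.cord_discriminating)
    expected = np.zeros(7)
    expected[2] = 1.0
    np.testing.assert_allclose(comp.proportions.to_numpy()[0], expected, atol=1e-6)


def test_deconvolution_noisy_mixtures_accurate(rng):
    panels = _panels()
    f = panels.cord.loc[:, panels.cord_discriminating].to_numpy()
    p_true = rng.dirichlet(20 * simcohort.CORD_MEAN_COMPOSITION, 200)
    y = p_true @ f + rng.normal(0, 0.02, (200, f.shape[1]))
    y = np.clip(y, 0, 1)
    frame = pd.DataFrame(y.T, index=panels.cord_discriminating,
                         columns=[f"s{i}" for i in range(200)])
    comp = estimate_cell_composition(frame, panels.cord, panels.cord_discriminating)
    err = np.abs(comp.proportions.to_numpy() - p_true).mean(axis=0)
    assert err.mean() < 0.05


def test_deconvolution_output_on_simplex(small_prep):
    for comp in small_prep.composition.values():
        arr = comp.proportions.to_numpy()
        assert (arr >= -1e-12).all()
        np.testing.assert_allclose(arr.sum(axis=1), 1.0, atol=1e-8)


def test_deconvolution_rejects_dependent_panel():
    panels = _panels()
    bad = panels.cord.copy()
    bad.iloc[1] = bad.iloc[0]
    with pytest.raises(ValidationError, match="identifiab"):
        estimate_cell_composition(
            pd.DataFrame(
                0.5, index=panels.cord_discriminating, columns=["s1"]
            ),
            bad,
            panels.cord_discriminating,
        )


# ---------------------------------------------------------------------------
# residualization
# ---------------------------------------------------------------------------


def test_residuals_orthogonal_to_design(small_sim, small_prep):
    study = small_prep.study
    for tp, res in small_prep.residuals.items():
        ids = study.samples_at(tp)
        props = small_prep.composition[tp].proportions.loc[ids]
        kept = [c for c in props.columns if c != props.mean().idxmax()]
        x = np.column_stack(
            [np.ones(len(ids)), props[kept].to_numpy(),
             study.sample_metadata.loc[ids, "age"].to_numpy()]
        )
        inner = res.to_numpy() @ x
        scale = np.abs(res.to_numpy()).max() * len(ids)
        assert np.abs(inner).max() / scale < 1e-8


def test_residualize_perfect_fit_gives_zero_residuals(rng):
    """M that is exactly linear in cell proportions and age leaves ~0."""
    panels = _panels(n_cpgs=200)
    n = 60
    props = rng.dirichlet(20 * simcohort.CORD_MEAN_COMPOSITION, n)
    age = rng.uniform(37, 41, n)
    load = rng.standard_normal((30, 8))
    m = load[:, :7] @ props.T + np.outer(load[:, 7], age)
    ids = [f"s{i}" for i in range(n)]
    meta = pd.DataFrame(
        {"subject_id": ids, "timepoint": "birth", "batch": "b1", "age": age}, index=ids
    )
    ann = pd.DataFrame(
        {"chrom": "1", "pos": np.arange(1, 31) * 100},
        index=pd.Index([f"cg{i:05d}" for i in range(30)], name="cpg_id"),
    )
    study = MethylationStudy(
        beta=pd.DataFrame(m_to_beta(m / 10), index=ann.index, columns=ids),
        sample_metadata=meta,
        cpg_annotation=ann,
    )
    comp = CellComposition(
        proportions=pd.DataFrame(props, index=ids, columns=panels.cord.index)
    )
    res = residualize(study, comp, "birth")
    assert np.abs(res.to_numpy()).max() < 1e-8


def test_residualize_preserves_independent_exposure_slope(rng):
    """An exposure orthogonal to cells/age keeps its planted slope."""
    n = 400
    props = rng.dirichlet(20 * simcohort.CORD_MEAN_COMPOSITION, n)
    age = rng.uniform(37, 41, n)
    exposure = rng.standard_normal(n)
    planted = 0.3
    noise = rng.normal(0, 0.5, (20, n))
    m = (
        rng.standard_normal((20, 7)) @ props.T
        + np.outer(rng.standard_normal(20) * 0.05, age)
        + planted * exposure[None, :]
        + noise
    )
    ids = [f"s{i}" for i in range(n)]
    meta = pd.DataFrame(
        {"subject_id": ids, "timepoint": "birth", "batch": "b1", "age": age}, index=ids
    )
    ann = pd.DataFrame(
        {"chrom": "1", "pos": np.arange(1, 21) * 100},
        index=pd.Index([f"cg{i:05d}" for i in range(20)], name="cpg_id"),
    )
    study = MethylationStudy(
        beta=pd.DataFrame(m_to_beta(m / 20), index=ann.index, columns=ids),
        sample_metadata=meta,
        cpg_annotation=ann,
    )
    comp = CellComposition(
        proportions=pd.DataFrame(props, index=ids, columns=list(simcohort.CORD_CELL_TYPES))
    )
    res = residualize(study, comp, "birth") * 20  # undo the M-scale shrink
    x = np.column_stack([np.ones(n), exposure])
    slopes = np.linalg.lstsq(x, res.to_numpy().T, rcond=None)[0][1]
    se = 0.5 / np.sqrt(n)  # approximate slope SE at unit exposure variance
    assert np.abs(slopes - planted).max() < 4 * se * np.sqrt(2)


def test_residualize_rank_deficient_design_raises(rng):
    ids = ["s0", "s1", "s2"]
    meta = pd.DataFrame(
        {"subject_id": ids, "timepoint": "birth", "batch": "b1", "age": 39.0}, index=ids
    )
    ann = pd.DataFrame(
        {"chrom": "1", "pos": [100, 200]},
        index=pd.Index(["cg1", "cg2"], name="cpg_id"),
    )
    study = MethylationStudy(
        beta=pd.DataFrame(rng.uniform(0.3, 0.7, (2, 3)), index=ann.index, columns=ids),
        sample_metadata=meta,
        cpg_annotation=ann,
    )
    comp = CellComposition(
        proportions=pd.DataFrame(
            np.tile([0.5, 0.5], (3, 1)), index=ids, columns=["t1", "t2"]
        )
    )
    with pytest.raises(ValidationError, match="rank"):
        residualize(study, comp, "birth")
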