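"""Synthetic mother-child longitudinal methylation studies with known truth.

The generator emulates the structure of a prospective pregnancy cohort with
DNA methylation measured in cord blood at delivery and in peripheral blood at
about five years of age: 539 dyads of which 440 contribute a cord sample, 293
a 5-year sample and 194 both (the flowchart identity
n_birth + n_age5 - n_both = n_dyads).  Maternal covariates and the OGTT
glucose triplet are drawn to match the published cohort marginals; glucose is
a correlated trivariate log-normal so the trapezoidal AUC has a realistic
spread.  Methylation is generated on the M-value scale as

    M = probe baseline + cell-composition term + age term + batch shift
        + planted_effect * (AUC - mean AUC)      (causal CpGs only)
        + subject random intercept + residual noise

and stored as beta = logistic2(M).  A ``TruthTable`` records every planted
quantity so downstream stages can be tested by parameter recovery.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DataError
from .glycemia import GlucoseProfile
from .preprocess import MethylationStudy, beta_to_m, m_to_beta

# --- cell panels -----------------------------------------------------------

CORD_CELL_TYPES = ("CD8T", "CD4T", "Mono", "NK", "Bcell", "Gran", "nRBC")
PERIPHERAL_CELL_TYPES = ("CD8T", "CD4T", "Mono", "NK", "Bcell", "Neu")

#: Mean cell compositions used as Dirichlet centres.  The source study does
#: not report composition distributions; these are typical reference-based
#: estimates for cord and young-child peripheral blood.
CORD_MEAN_COMPOSITION = np.array([0.07, 0.15, 0.07, 0.05, 0.07, 0.50, 0.09])
PERIPHERAL_MEAN_COMPOSITION = np.array([0.12, 0.20, 0.08, 0.06, 0.10, 0.44])
DIRICHLET_CONCENTRATION = 20.0
N_DISCRIMINATING_PER_TYPE = 10

# --- covariate marginals (cohort descriptive table) ------------------------

MATERNAL_AGE_MEAN, MATERNAL_AGE_SD = 28.2, 4.2
BMI_MEDIAN, BMI_LOG_SD = 23.9, 0.190
PRIMIGRAVID_RATE = 0.334
SMOKING_RATE = 0.091
GIRL_RATE = 0.468
GA_BIRTH_MEDIAN, GA_BIRTH_SD = 39.7, 1.11
CHILD_AGE_MEDIAN, CHILD_AGE_SD = 5.2, 0.22
#: Log-scale parameters of the fasting/1 h/2 h glucose triplet (mmol/L);
#: medians 4.2 / 7.1 / 5.7 with log-SDs back-solved from the printed IQRs,
#: pairwise correlation 0.5 on the log scale.
GLUCOSE_LOG_MEAN = np.log([4.2, 7.1, 5.7])
GLUCOSE_LOG_SD = np.array([0.089, 0.232, 0.236])
GLUCOSE_CORR = 0.5

#: Fraction of probes carrying each exclusion flag in the generated annotation.
FLAG_FRACTION = 0.01

TIME_PROFILES = ("both", "birth-only", "5y-only")


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the synthetic study; defaults are the emulated cohort."""

    n_dyads: int = 539
    n_birth: int = 440
    n_age5: int = 293
    n_both: int = 194
    n_cpgs: int = 2000
    n_causal: int = 50
    effect_size_range: tuple[float, float] = (0.02, 0.04)
    sigma_subject: float = 0.12
    sigma_resid: float = 0.22
    n_batches: int = 4
    batch_shift_sd: float = 0.1
    cell_effect_sd: float = 0.5
    age_effect_sd: float = 0.02
    seed: int = 0

    def validate(self) -> None:
        if self.n_birth + self.n_age5 - self.n_both != self.n_dyads:
            raise ConfigurationError(
                "flowchart identity violated: n_birth + n_age5 - n_both must equal "
                f"n_dyads ({self.n_birth} + {self.n_age5} - {self.n_both} != {self.n_dyads})"
            )
        if not (0 <= self.n_both <= min(self.n_birth, self.n_age5)):
            raise ConfigurationError("n_both must be <= min(n_birth, n_age5) and >= 0")
        if min(self.n_dyads, self.n_birth, self.n_age5) < 1:
            raise ConfigurationError("n_dyads, n_birth and n_age5 must be positive")
        if self.n_cpgs < 1:
            raise ConfigurationError("n_cpgs must be positive")
        if not (0 <= self.n_causal <= self.n_cpgs):
            raise ConfigurationError("n_causal must satisfy 0 <= n_causal <= n_cpgs")
        lo, hi = self.effect_size_range
        if not (0 <= lo <= hi):
            raise ConfigurationError("effect_size_range bounds must be ordered and >= 0")
        if self.sigma_subject < 0:
            raise ConfigurationError("sigma_subject must be >= 0")
        if self.sigma_resid <= 0:
            raise ConfigurationError("sigma_resid must be > 0")
        if self.n_batches < 1:
            raise ConfigurationError("n_batches must be >= 1")
        if self.batch_shift_sd < 0 or self.cell_effect_sd < 0 or self.age_effect_sd < 0:
            raise ConfigurationError("effect SDs must be >= 0")


@dataclass(frozen=True)
class SubjectRecord:
    """One mother-child dyad with covariates, OGTT profile and sample flags."""

    subject_id: str
    maternal_age: float
    bmi_t1: float
    gravidity: bool   # primigravid yes/no
    smoking: bool
    child_sex: bool   # girl yes/no
    glucose: GlucoseProfile
    gestational_age_birth: float
    child_age_5y: float
    has_birth_sample: bool
    has_5y_sample: bool

    def __post_init__(self) -> None:
        if not (30 <= self.gestational_age_birth <= 43):
            raise ConfigurationError("gestational_age_birth must lie in [30, 43] weeks")
        if not (4.5 <= self.child_age_5y <= 6.5):
            raise ConfigurationError("child_age_5y must lie in [4.5, 6.5] years")
        if not (self.has_birth_sample or self.has_5y_sample):
            raise ConfigurationError("a subject must contribute at least one sample")


@dataclass
class ReferencePanels:
    """Cell-type mean-beta reference matrices for the two time points."""

    cord: pd.DataFrame        # 7 x n_cpgs
    peripheral: pd.DataFrame  # 6 x n_cpgs
    cord_discriminating: list[str]
    peripheral_discriminating: list[str]


@dataclass
class TruthTable:
    """Everything that was planted, for parameter-recovery tests."""

    effects: pd.DataFrame        # cpg_id (index), planted_effect, time_profile
    sigma_subject: float
    sigma_resid: float
    batch_shifts: pd.DataFrame   # probe x batch
    cell_proportions: pd.DataFrame  # sample x cell type (union of both panels)
    age_slopes: pd.Series        # probe
    auc: pd.Series               # subject

    @property
    def causal(self) -> pd.DataFrame:
        return self.effects[self.effects["planted_effect"] != 0.0]


class SimulatedStudy(NamedTuple):
    subjects: list[SubjectRecord]
    panels: ReferencePanels
    study: MethylationStudy
    truth: TruthTable


def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    """One named generator per study and stream, seeded from the config only."""
    return np.random.default_rng([int(config.seed), stream])


def cpg_ids(n_cpgs: int) -> list[str]:
    return [f"cg{i:08d}" for i in range(n_cpgs)]


def simulate_cohort(config: SimulationConfig) -> list[SubjectRecord]:
    """Draw the mother-child dyads with the configured missingness pattern.

    Covariate marginals follow the emulated cohort: maternal age
    N(28.2, 4.2) years, first-trimester BMI log-normal with median 23.9,
    smoking 9.1%, primigravid 33.4%, girls 46.8%, and a correlated
    log-normal OGTT triplet with medians 4.2/7.1/5.7 mmol/L.  Exactly
    ``n_both`` subjects carry both sample flags.  Deterministic given seed.
    """
    config.validate()
    rng = _rng(config, 0)
    n = config.n_dyads

    age = np.clip(rng.normal(MATERNAL_AGE_MEAN, MATERNAL_AGE_SD, n), 18.0, 45.0)
    bmi = np.exp(rng.normal(np.log(BMI_MEDIAN), BMI_LOG_SD, n))
    grav = rng.random(n) < PRIMIGRAVID_RATE
    smoke = rng.random(n) < SMOKING_RATE
    girl = rng.random(n) < GIRL_RATE
    corr = np.full((3, 3), GLUCOSE_CORR)
    np.fill_diagonal(corr, 1.0)
    chol = np.linalg.cholesky(corr)
    z = rng.standard_normal((n, 3)) @ chol.T
    glucose = np.exp(GLUCOSE_LOG_MEAN + GLUCOSE_LOG_SD * z)
    ga = np.clip(rng.normal(GA_BIRTH_MEDIAN, GA_BIRTH_SD, n), 30.0, 43.0)
    age5 = np.clip(rng.normal(CHILD_AGE_MEDIAN, CHILD_AGE_SD, n), 4.5, 6.5)

    order = rng.permutation(n)
    has_birth = np.zeros(n, dtype=bool)
    has_5y = np.zeros(n, dtype=bool)
    both = order[: config.n_both]
    birth_only = order[config.n_both : config.n_both + (config.n_birth - config.n_both)]
    age5_only = order[config.n_both + (config.n_birth - config.n_both) :]
    has_birth[both] = has_birth[birth_only] = True
    has_5y[both] = has_5y[age5_only] = True

    subjects = []
    for i in range(n):
        subjects.append(
            SubjectRecord(
                subject_id=f"S{i:04d}",
                maternal_age=float(age[i]),
                bmi_t1=float(bmi[i]),
                gravidity=bool(grav[i]),
                smoking=bool(smoke[i]),
                child_sex=bool(girl[i]),
                glucose=GlucoseProfile(values=tuple(glucose[i])),
                gestational_age_birth=float(ga[i]),
                child_age_5y=float(age5[i]),
                has_birth_sample=bool(has_birth[i]),
                has_5y_sample=bool(has_5y[i]),
            )
        )
    return subjects


def subjects_frame(subjects: Sequence[SubjectRecord]) -> pd.DataFrame:
    """Per-subject table (one row per dyad) for description and IO."""
    rows = []
    for s in subjects:
        rows.append(
            {
                "subject_id": s.subject_id,
                "maternal_age": s.maternal_age,
                "bmi_t1": s.bmi_t1,
                "gravidity": int(s.gravidity),
                "smoking": int(s.smoking),
                "child_sex": int(s.child_sex),
                "glucose_0": s.glucose.values[0],
                "glucose_1": s.glucose.values[1],
                "glucose_2": s.glucose.values[2],
                "auc": s.glucose.auc,
                "gestational_age_birth": s.gestational_age_birth,
                "child_age_5y": s.child_age_5y,
                "has_birth_sample": int(s.has_birth_sample),
                "has_5y_sample": int(s.has_5y_sample),
            }
        )
    return pd.DataFrame(rows).set_index("subject_id")


def simulate_reference_panels(config: SimulationConfig) -> ReferencePanels:
    """Cord (7 types, incl. nRBC) and peripheral (6 types) mean-beta panels.

    Non-discriminating CpGs share a common baseline across cell types (small
    jitter); each cell type additionally owns a block of discriminating CpGs
    where its mean beta is high (~0.85) and every other type is low (~0.15),
    giving a between-type spread >= 0.3 so deconvolution is identifiable.
    Cord and peripheral discriminating blocks are disjoint where n_cpgs allows.
    """
    config.validate()
    rng = _rng(config, 1)
    ids = cpg_ids(config.n_cpgs)
    baseline = rng.uniform(0.1, 0.9, config.n_cpgs)

    def build(types: tuple[str, ...], offset: int) -> tuple[pd.DataFrame, list[str]]:
        k = len(types)
        f = np.clip(
            baseline[None, :] + rng.normal(0, 0.01, (k, config.n_cpgs)), 0.01, 0.99
        )
        disc: list[str] = []
        for t in range(k):
            start = offset + t * N_DISCRIMINATING_PER_TYPE
            stop = min(start + N_DISCRIMINATING_PER_TYPE, config.n_cpgs)
            if start >= config.n_cpgs:
                break
            block = slice(start, stop)
            f[:, block] = np.clip(
                0.15 + rng.normal(0, 0.005, (k, stop - start)), 0.01, 0.99
            )
            f[t, block] = np.clip(
                0.85 + rng.normal(0, 0.005, stop - start), 0.01, 0.99
            )
            disc.extend(ids[start:stop])
        return pd.DataFrame(f, index=list(types), columns=ids), disc

    cord, cord_disc = build(CORD_CELL_TYPES, 0)
    periph, periph_disc = build(
        PERIPHERAL_CELL_TYPES, len(CORD_CELL_TYPES) * N_DISCRIMINATING_PER_TYPE
    )
    return ReferencePanels(
        cord=cord,
        peripheral=periph,
        cord_discriminating=cord_disc,
        peripheral_discriminating=periph_disc,
    )


def simulate_methylation(
    subjects: Sequence[SubjectRecord],
    panels: ReferencePanels,
    config: SimulationConfig,
    time_profile: str = "both",
) -> tuple[MethylationStudy, TruthTable]:
    """Generate the beta matrix, sample sheet, annotation and truth table.

    ``time_profile`` sets the default planted-effect profile ("both",
    "birth-only" or "5y-only").  Causal CpGs are chosen among flag-free
    autosomal probes outside the deconvolution discriminating blocks.
    """
    config.validate()
    if len(subjects) == 0:
        raise DataError("simulate_methylation needs a non-empty subject list")
    if panels.cord.shape[1] != config.n_cpgs:
        raise DataError(
            f"panels cover {panels.cord.shape[1]} CpGs but config.n_cpgs={config.n_cpgs}"
        )
    if time_profile not in TIME_PROFILES:
        raise DataError(f"time_profile must be one of {TIME_PROFILES}")
    rng = _rng(config, 2)
    ids = list(panels.cord.columns)
    g = config.n_cpgs

    # --- annotation -------------------------------------------------------
    chrom = rng.integers(1, 23, g).astype(str)
    flags = {
        "is_sex_chrom": rng.random(g) < FLAG_FRACTION,
        "is_snp_maf05": rng.random(g) < FLAG_FRACTION,
        "is_cross_reactive": rng.random(g) < FLAG_FRACTION,
        "is_noncpg": rng.random(g) < FLAG_FRACTION,
    }
    chrom[flags["is_sex_chrom"]] = "X"
    pos = np.empty(g, dtype=int)
    for c in np.unique(chrom):
        idx = np.flatnonzero(chrom == c)
        gaps = rng.integers(1000, 100000, idx.size)
        pos[idx] = np.cumsum(gaps)
    annotation = pd.DataFrame({"chrom": chrom, "pos": pos, **flags}, index=pd.Index(ids, name="cpg_id"))

    # --- causal CpGs ------------------------------------------------------
    flagged = np.zeros(g, dtype=bool)
    for v in flags.values():
        flagged |= v
    disc = set(panels.cord_discriminating) | set(panels.peripheral_discriminating)
    eligible = np.flatnonzero(~flagged & ~np.isin(ids, list(disc)))
    if config.n_causal > eligible.size:
        raise DataError(
            f"cannot place {config.n_causal} causal CpGs among {eligible.size} eligible probes"
        )
    causal = rng.choice(eligible, config.n_causal, replace=False)
    lo, hi = config.effect_size_range
    magnitudes = rng.uniform(lo, hi, config.n_causal)
    signs = rng.choice([-1.0, 1.0], config.n_causal)
    effects = np.zeros(g)
    effects[causal] = magnitudes * signs
    profiles = np.array(["none"] * g, dtype=object)
    profiles[causal] = time_profile

    # --- samples ----------------------------------------------------------
    frame = subjects_frame(subjects)
    sample_rows = []
    for s in subjects:
        if s.has_birth_sample:
            sample_rows.append((f"{s.subject_id}_B", s.subject_id, "birth", s.gestational_age_birth))
        if s.has_5y_sample:
            sample_rows.append((f"{s.subject_id}_5y", s.subject_id, "5y", s.child_age_5y))
    samples = pd.DataFrame(
        sample_rows, columns=["sample_id", "subject_id", "timepoint", "age"]
    ).set_index("sample_id")
    n_samples = len(samples)
    samples["batch"] = [
        f"batch{b + 1}" for b in rng.integers(0, config.n_batches, n_samples)
    ]
    for col in ["maternal_age", "bmi_t1", "gravidity", "smoking", "child_sex",
                "glucose_0", "glucose_1", "glucose_2", "auc"]:
        samples[col] = frame.loc[samples["subject_id"], col].to_numpy()

    # --- M-value construction --------------------------------------------
    mix = rng.choice(3, g, p=[0.4, 0.4, 0.2])
    baseline = rng.normal(np.array([-3.0, 3.0, 0.0])[mix], 1.0)
    age_slopes = rng.normal(0.0, config.age_effect_sd, g)
    batch_levels = sorted(samples["batch"].unique())
    batch_shifts = rng.normal(0.0, config.batch_shift_sd, (g, len(batch_levels)))
    subject_index = {s.subject_id: i for i, s in enumerate(subjects)}
    intercepts = rng.normal(0.0, config.sigma_subject, (g, len(subjects)))

    auc = frame["auc"]
    auc_centered = (auc - auc.mean()).to_dict()

    union_types = list(dict.fromkeys(CORD_CELL_TYPES + PERIPHERAL_CELL_TYPES))
    all_props = pd.DataFrame(0.0, index=samples.index, columns=union_types)

    m = np.empty((g, n_samples))
    panel_logit = {
        "birth": beta_to_m(panels.cord.to_numpy()),
        "5y": beta_to_m(panels.peripheral.to_numpy()),
    }
    mean_comp = {"birth": CORD_MEAN_COMPOSITION, "5y": PERIPHERAL_MEAN_COMPOSITION}
    panel_types = {"birth": CORD_CELL_TYPES, "5y": PERIPHERAL_CELL_TYPES}
    tp_idx = {tp: np.flatnonzero((samples["timepoint"] == tp).to_numpy()) for tp in ("birth", "5y")}

    disc_mask = np.isin(ids, list(disc))
    for tp in ("birth", "5y"):
        idx = tp_idx[tp]
        if idx.size == 0:
            continue
        alpha = DIRICHLET_CONCENTRATION * mean_comp[tp]
        props = rng.dirichlet(alpha, idx.size)          # samples x types
        all_props.iloc[idx, [union_types.index(t) for t in panel_types[tp]]] = props
        logits = panel_logit[tp]                        # types x cpgs
        centered_logit = logits - mean_comp[tp] @ logits
        cell_term = config.cell_effect_sd * (props @ centered_logit)  # samples x cpgs
        # Discriminating probes are cell-type markers: their methylation IS
        # the composition mixture of the panel logits (no background
        # baseline), so reference-based deconvolution sees real mixtures.
        cell_term[:, disc_mask] = (props @ logits)[:, disc_mask]
        ages = samples["age"].to_numpy()[idx]
        age_term = np.outer(age_slopes, ages - ages.mean())
        effect_on = time_profile == "both" or (
            (time_profile == "birth-only") == (tp == "birth")
        )
        base = np.where(disc_mask, 0.0, baseline)
        block = base[:, None] + cell_term.T + age_term
        if effect_on:
            e = np.array([auc_centered[sid] for sid in samples["subject_id"].iloc[idx]])
            block += np.outer(effects, e)
        subj = [subject_index[sid] for sid in samples["subject_id"].iloc[idx]]
        block += intercepts[:, subj]
        bcodes = [batch_levels.index(b) for b in samples["batch"].iloc[idx]]
        block += batch_shifts[:, bcodes]
        block += rng.normal(0.0, config.sigma_resid, block.shape)
        m[:, idx] = block

    beta = pd.DataFrame(m_to_beta(m), index=annotation.index, columns=samples.index)
    study = MethylationStudy(beta=beta, sample_metadata=samples, cpg_annotation=annotation)
    truth = TruthTable(
        effects=pd.DataFrame(
            {"planted_effect": effects, "time_profile": profiles}, index=annotation.index
        ),
        sigma_subject=config.sigma_subject,
        sigma_resid=config.sigma_resid,
        batch_shifts=pd.DataFrame(batch_shifts, index=annotation.index, columns=batch_levels),
        cell_proportions=all_props,
        age_slopes=pd.Series(age_slopes, index=annotation.index),
        auc=auc,
    )
    return study, truth


def simulate_study(config: SimulationConfig, time_profile: str = "both") -> SimulatedStudy:
    """Convenience wrapper running cohort, panels and methylation generation."""
    subjects = simulate_cohort(config)
    panels = simulate_reference_panels(config)
    study, truth = simulate_methylation(subjects, panels, config, time_profile)
    return SimulatedStudy(subjects=subjects, panels=panels, study=study, truth=truth)


def simulate_region_study(
    config: SimulationConfig | None = None,
    n_null: int = 200,
    region_size: int = 3,
    region_effect: float = 0.03,
    region_rho: float = 0.7,
    sigma: float = 0.22,
    sigma_subject: float = 0.12,
    seed: int = 0,
):
    """Residual-scale study with one planted correlated CpG region.

    Generates per-observation residual outcomes directly (as if cell/age
    residualization had already run): the first ``region_size`` CpGs sit
    within 500 bp on one chromosome, share ``region_effect`` on the AUC and
    have cross-CpG residual correlation ``region_rho``; the ``n_null``
    remaining CpGs are independent nulls spaced far apart.  Returns
    ``(residuals, samples, annotation, truth_effects)`` ready for the
    association and DMR stages.
    """
    if config is None:
        config = SimulationConfig(seed=seed)
    subjects = simulate_cohort(config)
    frame = subjects_frame(subjects)
    rng = np.random.default_rng([int(seed), 17])

    g = region_size + n_null
    ids = cpg_ids(g)
    chrom = np.array(["1"] * region_size + ["2"] * n_null)
    pos = np.concatenate(
        [10_000 + 200 * np.arange(region_size), 10_000 + 10_000 * np.arange(n_null)]
    )
    annotation = pd.DataFrame({"chrom": chrom, "pos": pos}, index=pd.Index(ids, name="cpg_id"))

    sample_rows = []
    for s in subjects:
        if s.has_birth_sample:
            sample_rows.append((f"{s.subject_id}_B", s.subject_id, "birth", s.gestational_age_birth))
        if s.has_5y_sample:
            sample_rows.append((f"{s.subject_id}_5y", s.subject_id, "5y", s.child_age_5y))
    samples = pd.DataFrame(
        sample_rows, columns=["sample_id", "subject_id", "timepoint", "age"]
    ).set_index("sample_id")
    for col in ["maternal_age", "bmi_t1", "gravidity", "smoking", "child_sex",
                "glucose_0", "glucose_1", "glucose_2", "auc"]:
        samples[col] = frame.loc[samples["subject_id"], col].to_numpy()

    auc_c = samples["auc"] - frame["auc"].mean()
    n_obs = len(samples)
    subj_codes = pd.factorize(samples["subject_id"])[0]
    intercepts = rng.normal(0.0, sigma_subject, (g, subj_codes.max() + 1))

    corr = np.full((region_size, region_size), region_rho)
    np.fill_diagonal(corr, 1.0)
    chol = np.linalg.cholesky(corr)
    region_noise = (rng.standard_normal((n_obs, region_size)) @ chol.T).T * sigma
    null_noise = rng.normal(0.0, sigma, (n_null, n_obs))

    y = np.vstack([region_noise, null_noise]) + intercepts[:, subj_codes]
    y[:region_size] += region_effect * auc_c.to_numpy()[None, :]

    residuals = {
        tp: pd.DataFrame(
            y[:, (samples["timepoint"] == tp).to_numpy()],
            index=annotation.index,
            columns=samples.index[samples["timepoint"] == tp],
        )
        for tp in ("birth", "5y")
    }
    truth = pd.Series(
        [region_effect] * region_size + [0.0] * n_null, index=annotation.index
    )
    return residuals, samples, annotation, truth
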