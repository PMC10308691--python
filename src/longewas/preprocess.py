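"""From beta-values to analysis-ready residualized M-values.

Stages, in the order the pipeline applies them:

1. probe filtering (annotation flags, zero variance, detection failures);
2. empirical-Bayes location/scale batch adjustment on the M-value scale,
   protecting the biological covariates of interest (a re-implementation of
   the parametric ComBat algorithm);
3. reference-based cell-composition estimation per sample (non-negative
   least squares on a cell-type mean-beta panel, constrained to the simplex);
4. per-time-point residualization of M-values on cell proportions and age.

The residual matrices produced here are the outcomes of the downstream
per-CpG mixed models.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from .errors import DataError, ValidationError

logger = logging.getLogger(__name__)

#: Clipping bound applied to beta before the logit transform.
BETA_EPS = 1e-6

#: Weight of the sum-to-one row in the constrained deconvolution system.
_SIMPLEX_WEIGHT = 1000.0

TIMEPOINTS = ("birth", "5y")

#: Annotation flag columns consumed by :func:`filter_probes`.
FLAG_COLUMNS = ("is_noncpg", "is_sex_chrom", "is_snp_maf05", "is_cross_reactive")


@dataclass
class MethylationStudy:
    """A beta-value matrix with per-sample metadata and per-CpG annotation.

    ``beta`` is CpG x sample in (0, 1); ``sample_metadata`` is indexed by
    sample id (columns: subject_id, timepoint, batch, age, covariates,
    glucose_0/1/2, auc); ``cpg_annotation`` is indexed by CpG id (columns:
    chrom, pos and the exclusion flags).  ``detection_p`` optionally holds a
    CpG x sample detection p-value matrix.
    """

    beta: pd.DataFrame
    sample_metadata: pd.DataFrame
    cpg_annotation: pd.DataFrame
    detection_p: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if list(self.beta.columns) != list(self.sample_metadata.index):
            raise DataError("beta columns and sample_metadata rows disagree")
        if not self.beta.index.is_unique:
            raise DataError("CpG ids are not unique")
        if list(self.beta.index) != list(self.cpg_annotation.index):
            raise DataError("beta rows and cpg_annotation rows disagree")
        if "pos" in self.cpg_annotation and (self.cpg_annotation["pos"] < 1).any():
            raise DataError("positions must be >= 1 (1-based)")
        if self.detection_p is not None and self.detection_p.shape != self.beta.shape:
            raise DataError("detection_p shape differs from beta")

    @property
    def mvalues(self) -> pd.DataFrame:
        """M = log2(beta / (1 - beta)) with extreme betas clipped at 1e-6."""
        return pd.DataFrame(
            beta_to_m(self.beta.to_numpy()),
            index=self.beta.index,
            columns=self.beta.columns,
        )

    def samples_at(self, timepoint: str) -> pd.Index:
        if timepoint not in TIMEPOINTS:
            raise ValidationError(f"unknown timepoint {timepoint!r}; expected {TIMEPOINTS}")
        mask = self.sample_metadata["timepoint"] == timepoint
        return self.sample_metadata.index[mask]


def beta_to_m(beta, eps: float = BETA_EPS):
    """Logit (base 2) transform of methylation proportions.

    Values outside [0, 1] raise; values at exactly 0 or 1 are clipped to
    [eps, 1 - eps] (logged) so M stays finite.
    """
    arr = np.asarray(beta, dtype=float)
    if np.any((arr < 0) | (arr > 1) | ~np.isfinite(arr)):
        raise ValidationError("beta values must lie in [0, 1]")
    n_clip = int(np.sum((arr < eps) | (arr > 1 - eps)))
    if n_clip:
        logger.info("clipped %d beta values to [%.0e, 1-%.0e] before logit", n_clip, eps, eps)
    clipped = np.clip(arr, eps, 1 - eps)
    out = np.log2(clipped / (1 - clipped))
    return out if out.shape else float(out)


def m_to_beta(m):
    """Inverse of :func:`beta_to_m`: beta = 2^M / (1 + 2^M)."""
    arr = np.asarray(m, dtype=float)
    out = 1.0 / (1.0 + np.exp2(-arr))
    return out if out.shape else float(out)


def filter_probes(
    study: MethylationStudy,
    detection_alpha: float = 0.05,
    max_fail_fraction: float = 0.05,
) -> tuple[MethylationStudy, pd.DataFrame]:
    """Remove excluded probes and return the filtered study plus a report.

    Rules are applied in a fixed, documented order, and a probe failing
    several rules is attributed to the first one it fails:

    1. non-CpG probes (flag or an ``rs``/``ch`` id prefix);
    2. sex-chromosome probes;
    3. SNP-associated probes (MAF >= 0.05 flag);
    4. cross-reactive probes;
    5. zero-variance probes;
    6. probes whose detection p-value exceeds ``detection_alpha`` in at least
       ``max_fail_fraction`` of samples (skipped, and logged, when no
       detection matrix is present).

    The report has one row per rule with the number of probes removed.
    """
    ann = study.cpg_annotation
    beta = study.beta

    def flag(col: str) -> pd.Series:
        if col in ann.columns:
            return ann[col].astype(bool)
        return pd.Series(False, index=ann.index)

    noncpg = flag("is_noncpg") | ann.index.str.startswith(("rs", "ch"))
    sex = flag("is_sex_chrom")
    snp = flag("is_snp_maf05")
    xreact = flag("is_cross_reactive")
    values = beta.to_numpy()
    zero_var = pd.Series(np.ptp(values, axis=1) == 0.0, index=beta.index)
    if study.detection_p is not None:
        fail_frac = (study.detection_p.to_numpy() > detection_alpha).mean(axis=1)
        detect = pd.Series(fail_frac >= max_fail_fraction, index=beta.index)
    else:
        logger.info("no detection p-value matrix present; skipping the detection rule")
        detect = pd.Series(False, index=beta.index)

    removed = pd.Series(False, index=beta.index)
    counts: list[tuple[str, int]] = []
    for rule, mask in [
        ("non_cpg", noncpg),
        ("sex_chromosome", sex),
        ("snp_maf05", snp),
        ("cross_reactive", xreact),
        ("zero_variance", zero_var),
        ("detection_failure", detect),
    ]:
        new = mask & ~removed
        counts.append((rule, int(new.sum())))
        removed |= mask
    keep = ~removed

    report = pd.DataFrame(counts, columns=["rule", "n_removed"])
    report.loc[len(report)] = ["retained", int(keep.sum())]
    filtered = MethylationStudy(
        beta=beta.loc[keep],
        sample_metadata=study.sample_metadata,
        cpg_annotation=ann.loc[keep],
        detection_p=None if study.detection_p is None else study.detection_p.loc[keep],
    )
    return filtered, report


# ---------------------------------------------------------------------------
# Empirical-Bayes batch adjustment (parametric location/scale model)
# ---------------------------------------------------------------------------


@dataclass
class CombatModel:
    """Fitted batch-adjustment parameters.

    ``gamma_star``/``delta2_star`` are the empirical-Bayes posterior batch
    location and scale parameters (probe x batch, on the standardized scale);
    ``protected_columns`` names the covariates whose fitted effects were held
    out of the adjustment and restored unchanged.
    """

    batches: list[str]
    gamma_star: pd.DataFrame
    delta2_star: pd.DataFrame
    protected_columns: list[str]
    n_iter: pd.Series

    def __post_init__(self) -> None:
        if (self.delta2_star.to_numpy() <= 0).any():
            raise DataError("posterior scale parameters must be positive")


def combat_matrix(
    m: np.ndarray,
    batch: np.ndarray,
    protected: np.ndarray | None,
    protected_names: list[str] | None = None,
    tol: float = 1e-6,
    max_iter: int = 500,
) -> tuple[np.ndarray, CombatModel]:
    """Parametric empirical-Bayes batch adjustment of a probe x sample matrix.

    Per probe the model is  y_ij = alpha + x_j' beta + gamma_b(j) +
    delta_b(j) e_ij.  Probes are standardized under the protected design,
    per-batch location/scale estimates are shrunk with method-of-moments
    priors (normal for locations, inverse-gamma for scales) solved by the
    usual fixed-point iteration, and the data are back-transformed with the
    protected fitted effects restored unchanged.
    """
    m = np.asarray(m, dtype=float)
    batch = np.asarray(batch)
    levels, codes = np.unique(batch, return_inverse=True)
    n_batch = len(levels)
    n_probes, n_samples = m.shape
    counts = np.bincount(codes, minlength=n_batch)
    if counts.min() < 2:
        small = levels[counts < 2]
        raise ValidationError(f"every batch needs >= 2 samples; too small: {list(small)}")
    if n_batch == 1:
        # One batch: the location/scale model is degenerate (nothing to
        # adjust); return the input unchanged.
        model = CombatModel(
            batches=[str(levels[0])],
            gamma_star=pd.DataFrame(np.zeros((n_probes, 1)), columns=[str(levels[0])]),
            delta2_star=pd.DataFrame(np.ones((n_probes, 1)), columns=[str(levels[0])]),
            protected_columns=list(protected_names or []),
            n_iter=pd.Series(np.zeros(n_probes, dtype=int)),
        )
        return m.copy(), model

    onehot = np.zeros((n_samples, n_batch))
    onehot[np.arange(n_samples), codes] = 1.0
    if protected is not None and protected.size:
        protected = np.asarray(protected, dtype=float)
        design = np.hstack([onehot, protected])
    else:
        protected = np.zeros((n_samples, 0))
        design = onehot
    names = list(protected_names or [f"x{i}" for i in range(protected.shape[1])])
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        raise ValidationError(
            "batch indicators plus protected design are rank deficient; "
            f"check for collinear protected columns among {names}"
        )

    # Per-probe OLS under [batch one-hots | protected covariates].
    coef, *_ = np.linalg.lstsq(design, m.T, rcond=None)
    gamma_hat_full = coef[:n_batch]                      # batch x probe
    beta_prot = coef[n_batch:]                            # q x probe
    grand = (counts / n_samples) @ gamma_hat_full         # probe
    resid = m - (design @ coef).T
    var_pooled = np.mean(resid**2, axis=1)                # probe
    var_pooled = np.maximum(var_pooled, 1e-12)
    stand_mean = grand[:, None] + (protected @ beta_prot).T
    z = (m - stand_mean) / np.sqrt(var_pooled)[:, None]

    gamma_star = np.empty((n_probes, n_batch))
    delta2_star = np.empty((n_probes, n_batch))
    iters = np.zeros(n_probes, dtype=int)
    for b in range(n_batch):
        zb = z[:, codes == b]
        nb = zb.shape[1]
        g_hat = zb.mean(axis=1)
        d_hat = zb.var(axis=1, ddof=1)
        g_bar = g_hat.mean()
        t2 = g_hat.var(ddof=1)
        m_d = d_hat.mean()
        s2_d = d_hat.var(ddof=1)
        if t2 <= 0 or s2_d <= 0:
            # Degenerate priors (e.g. near-identical probes): no shrinkage.
            gamma_star[:, b] = g_hat
            delta2_star[:, b] = np.maximum(d_hat, 1e-12)
            continue
        a_prior = (2 * s2_d + m_d**2) / s2_d
        b_prior = (m_d * s2_d + m_d**3) / s2_d
        g_star = g_hat.copy()
        d_star = d_hat.copy()
        for it in range(max_iter):
            g_new = (nb * t2 * g_hat + d_star * g_bar) / (nb * t2 + d_star)
            ssq = ((zb - g_new[:, None]) ** 2).sum(axis=1)
            d_new = (b_prior + 0.5 * ssq) / (nb / 2 + a_prior - 1)
            change = max(
                np.max(np.abs(g_new - g_star)), np.max(np.abs(d_new - d_star))
            )
            g_star, d_star = g_new, d_new
            if change < tol:
                break
        else:
            logger.warning("EB iteration hit the cap (%d) for batch %s", max_iter, levels[b])
        iters = np.maximum(iters, it + 1)
        gamma_star[:, b] = g_star
        delta2_star[:, b] = np.maximum(d_star, 1e-12)

    z_adj = (z - gamma_star[:, codes]) / np.sqrt(delta2_star[:, codes])
    adjusted = z_adj * np.sqrt(var_pooled)[:, None] + stand_mean
    model = CombatModel(
        batches=[str(b) for b in levels],
        gamma_star=pd.DataFrame(gamma_star, columns=[str(b) for b in levels]),
        delta2_star=pd.DataFrame(delta2_star, columns=[str(b) for b in levels]),
        protected_columns=names,
        n_iter=pd.Series(iters),
    )
    return adjusted, model


#: Covariates protected during batch adjustment: the three OGTT glucose
#: values plus the maternal/child covariates of the association models.
PROTECTED_COLUMNS = (
    "glucose_0",
    "glucose_1",
    "glucose_2",
    "maternal_age",
    "bmi_t1",
    "gravidity",
    "smoking",
    "child_sex",
)


def protected_design(metadata: pd.DataFrame, columns=PROTECTED_COLUMNS) -> np.ndarray:
    """Numeric protected-covariate matrix from the sample metadata."""
    missing = [c for c in columns if c not in metadata.columns]
    if missing:
        raise DataError(f"sample metadata lacks protected columns {missing}")
    return metadata.loc[:, list(columns)].astype(float).to_numpy()


def combat_adjust(
    study: MethylationStudy,
    batch_labels: pd.Series | None = None,
    protected: pd.DataFrame | np.ndarray | None = None,
) -> tuple[MethylationStudy, CombatModel]:
    """Batch-adjust a study on the M-value scale; returns a new study.

    Defaults take batches from ``sample_metadata['batch']`` and protect the
    glucose triplet plus the model covariates.  The adjusted M-values are
    mapped back to beta so the container invariant (beta in (0, 1)) holds.
    """
    meta = study.sample_metadata
    if batch_labels is None:
        batch_labels = meta["batch"]
    names: list[str] | None
    if protected is None:
        prot = protected_design(meta)
        names = list(PROTECTED_COLUMNS)
    elif isinstance(protected, pd.DataFrame):
        prot = protected.to_numpy(dtype=float)
        names = list(protected.columns)
    else:
        prot = np.asarray(protected, dtype=float)
        names = None
    adjusted_m, model = combat_matrix(
        study.mvalues.to_numpy(), np.asarray(batch_labels), prot, names
    )
    beta_adj = pd.DataFrame(
        m_to_beta(adjusted_m), index=study.beta.index, columns=study.beta.columns
    )
    return replace(study, beta=beta_adj, detection_p=study.detection_p), model


# ---------------------------------------------------------------------------
# Reference-based cell-composition estimation
# ---------------------------------------------------------------------------


@dataclass
class CellComposition:
    """Per-sample cell-type proportions on the simplex of one panel."""

    proportions: pd.DataFrame  # sample x cell type

    def __post_init__(self) -> None:
        arr = self.proportions.to_numpy()
        if (arr < -1e-12).any():
            raise DataError("cell proportions must be non-negative")
        if np.max(np.abs(arr.sum(axis=1) - 1.0)) > 1e-8:
            raise DataError("cell proportions must sum to 1 within 1e-8")


def estimate_cell_composition(
    study_or_beta: MethylationStudy | pd.DataFrame,
    panel: pd.DataFrame,
    discriminating: list[str] | None = None,
    samples: pd.Index | None = None,
) -> CellComposition:
    """Constrained projection of sample betas onto a cell-type reference panel.

    For each sample solve  min || y - F^T p ||^2  s.t.  p >= 0, sum(p) = 1,
    where ``y`` is the sample's beta at the panel's discriminating CpGs and
    ``F`` is the panel (cell type x CpG mean beta).  The simplex constraint is
    enforced by a heavily weighted sum-to-one row in a non-negative
    least-squares system, followed by exact renormalization.  Deterministic.
    """
    beta = study_or_beta.beta if isinstance(study_or_beta, MethylationStudy) else study_or_beta
    if samples is not None:
        beta = beta.loc[:, samples]
    cpgs = list(discriminating) if discriminating is not None else list(panel.columns)
    missing = [c for c in cpgs if c not in beta.index]
    if missing:
        raise DataError(f"{len(missing)} panel CpGs absent from the study (e.g. {missing[:3]})")
    k = panel.shape[0]
    if len(cpgs) < k:
        raise ValidationError(
            f"need at least as many discriminating CpGs ({len(cpgs)}) as cell types ({k})"
        )
    f = panel.loc[:, cpgs].to_numpy(dtype=float)  # k x d
    if np.linalg.matrix_rank(f) < k:
        raise ValidationError(
            "reference panel has linearly dependent cell-type profiles; "
            "composition is not identifiable"
        )
    a = np.vstack([f.T, _SIMPLEX_WEIGHT * np.ones((1, k))])
    y = beta.loc[cpgs].to_numpy(dtype=float)
    out = np.empty((y.shape[1], k))
    for j in range(y.shape[1]):
        b = np.append(y[:, j], _SIMPLEX_WEIGHT)
        p, _ = nnls(a, b)
        total = p.sum()
        out[j] = p / total if total > 0 else np.full(k, 1.0 / k)
    return CellComposition(
        proportions=pd.DataFrame(out, index=beta.columns, columns=panel.index)
    )


# ---------------------------------------------------------------------------
# Per-time-point residualization
# ---------------------------------------------------------------------------


def residualize(
    study: MethylationStudy,
    composition: CellComposition,
    timepoint: str,
    drop_cell_type: str | None = None,
) -> pd.DataFrame:
    """OLS residuals of M-values on cell proportions and age, one time point.

    The design is [intercept, cell proportions with one type dropped, age];
    the dropped type defaults to the panel's most abundant (mean) type, which
    removes the sum-to-one collinearity of the simplex.  Age is gestational
    weeks at birth and years at 5 y (the metadata ``age`` column).  Residuals
    are exactly orthogonal to every design column (QR projection).
    """
    sample_ids = study.samples_at(timepoint)
    if len(sample_ids) == 0:
        raise DataError(f"no samples at timepoint {timepoint!r}")
    props = composition.proportions.loc[sample_ids]
    if drop_cell_type is None:
        drop_cell_type = props.mean(axis=0).idxmax()
    kept = [c for c in props.columns if c != drop_cell_type]
    age = study.sample_metadata.loc[sample_ids, "age"].astype(float).to_numpy()
    x = np.column_stack(
        [np.ones(len(sample_ids)), props[kept].to_numpy(dtype=float), age]
    )
    if np.linalg.matrix_rank(x) < x.shape[1]:
        raise ValidationError(
            f"residualization design is rank deficient at {timepoint} "
            f"(cell columns {kept} + age)"
        )
    q, _ = np.linalg.qr(x)
    m = study.mvalues.loc[:, sample_ids].to_numpy()
    resid = m - (m @ q) @ q.T
    return pd.DataFrame(resid, index=study.beta.index, columns=sample_ids)


@dataclass
class PreprocessResult:
    """All artifacts of the preprocessing stage."""

    study: MethylationStudy            # filtered + batch-adjusted
    residuals: dict[str, pd.DataFrame]  # timepoint -> CpG x sample residual matrix
    composition: dict[str, CellComposition]
    filter_report: pd.DataFrame
    combat_model: CombatModel


def preprocess_study(
    study: MethylationStudy,
    panels,
    detection_alpha: float = 0.05,
    max_fail_fraction: float = 0.05,
    adjust_batches: bool = True,
) -> PreprocessResult:
    """Run filtering, batch adjustment, deconvolution and residualization.

    ``panels`` carries the cord/peripheral reference matrices and their
    discriminating CpG lists (see ``simcohort.ReferencePanels``).  Cell
    composition is estimated from the unadjusted betas (reference panels are
    defined on raw proportions); residualization uses the batch-adjusted
    M-values of the filtered study.
    """
    composition = {
        "birth": estimate_cell_composition(
            study, panels.cord, panels.cord_discriminating, study.samples_at("birth")
        ),
        "5y": estimate_cell_composition(
            study,
            panels.peripheral,
            panels.peripheral_discriminating,
            study.samples_at("5y"),
        ),
    }
    filtered, report = filter_probes(study, detection_alpha, max_fail_fraction)
    if adjust_batches and study.sample_metadata["batch"].nunique() > 1:
        adjusted, model = combat_adjust(filtered)
    else:
        adjusted, model = combat_adjust(
            filtered, batch_labels=pd.Series("all", index=filtered.beta.columns)
        )
    residuals = {
        tp: residualize(adjusted, composition[tp], tp) for tp in TIMEPOINTS
    }
    return PreprocessResult(
        study=adjusted,
        residuals=residuals,
        composition=composition,
        filter_report=report,
        combat_model=model,
    )
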