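"""Per-CpG association models: random-intercept REML and single-time-point OLS.

The longitudinal model for CpG residual y_ij of subject i at occasion j is

    y_ij = x_ij' theta + b_i + e_ij,   b_i ~ N(0, sigma_b^2),  e_ij ~ N(0, sigma_e^2)

with fixed effects x_ij = (1, exposure, maternal covariates, time point).
Each subject contributes one or two rows, so with the variance ratio
gamma = sigma_b^2 / sigma_e^2 the per-subject covariance V_i = I + gamma J
(J the all-ones block) has the closed-form inverse
V_i^{-1} = I - gamma / (1 + n_i gamma) J for block sizes 1-2.  The restricted
(REML) log-likelihood is profiled to the scalar gamma >= 0 and maximized by
bounded scalar search on the log scale; the gamma = 0 boundary (which makes
the fit identical to OLS on the stacked rows) is always evaluated and kept
when superior.  Inference is Wald with a normal reference.

A deliberately naive full-matrix REML likelihood
(:func:`reml_loglik_full`) is included as a slow reference for validation;
it shares no code with the profiled fast path.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .errors import DataError, ValidationError

GAMMA_MAX = 100.0
_GAMMA_FLOOR = 1e-8

#: Fixed covariates of the association models (always with an intercept; the
#: longitudinal model adds the binary time-point indicator, birth=0 / 5y=1).
DEFAULT_COVARIATES = ("maternal_age", "gravidity", "smoking", "child_sex", "bmi_t1")

#: Exposure name -> sample-sheet column.
EXPOSURE_COLUMNS = {
    "auc": "auc",
    "fasting": "glucose_0",
    "1h": "glucose_1",
    "2h": "glucose_2",
}

EWAS_COLUMNS = [
    "cpg_id", "chrom", "pos", "exposure", "model", "estimate", "se", "z", "p",
    "n_obs", "n_subjects", "status",
]


@dataclass
class LongitudinalDesign:
    """Stacked fixed-effect design with subject grouping precomputations."""

    x: np.ndarray                 # n_obs x p
    columns: list[str]
    subject_codes: np.ndarray     # n_obs, 0..n_subjects-1
    sample_ids: list[str]
    n_subjects: int
    single_rows: np.ndarray       # indices of rows from single-observation subjects
    pair_rows: np.ndarray         # m2 x 2 row indices of two-observation subjects
    xtx: np.ndarray
    g1: np.ndarray                # sum over singleton rows of x x'
    g2: np.ndarray                # sum over pairs of (x1+x2)(x1+x2)'
    sx: np.ndarray                # m2 x p pair row-sums of x

    @property
    def n_obs(self) -> int:
        return self.x.shape[0]

    @property
    def p(self) -> int:
        return self.x.shape[1]


def build_longitudinal_design(
    samples: pd.DataFrame,
    exposure: str = "auc",
    covariates: Sequence[str] = DEFAULT_COVARIATES,
) -> LongitudinalDesign:
    """Design from a stacked sample sheet covering one or both time points.

    Complete cases only: rows missing the exposure or a covariate are dropped
    (counts logged by the caller via the returned size).  Validates the
    one-row-per-(subject, timepoint) contract and that the exposure varies.
    """
    exp_col = EXPOSURE_COLUMNS.get(exposure, exposure)
    needed = [exp_col, *covariates, "subject_id", "timepoint"]
    missing = [c for c in needed if c not in samples.columns]
    if missing:
        raise DataError(f"sample sheet lacks columns {missing}")
    frame = samples.dropna(subset=[exp_col, *covariates])
    if frame.duplicated(subset=["subject_id", "timepoint"]).any():
        raise DataError("at most one row per (subject, timepoint) is allowed")
    e = frame[exp_col].astype(float).to_numpy()
    if e.size == 0:
        raise DataError("no complete-case rows available")
    if np.ptp(e) == 0:
        raise ValidationError(f"exposure {exposure!r} has zero variance")
    t = (frame["timepoint"] == "5y").astype(float).to_numpy()
    cov = frame.loc[:, list(covariates)].astype(float).to_numpy()
    if np.ptp(t) > 0:
        x = np.column_stack([np.ones(len(frame)), e, cov, t])
        columns = ["intercept", exposure, *covariates, "timepoint"]
    else:
        # single time point: the indicator is constant and is dropped
        x = np.column_stack([np.ones(len(frame)), e, cov])
        columns = ["intercept", exposure, *covariates]
    if np.linalg.matrix_rank(x) < x.shape[1]:
        raise ValidationError("fixed-effect design is rank deficient")
    codes, _ = pd.factorize(frame["subject_id"])
    return _finalize_design(x, columns, codes, list(frame.index))


def _finalize_design(
    x: np.ndarray, columns: list[str], codes: np.ndarray, sample_ids: list[str]
) -> LongitudinalDesign:
    codes = np.asarray(codes)
    n_subjects = codes.max() + 1
    counts = np.bincount(codes, minlength=n_subjects)
    if counts.max() > 2:
        raise DataError("a subject may contribute at most two rows (one per time point)")
    order = np.argsort(codes, kind="stable")
    single_rows = order[np.isin(codes[order], np.flatnonzero(counts == 1))]
    pair_subjects = np.flatnonzero(counts == 2)
    pair_rows = order[np.isin(codes[order], pair_subjects)].reshape(-1, 2)
    sx = x[pair_rows[:, 0]] + x[pair_rows[:, 1]] if len(pair_rows) else np.zeros((0, x.shape[1]))
    xs = x[single_rows]
    return LongitudinalDesign(
        x=x,
        columns=columns,
        subject_codes=codes,
        sample_ids=sample_ids,
        n_subjects=int(n_subjects),
        single_rows=single_rows,
        pair_rows=pair_rows,
        xtx=x.T @ x,
        g1=xs.T @ xs,
        g2=sx.T @ sx,
        sx=sx,
    )


@dataclass
class RandomInterceptFit:
    """A fitted per-CpG random-intercept model."""

    coefficients: pd.Series
    se: pd.Series
    z: pd.Series
    p: pd.Series
    sigma2_subject: float
    sigma2_resid: float
    gamma: float
    n_obs: int
    n_subjects: int
    converged: bool
    reml_loglik: float

    def __post_init__(self) -> None:
        if self.sigma2_subject < 0 or self.sigma2_resid <= 0:
            raise DataError("variance components out of range")


class _PerOutcomeStats:
    """Sufficient statistics of one outcome vector against a fixed design."""

    __slots__ = ("xty", "yty", "b1", "y1sq", "b2", "s2sq")

    def __init__(self, design: LongitudinalDesign, y: np.ndarray):
        self.xty = design.x.T @ y
        self.yty = float(y @ y)
        ys = y[design.single_rows]
        self.b1 = design.x[design.single_rows].T @ ys
        self.y1sq = float(ys @ ys)
        if len(design.pair_rows):
            sy = y[design.pair_rows[:, 0]] + y[design.pair_rows[:, 1]]
            self.b2 = design.sx.T @ sy
            self.s2sq = float(sy @ sy)
        else:
            self.b2 = np.zeros(design.p)
            self.s2sq = 0.0


def _profiled_reml(design: LongitudinalDesign, st: _PerOutcomeStats, gamma: float):
    """GLS solve and profiled REML criterion at a fixed variance ratio."""
    c1 = gamma / (1.0 + gamma)
    c2 = gamma / (1.0 + 2.0 * gamma)
    a = design.xtx - c1 * design.g1 - c2 * design.g2
    u = st.xty - c1 * st.b1 - c2 * st.b2
    q = st.yty - c1 * st.y1sq - c2 * st.s2sq
    chol = np.linalg.cholesky(a)
    theta = np.linalg.solve(a, u)
    rss = max(q - u @ theta, 1e-300)
    df = design.n_obs - design.p
    sigma2 = rss / df
    m1 = len(design.single_rows)
    m2 = len(design.pair_rows)
    logdet_v = m1 * np.log1p(gamma) + m2 * np.log1p(2.0 * gamma)
    logdet_a = 2.0 * np.sum(np.log(np.diag(chol)))
    loglik = -0.5 * (df * np.log(sigma2) + logdet_v + logdet_a)
    return loglik, theta, sigma2, a


def fit_random_intercept_reml(
    design: LongitudinalDesign,
    outcome: np.ndarray,
    gamma_max: float = GAMMA_MAX,
) -> RandomInterceptFit:
    """REML fit of the random-intercept model, profiled to gamma.

    When no subject repeats, the intercept variance is unidentifiable and the
    boundary fit gamma = 0 (exactly OLS) is returned.  Otherwise gamma is
    found by bounded maximization of the profiled criterion on
    log-gamma in [log 1e-8, log gamma_max], explicitly compared against the
    gamma = 0 boundary.
    """
    y = np.asarray(outcome, dtype=float)
    if y.shape != (design.n_obs,):
        raise DataError(f"outcome length {y.shape} != design rows {design.n_obs}")
    st = _PerOutcomeStats(design, y)
    gamma, converged = _optimize_gamma(design, st, gamma_max, polish=True)
    loglik, theta, sigma2, a = _profiled_reml(design, st, gamma)
    cov = sigma2 * np.linalg.inv(a)
    se = np.sqrt(np.diag(cov))
    z = theta / se
    p = 2.0 * stats.norm.sf(np.abs(z))
    idx = pd.Index(design.columns)
    return RandomInterceptFit(
        coefficients=pd.Series(theta, index=idx),
        se=pd.Series(se, index=idx),
        z=pd.Series(z, index=idx),
        p=pd.Series(np.clip(p, np.nextafter(0, 1), 1.0), index=idx),
        sigma2_subject=float(gamma * sigma2),
        sigma2_resid=float(sigma2),
        gamma=float(gamma),
        n_obs=design.n_obs,
        n_subjects=design.n_subjects,
        converged=converged,
        reml_loglik=float(loglik),
    )


def _quadratic_polish(fun, gamma: float, half_width: float) -> float:
    """Refine a scalar maximizer by a local parabola fit.

    Single likelihood evaluations carry O(1e-13) floating-point noise, which
    caps bracketing optimizers near sqrt(noise/curvature); a least-squares
    parabola over a small grid averages the noise out and its vertex
    localizes the optimum one to two orders of magnitude more precisely.
    """
    grid = gamma + np.linspace(-half_width, half_width, 11)
    grid = grid[grid > 0]
    if len(grid) < 5:
        return gamma
    vals = np.array([fun(g) for g in grid])
    coef = np.polyfit(grid - gamma, vals, 2)
    if coef[0] >= 0:  # not locally concave at this scale
        return gamma
    vertex = gamma - coef[1] / (2.0 * coef[0])
    lo, hi = grid[0], grid[-1]
    return float(vertex) if lo <= vertex <= hi else gamma


def _optimize_gamma(
    design: LongitudinalDesign, st: _PerOutcomeStats, gamma_max: float, polish: bool = False
) -> tuple[float, bool]:
    if len(design.pair_rows) == 0:
        return 0.0, True
    def neg(u: float) -> float:
        return -_profiled_reml(design, st, float(np.exp(u)))[0]
    res = optimize.minimize_scalar(
        neg,
        bounds=(np.log(_GAMMA_FLOOR), np.log(gamma_max)),
        method="bounded",
        options={"xatol": 1e-13, "maxiter": 500},
    )
    gamma = float(np.exp(res.x))
    ll_hat = -res.fun
    ll_zero = _profiled_reml(design, st, 0.0)[0]
    if ll_zero >= ll_hat or gamma <= _GAMMA_FLOOR * (1 + 1e-6):
        return 0.0, True
    if polish:
        gamma = _quadratic_polish(
            lambda g: _profiled_reml(design, st, g)[0], gamma, max(1e-4 * gamma, 1e-7)
        )
    return gamma, bool(res.success)


# ---------------------------------------------------------------------------
# Naive full-matrix REML reference (validation only; no shared code path)
# ---------------------------------------------------------------------------


def reml_loglik_full(
    gamma: float, x: np.ndarray, y: np.ndarray, subject_codes: np.ndarray
) -> float:
    """Profiled REML log-likelihood via dense V = I + gamma ZZ' (slow path)."""
    n, p = x.shape
    z = np.zeros((n, subject_codes.max() + 1))
    z[np.arange(n), subject_codes] = 1.0
    v = np.eye(n) + gamma * z @ z.T
    vinv = np.linalg.inv(v)
    xtvx = x.T @ vinv @ x
    theta = np.linalg.solve(xtvx, x.T @ vinv @ y)
    r = y - x @ theta
    sigma2 = (r @ vinv @ r) / (n - p)
    _, ld_v = np.linalg.slogdet(v)
    _, ld_a = np.linalg.slogdet(xtvx)
    return float(-0.5 * ((n - p) * np.log(sigma2) + ld_v + ld_a))


def fit_random_intercept_full(
    x: np.ndarray, y: np.ndarray, subject_codes: np.ndarray, gamma_max: float = GAMMA_MAX
):
    """Brute-force REML fit by generic scalar maximization of the dense
    likelihood; returns (theta, sigma2_subject, sigma2_resid, gamma)."""
    res = optimize.minimize_scalar(
        lambda g: -reml_loglik_full(g, x, y, subject_codes),
        bounds=(0.0, gamma_max),
        method="bounded",
        options={"xatol": 1e-13, "maxiter": 1000},
    )
    gamma = float(res.x)
    if reml_loglik_full(0.0, x, y, subject_codes) >= -res.fun:
        gamma = 0.0
    else:
        gamma = _quadratic_polish(
            lambda g: reml_loglik_full(g, x, y, subject_codes),
            gamma,
            max(1e-4 * gamma, 1e-7),
        )
    n, p = x.shape
    z = np.zeros((n, subject_codes.max() + 1))
    z[np.arange(n), subject_codes] = 1.0
    vinv = np.linalg.inv(np.eye(n) + gamma * z @ z.T)
    xtvx = x.T @ vinv @ x
    theta = np.linalg.solve(xtvx, x.T @ vinv @ y)
    r = y - x @ theta
    sigma2 = float((r @ vinv @ r) / (n - p))
    return theta, gamma * sigma2, sigma2, gamma


# ---------------------------------------------------------------------------
# EWAS drivers
# ---------------------------------------------------------------------------


def _annotate(table: pd.DataFrame, annotation: pd.DataFrame | None) -> pd.DataFrame:
    if annotation is not None:
        table["chrom"] = annotation["chrom"].reindex(table["cpg_id"]).to_numpy()
        table["pos"] = annotation["pos"].reindex(table["cpg_id"]).to_numpy()
    else:
        table["chrom"] = pd.NA
        table["pos"] = pd.NA
    return table[EWAS_COLUMNS]


def ewas_lmm(
    residuals: Mapping[str, pd.DataFrame],
    samples: pd.DataFrame,
    exposure: str = "auc",
    covariates: Sequence[str] = DEFAULT_COVARIATES,
    annotation: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Longitudinal EWAS: one random-intercept fit per CpG on stacked residuals.

    ``residuals`` maps time point -> CpG x sample residual matrix; the two
    matrices are stacked column-wise, subjects linked through the sample
    sheet.  Returns one row per CpG with the exposure coefficient (mean
    difference in DNAm residuals per unit exposure), its SE, Wald z, p,
    sample sizes and a convergence status.  Deterministic.
    """
    tps = [tp for tp in ("birth", "5y") if tp in residuals]
    if not tps:
        raise DataError("residuals must contain at least one of 'birth'/'5y'")
    common = residuals[tps[0]].index
    for tp in tps[1:]:
        common = common.intersection(residuals[tp].index)
    if len(common) == 0:
        raise DataError("the residual matrices share no CpG ids")
    stacked_cols = [c for tp in tps for c in residuals[tp].columns]
    design = build_longitudinal_design(samples.loc[stacked_cols], exposure, covariates)
    col_pos = {c: i for i, c in enumerate(stacked_cols)}
    keep = np.array([col_pos[c] for c in design.sample_ids])
    ymat = np.hstack([residuals[tp].loc[common].to_numpy() for tp in tps])[:, keep]

    e_idx = design.columns.index(exposure)
    rows = []
    for i, cpg in enumerate(common):
        st = _PerOutcomeStats(design, ymat[i])
        gamma, converged = _optimize_gamma(design, st, GAMMA_MAX)
        _, theta, sigma2, a = _profiled_reml(design, st, gamma)
        var_e = sigma2 * np.linalg.inv(a)[e_idx, e_idx]
        se = np.sqrt(var_e)
        zval = theta[e_idx] / se
        pval = 2.0 * stats.norm.sf(abs(zval))
        rows.append(
            (cpg, exposure, "lmm", theta[e_idx], se, zval, max(pval, np.nextafter(0, 1)),
             design.n_obs, design.n_subjects, "ok" if converged else "nonconverged")
        )
    table = pd.DataFrame(
        rows,
        columns=["cpg_id", "exposure", "model", "estimate", "se", "z", "p",
                 "n_obs", "n_subjects", "status"],
    )
    return _annotate(table, annotation)


def ewas_linear(
    residual: pd.DataFrame,
    samples: pd.DataFrame,
    exposure: str = "auc",
    timepoint: str = "birth",
    covariates: Sequence[str] = DEFAULT_COVARIATES,
    annotation: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Single-time-point EWAS: vectorized per-CpG OLS, same covariates, no T.

    With one observation per subject the random-intercept model collapses to
    OLS, so this equals :func:`ewas_lmm` restricted to that time point.
    """
    frame = samples.loc[residual.columns]
    exp_col = EXPOSURE_COLUMNS.get(exposure, exposure)
    needed = [exp_col, *covariates]
    missing = [c for c in needed if c not in frame.columns]
    if missing:
        raise DataError(f"sample sheet lacks columns {missing}")
    frame = frame.dropna(subset=needed)
    e = frame[exp_col].astype(float).to_numpy()
    if e.size == 0:
        raise DataError("no complete-case rows available")
    if np.ptp(e) == 0:
        raise ValidationError(f"exposure {exposure!r} has zero variance")
    x = np.column_stack(
        [np.ones(len(frame)), e, frame.loc[:, list(covariates)].astype(float).to_numpy()]
    )
    if np.linalg.matrix_rank(x) < x.shape[1]:
        raise ValidationError("fixed-effect design is rank deficient")
    ymat = residual.loc[:, frame.index].to_numpy()
    n, p = x.shape
    xtx_inv = np.linalg.inv(x.T @ x)
    coef = ymat @ x @ xtx_inv.T                     # G x p
    rss = np.sum((ymat - coef @ x.T) ** 2, axis=1)
    sigma2 = rss / (n - p)
    se = np.sqrt(sigma2 * xtx_inv[1, 1])
    est = coef[:, 1]
    zval = est / se
    pval = np.clip(2.0 * stats.norm.sf(np.abs(zval)), np.nextafter(0, 1), 1.0)
    table = pd.DataFrame(
        {
            "cpg_id": residual.index,
            "exposure": exposure,
            "model": f"linear_{timepoint}",
            "estimate": est,
            "se": se,
            "z": zval,
            "p": pval,
            "n_obs": n,
            "n_subjects": frame["subject_id"].nunique() if "subject_id" in frame else n,
            "status": "ok",
        }
    )
    return _annotate(table, annotation)


def run_all_exposures(
    residuals: Mapping[str, pd.DataFrame],
    samples: pd.DataFrame,
    covariates: Sequence[str] = DEFAULT_COVARIATES,
    annotation: pd.DataFrame | None = None,
    include_linear: bool = False,
    exposures: Sequence[str] = ("auc", "fasting", "1h", "2h"),
) -> dict[str, dict[str, pd.DataFrame]]:
    """All four glycemic exposures over a shared CpG universe.

    Returns ``{exposure: {"lmm": table, ["linear_birth": ..., "linear_5y": ...]}}``.
    """
    for name in exposures:
        col = EXPOSURE_COLUMNS.get(name, name)
        if col not in samples.columns:
            raise DataError(f"sample sheet lacks exposure column {col!r} for {name!r}")
    out: dict[str, dict[str, pd.DataFrame]] = {}
    for name in exposures:
        tables = {"lmm": ewas_lmm(residuals, samples, name, covariates, annotation)}
        if include_linear:
            for tp in ("birth", "5y"):
                if tp in residuals:
                    tables[f"linear_{tp}"] = ewas_linear(
                        residuals[tp], samples, name, tp, covariates, annotation
                    )
        out[name] = tables
    return out
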