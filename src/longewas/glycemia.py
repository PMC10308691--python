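"""Maternal glycemic exposures derived from a 75 g oral glucose tolerance test.

The primary exposure of the pipeline is the area under the glucose curve
(AUC_glu, mmol/L*h) over the 0/1/2 h OGTT measurements, computed with the
trapezoidal rule.  Secondary exposures are the individual glucose components
(fasting, 1 h, 2 h).  This module also provides a GDM classifier with
configurable cutoffs and the cohort descriptive table (N, mean +/- SD,
median [IQR], N (%)) used to summarise a study sample.

Glucose values are in mmol/L, times in hours, AUC in mmol/L*h.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_EVEN, Decimal
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError

#: Standard OGTT sampling times in hours (fasting, 1 h, 2 h post-load).
DEFAULT_OGTT_TIMES: tuple[float, ...] = (0.0, 1.0, 2.0)

#: IADPSG-style one-step diagnostic cutoffs (mmol/L) at 0/1/2 h.  These are a
#: documented assumption of this package, not a value reported by any single
#: cohort; they are configurable in :func:`classify_gdm`.
IADPSG_THRESHOLDS: tuple[float, float, float] = (5.1, 10.0, 8.5)


@dataclass(frozen=True)
class GlucoseProfile:
    """An OGTT time/value series for one mother.

    Parameters
    ----------
    values:
        Glucose concentrations in mmol/L, one per time point.
    times:
        Sampling times in hours, strictly increasing.  Defaults to the
        standard 0/1/2 h grid.
    """

    values: tuple[float, ...]
    times: tuple[float, ...] = DEFAULT_OGTT_TIMES

    def __post_init__(self) -> None:
        values = tuple(float(v) for v in self.values)
        times = tuple(float(t) for t in self.times)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "times", times)
        if len(values) != len(times):
            raise ValidationError(
                f"times ({len(times)}) and values ({len(values)}) differ in length"
            )
        if len(values) == 0:
            raise ValidationError("profile needs at least one measurement")
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise ValidationError(f"times must be strictly increasing, got {times}")
        if any(not np.isfinite(v) or v <= 0 for v in values):
            raise ValidationError(f"glucose values must be positive, got {values}")

    @property
    def auc(self) -> float:
        """Trapezoidal AUC in mmol/L*h (requires >= 2 points)."""
        return auc_trapezoid(self)


def auc_trapezoid(profile: GlucoseProfile) -> float:
    """Area under the glucose curve by the trapezoidal rule.

    Returns sum_k (t_{k+1} - t_k) * (g_k + g_{k+1}) / 2 in mmol/L*h.
    Linear in the glucose values and invariant to inserting a point that
    lies exactly on the line between its neighbours.
    """
    if len(profile.values) < 2:
        raise ValidationError("AUC requires at least two OGTT time points")
    return float(np.trapezoid(profile.values, profile.times))


def classify_gdm(
    profile: GlucoseProfile,
    thresholds: Sequence[float] = IADPSG_THRESHOLDS,
) -> bool:
    """Flag gestational diabetes: any OGTT value at/above its cutoff.

    The rule is monotone in every glucose value.  ``thresholds`` are the
    0/1/2 h cutoffs in mmol/L; the default is an IADPSG-style convention
    (a package assumption, configurable).
    """
    if len(profile.values) != 3:
        raise ValidationError(
            f"GDM classification needs the 0/1/2 h triplet, got {len(profile.values)} values"
        )
    if len(thresholds) != 3:
        raise ValidationError("exactly three cutoffs (0/1/2 h) are required")
    return any(v >= c for v, c in zip(profile.values, thresholds))


def round_half_even(x: float, ndigits: int = 1) -> float:
    """Decimal round-half-to-even at ``ndigits``, robust to binary-float fuzz.

    The value is first quantised at ``ndigits + 6`` decimals to strip float
    representation noise (e.g. 12.050000000000001 -> 12.05) and then rounded
    half-to-even at the target precision (12.05 -> 12.0).  This is the rule
    used for every number printed in report tables.
    """
    if not np.isfinite(x):
        return float(x)
    d = Decimal(repr(float(x)))
    d = d.quantize(Decimal(1).scaleb(-(ndigits + 6)), rounding=ROUND_HALF_EVEN)
    d = d.quantize(Decimal(1).scaleb(-ndigits), rounding=ROUND_HALF_EVEN)
    return float(d)


def _fmt(x: float, ndigits: int = 1) -> str:
    return f"{round_half_even(x, ndigits):.{ndigits}f}"


def mean_sd(values: Iterable[float], ndigits: int = 1) -> str:
    """``mean +/- SD`` formatted at one decimal; ``NA`` when SD is undefined."""
    arr = np.asarray([v for v in values if np.isfinite(v)], dtype=float)
    if arr.size == 0:
        return "NA"
    if arr.size == 1:
        return f"{_fmt(arr[0], ndigits)} ± NA"
    return f"{_fmt(arr.mean(), ndigits)} ± {_fmt(arr.std(ddof=1), ndigits)}"


def median_iqr(values: Iterable[float], ndigits: int = 1) -> str:
    """``median [Q1; Q3]`` using linear interpolation between order statistics."""
    arr = np.asarray([v for v in values if np.isfinite(v)], dtype=float)
    if arr.size == 0:
        return "NA"
    med, q1, q3 = np.percentile(arr, [50, 25, 75], method="linear")
    return f"{_fmt(med, ndigits)} [{_fmt(q1, ndigits)}; {_fmt(q3, ndigits)}]"


def n_pct(flags: Iterable[bool], ndigits: int = 1) -> str:
    """``k (pct%)`` over non-missing flags."""
    arr = [bool(f) for f in flags]
    n = len(arr)
    if n == 0:
        return "NA"
    k = sum(arr)
    return f"{k} ({_fmt(100.0 * k / n, ndigits)}%)"


def summarize_cohort(subjects: Sequence) -> pd.DataFrame:
    """Cohort descriptive table in the conventional clinical layout.

    ``subjects`` are records with the attributes produced by the synthetic
    cohort generator (maternal_age, bmi_t1, gravidity, smoking, child_sex,
    glucose profile, gestational_age_birth, child_age_5y, sample flags).
    One row per variable: section, variable, N and a formatted summary
    (mean +/- SD for age, median [IQR] for skewed continuous variables,
    N (%) for binaries).  Missing values reduce N.
    """
    if len(subjects) == 0:
        raise ValidationError("summarize_cohort requires at least one subject")

    ages = [s.maternal_age for s in subjects]
    bmi = [s.bmi_t1 for s in subjects]
    grav = [s.gravidity for s in subjects]
    smoke = [s.smoking for s in subjects]
    girls = [s.child_sex for s in subjects]
    gdm = [classify_gdm(s.glucose) for s in subjects]
    g0 = [s.glucose.values[0] for s in subjects]
    g1 = [s.glucose.values[1] for s in subjects]
    g2 = [s.glucose.values[2] for s in subjects]
    auc = [s.glucose.auc for s in subjects]
    ga = [s.gestational_age_birth for s in subjects]
    five = [s for s in subjects if s.has_5y_sample]
    age5 = [s.child_age_5y for s in five]
    girls5 = [s.child_sex for s in five]

    n = len(subjects)
    rows = [
        ("maternal_1st_trimester", "age_years", n, mean_sd(ages)),
        ("maternal_1st_trimester", "primigravid_yes", n, n_pct(grav)),
        ("maternal_1st_trimester", "smoking_yes", n, n_pct(smoke)),
        ("maternal_1st_trimester", "bmi_kg_m2", n, median_iqr(bmi)),
        ("maternal_2nd_trimester", "gdm_yes", n, n_pct(gdm)),
        ("maternal_2nd_trimester", "glucose_fasting_mmol_l", n, median_iqr(g0)),
        ("maternal_2nd_trimester", "glucose_1h_mmol_l", n, median_iqr(g1)),
        ("maternal_2nd_trimester", "glucose_2h_mmol_l", n, median_iqr(g2)),
        ("maternal_2nd_trimester", "auc_glu_mmol_l_h", n, median_iqr(auc)),
        ("delivery", "gestational_age_weeks", n, median_iqr(ga)),
        ("delivery", "sex_girls", n, n_pct(girls)),
        ("child_5_years", "age_years", len(five), median_iqr(age5)),
        ("child_5_years", "sex_girls", len(five), n_pct(girls5)),
    ]
    return pd.DataFrame(rows, columns=["section", "variable", "n", "summary"])
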