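"""Genome-wide inference on per-CpG EWAS tables.

Covers the multiple-testing thresholds (Bonferroni genome-wide, strict "<";
a suggestive tier at p <= 1e-5), the median-based genomic inflation factor
lambda, correlation-adjusted differentially methylated regions (inverse
variance GLS combination over candidate runs of nearby same-sign CpGs, using
the individual-level residuals for the CpG correlation), exposure set
overlaps, nearest-gene annotation against a 1-based inclusive interval
table, and plot-ready Manhattan/QQ/regional exports.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataError, ValidationError

logger = logging.getLogger(__name__)

#: Median of the chi-square distribution with one degree of freedom.
CHI2_1_MEDIAN = 0.4549364

DMR_MAXGAP = 500
DMR_P_CANDIDATE = 0.05
SUGGESTIVE_P = 1e-5
_RIDGE = 1e-6


def bonferroni_threshold(alpha: float = 0.05, n_tests: int = 1) -> float:
    """alpha / n_tests; see :func:`format_threshold` for report formatting."""
    if not (0 < alpha < 1):
        raise ValidationError(f"alpha must lie in (0, 1), got {alpha}")
    if n_tests < 1:
        raise ValidationError(f"n_tests must be >= 1, got {n_tests}")
    return alpha / n_tests


def format_threshold(threshold: float) -> str:
    """Scientific notation with the mantissa truncated to two significant
    figures (e.g. 6.95e-8 prints as ``6.9e-08``), the convention used for the
    genome-wide line in report text."""
    if threshold <= 0:
        raise ValidationError("threshold must be positive")
    exp = int(np.floor(np.log10(threshold)))
    mantissa = np.floor(threshold / 10.0**exp * 10.0) / 10.0
    if mantissa >= 10.0:  # guard the floor/exponent edge
        mantissa /= 10.0
        exp += 1
    return f"{mantissa:.1f}e{exp:+03d}"


def truncated_threshold(alpha: float, n_tests: int) -> float:
    """The Bonferroni threshold as printed (mantissa-truncated) — a float."""
    return float(format_threshold(bonferroni_threshold(alpha, n_tests)))


def flag_significance(
    table: pd.DataFrame,
    alpha: float = 0.05,
    suggestive: float = SUGGESTIVE_P,
    n_tests: int | None = None,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Add a ``tier`` column: genome-wide (p < alpha/n), suggestive (p <= 1e-5),
    or none.  Boundary conventions follow the printed inequalities: strict
    "<" at genome-wide, "<=" at suggestive."""
    ok = table["status"] == "ok" if "status" in table else pd.Series(True, index=table.index)
    if n_tests is None:
        n_tests = int(ok.sum())
    gw = bonferroni_threshold(alpha, n_tests)
    p = table["p"].to_numpy(dtype=float)
    tier = np.where(p < gw, "genome-wide", np.where(p <= suggestive, "suggestive", "none"))
    tier = np.where(ok.to_numpy(), tier, "none")
    out = table.copy()
    out["tier"] = tier
    counts = {
        "genome-wide": int((tier == "genome-wide").sum()),
        "suggestive": int((tier == "suggestive").sum()),
        "none": int((tier == "none").sum()),
        "n_tests": n_tests,
    }
    return out, counts


@dataclass
class InflationReport:
    """Genomic inflation factor with QQ-plot quantile pairs."""

    lam: float
    n_tests: int
    expected: np.ndarray  # ascending uniform quantiles (i - 0.5) / n
    observed: np.ndarray  # sorted observed p ascending

    def __post_init__(self) -> None:
        if self.lam <= 0:
            raise DataError("lambda must be positive")


def genomic_lambda(table_or_p) -> InflationReport:
    """Median-based inflation factor: median(chi2_1 quantiles of observed p)
    divided by 0.4549364 (the chi2_1 median).  Converged tests only."""
    if isinstance(table_or_p, pd.DataFrame):
        tab = table_or_p
        if "status" in tab:
            tab = tab[tab["status"] == "ok"]
        p = tab["p"].to_numpy(dtype=float)
    else:
        p = np.asarray(table_or_p, dtype=float)
    if p.size < 10:
        raise ValidationError(f"lambda needs >= 10 converged tests, got {p.size}")
    chi = stats.chi2.isf(p, df=1)
    lam = float(np.median(chi) / CHI2_1_MEDIAN)
    obs = np.sort(p)
    exp = (np.arange(1, p.size + 1) - 0.5) / p.size
    return InflationReport(lam=lam, n_tests=int(p.size), expected=exp, observed=obs)


# ---------------------------------------------------------------------------
# Differentially methylated regions
# ---------------------------------------------------------------------------


def combine_region(
    estimates: np.ndarray, ses: np.ndarray, corr: np.ndarray
) -> tuple[float, float, float, float, bool]:
    """Correlation-adjusted inverse-variance combination of a CpG run.

    With D = diag(SE) and R the CpG residual correlation, S = D R D and
    B = (1' S^-1 beta) / (1' S^-1 1), Var(B) = 1 / (1' S^-1 1).  A singular S
    is ridge-regularized (R + 1e-6 I) and flagged.  Returns
    (B, SE(B), z, two-sided p, ridge_flag).
    """
    b = np.asarray(estimates, dtype=float)
    s = np.asarray(ses, dtype=float)
    r = np.asarray(corr, dtype=float)
    if len(b) == 1:  # scalar S: the combination is the CpG's own Wald test
        z = b[0] / s[0]
        p = float(2.0 * stats.norm.sf(abs(z)))
        return float(b[0]), float(s[0]), float(z), max(p, np.nextafter(0, 1)), False
    cov = np.outer(s, s) * r
    ridge = False
    try:
        w = np.linalg.solve(cov, np.ones_like(b))
        if not np.isfinite(w).all() or (np.ones_like(b) @ w) <= 0:
            raise np.linalg.LinAlgError
    except np.linalg.LinAlgError:
        ridge = True
        cov = np.outer(s, s) * (r + _RIDGE * np.eye(len(b)))
        w = np.linalg.solve(cov, np.ones_like(b))
    denom = float(np.ones_like(b) @ w)
    combined = float(w @ b) / denom
    var = 1.0 / denom
    z = combined / np.sqrt(var)
    p = float(2.0 * stats.norm.sf(abs(z)))
    return combined, float(np.sqrt(var)), float(z), max(p, np.nextafter(0, 1)), ridge


def find_dmrs(
    table: pd.DataFrame,
    residuals: pd.DataFrame,
    maxgap: int = DMR_MAXGAP,
    p_candidate: float = DMR_P_CANDIDATE,
) -> pd.DataFrame:
    """Differentially methylated regions from an EWAS table + residuals.

    Candidates are maximal runs of consecutive table CpGs on one chromosome
    with every CpG at p < ``p_candidate``, all estimates of one sign and
    successive positions at most ``maxgap`` bp apart (an intervening
    non-candidate CpG breaks the run).  Each candidate is combined with
    :func:`combine_region`, the CpG correlation computed from the stacked
    residual rows; adjusted p is Bonferroni over the number of candidates.
    """
    needed = {"cpg_id", "chrom", "pos", "estimate", "se", "p"}
    if not needed.issubset(table.columns):
        raise DataError(f"table lacks columns {sorted(needed - set(table.columns))}")
    tab = table.copy()
    if "status" in tab:
        tab = tab[tab["status"] == "ok"]
    missing = set(tab["cpg_id"]) - set(residuals.index)
    if missing:
        raise DataError(f"residuals lack {len(missing)} table CpGs")
    tab = tab.sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)

    candidates: list[list[int]] = []
    run: list[int] = []
    prev_chrom, prev_pos, prev_sign = None, None, 0.0
    for i, row in tab.iterrows():
        eligible = row["p"] < p_candidate and row["estimate"] != 0
        sign = np.sign(row["estimate"])
        if (
            eligible
            and run
            and row["chrom"] == prev_chrom
            and row["pos"] - prev_pos <= maxgap
            and sign == prev_sign
        ):
            run.append(i)
        else:
            if run:
                candidates.append(run)
            run = [i] if eligible else []
        if eligible:
            prev_chrom, prev_pos, prev_sign = row["chrom"], row["pos"], sign
        else:
            prev_chrom = None
    if run:
        candidates.append(run)

    rows = []
    for run in candidates:
        sub = tab.loc[run]
        k = len(run)
        if k == 1:
            corr = np.ones((1, 1))
        else:
            res = residuals.loc[sub["cpg_id"]].to_numpy(dtype=float)
            mask = np.isfinite(res).all(axis=0)
            corr = np.corrcoef(res[:, mask])
        combined, se, z, p, ridge = combine_region(
            sub["estimate"].to_numpy(), sub["se"].to_numpy(), corr
        )
        rows.append(
            {
                "chrom": sub["chrom"].iloc[0],
                "start": int(sub["pos"].min()),
                "end": int(sub["pos"].max()),
                "n_cpgs": k,
                "cpg_ids": ",".join(sub["cpg_id"]),
                "estimate": combined,
                "se": se,
                "z": z,
                "p": p,
                "ridge_flag": ridge,
            }
        )
    dmrs = pd.DataFrame(
        rows,
        columns=["chrom", "start", "end", "n_cpgs", "cpg_ids", "estimate", "se",
                 "z", "p", "ridge_flag"],
    )
    if len(dmrs):
        dmrs["p_adjusted"] = np.minimum(1.0, dmrs["p"] * len(dmrs))
        dmrs = dmrs.sort_values("p", kind="stable").reset_index(drop=True)
    else:
        dmrs["p_adjusted"] = pd.Series(dtype=float)
    return dmrs


# ---------------------------------------------------------------------------
# Exposure overlaps
# ---------------------------------------------------------------------------


@dataclass
class OverlapReport:
    """Tier CpG sets per exposure and every intersection among them."""

    sets: dict[str, set[str]]
    intersections: dict[tuple[str, ...], set[str]]

    def counts(self) -> pd.DataFrame:
        rows = [
            {"exposures": "&".join(k), "order": len(k), "n": len(v),
             "cpg_ids": ",".join(sorted(v))}
            for k, v in self.intersections.items()
        ]
        return pd.DataFrame(rows, columns=["exposures", "order", "n", "cpg_ids"])


def overlap_sets(
    tables: Mapping[str, pd.DataFrame],
    tier: str = "suggestive",
    alpha: float = 0.05,
    suggestive: float = SUGGESTIVE_P,
) -> OverlapReport:
    """Per-exposure tier CpG sets and all pairwise/higher-order intersections.

    All tables must share one CpG universe.  ``tier`` selects the suggestive
    (p <= 1e-5) or genome-wide (p < alpha/n) membership rule.
    """
    names = list(tables)
    if not names:
        raise DataError("no tables supplied")
    universe = set(tables[names[0]]["cpg_id"])
    for name in names[1:]:
        if set(tables[name]["cpg_id"]) != universe:
            raise DataError(f"table {name!r} has a different CpG universe")
    sets: dict[str, set[str]] = {}
    for name in names:
        flagged, _ = flag_significance(tables[name], alpha, suggestive)
        if tier == "suggestive":
            member = flagged["tier"].isin(["suggestive", "genome-wide"])
        elif tier == "genome-wide":
            member = flagged["tier"] == "genome-wide"
        else:
            raise ValidationError(f"unknown tier {tier!r}")
        sets[name] = set(flagged.loc[member, "cpg_id"])
    inter: dict[tuple[str, ...], set[str]] = {}
    for r in range(1, len(names) + 1):
        for combo in combinations(names, r):
            s = set.intersection(*(sets[c] for c in combo))
            inter[combo] = s
    return OverlapReport(sets=sets, intersections=inter)


# ---------------------------------------------------------------------------
# Nearest-gene annotation
# ---------------------------------------------------------------------------


def bed_to_intervals(bed: pd.DataFrame) -> pd.DataFrame:
    """Convert 0-based half-open BED rows to the 1-based inclusive dialect
    used here (start + 1, end unchanged)."""
    out = bed.copy()
    out["start"] = out["start"].astype(int) + 1
    out["end"] = out["end"].astype(int)
    return out


def annotate_nearest_gene(table: pd.DataFrame, genes: pd.DataFrame) -> pd.DataFrame:
    """Assign each CpG its containing gene, else the nearest interval edge.

    ``genes`` has columns chrom/start/end/name with 1-based inclusive
    coordinates.  Distance ties break to the interval with the smaller start.
    CpGs on chromosomes absent from ``genes`` get an empty annotation
    (logged).  Adds ``gene`` and ``gene_distance`` columns.
    """
    for col in ("chrom", "start", "end", "name"):
        if col not in genes.columns:
            raise DataError(f"gene table lacks column {col!r}")
    out = table.copy()
    gene_col = np.full(len(out), "", dtype=object)
    dist_col = np.full(len(out), np.nan)
    by_chrom = {str(c): g.sort_values(["start", "end"]) for c, g in genes.groupby("chrom")}
    n_missing = 0
    chroms = out["chrom"].astype(str).to_numpy()
    poss = out["pos"].to_numpy()
    for i in range(len(out)):
        g = by_chrom.get(chroms[i])
        if g is None:
            n_missing += 1
            continue
        start = g["start"].to_numpy()
        end = g["end"].to_numpy()
        pos = poss[i]
        dist = np.maximum(0, np.maximum(start - pos, pos - end))
        order = np.lexsort((start, dist))
        j = order[0]
        gene_col[i] = g["name"].iloc[j]
        dist_col[i] = dist[j]
    if n_missing:
        logger.info("%d CpGs on chromosomes absent from the gene table", n_missing)
    out["gene"] = gene_col
    out["gene_distance"] = dist_col
    return out


# ---------------------------------------------------------------------------
# Plot-ready exports
# ---------------------------------------------------------------------------


def manhattan_data(
    table: pd.DataFrame,
    alpha: float = 0.05,
    suggestive: float = SUGGESTIVE_P,
    n_tests: int | None = None,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Per-CpG (chrom, pos, -log10 p, tier) plus the two threshold lines."""
    flagged, counts = flag_significance(table, alpha, suggestive, n_tests)
    gw = bonferroni_threshold(alpha, counts["n_tests"])
    data = flagged.loc[:, ["chrom", "pos", "cpg_id", "p", "tier"]].copy()
    data["neglog10_p"] = -np.log10(data["p"].astype(float))
    meta = {
        "genome_wide_p": gw,
        "genome_wide_p_printed": float(format_threshold(gw)),
        "suggestive_p": suggestive,
        "genome_wide_neglog10": float(-np.log10(float(format_threshold(gw)))),
        "suggestive_neglog10": float(-np.log10(suggestive)),
        "n_tests": float(counts["n_tests"]),
    }
    return data.drop(columns="p"), meta


def regional_slice(
    table: pd.DataFrame,
    anchor: str,
    window: int = 50_000,
    genes: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """All CpGs within +/- ``window`` bp of a named CpG or annotated gene."""
    if anchor in set(table["cpg_id"]):
        row = table.loc[table["cpg_id"] == anchor].iloc[0]
        chrom, center_lo = row["chrom"], int(row["pos"])
        center_hi = center_lo
    elif genes is not None and anchor in set(genes["name"]):
        g = genes.loc[genes["name"] == anchor].iloc[0]
        chrom, center_lo, center_hi = g["chrom"], int(g["start"]), int(g["end"])
    elif "gene" in table.columns and anchor in set(table["gene"]):
        sub = table.loc[table["gene"] == anchor]
        chrom = sub["chrom"].iloc[0]
        center_lo, center_hi = int(sub["pos"].min()), int(sub["pos"].max())
    else:
        raise ValidationError(f"unknown regional anchor {anchor!r}")
    mask = (table["chrom"].astype(str) == str(chrom)) & (
        table["pos"].astype(int).between(center_lo - window, center_hi + window)
    )
    out = table.loc[mask].copy()
    out["neglog10_p"] = -np.log10(out["p"].astype(float))
    return out.sort_values("pos").reset_index(drop=True)


def export_plots(
    table: pd.DataFrame,
    out_dir: str | Path,
    inflation: InflationReport | None = None,
    alpha: float = 0.05,
    suggestive: float = SUGGESTIVE_P,
    regional_anchors: tuple[str, ...] = (),
    genes: pd.DataFrame | None = None,
    images: bool = False,
) -> dict[str, Path]:
    """Write plot-ready TSVs (+ optional PNGs) and a threshold metadata file."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    data, meta = manhattan_data(table, alpha, suggestive)
    path = out_dir / "manhattan.tsv"
    data.to_csv(path, sep="\t", index=False)
    written["manhattan"] = path
    meta_path = out_dir / "thresholds.json"
    meta_path.write_text(json.dumps(meta, indent=2))
    written["thresholds"] = meta_path

    if inflation is not None:
        qq = pd.DataFrame(
            {
                "expected_neglog10": -np.log10(inflation.expected),
                "observed_neglog10": -np.log10(inflation.observed),
            }
        )
        path = out_dir / "qq.tsv"
        qq.to_csv(path, sep="\t", index=False)
        written["qq"] = path

    for anchor in regional_anchors:
        sl = regional_slice(table, anchor, genes=genes)
        path = out_dir / f"regional_{anchor}.tsv"
        sl.to_csv(path, sep="\t", index=False)
        written[f"regional_{anchor}"] = path

    if images:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(9, 3))
        for chrom, sub in data.groupby("chrom"):
            ax.scatter(sub["pos"], sub["neglog10_p"], s=4, label=str(chrom))
        ax.axhline(meta["genome_wide_neglog10"], color="red", lw=0.8)
        ax.axhline(meta["suggestive_neglog10"], color="blue", lw=0.8)
        ax.set_xlabel("position")
        ax.set_ylabel("-log10 p")
        fig.tight_layout()
        img = out_dir / "manhattan.png"
        fig.savefig(img, dpi=150)
        plt.close(fig)
        written["manhattan_png"] = img
    return written
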