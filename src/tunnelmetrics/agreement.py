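"""Agreement statistics: ICC(2,1) with 95% CI, qualitative bands, and
mean ± SD differences against the drill size.

The intraclass correlation used throughout is the two-way random-effects,
single-measures, *absolute agreement* form — ICC(2,1) in the
Shrout-Fleiss numbering, ICC(A,1) in McGraw-Wong.  From the two-way ANOVA
mean squares (MSR between subjects, MSC between raters, MSE residual):

    ICC = (MSR - MSE) / (MSR + (k-1) MSE + (k/n) (MSC - MSE))

with the F-distribution confidence interval of the McGraw-Wong
construction.  Qualitative bands: > 0.75 excellent, 0.40-0.75 (inclusive)
fair to good, < 0.40 poor; negative estimates are reported as-is and
classified poor.

The drill size (known ground-truth diameter) is treated as one rater
column, so "agreement with the drill size" is a two-rater absolute
agreement ICC.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import f as f_dist

__all__ = [
    "ICCClass",
    "ICCResult",
    "DifferenceSummary",
    "icc_2_1",
    "classify_icc",
    "difference_summary",
    "agreement_report",
]


class ICCClass(str, Enum):
    EXCELLENT = "excellent"
    FAIR_TO_GOOD = "fair_to_good"
    POOR = "poor"


def classify_icc(icc: float) -> ICCClass:
    """Qualitative band: > 0.75 excellent; 0.40-0.75 (both ends inclusive)
    fair to good; < 0.40 (including negatives) poor."""
    if icc > 0.75:
        return ICCClass.EXCELLENT
    if icc >= 0.40:
        return ICCClass.FAIR_TO_GOOD
    return ICCClass.POOR


@dataclass
class ICCResult:
    icc: float
    ci_low: float
    ci_high: float
    n: int
    k: int
    mean_squares: dict[str, float]
    classification: ICCClass = field(init=False)

    def __post_init__(self) -> None:
        # CI endpoints must bracket the point estimate; tiny numerical
        # violations from the F quantiles are clamped
        self.ci_low = min(self.ci_low, self.icc)
        self.ci_high = max(self.ci_high, self.icc)
        self.classification = classify_icc(self.icc)


def _anova_mean_squares(x: np.ndarray) -> dict[str, float]:
    n, k = x.shape
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ssr = k * ((row_means - grand) ** 2).sum()
    ssc = n * ((col_means - grand) ** 2).sum()
    sst = ((x - grand) ** 2).sum()
    sse = sst - ssr - ssc
    return {
        "MSR": ssr / (n - 1),
        "MSC": ssc / (k - 1),
        "MSE": max(sse, 0.0) / ((n - 1) * (k - 1)),
    }


def icc_2_1(table, alpha: float = 0.05) -> ICCResult:
    """Two-way random, single-measures, absolute-agreement ICC.

    Parameters
    ----------
    table : (n, k) array or DataFrame — rows are subjects (tunnels), columns
        raters/methods; complete (no missing cells), n >= 3, k >= 2.
    alpha : two-sided CI level (default 95% CI).

    A table whose cells are all equal has no variance to apportion; it is
    defined here as perfect agreement (ICC 1, CI [1, 1]) with a warning.
    """
    if isinstance(table, pd.DataFrame):
        x = table.to_numpy(dtype=float)
    else:
        x = np.asarray(table, dtype=float)
    if x.ndim != 2:
        raise ValueError("rating table must be 2D (subjects x raters)")
    n, k = x.shape
    if n < 3:
        raise ValueError(f"need at least 3 subjects, got {n}")
    if k < 2:
        raise ValueError(f"need at least 2 raters, got {k}")
    if not np.isfinite(x).all():
        raise ValueError("rating table must be complete (no missing cells)")

    ms = _anova_mean_squares(x)
    msr, msc, mse = ms["MSR"], ms["MSC"], ms["MSE"]

    denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
    if denom <= 1e-30:
        if np.allclose(x, x.flat[0]):
            warnings.warn("all ratings identical; ICC defined as 1 with degenerate CI",
                          stacklevel=2)
            return ICCResult(1.0, 1.0, 1.0, n, k, ms)
        raise ZeroDivisionError("degenerate rating table: zero ICC denominator")
    icc = (msr - mse) / denom

    if abs(1.0 - icc) < 1e-12 and mse <= 1e-30 and msc <= 1e-30:
        return ICCResult(1.0, 1.0, 1.0, n, k, ms)

    # McGraw-Wong F-based interval for ICC(A,1)
    with np.errstate(divide="ignore", invalid="ignore"):
        a = (k * icc) / (n * (1.0 - icc)) if icc < 1.0 else np.inf
        b = 1.0 + (k * icc * (n - 1.0)) / (n * (1.0 - icc)) if icc < 1.0 else np.inf
        if np.isfinite(a) and np.isfinite(b) and (a * msc + b * mse) > 0:
            v = (a * msc + b * mse) ** 2 / (
                (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
            )
        else:
            v = (n - 1) * (k - 1)
    v = max(float(v), 1.0)
    f1 = f_dist.ppf(1 - alpha / 2, n - 1, v)
    f2 = f_dist.ppf(1 - alpha / 2, v, n - 1)
    lower = n * (msr - f1 * mse) / (f1 * (k * msc + (k * n - k - n) * mse) + n * msr)
    upper = n * (f2 * msr - mse) / (k * msc + (k * n - k - n) * mse + n * f2 * msr)
    return ICCResult(float(icc), float(lower), float(upper), n, k, ms)


@dataclass
class DifferenceSummary:
    """Mean ± SD of signed per-subject differences (measured − truth)."""

    mean_diff_mm: float
    sd_diff_mm: float
    differences_mm: np.ndarray

    def __post_init__(self) -> None:
        self.differences_mm = np.asarray(self.differences_mm, dtype=float)


def difference_summary(measured, truth) -> DifferenceSummary:
    """Signed differences measured − truth, with mean and sample SD
    (n − 1 denominator)."""
    m = np.asarray(measured, dtype=float).reshape(-1)
    t = np.asarray(truth, dtype=float).reshape(-1)
    if len(m) != len(t):
        raise ValueError(f"length mismatch: {len(m)} measurements vs {len(t)} truths")
    if len(m) < 2:
        raise ValueError("need at least 2 paired values")
    d = m - t
    return DifferenceSummary(float(d.mean()), float(d.std(ddof=1)), d)


def agreement_report(
    measurements: pd.DataFrame,
    truths: dict[str, float] | pd.Series,
    repeats: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-method agreement against the known drill diameters.

    Parameters
    ----------
    measurements : long-format DataFrame with columns
        ``tunnel_id, method, diameter_mm`` (failed records may carry NaN and
        are dropped per method).
    truths : mapping tunnel_id -> true (drill) diameter in mm.
    repeats : optional second set of measurements with the same columns;
        adds a per-method intra-rater (measurement-remeasurement) ICC.

    Returns one row per method: ICC vs truth + CI + classification +
    mean ± SD difference, and intra-rater ICC when repeats are given.
    """
    truths = pd.Series(truths, dtype=float)
    rows = []
    for method, grp in measurements.groupby("method", sort=True):
        grp = grp.dropna(subset=["diameter_mm"]).set_index("tunnel_id")
        common = grp.index.intersection(truths.index)
        row: dict = {"method": method, "n": len(common)}
        try:
            if len(common) < 3:
                raise ValueError(f"fewer than 3 usable tunnels for method {method}")
            measured = grp.loc[common, "diameter_mm"].to_numpy(dtype=float)
            truth_vals = truths.loc[common].to_numpy(dtype=float)
            res = icc_2_1(np.column_stack([measured, truth_vals]))
            diff = difference_summary(measured, truth_vals)
            row.update(
                icc=res.icc, ci_low=res.ci_low, ci_high=res.ci_high,
                classification=res.classification.value,
                mean_diff_mm=diff.mean_diff_mm, sd_diff_mm=diff.sd_diff_mm,
            )
        except Exception as exc:
            row["error"] = f"{type(exc).__name__}: {exc}"
        if repeats is not None and "error" not in row:
            try:
                rep = (repeats[repeats["method"] == method]
                       .dropna(subset=["diameter_mm"]).set_index("tunnel_id"))
                both = grp.index.intersection(rep.index)
                pair = np.column_stack([
                    grp.loc[both, "diameter_mm"].to_numpy(dtype=float),
                    rep.loc[both, "diameter_mm"].to_numpy(dtype=float),
                ])
                rres = icc_2_1(pair)
                row.update(intra_icc=rres.icc, intra_ci_low=rres.ci_low,
                           intra_ci_high=rres.ci_high,
                           intra_classification=rres.classification.value)
            except Exception as exc:
                row["intra_error"] = f"{type(exc).__name__}: {exc}"
        rows.append(row)
    return pd.DataFrame(rows)


def write_report(report: pd.DataFrame, csv_path: str | Path, json_path: str | Path | None = None) -> None:
    report.to_csv(csv_path, index=False, float_format="%.6f")
    if json_path is not None:
        Path(json_path).write_text(json.dumps(report.to_dict(orient="records"), indent=2))


def read_ratings_csv(path: str | Path) -> pd.DataFrame:
    """Read a rating table from CSV: long format (tunnel_id, rater, value_mm)
    is pivoted to wide; anything else is taken as already-wide (first column
    = subject id)."""
    df = pd.read_csv(path)
    cols = {c.lower() for c in df.columns}
    if {"tunnel_id", "rater", "value_mm"} <= cols:
        df.columns = [c.lower() for c in df.columns]
        return df.pivot(index="tunnel_id", columns="rater", values="value_mm")
    return df.set_index(df.columns[0])
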