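"""Agreement statistics between manual and automatic radiomics features.

The headline statistic is the intraclass correlation coefficient ICC(2,1):
two-way random-effects ANOVA, absolute agreement, single measurement.  With n
targets (patients), k raters (mask sources) and mean squares MSR (rows/
targets), MSC (columns/raters) and MSE (residual),

    ICC(2,1) = (MSR - MSE) / (MSR + (k-1)·MSE + (k/n)·(MSC - MSE)).

Significance is the F test of the target effect, F = MSR/MSE with
(n-1, (n-1)(k-1)) degrees of freedom; the 95% CI follows the classical
F-distribution (Shrout–Fleiss / McGraw–Wong) construction.  ICC estimates are
categorized as poor (< 0.50), moderate (0.50–0.75), good (0.75–0.90) or
excellent (> 0.90); interval endpoints are resolved as documented in
:func:`categorize_icc`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .radiomics.manifest import ALL_FEATURE_NAMES, FAMILIES

__all__ = [
    "RatingsTable",
    "ICCResult",
    "FamilySummary",
    "icc_2_1",
    "categorize_icc",
    "feature_group_summary",
    "pool_group_means",
]


@dataclass(frozen=True)
class RatingsTable:
    """n targets × k raters matrix of one feature's values (no missing cells)."""

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float64)
        if v.ndim != 2:
            raise ValueError("ratings must be a 2D (targets × raters) array")
        if v.shape[0] < 2 or v.shape[1] < 2:
            raise ValueError("need at least 2 targets and 2 raters")
        if not np.isfinite(v).all():
            raise ValueError("ratings contain missing or non-finite cells")
        object.__setattr__(self, "values", v)

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def k(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class ICCResult:
    icc: float
    ms_rows: float
    ms_cols: float
    ms_error: float
    f_stat: float
    p_value: float
    ci95: tuple[float, float]
    category: str
    degenerate: bool = False


def icc_2_1(table: RatingsTable | np.ndarray, alpha: float = 0.05) -> ICCResult:
    """ICC(2,1): two-way random effects, absolute agreement, single rater.

    A constant table (zero variance everywhere) has no defined ICC; the
    result is flagged ``degenerate`` with ``icc = nan`` rather than raising
    or silently returning NaN mean squares.
    """
    if not isinstance(table, RatingsTable):
        table = RatingsTable(np.asarray(table))
    x = table.values
    n, k = table.n, table.k

    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_rows = k * ((row_means - grand) ** 2).sum()
    ss_cols = n * ((col_means - grand) ** 2).sum()
    ss_total = ((x - grand) ** 2).sum()
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = max(ss_err / ((n - 1) * (k - 1)), 0.0)

    denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
    if denom <= 0:
        return ICCResult(
            icc=float("nan"), ms_rows=msr, ms_cols=msc, ms_error=mse,
            f_stat=float("nan"), p_value=1.0, ci95=(float("nan"), float("nan")),
            category="undefined", degenerate=True,
        )
    icc = (msr - mse) / denom

    df1, df2 = n - 1, (n - 1) * (k - 1)
    if mse > 0:
        f_stat = msr / mse
        p = float(stats.f.sf(f_stat, df1, df2))
        p = max(p, np.finfo(float).tiny)  # p in (0, 1]
    else:
        f_stat = float("inf")
        p = float(np.finfo(float).tiny)

    # F-based 95% CI (Shrout-Fleiss form with Satterthwaite df)
    if mse > 0 and icc < 1.0:
        a = (k * icc) / (n * (1.0 - icc))
        b = 1.0 + (k * icc * (n - 1)) / (n * (1.0 - icc))
        v = (a * msc + b * mse) ** 2 / (
            (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
        )
        with np.errstate(invalid="ignore", divide="ignore"):
            f1 = stats.f.ppf(1 - alpha / 2, n - 1, v)
            f2 = stats.f.ppf(1 - alpha / 2, v, n - 1)
            lower = n * (msr - f1 * mse) / (f1 * (k * msc + (k * n - k - n) * mse) + n * msr)
            upper = n * (f2 * msr - mse) / (k * msc + (k * n - k - n) * mse + n * f2 * msr)
        # pathological tables (strong anti-agreement) give v -> 0 and an
        # uninformative interval; clamp to the valid ICC range
        lower = float(lower) if np.isfinite(lower) else -1.0
        upper = float(upper) if np.isfinite(upper) else 1.0
        ci = (max(lower, -1.0), min(upper, 1.0))
    else:
        ci = (float(icc), float(icc))

    return ICCResult(
        icc=float(icc), ms_rows=float(msr), ms_cols=float(msc), ms_error=float(mse),
        f_stat=float(f_stat), p_value=p, ci95=ci, category=categorize_icc(icc),
    )


def categorize_icc(value: float) -> str:
    """Reliability bin of an ICC estimate.

    Bins: poor < 0.50; moderate [0.50, 0.75); good [0.75, 0.90]; excellent
    > 0.90.  The published interval endpoints overlap ("0.50-0.75",
    "0.75-0.90"); here 0.75 counts as good and 0.90 as good, with excellent
    strictly above 0.90.
    """
    if value > 1.0 + 1e-12:
        raise ValueError(f"ICC cannot exceed 1, got {value}")
    if value < 0.50:
        return "poor"
    if value < 0.75:
        return "moderate"
    if value <= 0.90:
        return "good"
    return "excellent"


@dataclass(frozen=True)
class FamilySummary:
    family: str
    n_features: int
    median_icc: float
    iqr: tuple[float, float]


def feature_group_summary(icc_per_feature: dict[str, float]) -> list[FamilySummary]:
    """Median and IQR of ICC estimates per feature family.

    Requires all 107 features; raises naming any missing one.  Quartiles use
    linear interpolation.
    """
    missing = [n for n in ALL_FEATURE_NAMES if n not in icc_per_feature]
    if missing:
        raise ValueError(f"missing ICC for feature(s): {missing[:5]}")
    out = []
    for fam, names in FAMILIES.items():
        vals = np.array([icc_per_feature[f"{fam}_{n}"] for n in names], dtype=float)
        q1, med, q3 = np.percentile(vals, [25, 50, 75])
        out.append(FamilySummary(family=fam, n_features=len(names),
                                 median_icc=float(med), iqr=(float(q1), float(q3))))
    return out


def pool_group_means(groups: list[tuple[float, int]]) -> float:
    """Count-weighted pooled mean of per-group means: Σ(mean·n) / Σn."""
    if not groups:
        raise ValueError("no groups to pool")
    if any(n < 1 for _, n in groups):
        raise ValueError("group sizes must be >= 1")
    total = sum(n for _, n in groups)
    return float(sum(m * n for m, n in groups) / total)
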