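"""Joint-level agreement and lesion-level detection reliability statistics.

Joint-level: two measurement methods score the same joints for one metric
(interruption count or surface). Agreement is the single-measure
intraclass correlation ICC(2,1) — two-way random effects, absolute
agreement — with a 95% F-distribution confidence interval, plus the
two-sided Wilcoxon signed-rank test for a systematic difference.

Lesion-level: PPV = matched test-side detections / all test-side
detections; sensitivity = matched reference lesions / all reference
lesions, both in percent.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from cortigap.errors import UndefinedMetricError


@dataclass
class PairedJointTable:
    """Per-joint measurements of one metric by two methods (columns A, B)."""

    a: np.ndarray
    b: np.ndarray
    metric: str = ""

    def __post_init__(self) -> None:
        self.a = np.asarray(self.a, dtype=float)
        self.b = np.asarray(self.b, dtype=float)
        if self.a.shape != self.b.shape or self.a.ndim != 1:
            raise ValueError("columns must be 1D and equal length")
        if self.a.size < 2:
            raise ValueError("need at least 2 joints")

    @classmethod
    def from_frame(cls, df: pd.DataFrame, col_a: str, col_b: str, metric: str = "") -> "PairedJointTable":
        return cls(df[col_a].to_numpy(), df[col_b].to_numpy(), metric or f"{col_a}/{col_b}")


def icc_two_way_random_absolute(
    table: PairedJointTable, ci: float = 0.95
) -> tuple[float, float, float]:
    """Single-measure ICC(2,1), two-way random effects, absolute agreement.

    From the two-way ANOVA mean squares (rows = joints, columns = methods):

        ICC = (MSR - MSE) / (MSR + (k-1) MSE + (k/n)(MSC - MSE))

    with k = 2 methods and n joints. The confidence interval follows the
    standard F-bound construction with a Satterthwaite-approximated
    denominator degrees of freedom (as implemented by SPSS). Returns
    ``(icc, ci_low, ci_high)``; NaNs with a warning when the between-joint
    variance is zero (agreement undefined).
    """
    Y = np.column_stack([table.a, table.b])
    n, k = Y.shape
    grand = Y.mean()
    row_means = Y.mean(axis=1)
    col_means = Y.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((Y - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))

    denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
    if np.isclose(msr, 0.0) and np.isclose(denom, 0.0):
        warnings.warn("zero between-joint variance: ICC undefined", stacklevel=2)
        return float("nan"), float("nan"), float("nan")
    icc = (msr - mse) / denom
    if mse == 0.0 and msc == msr:
        return 1.0, 1.0, 1.0

    alpha = 1.0 - ci
    a_ = (k * icc) / (n * (1.0 - icc)) if icc < 1.0 else np.inf
    b_ = 1.0 + (k * icc * (n - 1.0)) / (n * (1.0 - icc)) if icc < 1.0 else np.inf
    with np.errstate(invalid="ignore", divide="ignore"):
        v = (a_ * msc + b_ * mse) ** 2 / (
            (a_ * msc) ** 2 / (k - 1) + (b_ * mse) ** 2 / ((n - 1) * (k - 1))
        )
    if not np.isfinite(v):
        return float(icc), float("nan"), float("nan")
    f1 = stats.f.ppf(1.0 - alpha / 2.0, n - 1, v)
    f2 = stats.f.ppf(1.0 - alpha / 2.0, v, n - 1)
    lower = n * (msr - f1 * mse) / (f1 * (k * msc + (k * n - k - n) * mse) + n * msr)
    upper = n * (f2 * msr - mse) / (k * msc + (k * n - k - n) * mse + n * f2 * msr)
    return float(icc), float(lower), float(upper)


def wilcoxon_signed_rank(table: PairedJointTable, method: str = "auto") -> float:
    """Two-sided Wilcoxon signed-rank p for a paired difference.

    Zero differences are dropped (classic Wilcoxon convention); all-zero
    differences return p = 1 with a warning. ``method='auto'`` uses the
    exact null distribution for up to 25 informative tie-free pairs and
    the tie-corrected normal approximation otherwise; ``'exact'`` and
    ``'approx'`` force the choice.
    """
    d = table.a - table.b
    d = d[d != 0]
    if d.size == 0:
        warnings.warn("all paired differences are zero; p = 1", stacklevel=2)
        return 1.0
    has_ties = np.unique(np.abs(d)).size < d.size
    if method == "auto":
        method = "exact" if (d.size <= 25 and not has_ties) else "approx"
    if method == "exact" and has_ties:
        warnings.warn("ties present; falling back to normal approximation", stacklevel=2)
        method = "approx"
    res = stats.wilcoxon(
        d, zero_method="wilcox", alternative="two-sided", correction=False, method=method
    )
    return float(res.pvalue)


def ppv(matched: int, n_detected_A: int) -> float:
    """Positive predictive value, percent: matched / test-side detections."""
    if n_detected_A < 1:
        raise UndefinedMetricError("PPV undefined with zero test-side detections")
    if not 0 <= matched <= n_detected_A:
        raise ValueError(f"matched must be in [0, {n_detected_A}], got {matched}")
    return 100.0 * matched / n_detected_A


def sensitivity(matched: int, n_detected_B: int) -> float:
    """Sensitivity, percent: matched / reference-side lesions."""
    if n_detected_B < 1:
        raise UndefinedMetricError("sensitivity undefined with zero reference lesions")
    if not 0 <= matched <= n_detected_B:
        raise ValueError(f"matched must be in [0, {n_detected_B}], got {matched}")
    return 100.0 * matched / n_detected_B


def icc_strength_label(icc: float) -> str:
    """Qualitative agreement label for an ICC value (Landis-Koch style)."""
    if np.isnan(icc):
        return "undefined"
    if icc >= 0.81:
        return "almost perfect"
    if icc >= 0.61:
        return "substantial"
    if icc >= 0.41:
        return "moderate"
    if icc >= 0.21:
        return "fair"
    return "slight"


@dataclass
class ReliabilityReport:
    """Joint-level and lesion-level reliability summary for one cut-off."""

    metric: str
    mean_sd_A: tuple[float, float]
    mean_sd_B: tuple[float, float]
    wilcoxon_p: float
    icc: float
    icc_ci: tuple[float, float]
    ppv_percent: float | None = None
    sensitivity_percent: float | None = None
    mode: str = ""

    @property
    def icc_label(self) -> str:
        return icc_strength_label(self.icc)

    def to_dict(self) -> dict:
        return {
            "metric": self.metric,
            "mode": self.mode,
            "A_mean": self.mean_sd_A[0],
            "A_sd": self.mean_sd_A[1],
            "B_mean": self.mean_sd_B[0],
            "B_sd": self.mean_sd_B[1],
            "wilcoxon_p": self.wilcoxon_p,
            "icc": self.icc,
            "icc_ci_low": self.icc_ci[0],
            "icc_ci_high": self.icc_ci[1],
            "icc_label": self.icc_label,
            "ppv_percent": self.ppv_percent,
            "sensitivity_percent": self.sensitivity_percent,
        }


def joint_level_report(table: PairedJointTable, mode: str = "") -> ReliabilityReport:
    """Assemble the joint-level block: means(SD), Wilcoxon p, ICC(2,1) + CI."""
    icc, lo, hi = icc_two_way_random_absolute(table)
    return ReliabilityReport(
        metric=table.metric,
        mean_sd_A=(float(table.a.mean()), float(table.a.std(ddof=1))),
        mean_sd_B=(float(table.b.mean()), float(table.b.std(ddof=1))),
        wilcoxon_p=wilcoxon_signed_rank(table),
        icc=icc,
        icc_ci=(lo, hi),
        mode=mode,
    )
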