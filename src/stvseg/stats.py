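"""Normality-gated paired comparisons and Bland-Altman agreement analysis.

The comparison protocol mirrors standard practice for method-comparison
studies of volume measurements: paired differences are first screened with
a Shapiro-Wilk normality test at alpha = 0.05; normal-looking differences
go to a two-tailed paired t-test, everything else to a Wilcoxon
matched-pairs signed-rank test. Agreement between two methods is summarised
by the Bland-Altman bias (mean difference) and 1.96-SD limits of agreement.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "PairedSample",
    "ComparisonResult",
    "BlandAltmanSummary",
    "normality_test",
    "paired_compare",
    "bland_altman",
    "bland_altman_plot",
    "compare_methods_report",
]

ALPHA = 0.05
LOA_MULTIPLIER = 1.96


@dataclass(frozen=True)
class PairedSample:
    """Matched measurements of one quantity by two methods/raters."""

    a: np.ndarray
    b: np.ndarray
    label: str = ""
    units: str = ""

    def __post_init__(self) -> None:
        a = np.asarray(self.a, dtype=np.float64)
        b = np.asarray(self.b, dtype=np.float64)
        if a.ndim != 1 or a.shape != b.shape:
            raise ValueError("paired samples must be 1D and equal length")
        if len(a) < 3:
            raise ValueError("need at least 3 matched pairs")
        if not (np.isfinite(a).all() and np.isfinite(b).all()):
            raise ValueError("paired samples must be finite")
        object.__setattr__(self, "a", a)
        object.__setattr__(self, "b", b)

    @property
    def differences(self) -> np.ndarray:
        return self.a - self.b


@dataclass(frozen=True)
class ComparisonResult:
    """Outcome of one normality-gated paired comparison."""

    test_used: str  # "paired_t" | "wilcoxon" | "identical"
    statistic: float
    p_value: float
    normality_p: float
    alpha: float = ALPHA
    n: int = 0
    label: str = ""

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError("p_value must lie in [0, 1]")

    @property
    def significant(self) -> bool:
        return self.p_value < self.alpha


@dataclass(frozen=True)
class BlandAltmanSummary:
    """Bias and limits of agreement of paired differences (a - b)."""

    means: np.ndarray  # per-pair (a + b) / 2
    differences: np.ndarray  # per-pair a - b
    bias: float
    sd: float
    loa_lower: float
    loa_upper: float
    label: str = ""
    units: str = ""

    def __post_init__(self) -> None:
        if not self.loa_lower <= self.bias <= self.loa_upper:
            raise ValueError("limits of agreement must bracket the bias")


def normality_test(values: np.ndarray) -> tuple[float, float]:
    """Shapiro-Wilk W and p for a sample of 3 to 5000 values."""
    v = np.asarray(values, dtype=np.float64)
    if v.ndim != 1 or not 3 <= len(v) <= 5000:
        raise ValueError("Shapiro-Wilk requires a 1D sample with 3 <= n <= 5000")
    if np.ptp(v) == 0:
        raise ValueError("normality is undefined for a constant sample")
    res = sps.shapiro(v)
    return float(res.statistic), float(res.pvalue)


def paired_compare(s: PairedSample, alpha: float = ALPHA) -> ComparisonResult:
    """Normality-gated two-tailed paired comparison.

    Shapiro-Wilk is run on the paired differences: p >= alpha selects the
    paired t-test, otherwise the Wilcoxon matched-pairs signed-rank test
    (zero differences dropped; exact null for small tie-free samples, normal
    approximation with continuity correction otherwise). Identical samples
    short-circuit to p = 1 with the ``identical`` flag.
    """
    d = s.differences
    n = len(d)
    if np.all(d == 0):
        return ComparisonResult("identical", 0.0, 1.0, float("nan"),
                                alpha=alpha, n=n, label=s.label)
    if np.ptp(d) == 0:
        # constant nonzero shift: zero-variance t statistic diverges
        return ComparisonResult("paired_t", float("inf"), 0.0, float("nan"),
                                alpha=alpha, n=n, label=s.label)
    _, norm_p = normality_test(d)
    if norm_p >= alpha:
        res = sps.ttest_rel(s.a, s.b)
        return ComparisonResult("paired_t", float(res.statistic),
                                float(res.pvalue), norm_p,
                                alpha=alpha, n=n, label=s.label)
    res = sps.wilcoxon(s.a, s.b, zero_method="wilcox", correction=True,
                       method="auto", alternative="two-sided")
    return ComparisonResult("wilcoxon", float(res.statistic),
                            float(res.pvalue), norm_p,
                            alpha=alpha, n=n, label=s.label)


def bland_altman(s: PairedSample) -> BlandAltmanSummary:
    """Bias, SD of differences (n-1 denominator) and 1.96-SD limits of
    agreement for differences oriented ``a - b``."""
    d = s.differences
    means = (s.a + s.b) / 2.0
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return BlandAltmanSummary(
        means=means, differences=d, bias=bias, sd=sd,
        loa_lower=bias - LOA_MULTIPLIER * sd,
        loa_upper=bias + LOA_MULTIPLIER * sd,
        label=s.label, units=s.units,
    )


def bland_altman_plot(summary: BlandAltmanSummary, path: str) -> None:
    """Render the standard Bland-Altman scatter with bias and LoA lines."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(summary.means, summary.differences, s=18, alpha=0.8)
    ax.axhline(summary.bias, color="k", lw=1.2, label=f"bias {summary.bias:.3g}")
    for y, name in ((summary.loa_upper, "+1.96 SD"), (summary.loa_lower, "-1.96 SD")):
        ax.axhline(y, color="grey", lw=1.0, ls="--", label=f"{name} {y:.3g}")
    unit = f" ({summary.units})" if summary.units else ""
    ax.set_xlabel(f"mean of methods{unit}")
    ax.set_ylabel(f"difference{unit}")
    if summary.label:
        ax.set_title(summary.label)
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def compare_methods_report(
    records_a: list,
    records_b: list,
    method_names: tuple[str, str] = ("method A", "method B"),
    alpha: float = ALPHA,
) -> pd.DataFrame:
    """Per-metric mean +- SD for two methods and the gated paired p-value.

    ``records_a`` and ``records_b`` are matched per-volume
    :class:`~stvseg.metrics.MetricsRecord` lists (same volumes, same order).
    Pairs with a NaN in either method are dropped per metric.
    """
    if len(records_a) != len(records_b):
        raise ValueError("methods must cover the same volumes")
    if len(records_a) < 3:
        raise ValueError("need at least 3 matched volumes to compare methods")
    rows_a = pd.DataFrame([r.to_row() for r in records_a])
    rows_b = pd.DataFrame([r.to_row() for r in records_b])
    out = []
    na, nb = method_names
    for col in rows_a.columns:
        a = rows_a[col].to_numpy()
        b = rows_b[col].to_numpy()
        ok = np.isfinite(a) & np.isfinite(b)
        row = {
            "Metric": col,
            f"{na} mean": float(np.nanmean(a)) if np.isfinite(a).any() else np.nan,
            f"{na} SD": float(np.nanstd(a, ddof=1)) if ok.sum() > 1 else np.nan,
            f"{nb} mean": float(np.nanmean(b)) if np.isfinite(b).any() else np.nan,
            f"{nb} SD": float(np.nanstd(b, ddof=1)) if ok.sum() > 1 else np.nan,
        }
        if ok.sum() >= 3:
            res = paired_compare(PairedSample(a[ok], b[ok], label=col), alpha)
            row["Test"] = res.test_used
            row["P-value"] = res.p_value
        else:
            row["Test"] = "n/a"
            row["P-value"] = np.nan
        out.append(row)
    return pd.DataFrame(out)
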