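"""Group comparison: two-sided Mann-Whitney U, notched-boxplot summaries.

The comparisons mirror common practice for small biological samples:
a two-sided Mann-Whitney U (Wilcoxon rank-sum) test, exact by enumeration
for small tie-free samples and normal-approximated (with tie and
continuity corrections) otherwise, summarised by notched boxplots
(median, quartiles, and the McGill notch 1.57 * IQR / sqrt(n) as an
approximate 95% confidence half-width on the median) and the conventional
significance stars: *, **, ***, ****, ***** for p < 0.05, 0.01, 0.001,
1e-4, 1e-5.
"""

from __future__ import annotations

from dataclasses import dataclass
import numpy as np
from scipy import stats

#: Largest total sample size for which the exact null distribution is used
#: automatically (tie-free data only).
EXACT_MAX_N = 12

_STAR_THRESHOLDS = ((1e-5, "*****"), (1e-4, "****"), (1e-3, "***"), (1e-2, "**"), (5e-2, "*"))


@dataclass(frozen=True)
class NotchSummary:
    median: float
    q1: float
    q3: float
    notch: float
    n: int


@dataclass(frozen=True)
class GroupComparison:
    """Result of a two-group Mann-Whitney comparison."""

    u_statistic: float
    p_value: float
    method: str
    group_x: NotchSummary
    group_y: NotchSummary
    stars: str

    def to_dict(self) -> dict:
        return {
            "U": self.u_statistic,
            "p": self.p_value,
            "method": self.method,
            "stars": self.stars,
            "x": vars(self.group_x),
            "y": vars(self.group_y),
        }


def star_label(p: float) -> str:
    """Significance stars for a p-value; 'ns' when p >= 0.05."""
    if not (0 < p <= 1):
        raise ValueError(f"p-value must lie in (0, 1], got {p}")
    for thr, lab in _STAR_THRESHOLDS:
        if p < thr:
            return lab
    return "ns"


def notch_summary(sample) -> NotchSummary:
    """Median, quartiles (linear interpolation) and notch half-width.

    The notch half-width is 1.57 * IQR / sqrt(n), an approximate 95%
    confidence interval on the median.
    """
    a = np.asarray(sample, dtype=float)
    if a.size < 3:
        raise ValueError(f"need at least 3 samples for a boxplot summary, got {a.size}")
    q1, med, q3 = np.percentile(a, [25, 50, 75])  # linear interpolation
    notch = 1.57 * (q3 - q1) / np.sqrt(a.size)
    return NotchSummary(median=float(med), q1=float(q1), q3=float(q3), notch=float(notch), n=int(a.size))


def mann_whitney(x, y, mode: str = "auto") -> GroupComparison:
    """Two-sided Mann-Whitney U test between two samples.

    mode 'auto' uses the exact null distribution when n1 + n2 <= 12 and the
    data are tie-free, otherwise the normal approximation with tie and
    continuity corrections; 'exact' and 'asymptotic' force either path.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    has_ties = np.unique(np.concatenate([x, y])).size < x.size + y.size
    if mode == "auto":
        method = "exact" if (x.size + y.size <= EXACT_MAX_N and not has_ties) else "asymptotic"
    elif mode in ("exact", "asymptotic"):
        method = mode
    else:
        raise ValueError(f"unknown mode {mode!r}")
    if method == "exact" and has_ties:
        method = "asymptotic"  # exact null is not valid under ties
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method, use_continuity=True)
    p = float(min(res.pvalue, 1.0))
    return GroupComparison(
        u_statistic=float(res.statistic),
        p_value=p,
        method=method,
        group_x=notch_summary(x) if x.size >= 3 else NotchSummary(float(np.median(x)), np.nan, np.nan, np.nan, x.size),
        group_y=notch_summary(y) if y.size >= 3 else NotchSummary(float(np.median(y)), np.nan, np.nan, np.nan, y.size),
        stars=star_label(p),
    )


def compare_conditions(values: dict[str, np.ndarray], control: str) -> list[dict]:
    """All pairwise comparisons of each condition against the control.

    No multiple-testing correction is applied: each condition is tested
    against the control on its own, as is conventional for these assays.
    """
    if control not in values:
        raise ValueError(f"control condition {control!r} missing")
    out = []
    for cond, vals in values.items():
        if cond == control:
            continue
        cmp = mann_whitney(np.asarray(vals), np.asarray(values[control]))
        out.append({"condition": cond, "control": control, **cmp.to_dict()})
    return out


def notched_boxplot(values: dict[str, np.ndarray], path, ylabel: str = "") -> None:
    """Write a notched-boxplot figure of the per-condition values."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(1.2 * len(values) + 1.5, 4))
    labels = list(values)
    ax.boxplot([np.asarray(values[k], float) for k in labels], notch=True, tick_labels=labels)
    ax.set_ylabel(ylabel)
    plt.setp(ax.get_xticklabels(), rotation=30, ha="right")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
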