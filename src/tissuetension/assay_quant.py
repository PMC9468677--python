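"""Wound-healing coverage and transwell invasion index.

Wound coverage at time t is the fraction of the original scratch area that
cells have re-occupied, 1 - A(t)/A(0).  The invasion index of a condition
is the ratio of its mean per-field invading-cell count to that of the
control condition; the control's index is 1 by definition.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class WoundSeries:
    """Wound areas (or masks) over time for one scratch field.

    ``areas`` are in any consistent unit (px^2 or um^2); coverage is a
    ratio and does not depend on the unit.  Build from masks with
    :meth:`from_masks`.
    """

    timepoints_h: np.ndarray
    areas: np.ndarray
    field_id: str = "field0"

    def __post_init__(self) -> None:
        t = np.asarray(self.timepoints_h, dtype=float)
        a = np.asarray(self.areas, dtype=float)
        if t.shape != a.shape:
            raise ValueError("timepoints and areas must have equal length")
        if 0.0 not in t:
            raise ValueError("the t = 0 h reference timepoint is required")
        if np.any(a < 0):
            raise ValueError("wound areas must be non-negative")

    @classmethod
    def from_masks(cls, timepoints_h: Sequence[float], masks: Sequence[np.ndarray], field_id: str = "field0"):
        """Areas from binary wound masks (nonzero = wound), in pixels^2."""
        areas = [float(np.count_nonzero(m)) for m in masks]
        return cls(np.asarray(timepoints_h, float), np.asarray(areas), field_id)


@dataclass(frozen=True)
class InvasionCounts:
    """Per-field invading-cell counts for one condition.

    ``counts`` is a mapping replicate -> list of per-field counts; counts
    are non-negative integers.
    """

    condition: str
    counts: dict[str, list[int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for rep, vals in self.counts.items():
            arr = np.asarray(vals)
            if arr.size == 0:
                raise ValueError(f"replicate {rep!r} has no fields")
            if np.any(arr < 0) or not np.issubdtype(arr.dtype, np.integer):
                raise ValueError(f"replicate {rep!r}: counts must be non-negative integers")

    @property
    def pooled(self) -> np.ndarray:
        """All per-field counts pooled across replicates."""
        return np.concatenate([np.asarray(v) for v in self.counts.values()])

    @property
    def replicate_means(self) -> dict[str, float]:
        return {rep: float(np.mean(v)) for rep, v in self.counts.items()}

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, condition: str) -> "InvasionCounts":
        sub = df[df["condition"] == condition]
        counts = {
            str(rep): g["count"].astype(int).tolist() for rep, g in sub.groupby("replicate")
        }
        return cls(condition=condition, counts=counts)


def wound_coverage(series: WoundSeries) -> pd.DataFrame:
    """Coverage fraction 1 - A(t)/A(0) per timepoint, clipped to [0, 1]."""
    t = np.asarray(series.timepoints_h, float)
    a = np.asarray(series.areas, float)
    order = np.argsort(t)
    t, a = t[order], a[order]
    a0 = a[t == 0.0][0]
    if a0 <= 0:
        raise ValueError("initial wound area A(0) must be positive")
    cov = np.clip(1.0 - a / a0, 0.0, 1.0)
    return pd.DataFrame({"time_h": t, "area": a, "coverage": cov, "field": series.field_id})


def invasion_index(test: InvasionCounts, control: InvasionCounts) -> float:
    """Ratio of mean per-field invading-cell counts, test over control.

    Fields are pooled across replicates; the control condition against
    itself gives exactly 1.
    """
    ctrl = control.pooled
    if ctrl.size == 0 or float(np.mean(ctrl)) <= 0:
        raise ValueError("control condition must have a positive mean count")
    return float(np.mean(test.pooled)) / float(np.mean(ctrl))


def invasion_index_per_replicate(test: InvasionCounts, control: InvasionCounts) -> pd.DataFrame:
    """Per-replicate indices (matched by replicate id) with their SEM.

    Reported alongside the pooled index because biological studies usually
    quote means +/- SEM over independent replicates.
    """
    tm, cm = test.replicate_means, control.replicate_means
    shared = sorted(set(tm) & set(cm))
    if not shared:
        raise ValueError("test and control share no replicate identifiers")
    idx = []
    for rep in shared:
        if cm[rep] <= 0:
            raise ValueError(f"control replicate {rep!r} has zero mean count")
        idx.append(tm[rep] / cm[rep])
    idx = np.asarray(idx)
    sem = float(np.std(idx, ddof=1) / np.sqrt(len(idx))) if len(idx) > 1 else 0.0
    return pd.DataFrame(
        {"replicate": shared, "index": idx, "mean_index": np.mean(idx), "sem": sem}
    )
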