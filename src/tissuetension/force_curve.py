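"""AFM cell-cell detachment force from a retract segment.

A single-cell force spectroscopy record has three segments: approach (ramp
to a set contact force), dwell (height held while the cells adhere) and
retract (constant-velocity pull-off).  Adhesion shows up as a negative
force excursion on retract; the detachment force is the magnitude of its
lowest point after baseline correction.

Baseline model: a straight line fitted to the final fraction of the retract
segment (far from contact at the pull-off speeds used, so guaranteed
off-contact) and subtracted from the whole retract trace.  This removes
both a constant offset and linear drift.  A dip shallower than the noise
floor (3x the corrected-tail standard deviation by default) is reported as
zero detachment force.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

SEGMENTS = ("approach", "dwell", "retract")
MIN_RETRACT_SAMPLES = 20


@dataclass(frozen=True)
class ForceCurve:
    """Time (s), piezo height (um), force (nN) and per-sample segment label."""

    time: np.ndarray
    height: np.ndarray
    force: np.ndarray
    segment: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.time)
        if not (len(self.height) == len(self.force) == len(self.segment) == n):
            raise ValueError("all channels must have equal length")
        labels = pd.unique(np.asarray(self.segment))
        order = [s for s in SEGMENTS if s in labels]
        if list(labels) != order:
            raise ValueError(f"segments must be contiguous and ordered {SEGMENTS}, got {list(labels)}")
        if "retract" not in labels:
            raise ValueError("curve has no retract segment")

    def segment_slice(self, name: str) -> np.ndarray:
        return np.asarray(self.segment) == name

    @property
    def retract_force(self) -> np.ndarray:
        return self.force[self.segment_slice("retract")]

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "ForceCurve":
        return cls(
            time=df["time_s"].to_numpy(float),
            height=df["height_um"].to_numpy(float),
            force=df["force_nn"].to_numpy(float),
            segment=df["segment"].to_numpy(),
        )

    @classmethod
    def from_csv(cls, path) -> "ForceCurve":
        return cls.from_dataframe(pd.read_csv(path, sep=None, engine="python"))

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time_s": self.time, "height_um": self.height, "force_nn": self.force, "segment": self.segment}
        )


def baseline_correct(curve: ForceCurve, window_fraction: float = 0.2) -> ForceCurve:
    """Subtract a line fitted to the retract tail from the retract force.

    ``window_fraction`` is the trailing fraction of the retract segment used
    for the fit; it must give at least two samples.  The corrected tail has
    zero mean (to within noise) and zero slope by construction.
    """
    if not 0 < window_fraction <= 1:
        raise ValueError("window_fraction must lie in (0, 1]")
    ret = curve.segment_slice("retract")
    n_ret = int(ret.sum())
    if n_ret < MIN_RETRACT_SAMPLES:
        raise ValueError(f"retract segment has {n_ret} samples; need >= {MIN_RETRACT_SAMPLES}")
    t_ret = curve.time[ret]
    f_ret = curve.force[ret]
    n_win = max(2, int(round(window_fraction * n_ret)))
    coef = np.polyfit(t_ret[-n_win:], f_ret[-n_win:], 1)
    corrected = curve.force.copy()
    corrected[ret] = f_ret - np.polyval(coef, t_ret)
    return replace(curve, force=corrected)


def detachment_force(
    curve: ForceCurve,
    window_fraction: float = 0.2,
    noise_floor_sigmas: float = 3.0,
    corrected: bool = False,
) -> float:
    """Detachment force (nN, positive magnitude) of a force curve.

    The lowest point of the baseline-corrected retract trace, reported as a
    positive magnitude; 0.0 when the minimum does not dip below
    ``noise_floor_sigmas`` times the corrected-tail standard deviation (no
    detectable adhesion).  Set ``corrected=True`` if the curve has already
    been baseline-corrected.
    """
    if not corrected:
        curve = baseline_correct(curve, window_fraction)
    f_ret = curve.retract_force
    n_win = max(2, int(round(window_fraction * len(f_ret))))
    noise_sd = float(np.std(f_ret[-n_win:]))
    fmin = float(f_ret.min())
    if fmin >= -noise_floor_sigmas * noise_sd:
        return 0.0
    return -fmin


def analyze_curve(curve: ForceCurve, window_fraction: float = 0.2) -> dict:
    """Per-curve summary: detachment force and baseline diagnostics."""
    corr = baseline_correct(curve, window_fraction)
    f_ret = corr.retract_force
    n_win = max(2, int(round(window_fraction * len(f_ret))))
    return {
        "detachment_force_nn": detachment_force(corr, window_fraction, corrected=True),
        "tail_mean_nn": float(np.mean(f_ret[-n_win:])),
        "tail_sd_nn": float(np.std(f_ret[-n_win:])),
        "n_retract": int(len(f_ret)),
    }


def batch_summary(curves: dict[str, list[ForceCurve]]) -> pd.DataFrame:
    """Per-condition mean +/- sd of detachment forces over a batch of curves."""
    rows = []
    for condition, clist in curves.items():
        forces = [detachment_force(c) for c in clist]
        rows.append(
            {
                "condition": condition,
                "n": len(forces),
                "mean_nn": float(np.mean(forces)),
                "sd_nn": float(np.std(forces, ddof=1)) if len(forces) > 1 else 0.0,
            }
        )
    return pd.DataFrame(rows)
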