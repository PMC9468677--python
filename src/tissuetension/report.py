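"""Aggregate a synthetic (or real) study into summary tables and comparisons."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .assay_quant import invasion_index, wound_coverage
from .force_curve import detachment_force
from .stats_report import compare_conditions, notch_summary
from .synthetic_data import StudyDataset


def detachment_by_condition(dataset: StudyDataset) -> dict[str, np.ndarray]:
    return {cond: np.asarray([detachment_force(c) for c in curves]) for cond, curves in dataset.afm.items()}


def coverage_at(dataset: StudyDataset, time_h: float) -> dict[str, np.ndarray]:
    """Per-condition wound coverage fractions of every field at one timepoint."""
    out = {}
    for cond, series_list in dataset.wound.items():
        vals = []
        for s in series_list:
            df = wound_coverage(s)
            row = df[df["time_h"] == time_h]
            if len(row):
                vals.append(float(row["coverage"].iloc[0]))
        out[cond] = np.asarray(vals)
    return out


def invasion_indices(dataset: StudyDataset) -> dict[str, float]:
    control = dataset.invasion[dataset.config.control]
    return {cond: invasion_index(counts, control) for cond, counts in dataset.invasion.items()}


def summarize_study(dataset: StudyDataset) -> dict:
    """Summary tables + Mann-Whitney comparisons against the control.

    Mirrors the figures of a tensiometry/EMT study: per-condition surface
    tension, detachment force, wound coverage at 24 h and invasion index,
    each with star-annotated comparisons to the control condition.
    """
    control = dataset.config.control
    gamma = dataset.gamma_fitted()
    detach = detachment_by_condition(dataset)
    cov24 = coverage_at(dataset, 24.0)
    inv = invasion_indices(dataset)

    def table(values: dict[str, np.ndarray]) -> list[dict]:
        rows = []
        for cond, vals in values.items():
            v = np.asarray(vals, float)
            entry = {"condition": cond, "n": int(v.size), "mean": float(np.mean(v)), "sd": float(np.std(v, ddof=1)) if v.size > 1 else 0.0}
            if v.size >= 3:
                ns = notch_summary(v)
                entry.update(median=ns.median, q1=ns.q1, q3=ns.q3, notch=ns.notch)
            rows.append(entry)
        return rows

    return {
        "control": control,
        "surface_tension_mn_per_m": {
            "summary": table(gamma),
            "comparisons": compare_conditions(gamma, control),
        },
        "detachment_force_nn": {
            "summary": table(detach),
            "comparisons": compare_conditions(detach, control),
        },
        "wound_coverage_24h": {
            "summary": table(cov24),
            "comparisons": compare_conditions(cov24, control),
        },
        "invasion_index": inv,
    }


def summary_frame(summary: dict, block: str) -> pd.DataFrame:
    return pd.DataFrame(summary[block]["summary"]).set_index("condition")
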